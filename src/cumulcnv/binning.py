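"""Genomic binning: reduce probe-level log2 ratios to bin-level medians.

The genome is tiled chromosome by chromosome into fixed-size windows
(default 50 kb) which are merged left to right until each emitted bin holds
at least ``min_probes`` probes (default 15); a trailing remainder below the
floor is merged back into the previously emitted bin.  Each bin's value per
sample is the median log2 ratio of its member probes; the population
variance of those probes is kept as the weight basis for weighted CBS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ProbeTable
from .normalize import LogRatioMatrix

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 50_000
DEFAULT_MIN_PROBES = 15


@dataclass
class BinMap:
    """Sorted, non-overlapping genomic bins with their member probes.

    ``table``: bin_id, chrom, start, end (1-based inclusive), n_probes.
    ``probe_ids``: list (per bin) of member probe ids; may be empty lists for
    synthetic bin maps that were never derived from probes.
    """

    table: pd.DataFrame
    probe_ids: list[list[str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Global row indices of one chromosome's bins, in order."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def write_bed(self, path) -> None:
        bed = pd.DataFrame({
            "chrom": self.table["chrom"],
            "start": self.table["start"] - 1,  # 1-based inclusive -> BED
            "end": self.table["end"],
            "bin_id": self.table["bin_id"],
            "n_probes": self.table["n_probes"],
        })
        bed.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class BinMatrix:
    """Bins x samples log2-ratio matrix with per-bin per-sample probe variance."""

    values: np.ndarray
    bin_map: BinMap
    samples: list[str]
    probe_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bin_map), len(self.samples)):
            raise ValueError("bin matrix shape inconsistent with bin map / samples")
        if not np.isfinite(self.values).all():
            raise ValueError("bin matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.bin_map.chrom_slice(chrom)]


def build_bin_map(probes: ProbeTable, bin_size: int = DEFAULT_BIN_SIZE,
                  min_probes: int = DEFAULT_MIN_PROBES) -> BinMap:
    """Tile each chromosome and merge windows until every bin has enough probes.

    Windows are scanned left to right; consecutive windows accumulate until
    the probe count reaches ``min_probes``, at which point a bin is emitted.
    A trailing accumulation below the floor is merged into the last emitted
    bin (or forms the only bin when the whole chromosome is short of probes).
    """
    if bin_size <= 0 or min_probes < 1:
        raise ValueError("bin_size must be positive and min_probes >= 1")
    rows: list[dict] = []
    members: list[list[str]] = []
    t = probes.table
    for chrom in probes.layout:
        sub = t[t["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        max_pos = int(pos.max())
        n_windows = (max_pos + bin_size - 1) // bin_size
        # probe counts per window via searchsorted on window edges
        edges = np.arange(0, (n_windows + 1) * bin_size, bin_size)
        idx = np.searchsorted(pos, edges[1:], side="right")
        idx = np.concatenate([[0], idx])
        acc_start = 1
        acc_probes: list[str] = []
        for w in range(n_windows):
            acc_probes.extend(ids[idx[w]:idx[w + 1]])
            w_end = (w + 1) * bin_size
            if len(acc_probes) >= min_probes:
                rows.append({"chrom": chrom, "start": acc_start, "end": w_end,
                             "n_probes": len(acc_probes)})
                members.append(acc_probes)
                acc_start = w_end + 1
                acc_probes = []
        if acc_start <= n_windows * bin_size:  # trailing accumulation
            if rows and rows[-1]["chrom"] == chrom:
                rows[-1]["end"] = n_windows * bin_size
                rows[-1]["n_probes"] += len(acc_probes)
                members[-1] = members[-1] + acc_probes
            else:
                logger.warning("chromosome %s holds only %d probes (< %d); "
                               "emitting a single under-filled bin",
                               chrom, len(acc_probes), min_probes)
                rows.append({"chrom": chrom, "start": acc_start,
                             "end": n_windows * bin_size,
                             "n_probes": len(acc_probes)})
                members.append(acc_probes)
    if not rows:
        logger.warning("no probes on any chromosome of the layout; empty bin map")
        table = pd.DataFrame(columns=["bin_id", "chrom", "start", "end", "n_probes"])
        return BinMap(table, [])
    table = pd.DataFrame(rows)
    table.insert(0, "bin_id", np.arange(len(table)))
    return BinMap(table, members)


def aggregate_probes(log_ratios: LogRatioMatrix, bin_map: BinMap) -> BinMatrix:
    """Median per bin per sample, plus the per-bin probe variance used as weights."""
    index = {pid: i for i, pid in enumerate(log_ratios.probe_ids)}
    n_bins, n_samples = len(bin_map), len(log_ratios.samples)
    values = np.zeros((n_bins, n_samples))
    variance = np.zeros((n_bins, n_samples))
    for b, pids in enumerate(bin_map.probe_ids):
        rows = [index[p] for p in pids if p in index]
        if not rows:
            raise ValueError(f"bin {b} has no member probes in the log-ratio matrix")
        block = log_ratios.values[rows]
        values[b] = np.median(block, axis=0)
        variance[b] = block.var(axis=0)  # population variance
    return BinMatrix(values, bin_map, list(log_ratios.samples), variance)


def write_bin_matrix(bm: BinMatrix, path) -> None:
    """Serialize a BinMatrix to the toolkit's TSV interchange format."""
    df = bm.bin_map.table[["bin_id", "chrom", "start", "end", "n_probes"]].copy()
    for j, s in enumerate(bm.samples):
        df[s] = bm.values[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_bin_matrix(path) -> BinMatrix:
    """Read the TSV interchange format written by :func:`write_bin_matrix`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = ["bin_id", "chrom", "start", "end", "n_probes"]
    missing = set(meta) - set(df.columns)
    if missing:
        raise ValueError(f"bin matrix TSV missing columns: {sorted(missing)}")
    samples = [c for c in df.columns if c not in meta]
    bin_map = BinMap(df[meta].reset_index(drop=True),
                     [[] for _ in range(len(df))])
    return BinMatrix(df[samples].to_numpy(float), bin_map, samples)
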