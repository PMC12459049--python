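"""Genomic coordinate system: probe annotation, chromosome-arm tables, manifests.

Everything downstream (binning, segmentation, plots) is anchored to a
:class:`ProbeTable` — probe id, chromosome, 1-based position, optional gene
symbol — sorted along a fixed chromosome layout.  Arm definitions come in as
BED4 and are converted to the internal 1-based inclusive convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical human autosome + sex-chromosome ordering used for the genome axis.
DEFAULT_LAYOUT: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

ARRAY_TYPES = ("450k", "EPIC", "EPICv2", "mouse", "matrix")


class FormatError(ValueError):
    """A required column or field is missing from an input file."""


class ValidationError(ValueError):
    """Input parsed but violates an invariant (duplicates, overlaps, ...)."""


def canonical_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix: ``chr1`` -> ``1``, ``chrX`` -> ``X``."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass
class ProbeTable:
    """Probe annotation sorted by (chromosome, position).

    ``table`` has columns ``probe_id``, ``chrom``, ``pos`` and optionally
    ``gene``; positions are 1-based bp.  ``layout`` fixes chromosome order.
    """

    table: pd.DataFrame
    layout: tuple[str, ...] = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Series:
        return self.table["probe_id"]

    def chrom_order(self, chrom: str) -> int:
        return self.layout.index(chrom)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _validate_probe_frame(df: pd.DataFrame, layout: tuple[str, ...]) -> pd.DataFrame:
    required = {"probe_id", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"probe table missing columns: {sorted(missing)}")
    df = df.copy()
    df["chrom"] = df["chrom"].map(canonical_chrom)
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate probe_id: {dup.iloc[0]!r}")
    n_before = len(df)
    df = df[df["chrom"].isin(layout)]
    dropped = n_before - len(df)
    if dropped:
        logger.warning("dropped %d probes outside the genome layout", dropped)
    if (df["pos"] < 1).any():
        raise ValidationError("probe positions must be >= 1")
    order = {c: i for i, c in enumerate(layout)}
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    keep = ["probe_id", "chrom", "pos"] + (["gene"] if "gene" in df.columns else [])
    return df[keep].reset_index(drop=True)


def load_probe_table(path, layout: tuple[str, ...] = DEFAULT_LAYOUT) -> ProbeTable:
    """Load a TSV probe annotation (probe_id, chrom, pos[, gene]).

    Probes on chromosomes outside ``layout`` are dropped with a logged count;
    the result is sorted by (chrom, pos) in layout order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    return probe_table_from_frame(df, layout)


def probe_table_from_frame(df: pd.DataFrame, layout: tuple[str, ...] = DEFAULT_LAYOUT) -> ProbeTable:
    return ProbeTable(_validate_probe_frame(df, layout), layout)


@dataclass
class ArmTable:
    """Chromosome-arm spans, 1-based inclusive; p precedes q within a chromosome."""

    table: pd.DataFrame  # columns chrom, arm, start, end

    def __post_init__(self) -> None:
        t = self.table
        for chrom, grp in t.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"] >= g["end"] + 1).any():
                raise ValidationError(f"arm with start >= end on chromosome {chrom}")
            ends = g["end"].to_numpy()
            starts = g["start"].to_numpy()
            if (starts[1:] <= ends[:-1]).any():
                raise ValidationError(f"overlapping arms on chromosome {chrom}")
        self.table = t.reset_index(drop=True)

    def arm_of(self, chrom: str, pos: int) -> str | None:
        t = self.table
        hit = t[(t["chrom"] == chrom) & (t["start"] <= pos) & (t["end"] >= pos)]
        if hit.empty:
            return None
        return str(hit["arm"].iloc[0])

    @property
    def labels(self) -> pd.Series:
        return self.table["chrom"] + self.table["arm"]


def load_arm_table(path) -> ArmTable:
    """Load arm definitions from BED4 (0-based half-open; 4th column like ``1p``)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name"],
                     dtype={"chrom": str, "name": str})
    if df["name"].isna().any():
        raise FormatError("arm BED requires a 4th column with arm labels like '1p'")
    arm = df["name"].str[-1]
    if not arm.isin(["p", "q"]).all():
        raise ValidationError("arm labels must end in 'p' or 'q'")
    out = pd.DataFrame({
        "chrom": df["chrom"].map(canonical_chrom),
        "arm": arm,
        "start": df["start"].astype(int) + 1,  # BED -> 1-based inclusive
        "end": df["end"].astype(int),
    })
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    return ArmTable(out)


def arm_table_from_frame(df: pd.DataFrame) -> ArmTable:
    """Build an ArmTable from an already 1-based-inclusive frame (chrom, arm, start, end)."""
    return ArmTable(df[["chrom", "arm", "start", "end"]].reset_index(drop=True))


def harmonize_probe_sets(tables: list[ProbeTable]) -> ProbeTable:
    """Intersect probe sets across arrays; coordinates come from the first table.

    Stands in for cross-array projection onto the lowest array type: only
    probes shared by every input are kept (no imputation or liftover).
    """
    if not tables:
        raise ValueError("need at least one probe table")
    common = set(tables[0].probe_ids)
    for t in tables[1:]:
        common &= set(t.probe_ids)
    if not common:
        raise ValidationError(
            "probe sets have an empty intersection; analyse the arrays separately")
    first = tables[0].table
    kept = first[first["probe_id"].isin(common)].reset_index(drop=True)
    logger.info("harmonized %d tables to %d shared probes", len(tables), len(kept))
    return ProbeTable(kept, tables[0].layout)


@dataclass
class SampleManifest:
    """Cohort description: one row per sample (sample_id, path, array_type)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"sample_id", "path", "array_type"}
        missing = req - set(self.table.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in manifest")
        bad = set(self.table["array_type"]) - set(ARRAY_TYPES)
        if bad:
            raise ValidationError(f"unrecognized array_type: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)


def load_manifest(path) -> SampleManifest:
    return SampleManifest(pd.read_csv(path, sep="\t", dtype=str))
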