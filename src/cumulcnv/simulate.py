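"""Synthetic cohorts with known ground truth.

Bin-level cohorts are i.i.d. Gaussian noise (default sd 0.1, a typical
bin-level log2-ratio dispersion for good-quality arrays) plus injected broad
(arm/span) and focal events of known strength and affected fraction.
Probe-level cohorts draw lognormal intensities with a shared per-probe
baseline so that the normalization + binning chain recovers the bin-level
ground truth.  Every generator is seeded and returns the ground-truth event
table alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import BinMap, BinMatrix, DEFAULT_BIN_SIZE
from .genome import ArmTable, ProbeTable, arm_table_from_frame, probe_table_from_frame

DEFAULT_NOISE_SD = 0.1


@dataclass
class EventSpec:
    """One injected aberration: bins [start_bin, end_bin] on ``chrom`` (local,
    0-based inclusive), added ``strength`` (log2 units) in a ``fraction`` of
    samples."""

    chrom: str
    start_bin: int
    end_bin: int
    strength: float
    fraction: float = 1.0


@dataclass
class CohortSpec:
    """Conditions of a synthetic bin-level cohort."""

    n_samples: int = 60
    chrom_bins: dict[str, int] = field(
        default_factory=lambda: {"1": 500, "2": 500, "3": 500, "4": 500})
    noise_sd: float = DEFAULT_NOISE_SD
    sample_noise_mult: np.ndarray | None = None
    events: list[EventSpec] = field(default_factory=list)
    bin_size: int = DEFAULT_BIN_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        for ev in self.events:
            if ev.chrom not in self.chrom_bins:
                raise ValueError(f"event on unknown chromosome {ev.chrom}")
            if not 0 <= ev.start_bin <= ev.end_bin < self.chrom_bins[ev.chrom]:
                raise ValueError("event span outside its chromosome")


def make_bin_map(chrom_bins: dict[str, int], bin_size: int = DEFAULT_BIN_SIZE,
                 n_probes: int = 15) -> BinMap:
    """Synthetic contiguous bin map: equal-width bins, fixed probe count."""
    rows = []
    for chrom, n in chrom_bins.items():
        for k in range(n):
            rows.append({"chrom": chrom, "start": k * bin_size + 1,
                         "end": (k + 1) * bin_size, "n_probes": n_probes})
    table = pd.DataFrame(rows)
    table.insert(0, "bin_id", np.arange(len(table)))
    return BinMap(table, [[] for _ in range(len(table))])


def make_arm_table(chrom_bins: dict[str, int],
                   bin_size: int = DEFAULT_BIN_SIZE) -> ArmTable:
    """Synthetic arm table: p = first half of each chromosome, q = the rest."""
    rows = []
    for chrom, n in chrom_bins.items():
        half = (n // 2) * bin_size
        rows.append({"chrom": chrom, "arm": "p", "start": 1, "end": half})
        rows.append({"chrom": chrom, "arm": "q", "start": half + 1,
                     "end": n * bin_size})
    return arm_table_from_frame(pd.DataFrame(rows))


def synth_bin_cohort(spec: CohortSpec) -> tuple[BinMatrix, pd.DataFrame]:
    """Gaussian bin-level cohort plus its ground-truth event table.

    Ground truth columns: chrom, start_bin, end_bin (global bin indices),
    strength, fraction, affected (comma-joined sample ids).
    """
    rng = np.random.default_rng(spec.seed)
    bin_map = make_bin_map(spec.chrom_bins, spec.bin_size)
    n_bins = len(bin_map)
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    sd = np.full(spec.n_samples, spec.noise_sd)
    if spec.sample_noise_mult is not None:
        sd = sd * np.asarray(spec.sample_noise_mult, float)
    values = rng.normal(0.0, 1.0, size=(n_bins, spec.n_samples)) * sd[None, :]
    chrom_offset = {c: int(bin_map.chrom_slice(c)[0]) for c in bin_map.chroms}
    truth_rows = []
    for ev in spec.events:
        off = chrom_offset[ev.chrom]
        n_aff = int(round(ev.fraction * spec.n_samples))
        affected = rng.choice(spec.n_samples, size=n_aff, replace=False)
        values[off + ev.start_bin: off + ev.end_bin + 1, affected] += ev.strength
        truth_rows.append({
            "chrom": ev.chrom, "start_bin": off + ev.start_bin,
            "end_bin": off + ev.end_bin, "strength": ev.strength,
            "fraction": ev.fraction,
            "affected": ",".join(samples[a] for a in sorted(affected)),
        })
    truth = pd.DataFrame(truth_rows, columns=[
        "chrom", "start_bin", "end_bin", "strength", "fraction", "affected"])
    variance = np.tile(sd**2, (n_bins, 1))
    return BinMatrix(values, bin_map, samples, variance), truth


def synth_probe_cohort(spec: CohortSpec, probes_per_bin: int = 15,
                       n_controls: int = 8, probe_sd: float = 0.25,
                       baseline_sigma: float = 0.5
                       ) -> tuple[dict, ProbeTable, pd.DataFrame]:
    """Probe-level intensities whose preprocessing recovers the bin truth.

    Each probe has a lognormal baseline intensity shared by query and
    control samples; query samples multiply it by 2**signal where signal is
    the event strength on the probe's bin (0 elsewhere) plus per-probe
    lognormal measurement noise.  Returns a dict with ``query`` and
    ``controls`` IntensityMatrix objects, the probe table, and the
    ground-truth event table (global bin indices into the matching bin map).
    """
    from .normalize import IntensityMatrix

    rng = np.random.default_rng(spec.seed + 1)
    probe_rows = []
    signal_bins = []
    bin_index = 0
    for chrom, n in spec.chrom_bins.items():
        for k in range(n):
            start = k * spec.bin_size
            pos = np.sort(rng.integers(start + 1, start + spec.bin_size + 1,
                                       size=probes_per_bin))
            for p, bp in enumerate(pos):
                probe_rows.append({"probe_id": f"cg_{chrom}_{k}_{p}",
                                   "chrom": chrom, "pos": int(bp)})
                signal_bins.append(bin_index)
            bin_index += 1
    probe_df = pd.DataFrame(probe_rows)
    probes = probe_table_from_frame(probe_df)
    # probe_table_from_frame sorts by (chrom, pos); rebuild bin assignment in
    # sorted order (positions were generated sorted per bin so order is stable)
    signal_bins = np.asarray(signal_bins)

    n_probes = len(probe_df)
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    baseline = rng.lognormal(mean=np.log(5000), sigma=baseline_sigma, size=n_probes)

    signal = np.zeros((n_probes, spec.n_samples))
    bin_map = make_bin_map(spec.chrom_bins, spec.bin_size)
    chrom_offset = {c: int(bin_map.chrom_slice(c)[0]) for c in bin_map.chroms}
    truth_rows = []
    for ev in spec.events:
        off = chrom_offset[ev.chrom]
        n_aff = int(round(ev.fraction * spec.n_samples))
        affected = rng.choice(spec.n_samples, size=n_aff, replace=False)
        in_span = (signal_bins >= off + ev.start_bin) & (signal_bins <= off + ev.end_bin)
        for a in affected:
            signal[in_span, a] += ev.strength
        truth_rows.append({
            "chrom": ev.chrom, "start_bin": off + ev.start_bin,
            "end_bin": off + ev.end_bin, "strength": ev.strength,
            "fraction": ev.fraction,
            "affected": ",".join(samples[a] for a in sorted(affected)),
        })
    noise_q = rng.lognormal(mean=0.0, sigma=probe_sd,
                            size=(n_probes, spec.n_samples))
    query = IntensityMatrix(baseline[:, None] * 2.0**signal * noise_q,
                            probe_df["probe_id"].to_numpy(), samples)
    noise_c = rng.lognormal(mean=0.0, sigma=probe_sd,
                            size=(n_probes, n_controls))
    controls = IntensityMatrix(baseline[:, None] * noise_c,
                               probe_df["probe_id"].to_numpy(),
                               [f"C{i:02d}" for i in range(n_controls)])
    truth = pd.DataFrame(truth_rows, columns=[
        "chrom", "start_bin", "end_bin", "strength", "fraction", "affected"])
    return {"query": query, "controls": controls}, probes, truth
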