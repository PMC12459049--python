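"""Monte Carlo focal-aberration benchmark and CS-vs-SW concordance.

Each iteration plants one focal aberration into a fresh noise cohort: an
anchor region (a gene's bins when gene annotation is available, otherwise a
random bin) is padded by 3 bins on each side and widened to at least 7 bins,
a frequency is drawn from {0.2, 0.4, 0.6, 0.8, 1.0} and a strength from
{+0.5, +1, +1.5, +2}, and the strength is added to the padded span in the
drawn fraction of samples.  The aberration counts as found when the
segmentation returns a segment with exactly the injected boundaries
(tolerance configurable), even if the called frequency falls short of the
expected one.  Called regions disjoint from the injected span (after the
2-bin filter) are audited as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binning import BinMatrix
from .calling import AberrationMatrix, CallingConfig, arm_weighted_mean, call_aberrations
from .cbs import SampleSegmentation
from .genome import ArmTable
from .pcf import PCFConfig, SharedSegmentation, segment_genome_cs
from .simulate import CohortSpec, synth_bin_cohort

FREQUENCY_SET = (0.2, 0.4, 0.6, 0.8, 1.0)
STRENGTH_SET = (0.5, 1.0, 1.5, 2.0)
DEFAULT_PAD_BINS = 3
DEFAULT_MIN_BINS = 7


@dataclass
class FocalSimSpec:
    """One planted focal aberration (global bin indices, inclusive)."""

    chrom: str
    start_bin: int
    end_bin: int
    frequency: float
    strength: float
    affected: np.ndarray  # sample column indices
    pad_bins: int = DEFAULT_PAD_BINS
    min_bins: int = DEFAULT_MIN_BINS

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class SimResult:
    spec: FocalSimSpec
    found: bool
    observed_frequency: float
    false_positives: list[tuple[str, float]]
    gamma: float


def _pad_span(start: int, end: int, lo: int, hi: int,
              pad: int, min_bins: int) -> tuple[int, int]:
    """Pad [start, end] by ``pad`` bins each side, widen to ``min_bins``,
    and shift inward so the span stays within [lo, hi]."""
    a, b = start - pad, end + pad
    while b - a + 1 < min_bins:
        if b < hi:
            b += 1
        elif a > lo:
            a -= 1
        else:
            raise ValueError("chromosome shorter than the minimum span")
    if a < lo:
        b = min(hi, b + (lo - a))
        a = lo
    if b > hi:
        a = max(lo, a - (b - hi))
        b = hi
    if b - a + 1 < min_bins:
        raise ValueError("chromosome shorter than the padded span")
    return a, b


def draw_spec(rng: np.random.Generator, bin_matrix: BinMatrix,
              gene_bins: dict[str, tuple[str, int, int]] | None = None,
              pad_bins: int = DEFAULT_PAD_BINS,
              min_bins: int = DEFAULT_MIN_BINS) -> FocalSimSpec:
    """Draw a random focal-aberration specification.

    ``gene_bins`` maps gene symbol to (chrom, first_bin, last_bin) in global
    bin indices; when absent a single random bin anchors the aberration.
    Affected samples are a uniform subset of size round(frequency * S).
    """
    bm = bin_matrix.bin_map
    if gene_bins:
        gene = list(gene_bins)[int(rng.integers(len(gene_bins)))]
        chrom, g_start, g_end = gene_bins[gene]
    else:
        anchor = int(rng.integers(len(bm)))
        chrom = str(bm.table["chrom"].iloc[anchor])
        g_start = g_end = anchor
    idx = bm.chrom_slice(chrom)
    lo, hi = int(idx[0]), int(idx[-1])
    start, end = _pad_span(g_start, g_end, lo, hi, pad_bins, min_bins)
    frequency = float(rng.choice(FREQUENCY_SET))
    strength = float(rng.choice(STRENGTH_SET))
    n_samples = bin_matrix.n_samples
    n_aff = int(round(frequency * n_samples))
    affected = np.sort(rng.choice(n_samples, size=n_aff, replace=False))
    return FocalSimSpec(chrom, start, end, frequency, strength, affected,
                        pad_bins, min_bins)


def inject_aberration(bin_matrix: BinMatrix, spec: FocalSimSpec) -> BinMatrix:
    """Return a copy of the matrix with the aberration added to affected samples."""
    idx = bin_matrix.bin_map.chrom_slice(spec.chrom)
    if spec.start_bin < idx[0] or spec.end_bin > idx[-1]:
        raise ValueError("aberration span exceeds its chromosome")
    values = bin_matrix.values.copy()
    values[spec.start_bin:spec.end_bin + 1, spec.affected] += spec.strength
    return BinMatrix(values, bin_matrix.bin_map, list(bin_matrix.samples),
                     bin_matrix.probe_variance)


def score_detection(segmentation: SharedSegmentation, calls: AberrationMatrix,
                    spec: FocalSimSpec, gamma: float,
                    theta: float = 0.2, boundary_tol: int = 0) -> SimResult:
    """Score one iteration: exact-span recovery, observed frequency, FPs.

    found: a segment whose boundaries match the injected span within
    ``boundary_tol`` bins exists (regardless of observed frequency).
    observed frequency: fraction of samples whose mean on that segment
    exceeds the calling threshold in the direction of the injected strength.
    false positives: called regions (already min-bin filtered) disjoint from
    the injected span with at least one non-zero call, reported with their
    exceedance frequency.
    """
    seg = segmentation.segments
    match = seg[(seg["chrom"] == spec.chrom)
                & (abs(seg["start_bin"] - spec.start_bin) <= boundary_tol)
                & (abs(seg["end_bin"] - spec.end_bin) <= boundary_tol)]
    found = len(match) > 0
    observed = 0.0
    if found:
        row = match.index[0]
        means = segmentation.means[seg.index.get_loc(row)]
        if spec.strength >= 0:
            observed = float((means > theta).mean())
        else:
            observed = float((means < -theta).mean())
    fps: list[tuple[str, float]] = []
    reg = calls.regions
    freq = calls.gain_freq + calls.loss_freq
    for r in range(len(reg)):
        if freq[r] == 0:
            continue
        same_chrom = reg["chrom"].iloc[r] == spec.chrom
        overlaps = same_chrom and not (reg["end_bin"].iloc[r] < spec.start_bin
                                       or reg["start_bin"].iloc[r] > spec.end_bin)
        if not overlaps:
            fps.append((str(reg["label"].iloc[r]), float(freq[r])))
    return SimResult(spec, found, observed, fps, gamma)


def run_monte_carlo(n_iter: int, gammas: list[float],
                    cohort_spec: CohortSpec | None = None,
                    pcf_config: PCFConfig | None = None,
                    calling_config: CallingConfig | None = None,
                    boundary_tol: int = 0,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded Monte Carlo benchmark of the combined segmentation.

    Per iteration one noise cohort is generated and one focal aberration
    planted; every gamma in ``gammas`` segments the same injected matrix.
    Returns (summary, records): summary has one row per gamma x strength x
    frequency stratum plus detection counts; records holds one row per
    iteration x gamma with found/observed/false-positive fields.
    """
    cohort_spec = cohort_spec or CohortSpec()
    base_pcf = pcf_config or PCFConfig()
    calling_config = calling_config or CallingConfig()
    root = np.random.SeedSequence(seed)
    records = []
    for it, child in enumerate(root.spawn(n_iter)):
        it_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cohort, _ = synth_bin_cohort(replace(cohort_spec, seed=it_seed, events=[]))
        rng = np.random.default_rng(child.spawn(1)[0])
        spec = draw_spec(rng, cohort)
        injected = inject_aberration(cohort, spec)
        for gamma in gammas:
            cfg = replace(base_pcf, gamma=gamma)
            seg = segment_genome_cs(injected, cfg)
            calls = call_aberrations(seg, injected, calling_config)
            res = score_detection(seg, calls, spec, gamma,
                                  calling_config.theta, boundary_tol)
            records.append({
                "iteration": it, "gamma": gamma, "chrom": spec.chrom,
                "start_bin": spec.start_bin, "end_bin": spec.end_bin,
                "n_bins": spec.n_bins, "strength": spec.strength,
                "frequency": spec.frequency, "found": res.found,
                "observed_frequency": res.observed_frequency,
                "false_positive_count": len(res.false_positives),
            })
    rec = pd.DataFrame(records)
    summary = (rec.groupby(["gamma", "strength", "frequency"])
               .agg(n=("found", "size"), detected=("found", "sum"),
                    detection_rate=("found", "mean"),
                    false_positive_count=("false_positive_count", "sum"))
               .reset_index())
    return summary, rec


def mode_concordance(cs: SharedSegmentation, sw: list[SampleSegmentation],
                     arms: ArmTable, bin_matrix: BinMatrix) -> pd.Series:
    """Per-sample Pearson correlation of CS vs SW arm-level weighted means.

    Arms without bins are skipped; a sample with zero variance in either
    mode's arm vector gets NaN.
    """
    cs_arm = arm_weighted_mean(cs, arms, bin_matrix)
    sw_arm = arm_weighted_mean(sw, arms, bin_matrix)
    out = {}
    for sample in cs_arm.columns:
        x = cs_arm[sample].to_numpy(float)
        y = sw_arm[sample].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 2 or x.std() == 0 or y.std() == 0:
            out[sample] = np.nan
        else:
            out[sample] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")
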