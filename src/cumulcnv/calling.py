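"""Aberration calling: thresholded gain/loss matrices, arm condensation, ordering.

A segment is called a gain (+1) or loss (-1) in a sample when its mean log2
ratio strictly exceeds +theta / falls below -theta (default theta = 0.2).
For CBS-derived segments the threshold is additionally multiplied by a
per-segment noise factor (theta_CBS = theta * noise_seg, never below theta)
to damp false positives in noisy samples.  Segments narrower than
``min_bins`` (default 2) are removed from the matrix entirely.

Arm-level condensation computes the segment-length-weighted mean per
chromosome arm and thresholds it the same way; sample ordering clusters the
call columns by Hamming distance (average linkage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .binning import BinMatrix
from .cbs import SampleSegmentation
from .genome import ArmTable
from .pcf import SharedSegmentation

logger = logging.getLogger(__name__)


@dataclass
class CallingConfig:
    theta: float = 0.2
    min_bins: int = 2
    noise_adjust: bool = False
    arm_level: bool = False
    strict: bool = True

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")


@dataclass
class AberrationMatrix:
    """Regions x samples gain/loss calls with per-region frequencies.

    ``regions``: chrom, start_bin, end_bin, n_bins, label.  ``calls``:
    entries in {-1, 0, +1}.  Frequencies are the column fractions of +1
    (gain) and -1 (loss) per region.
    """

    regions: pd.DataFrame
    calls: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.regions), len(self.samples)):
            raise ValueError("calls shape inconsistent with regions/samples")
        if not np.isin(self.calls, (-1, 0, 1)).all():
            raise ValueError("calls must be in {-1, 0, +1}")

    @property
    def gain_freq(self) -> np.ndarray:
        if not self.samples:
            return np.zeros(len(self.regions))
        return (self.calls == 1).mean(axis=1)

    @property
    def loss_freq(self) -> np.ndarray:
        if not self.samples:
            return np.zeros(len(self.regions))
        return (self.calls == -1).mean(axis=1)

    def to_frame(self, order: list[str] | None = None) -> pd.DataFrame:
        cols = order or self.samples
        idx = [self.samples.index(c) for c in cols]
        df = pd.DataFrame(self.calls[:, idx], columns=cols)
        df.insert(0, "label", self.regions["label"].to_numpy())
        return df

    def write_tsv(self, path, order: list[str] | None = None) -> None:
        self.to_frame(order).to_csv(path, sep="\t", index=False)


def _threshold_calls(means: np.ndarray, theta_eff: np.ndarray | float,
                     strict: bool) -> np.ndarray:
    if strict:
        return np.where(means > theta_eff, 1, np.where(means < -theta_eff, -1, 0))
    return np.where(means >= theta_eff, 1, np.where(means <= -theta_eff, -1, 0))


def segment_noise_factor(residual_sd: float | None, reference_noise: float) -> float:
    """Noise multiplier for one (sample, segment): max(1, sd / reference).

    ``residual_sd`` is the standard deviation of the sample's bins about the
    segment mean (None for single-bin segments, where it is undefined and the
    factor is 1).  The floor at 1 means adjustment only ever raises the
    threshold.
    """
    if residual_sd is None or reference_noise <= 0:
        return 1.0
    return float(max(1.0, residual_sd / reference_noise))


def _residual_sds(values: np.ndarray, regions: pd.DataFrame,
                  means: np.ndarray) -> np.ndarray:
    """Residual sd of each sample's bins about its segment mean (NaN if 1 bin)."""
    k, s = means.shape
    out = np.full((k, s), np.nan)
    for r in range(k):
        a, b = int(regions["start_bin"].iloc[r]), int(regions["end_bin"].iloc[r])
        if b > a:
            block = values[a:b + 1]
            out[r] = np.sqrt(((block - means[r][None, :]) ** 2).mean(axis=0))
    return out


def _segments_to_matrix(segmentation, bin_matrix: BinMatrix):
    """Regions frame + means matrix from either segmentation flavour."""
    if isinstance(segmentation, SharedSegmentation):
        regions = segmentation.segments[["chrom", "start_bin", "end_bin", "n_bins"]].copy()
        return regions.reset_index(drop=True), segmentation.means.copy(), list(segmentation.samples)
    atoms, means, samples = disjoint_intervals(segmentation)
    return atoms, means, samples


def call_aberrations(segmentation, bin_matrix: BinMatrix,
                     config: CallingConfig | None = None) -> AberrationMatrix:
    """Gain/loss calls per segment per sample.

    Accepts a :class:`SharedSegmentation` (CS mode; rows are the shared
    segments) or a list of :class:`SampleSegmentation` (SW mode; rows are the
    atomic intervals of the pooled breakpoint set).  When
    ``config.noise_adjust`` is on, each (segment, sample) threshold is
    theta * noise_seg computed from the bin residuals.
    """
    config = config or CallingConfig()
    regions, means, samples = _segments_to_matrix(segmentation, bin_matrix)
    if regions.empty:
        regions = regions.assign(label=pd.Series(dtype=str))
        return AberrationMatrix(regions, np.zeros((0, len(samples)), dtype=int), samples)
    if config.noise_adjust:
        sds = _residual_sds(bin_matrix.values, regions, means)
        finite = sds[np.isfinite(sds)]
        ref = float(np.median(finite)) if finite.size else 0.0
        factors = np.ones_like(means)
        if ref > 0:
            factors = np.where(np.isfinite(sds), np.maximum(1.0, sds / ref), 1.0)
        theta_eff = config.theta * factors
    else:
        theta_eff = config.theta
    calls = _threshold_calls(means, theta_eff, config.strict)
    keep = regions["n_bins"].to_numpy() >= config.min_bins
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d segments below the %d-bin floor",
                    n_removed, config.min_bins)
    regions = regions[keep].reset_index(drop=True)
    calls = calls[keep]
    regions["label"] = [f"{c}:{a}-{b}" for c, a, b in zip(
        regions["chrom"], regions["start_bin"], regions["end_bin"])]
    return AberrationMatrix(regions, calls.astype(int), samples)


def disjoint_intervals(segmentations: list[SampleSegmentation]
                       ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Atomic intervals of the pooled per-sample breakpoints, with values.

    Atoms are the intervals between consecutive elements of the union of all
    samples' segment boundaries per chromosome; each sample's value on an
    atom is the mean of its covering segment.  Atoms partition the genome.
    """
    if not segmentations:
        raise ValueError("need at least one sample segmentation")
    samples = [s.sample_id for s in segmentations]
    chroms: list[str] = []
    for s in segmentations:
        for c in s.segments["chrom"]:
            if c not in chroms:
                chroms.append(c)
    rows = []
    values = []
    for chrom in chroms:
        cuts: set[int] = set()
        per_sample = []
        for s in segmentations:
            sub = s.segments[s.segments["chrom"] == chrom]
            per_sample.append(sub)
            cuts.update(sub["start_bin"].astype(int))
            cuts.update(sub["end_bin"].astype(int) + 1)
        bounds = sorted(cuts)
        for a, b in zip(bounds[:-1], bounds[1:]):
            vals = np.full(len(samples), np.nan)
            for k, sub in enumerate(per_sample):
                hit = sub[(sub["start_bin"] <= a) & (sub["end_bin"] >= b - 1)]
                if len(hit):
                    vals[k] = float(hit["mean"].iloc[0])
            rows.append({"chrom": chrom, "start_bin": a, "end_bin": b - 1,
                         "n_bins": b - a})
            values.append(vals)
    atoms = pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin", "n_bins"])
    means = np.vstack(values) if values else np.zeros((0, len(samples)))
    if np.isnan(means).any():
        raise ValueError("sample segments do not cover all atoms; "
                         "segmentations must partition each chromosome")
    return atoms, means, samples


def _bin_arm_labels(bin_map_table: pd.DataFrame, arms: ArmTable) -> pd.Series:
    """Arm label ('1p', ...) of each bin by its midpoint; None if uncovered."""
    mid = (bin_map_table["start"] + bin_map_table["end"]) // 2
    labels = []
    for chrom, m in zip(bin_map_table["chrom"], mid):
        arm = arms.arm_of(str(chrom), int(m))
        labels.append(f"{chrom}{arm}" if arm else None)
    return pd.Series(labels, index=bin_map_table.index)


def arm_weighted_mean(segmentation, arms: ArmTable,
                      bin_matrix: BinMatrix) -> pd.DataFrame:
    """Length-weighted mean segment value per chromosome arm per sample.

    Each segment is clipped to the arms via its bins' midpoints; the arm
    value is sum(len_piece * mean) / sum(len_piece) with lengths in bins.
    Arms containing no bins are emitted as NaN.
    """
    regions, means, samples = _segments_to_matrix(segmentation, bin_matrix)
    bin_arms = _bin_arm_labels(bin_matrix.bin_map.table, arms)
    arm_labels = [f"{c}{a}" for c, a in zip(arms.table["chrom"], arms.table["arm"])]
    num = {lab: np.zeros(len(samples)) for lab in arm_labels}
    den = {lab: 0.0 for lab in arm_labels}
    for r in range(len(regions)):
        a, b = int(regions["start_bin"].iloc[r]), int(regions["end_bin"].iloc[r])
        piece = bin_arms.iloc[a:b + 1].value_counts()
        for lab, n_bins in piece.items():
            if lab in num:
                num[lab] += n_bins * means[r]
                den[lab] += n_bins
    data = {lab: (num[lab] / den[lab] if den[lab] > 0 else np.full(len(samples), np.nan))
            for lab in arm_labels}
    return pd.DataFrame(data, index=samples).T


def classify_arms(arm_matrix: pd.DataFrame,
                  config: CallingConfig | None = None) -> AberrationMatrix:
    """Threshold arm-level weighted means into {-1, 0, +1} (no bin-count filter)."""
    config = config or CallingConfig()
    vals = arm_matrix.to_numpy(float)
    calls = np.where(np.isnan(vals), 0,
                     _threshold_calls(np.nan_to_num(vals), config.theta, config.strict))
    regions = pd.DataFrame({
        "chrom": [lab.rstrip("pq") for lab in arm_matrix.index],
        "start_bin": -1, "end_bin": -1, "n_bins": 0,
        "label": list(arm_matrix.index),
    })
    return AberrationMatrix(regions, calls.astype(int), list(arm_matrix.columns))


def order_by_similarity(matrix: AberrationMatrix) -> list[str]:
    """Similarity ordering of samples: average-linkage leaves on Hamming distance.

    Deterministic: equal columns stay in input order (stable tie-breaking of
    the linkage on an all-zero distance block).
    """
    s = len(matrix.samples)
    if s <= 2:
        return list(matrix.samples)
    cols = matrix.calls.T.astype(float)
    dist = pdist(cols, metric="hamming") if matrix.calls.size else np.zeros(s * (s - 1) // 2)
    if dist.size == 0 or np.allclose(dist, dist[0]):
        return list(matrix.samples)  # fully tied: keep input order
    order = leaves_list(average(dist))
    return [matrix.samples[i] for i in order]
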