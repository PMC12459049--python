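"""Probe-intensity normalization against control samples.

Copy number is inferred from the combined methylated+unmethylated signal of
each probe: a query sample is fitted against controls and the per-probe log2
ratio of observed over fitted intensity is carried forward.  Two fits are
offered:

``linear_reference_log2``
    a single scalar least-squares fit of the query against the per-probe
    median of the controls (the classic single-reference scheme);

``tangent_log2``
    least-squares projection of the query onto the linear span of all
    control profiles (tangent normalization), which absorbs any control-space
    component of the query before the ratio is taken.

Both are invariant to rescaling the query by a positive constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_RATIO_FLOOR = 1e-12


@dataclass
class IntensityMatrix:
    """Probes x samples matrix of non-negative combined signal intensities."""

    values: np.ndarray
    probe_ids: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("intensity values must be 2-D (probes x samples)")
        if self.values.shape != (len(self.probe_ids), len(self.samples)):
            raise ValueError("intensity matrix shape inconsistent with annotations")
        if (self.values < 0).any():
            raise ValueError("negative intensities are not allowed")


@dataclass
class LogRatioMatrix:
    """Probes x samples log2-ratio matrix plus the normalization mode used."""

    values: np.ndarray
    probe_ids: np.ndarray
    samples: list[str]
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        if not np.isfinite(self.values).all():
            raise ValueError("log-ratio matrix contains non-finite entries")


def read_intensity_tsv(path) -> IntensityMatrix:
    """Read a TSV intensity matrix: first column probe_id, one column per sample."""
    df = pd.read_csv(path, sep="\t")
    probe_col = df.columns[0]
    return IntensityMatrix(
        values=df.drop(columns=probe_col).to_numpy(float),
        probe_ids=df[probe_col].astype(str).to_numpy(),
        samples=[str(c) for c in df.columns[1:]],
    )


def write_log_ratio_tsv(lrm: LogRatioMatrix, path) -> None:
    df = pd.DataFrame(lrm.values, columns=lrm.samples)
    df.insert(0, "probe_id", lrm.probe_ids)
    df.to_csv(path, sep="\t", index=False)


def _check_aligned(query: IntensityMatrix, controls: IntensityMatrix) -> None:
    if len(query.probe_ids) != len(controls.probe_ids) or not np.array_equal(
            query.probe_ids, controls.probe_ids):
        raise ValueError("query and controls must share the same probe set and order")
    if controls.values.shape[1] < 1:
        raise ValueError("at least one control sample required")


def linear_reference_log2(query: IntensityMatrix,
                          controls: IntensityMatrix) -> LogRatioMatrix:
    """Log2 ratio of each query sample against a scalar fit of the control median.

    Per query sample q the scalar a = argmin ||q - a r||^2 = <q,r>/<r,r> is
    fitted against the per-probe control median r and log2(q / (a r)) is
    returned.  Probes with r = 0 are dropped (count logged).
    """
    _check_aligned(query, controls)
    ref = np.median(controls.values, axis=1)
    keep = ref > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d probes with zero control median", n_drop)
    if not keep.any():
        raise ValueError("all control medians are zero")
    r = ref[keep]
    q = query.values[keep]
    a = (q * r[:, None]).sum(axis=0) / (r @ r)  # per-sample scalar fit
    if (a <= 0).any():
        raise ValueError("non-positive fitted scale; query signal degenerate")
    ratio = q / (a[None, :] * r[:, None])
    values = np.log2(np.maximum(ratio, _RATIO_FLOOR))
    return LogRatioMatrix(values, query.probe_ids[keep], list(query.samples), "linear")


def tangent_log2(query: IntensityMatrix, controls: IntensityMatrix,
                 floor_scale: float = 1e-6) -> LogRatioMatrix:
    """Log2 ratio of each query sample against its projection onto the control span.

    The fitted profile is the ordinary least-squares linear combination of
    control columns; it is floored at ``floor_scale`` x median(fitted) before
    the ratio so the log stays finite.  Rank-deficient control sets are
    handled by the minimum-norm solution with a warning.
    """
    _check_aligned(query, controls)
    C = controls.values
    n_probes, n_ctrl = C.shape
    if n_ctrl >= n_probes:
        raise ValueError("tangent normalization needs fewer controls than probes")
    coef, _, rank, _ = np.linalg.lstsq(C, query.values, rcond=None)
    if rank < n_ctrl:
        logger.warning("control matrix rank-deficient (rank %d < %d controls)",
                       rank, n_ctrl)
    fitted = C @ coef
    med = np.median(fitted[fitted > 0]) if (fitted > 0).any() else 1.0
    eps = floor_scale * med
    fitted = np.maximum(fitted, eps)
    ratio = np.maximum(query.values, _RATIO_FLOOR) / fitted
    values = np.log2(ratio)
    return LogRatioMatrix(values, query.probe_ids.copy(), list(query.samples), "tangent")
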