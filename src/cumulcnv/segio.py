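"""Segment interchange I/O: IGV SEG export and breakpoint BED."""

from __future__ import annotations

import pandas as pd

from .binning import BinMatrix
from .cbs import SampleSegmentation
from .pcf import SharedSegmentation

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_marks", "seg_mean"]


def _bp(bin_table: pd.DataFrame, start_bin: int, end_bin: int) -> tuple[int, int]:
    return (int(bin_table["start"].iloc[start_bin]),
            int(bin_table["end"].iloc[end_bin]))


def shared_to_seg(seg: SharedSegmentation, bin_matrix: BinMatrix) -> pd.DataFrame:
    """One SEG row per sample x segment (start/end in bp, num_marks = bins)."""
    t = bin_matrix.bin_map.table
    rows = []
    for r in range(len(seg.segments)):
        chrom = seg.segments["chrom"].iloc[r]
        a, b = int(seg.segments["start_bin"].iloc[r]), int(seg.segments["end_bin"].iloc[r])
        start, end = _bp(t, a, b)
        for j, sample in enumerate(seg.samples):
            rows.append([sample, chrom, start, end, b - a + 1,
                         float(seg.means[r, j])])
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def samplewise_to_seg(segs: list[SampleSegmentation],
                      bin_matrix: BinMatrix) -> pd.DataFrame:
    t = bin_matrix.bin_map.table
    rows = []
    for s in segs:
        for _, r in s.segments.iterrows():
            start, end = _bp(t, int(r["start_bin"]), int(r["end_bin"]))
            rows.append([s.sample_id, r["chrom"], start, end,
                         int(r["n_bins"]), float(r["mean"])])
    return pd.DataFrame(rows, columns=SEG_COLUMNS)


def write_seg(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_breakpoint_bed(seg: SharedSegmentation, bin_matrix: BinMatrix,
                         path) -> None:
    """Interior shared breakpoints as zero-width-ish BED intervals."""
    t = bin_matrix.bin_map.table
    rows = []
    for chrom, bps in seg.breakpoints.items():
        for b in bps:
            # boundary before global bin b: position between bins b-1 and b
            pos = int(t["start"].iloc[b]) - 1
            rows.append([chrom, pos, pos + 1, f"bp_{chrom}_{b}"])
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def segment_sample_matrix(seg: SharedSegmentation) -> pd.DataFrame:
    """Segments x samples intensity matrix (the optional data-matrix output)."""
    labels = [f"{c}:{a}-{b}" for c, a, b in zip(
        seg.segments["chrom"], seg.segments["start_bin"], seg.segments["end_bin"])]
    return pd.DataFrame(seg.means, index=labels, columns=seg.samples)
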