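"""Cumulative CNV plot data and rendering.

Four plot kinds are built, two per segmentation mode:

* CS intensity — per-bin cross-sample mean as a jitter point layer, overlaid
  with the per-segment cross-sample mean lines, optionally gene-labelled.
* CS frequency — gain frequency upward, loss frequency downward per segment.
* SW intensity — one rectangle per sample-segment at its mean, with opacity
  1 / n_samples so recurrent aberrations darken.
* SW frequency — frequency bars on the atomic intervals of the pooled
  per-sample breakpoints.

The testable surface is the :class:`PlotData` layer tables (plain
DataFrames, lossless TSV round-trip); rendering is a thin matplotlib step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np
import pandas as pd

from .binning import BinMatrix
from .calling import AberrationMatrix, disjoint_intervals
from .cbs import SampleSegmentation
from .genome import ProbeTable
from .pcf import SharedSegmentation

logger = logging.getLogger(__name__)

GENE_LABEL_CUT = 0.15  # |bin mean| needed before a gene label is drawn


@dataclass
class PlotData:
    kind: str
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write_tsv(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, df in self.layers.items():
            df.to_csv(d / f"{self.kind}_{name}.tsv", sep="\t", index=False)


def _bin_coords(bin_matrix: BinMatrix) -> pd.DataFrame:
    t = bin_matrix.bin_map.table
    return pd.DataFrame({
        "bin_id": t["bin_id"], "chrom": t["chrom"],
        "start": t["start"], "end": t["end"],
        "mid": (t["start"] + t["end"]) / 2.0,
    })


def _segment_bp(regions: pd.DataFrame, bin_matrix: BinMatrix) -> pd.DataFrame:
    t = bin_matrix.bin_map.table
    out = regions.copy()
    out["start_bp"] = t["start"].to_numpy()[regions["start_bin"].to_numpy(int)]
    out["end_bp"] = t["end"].to_numpy()[regions["end_bin"].to_numpy(int)]
    return out


def cs_intensity_data(bin_matrix: BinMatrix, shared_seg: SharedSegmentation,
                      gene_list: list[str] | None = None,
                      probes: ProbeTable | None = None,
                      seed: int = 0) -> PlotData:
    """Jittered per-bin cross-sample means plus per-segment mean lines."""
    coords = _bin_coords(bin_matrix)
    rng = np.random.default_rng(seed)
    width = (coords["end"] - coords["start"]).to_numpy(float)
    jitter = rng.uniform(-0.4, 0.4, size=len(coords)) * width
    points = coords.assign(
        value=bin_matrix.values.mean(axis=1),
        x=coords["mid"].to_numpy() + jitter,
    )
    lines = _segment_bp(shared_seg.segments, bin_matrix).assign(
        value=shared_seg.means.mean(axis=1))
    layers = {"points": points, "segments": lines}
    if gene_list:
        if probes is None:
            raise ValueError("gene annotation requires a probe table")
        layers["genes"] = annotate_genes(gene_list, probes, bin_matrix.bin_map,
                                         bin_matrix.values.mean(axis=1))
    return PlotData("cs_intensity", layers)


def annotate_genes(gene_list: list[str], probes: ProbeTable, bin_map,
                   bin_means: np.ndarray) -> pd.DataFrame:
    """Gene label positions: the bin holding most of the gene's probes.

    Ties go to the leftmost bin; a label is emitted only when the chosen
    bin's mean intensity is >= +0.15 or <= -0.15 (boundary inclusive).
    """
    if "gene" not in probes.table.columns:
        raise ValueError("probe table has no gene column")
    probe_bin = {}
    for b, pids in enumerate(bin_map.probe_ids):
        for p in pids:
            probe_bin[p] = b
    rows = []
    for gene in gene_list:
        sub = probes.table[probes.table["gene"] == gene]
        if sub.empty:
            logger.warning("gene %s not found in probe annotation; skipped", gene)
            continue
        bins = [probe_bin[p] for p in sub["probe_id"] if p in probe_bin]
        if not bins:
            logger.warning("gene %s has no binned probes; skipped", gene)
            continue
        counts = pd.Series(bins).value_counts()
        top = counts[counts == counts.max()].index.min()  # leftmost on ties
        value = float(bin_means[top])
        if abs(value) >= GENE_LABEL_CUT:
            t = bin_map.table.iloc[top]
            rows.append({"gene": gene, "bin_id": int(t["bin_id"]),
                         "chrom": t["chrom"],
                         "mid": (t["start"] + t["end"]) / 2.0, "value": value})
    return pd.DataFrame(rows, columns=["gene", "bin_id", "chrom", "mid", "value"])


def cs_frequency_data(matrix: AberrationMatrix,
                      bin_matrix: BinMatrix) -> PlotData:
    """Gain frequency upward and loss frequency downward per called segment."""
    bars = _segment_bp(matrix.regions, bin_matrix).assign(
        gain_freq=matrix.gain_freq, loss_freq=matrix.loss_freq)
    return PlotData("cs_frequency", {"bars": bars})


def sw_intensity_data(sample_segmentations: list[SampleSegmentation],
                      bin_matrix: BinMatrix) -> PlotData:
    """One rectangle per sample-segment; opacity is exactly 1 / n_samples."""
    if not sample_segmentations:
        raise ValueError("need at least one sample segmentation")
    opacity = 1.0 / len(sample_segmentations)
    frames = []
    for seg in sample_segmentations:
        df = _segment_bp(seg.segments, bin_matrix).assign(
            sample=seg.sample_id, opacity=opacity)
        frames.append(df)
    rects = pd.concat(frames, ignore_index=True)
    return PlotData("sw_intensity", {"rectangles": rects})


def sw_frequency_data(matrix: AberrationMatrix,
                      bin_matrix: BinMatrix) -> PlotData:
    """Frequency bars on the atomic intervals (call matrix built on atoms)."""
    bars = _segment_bp(matrix.regions, bin_matrix).assign(
        gain_freq=matrix.gain_freq, loss_freq=matrix.loss_freq)
    return PlotData("sw_frequency", {"bars": bars})


def _genome_offsets(bin_matrix: BinMatrix) -> tuple[dict[str, float], float]:
    offsets = {}
    pos = 0.0
    t = bin_matrix.bin_map.table
    for chrom in bin_matrix.bin_map.chroms:
        offsets[chrom] = pos
        pos += float(t.loc[t["chrom"] == chrom, "end"].max())
    return offsets, pos


def render(plot_data: PlotData, bin_matrix: BinMatrix, path,
           figsize: tuple[float, float] = (14, 4)) -> None:
    """Draw the plot on a concatenated genome axis and save to ``path``.

    Output format follows the file extension (png/svg/pdf).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    offsets, total = _genome_offsets(bin_matrix)
    fig, ax = plt.subplots(figsize=figsize)
    kind = plot_data.kind
    if kind == "cs_intensity":
        pts = plot_data.layers["points"]
        x = pts["x"].to_numpy() + pts["chrom"].map(offsets).to_numpy()
        ax.scatter(x, pts["value"], s=2, alpha=0.4, color="0.5")
        seg = plot_data.layers["segments"]
        for _, r in seg.iterrows():
            o = offsets[r["chrom"]]
            ax.hlines(r["value"], o + r["start_bp"], o + r["end_bp"],
                      color="crimson", lw=2)
        genes = plot_data.layers.get("genes")
        if genes is not None:
            for _, g in genes.iterrows():
                ax.annotate(g["gene"], (offsets[g["chrom"]] + g["mid"], g["value"]),
                            fontsize=7, ha="center")
        ax.set_ylabel("mean log2 ratio")
    elif kind in ("cs_frequency", "sw_frequency"):
        bars = plot_data.layers["bars"]
        for _, r in bars.iterrows():
            o = offsets[r["chrom"]]
            w = r["end_bp"] - r["start_bp"]
            ax.bar(o + r["start_bp"], r["gain_freq"], width=w, align="edge",
                   color="firebrick")
            ax.bar(o + r["start_bp"], -r["loss_freq"], width=w, align="edge",
                   color="steelblue")
        ax.set_ylim(-1.05, 1.05)
        ax.set_ylabel("aberration frequency")
    elif kind == "sw_intensity":
        rects = plot_data.layers["rectangles"]
        for _, r in rects.iterrows():
            o = offsets[r["chrom"]]
            color = "firebrick" if r["mean"] > 0 else "steelblue"
            ax.fill_between([o + r["start_bp"], o + r["end_bp"]], 0, r["mean"],
                            alpha=r["opacity"], color=color, linewidth=0)
        ax.set_ylabel("segment mean log2 ratio")
    else:
        raise ValueError(f"unknown plot kind {kind!r}")
    for chrom, o in offsets.items():
        if o > 0:
            ax.axvline(o, color="0.8", lw=0.5)
        t = bin_matrix.bin_map.table
        center = o + float(t.loc[t["chrom"] == chrom, "end"].max()) / 2
        ax.text(center, ax.get_ylim()[1], str(chrom), ha="center", va="bottom",
                fontsize=7)
    ax.axhline(0, color="0.3", lw=0.5)
    ax.set_xlim(0, total)
    ax.set_xlabel("genome position")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
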