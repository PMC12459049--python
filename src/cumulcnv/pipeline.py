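"""End-to-end workflow: input -> processing -> outputs -> optional post-processing.

``run`` drives the whole analysis from a :class:`RunConfig`: load (or
normalize and bin) the cohort, segment it in the requested mode(s), call
aberrations, write SEG files, plot-data TSVs and figures, the optional
segment x sample intensity matrix and the similarity-ordered aberration
matrix, plus a YAML run log with config, seed and package version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binning import BinMatrix, aggregate_probes, build_bin_map, read_bin_matrix, write_bin_matrix
from .calling import (AberrationMatrix, CallingConfig, arm_weighted_mean,
                      call_aberrations, classify_arms, disjoint_intervals,
                      order_by_similarity)
from .cbs import CBSConfig, segment_cohort_sw
from .genome import ArmTable, ProbeTable, load_arm_table, load_manifest, load_probe_table
from .normalize import linear_reference_log2, read_intensity_tsv, tangent_log2
from .pcf import PCFConfig, segment_genome_cs
from .plots import (cs_frequency_data, cs_intensity_data, render,
                    sw_frequency_data, sw_intensity_data)
from .segio import (samplewise_to_seg, segment_sample_matrix, shared_to_seg,
                    write_breakpoint_bed, write_seg)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs; flags mirror the CLI options."""

    out_dir: str = "cumulcnv_out"
    mode: str = "both"                  # cs | sw | both
    bin_matrix: str | None = None       # TSV interchange input, or ...
    manifest: str | None = None         # ... intensity TSVs per sample
    controls: str | None = None         # control intensity TSV (with manifest)
    probe_table: str | None = None
    arm_bed: str | None = None
    normalization: str = "linear"       # linear | tangent
    gene_list: list[str] = field(default_factory=list)
    pcf: PCFConfig = field(default_factory=PCFConfig)
    cbs: CBSConfig = field(default_factory=CBSConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    arm_level: bool = False
    return_matrix: bool = False
    figure_format: str = "png"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cs", "sw", "both"):
            raise ValueError("mode must be cs, sw or both")


def _load_cohort(config: RunConfig) -> tuple[BinMatrix, ProbeTable | None]:
    if config.bin_matrix:
        return read_bin_matrix(config.bin_matrix), None
    if not (config.manifest and config.controls and config.probe_table):
        raise ValueError("provide either a bin-matrix TSV or a manifest with "
                         "controls and a probe table")
    manifest = load_manifest(config.manifest)
    probes = load_probe_table(config.probe_table)
    controls = read_intensity_tsv(config.controls)
    frames = []
    for _, row in manifest.table.iterrows():
        im = read_intensity_tsv(row["path"])
        col = row["sample_id"] if row["sample_id"] in im.samples else im.samples[0]
        frames.append(pd.Series(im.values[:, im.samples.index(col)],
                                index=im.probe_ids, name=row["sample_id"]))
    query_df = pd.concat(frames, axis=1, join="inner")
    shared = [p for p in controls.probe_ids if p in query_df.index]
    query_df = query_df.loc[shared]
    from .normalize import IntensityMatrix
    query = IntensityMatrix(query_df.to_numpy(float), np.asarray(shared, object),
                            list(query_df.columns))
    ctrl_idx = [list(controls.probe_ids).index(p) for p in shared]
    ctrl = IntensityMatrix(controls.values[ctrl_idx],
                           np.asarray(shared, object), list(controls.samples))
    norm = (linear_reference_log2 if config.normalization == "linear"
            else tangent_log2)(query, ctrl)
    keep = probes.table["probe_id"].isin(norm.probe_ids)
    probes = ProbeTable(probes.table[keep].reset_index(drop=True), probes.layout)
    order = {p: i for i, p in enumerate(norm.probe_ids)}
    # align log ratios to the sorted probe table
    rows = [order[p] for p in probes.table["probe_id"]]
    from .normalize import LogRatioMatrix
    lrm = LogRatioMatrix(norm.values[rows], probes.table["probe_id"].to_numpy(),
                         norm.samples, norm.mode)
    bin_map = build_bin_map(probes)
    return aggregate_probes(lrm, bin_map), probes


def run(config: RunConfig) -> dict[str, object]:
    """Execute the workflow; returns the in-memory artifacts it wrote."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}
    cohort, probes = _load_cohort(config)
    write_bin_matrix(cohort, out / "bin_matrix.tsv")
    arms: ArmTable | None = load_arm_table(config.arm_bed) if config.arm_bed else None

    if config.mode in ("cs", "both"):
        cs = segment_genome_cs(cohort, config.pcf)
        artifacts["cs"] = cs
        write_seg(shared_to_seg(cs, cohort), out / "cs_segments.seg")
        write_breakpoint_bed(cs, cohort, out / "cs_breakpoints.bed")
        cs_calls = call_aberrations(cs, cohort, config.calling)
        artifacts["cs_calls"] = cs_calls
        pd_int = cs_intensity_data(cohort, cs, config.gene_list or None,
                                   probes, seed=config.seed)
        pd_frq = cs_frequency_data(cs_calls, cohort)
        for p in (pd_int, pd_frq):
            p.write_tsv(out / "plot_data")
            render(p, cohort, out / f"{p.kind}.{config.figure_format}")
        if config.return_matrix:
            segment_sample_matrix(cs).to_csv(out / "cs_segment_matrix.tsv", sep="\t")
        _write_aberrations(cs_calls, out / "cs_aberrations.tsv")
        if config.arm_level and arms is not None:
            arm_vals = arm_weighted_mean(cs, arms, cohort)
            _write_aberrations(classify_arms(arm_vals, config.calling),
                               out / "cs_arm_aberrations.tsv")

    if config.mode in ("sw", "both"):
        sw = segment_cohort_sw(cohort, config.cbs)
        artifacts["sw"] = sw
        write_seg(samplewise_to_seg(sw, cohort), out / "sw_segments.seg")
        sw_cfg = CallingConfig(theta=config.calling.theta,
                               min_bins=config.calling.min_bins,
                               noise_adjust=True, strict=config.calling.strict)
        sw_calls = call_aberrations(sw, cohort, sw_cfg)
        artifacts["sw_calls"] = sw_calls
        pd_int = sw_intensity_data(sw, cohort)
        pd_frq = sw_frequency_data(sw_calls, cohort)
        for p in (pd_int, pd_frq):
            p.write_tsv(out / "plot_data")
            render(p, cohort, out / f"{p.kind}.{config.figure_format}")
        if arms is not None:
            # SW post-processing condenses to chromosome arms
            arm_vals = arm_weighted_mean(sw, arms, cohort)
            _write_aberrations(classify_arms(arm_vals, config.calling),
                               out / "sw_arm_aberrations.tsv")

    log = {"version": __version__, "seed": config.seed,
           "mode": config.mode, "normalization": config.normalization,
           "pcf": asdict(config.pcf), "cbs": asdict(config.cbs),
           "calling": asdict(config.calling)}
    (out / "run_log.yaml").write_text(yaml.safe_dump(_plain(log), sort_keys=True))
    artifacts["out_dir"] = out
    return artifacts


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _write_aberrations(matrix: AberrationMatrix, path) -> None:
    order = order_by_similarity(matrix)
    df = matrix.to_frame(order)
    df["gain_freq"] = matrix.gain_freq
    df["loss_freq"] = matrix.loss_freq
    df.to_csv(path, sep="\t", index=False)
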