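# cumulcnv

Cumulative copy-number-variation (CNV) analysis of DNA-methylation-array
cohorts, for researchers and diagnosticians who need one genome-wide CNV
picture of a whole case series rather than one plot per sample.

Copy number can be inferred from methylation arrays because the summed
methylated + unmethylated probe intensity tracks DNA quantity.  `cumulcnv`
takes probe intensities (or ready-made bin-level log2 ratios), normalizes
query samples against controls, reduces probes to genomic bins, and then
segments the cohort in either or both of two modes:

* **CS — combined segmentation.**  All S samples are segmented jointly with
  *shared* breakpoints by a multi-sample penalized least-squares
  piecewise-constant fit: minimise over segmentations

  $$\sum_s \mathrm{SSE}_s / \hat\sigma_s^2 \;+\; \gamma\,S\,2\ln(n)\cdot K$$

  where SSE_s is sample *s*'s within-segment sum of squares, σ̂_s its
  successive-difference MAD noise estimate, n the chromosome's bin count and
  K the number of breakpoints.  The exact minimiser comes from a dynamic
  program; long chromosomes are first sparsified by two high-pass
  moving-difference filters that propose candidate breakpoints.  γ is the
  user-facing sensitivity dial: 0.5 is sensitive, 5 conservative.

* **SW — sample-wise segmentation.**  Classic circular binary segmentation
  per sample (arc-vs-complement maximal t statistic, permutation p-values,
  recursive splitting), optionally weighted by inverse per-bin probe
  variance.

Segment means are thresholded into gains (+1) and losses (−1) at θ
(default 0.2, strict inequality; for CBS-derived segments θ is multiplied
by a per-segment noise factor, and segments under 2 bins are dropped).  On
top of the calls the package builds the four cumulative plots (CS/SW ×
intensity/frequency; SW rectangles drawn at opacity 1/S), arm-level
weighted-mean aberration matrices with similarity-ordered samples, and a
seeded Monte Carlo benchmark that measures focal-aberration sensitivity as
a function of γ.

## Worked example

```sh
python examples/01_simulate_and_segment.py
```

simulates 12 samples × 200 bins with a +1.0 gain on chromosome 1, bins
40–49, in 75% of samples, and segments the cohort jointly.  It prints:

```
shared segments (all samples share these boundaries):
chrom  start_bin  end_bin  n_bins
    1          0       39      40
    1         40       49      10
    1         50      119      70
    2        120      199      80

per-sample means of the middle chromosome-1 segment (affected samples ~ +1, others ~ 0):
  S000: -0.01
  S001: +1.07
  S002: +1.01
  ...
```

The fit recovers the injected 10-bin span exactly (one segment, bins
40–49) and its per-sample means separate carriers (≈ +1) from
non-carriers (≈ 0) — the quantities the intensity and frequency plots are
built from.  The other examples call aberrations and render the four
cumulative plots (`02`), condense CNVs to chromosome arms and reorder
samples by similarity (`03`), and run a small sensitivity benchmark (`04`).

The same workflow is available from the shell:

```sh
cumulcnv simulate --n-samples 20 --event 1:40-49:1.0:0.8 --out cohort.tsv
cumulcnv run --bin-matrix cohort.tsv --mode both --gamma 1.0 --theta 0.2 --out results/
```

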