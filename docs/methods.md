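# Methods

## Signal model and preprocessing

Copy number is read off methylation arrays through the combined
methylated + unmethylated intensity of each probe.  Two normalizations
against a control set are provided.  The *linear reference* mode fits, per
query sample, a single scalar a = ⟨q, r⟩ / ⟨r, r⟩ against the per-probe
control median r and reports log2(q / (a·r)); probes with zero control
median are dropped and counted.  The *tangent* mode projects the query
intensity vector onto the linear span of all control profiles by ordinary
least squares and reports log2(query / fitted), with the fitted profile
floored at 1e−6 × its median so the log stays finite.  Both modes are
exactly invariant to rescaling a query sample, so a global intensity factor
never mimics an aberration.  The tangent fit is unconstrained (not
non-negative) least squares: it is deterministic, has a closed-form oracle,
and rank-deficient control sets degrade gracefully to the minimum-norm
solution.  Whether the reference tools fit in log or linear intensity space
is not documented; the fit here is in linear space, a known divergence
risk for strongly skewed intensity distributions.

Probe-level ratios are reduced to genomic bins by tiling each chromosome
with 50-kb windows and merging consecutive windows left to right until a
bin holds at least 15 probes; a trailing remainder below the floor is
merged back into the last emitted bin.  The merge direction is a declared
convention — it is deterministic and independent of the data values.  Bin
value = median probe log2 ratio per sample; the population variance of the
member probes is kept per bin per sample as the weight basis for weighted
CBS.  Bins never cross chromosome boundaries; they may cross centromeres
(arm summaries later split by arm).

## Combined segmentation (CS)

All samples are segmented jointly with shared breakpoints by minimising

    sum_s SSE_s / sigma_s^2  +  P · K,        P = gamma · S_eff · 2 ln(n)

with per-sample noise sigma_s estimated by the successive-difference MAD
(median |v_{i+1} − v_i| / (0.6745·√2)), S_eff = S (default, `per_sample`)
or 1 (`per_cohort`), n the chromosome's bin count and K the breakpoint
count.  Standardization makes gamma noise-scale-free; it can be disabled.

The penalty calibration is the one genuinely open design choice.  A shared
breakpoint buys one extra mean parameter per sample, and on pure
standardized noise the best spurious split of a chromosome gains roughly a
chi-square with one degree of freedom per sample, inflated by the log of
the number of positions scanned.  A penalty proportional to S alone is
therefore *always* beaten by noise on large cohorts (the fit fragments);
the 2 ln(n) factor is the classical model-selection rate that keeps the
expected spurious gain below the penalty at gamma ≈ 1 for any cohort size.
Two anchors: at S = 1, n ≈ 400 the penalty is ≈ 12, the customary default
of single-sample piecewise-constant fitting on standardized data; and at
the benchmark conditions below, gamma = 0.5–5 spans sensitive (weakest
events found, rare boundary-level false positives possible) to
conservative (only strong or frequent events found, no false positives) —
the qualitative behaviour the gamma dial is meant to have.

The exact minimiser is found by the standard O(n²) dynamic program over
prefix sums (O(1) segment costs; per-sample values are centered before the
cost prefix sums are built, which removes catastrophic cancellation when
1/σ² weights are large).  Cost ties within 1e−12 break toward the smaller
predecessor index, i.e. parsimony.  Chromosomes above 400 bins are first
scanned by two high-pass filters: for half-widths w ∈ {1, 5} each interior
boundary is scored by the summed per-sample standardized absolute
difference of the w-bin window means on either side; boundaries that are a
local maximum for either filter and exceed a low threshold (default 1.0)
become candidates, and the same dynamic program runs on the candidate grid
(endpoints always included).  The restricted fit's cost is an upper bound
on the exact optimum by construction; on seeded single-sample noise
(n = 200, gamma = 1) it returns the exact solution in ≥ 95% of trials.

## Sample-wise segmentation (SW)

Per sample and chromosome, circular binary segmentation: the interval is
treated as a circle, the arc maximising |mean(arc) − mean(complement)| /
pooled SE is located (weighted means and weighted pooled variance when
inverse-variance bin weights are on; the SE is floored at 1e−12 × its
weight scale so noiseless steps give a large finite statistic), its
significance is assessed by permutation (p = (hits+1)/(n_perm+1), default
1000 permutations, early exit once p > alpha is guaranteed), and on
p ≤ alpha (default 0.01) the interval splits at the arc boundaries and the
pieces recurse.  Arcs and complements shorter than `min_seg_bins`
(default 2) are not considered, so no 1-bin slivers arise.  This is a
faithful but simplified CBS: no hybrid p-value approximation and no
undo/prune passes, hence no bit-compatibility with the reference
implementations.  Weights are 1/(probe variance + 1e−8), normalized to
mean 1 per sample; with equal variances weighted and plain CBS coincide
exactly.

## Calling, arms, ordering

A segment is a gain/loss in a sample when its mean strictly exceeds
±θ_eff.  θ defaults to 0.2; strictness is deliberate (a mean of exactly
−0.2, or the −0.193 kind of borderline case, is not called).  For
CBS-derived segments θ_eff = θ × noise_seg with noise_seg = max(1,
residual-sd / cohort-reference), the reference being the cohort median of
all per-(sample, segment) residual standard deviations; the floor at 1
means noise adjustment can only raise the threshold.  Single-bin segments
have undefined residual sd and get factor 1 — moot in practice because
regions under `min_bins` = 2 bins are removed from the call matrix
entirely (they remain in the SEG export).  SW-mode calls are made on the
atomic intervals of the pooled per-sample breakpoints, so the matrix rows
are comparable across samples.  Arm condensation is the
segment-length-weighted mean (lengths in bins, bins assigned to arms by
midpoint), thresholded the same way without the bin-count filter.  Sample
ordering is average-linkage clustering of the call columns under Hamming
distance, reporting dendrogram leaf order; fully tied distance matrices
keep the input order.

## Plots

The testable surface is the layer tables, not pixels: per-bin cross-sample
means with seeded horizontal jitter plus per-segment cross-sample mean
lines (CS intensity; the line is the cross-sample mean of per-sample
segment means, not a pooled refit), gain/loss frequency bars per called
region (CS/SW frequency), and one rectangle per sample-segment at opacity
exactly 1/S (SW intensity).  Gene labels go on the bin holding the most of
the gene's probes (leftmost on ties) and only when |bin mean| ≥ 0.15,
boundary inclusive.  Rendering concatenates chromosomes on one axis and
writes PNG/SVG/PDF via matplotlib.

## Synthetic cohorts and the Monte Carlo benchmark

The generator emulates bin-level cohorts as i.i.d. Gaussian noise (default
sd 0.1, a typical bin-level log2-ratio dispersion of good-quality arrays)
plus injected events of known span, strength and affected fraction;
probe-level cohorts are lognormal intensities over a shared baseline such
that normalization + binning recovers the bin truth.  It does *not*
emulate probe-type chemistry, batch or FFPE effects, spatially correlated
noise, or tumour purity dilution — passing benchmarks bound performance
under clean Gaussian noise, not on degraded clinical material.

Each benchmark iteration plants one focal aberration in a fresh noise
cohort: anchor region (random gene when annotation is present, else a
random bin) padded by 3 bins per side and widened to ≥ 7 bins (shifted
inward at chromosome ends), frequency drawn from {0.2, 0.4, 0.6, 0.8,
1.0}, strength from {+0.5, +1, +1.5, +2}, affected samples a uniform
subset of size round(frequency × S).  Detection requires a segment with
exactly the injected boundaries (tolerance 0 by default, configurable);
false positives are called regions (after the 2-bin filter) disjoint from
the span, audited per iteration.  The desk-scale study conditions are 200
iterations of 60 samples × 2,000 bins over 4 chromosomes at noise sd 0.1,
a scaled-down stand-in for resampling real control cohorts; at these
conditions detection is essentially complete at gamma ≤ 1 and degrades
first in the weakest stratum (strength +0.5, frequency 0.2) as gamma or
noise grows.

## Numerical choices and known limitations

* Noise floors: σ̂ floored at 1e−8 (PCF), pooled SE at 1e−12 × weight scale
  (CBS), fitted intensities at 1e−6 × median (tangent), ratio arguments at
  1e−12 (log safety).
* All randomness flows from explicit seeds (CBS permutations, jitter,
  generators, benchmark substreams via `SeedSequence.spawn`).
* Exact-boundary detection in small cohorts can fail at the weakest
  stratum when a filter local maximum lands one bin off the true boundary
  (~1 in 30 at S = 30); at S ≥ 60 this was not observed in 400 seeded
  iterations.  A boundary tolerance parameter exists for sensitivity
  analyses.
* Cross-array harmonization is probe-ID intersection, not model-based
  liftover; mixed-array cohorts lose the probes missing from any array.
* CBS permutation cost grows as O(n_perm · n²) per tested interval; the SW
  mode is meant for cohorts binned to a few hundred bins per chromosome.
* Thresholds are not corrected for tumour purity; choosing θ for diluted
  samples remains the analyst's responsibility.
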