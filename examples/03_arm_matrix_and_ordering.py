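"""Condense a cohort's CNVs to chromosome arms and order samples by similarity.

Simulates a cohort in which half the samples carry a -0.5 loss of the whole
p arm of chromosome 1, computes the segment-length-weighted mean per arm,
thresholds it into the {-1, 0, +1} arm matrix, and prints the matrix with
samples reordered so that similar CNV profiles sit next to each other.
"""

from cumulcnv import (CohortSpec, EventSpec, PCFConfig, arm_weighted_mean,
                      classify_arms, order_by_similarity, segment_genome_cs,
                      synth_bin_cohort)
from cumulcnv.simulate import make_arm_table

spec = CohortSpec(n_samples=8, chrom_bins={"1": 200, "2": 200}, noise_sd=0.1,
                  events=[EventSpec("1", 0, 99, strength=-0.5, fraction=0.5)],
                  seed=13)
cohort, truth = synth_bin_cohort(spec)
print("samples carrying the 1p loss:", truth["affected"].iloc[0], "\n")

seg = segment_genome_cs(cohort, PCFConfig(gamma=1.0))
arms = make_arm_table(spec.chrom_bins)
arm_values = arm_weighted_mean(seg, arms, cohort)
print("arm-level weighted means (rows = arms):")
print(arm_values.round(2).to_string(), "\n")

calls = classify_arms(arm_values)
order = order_by_similarity(calls)
print("similarity-ordered arm aberration matrix (1 gain, 0 none, -1 loss):")
print(calls.to_frame(order).to_string(index=False))
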