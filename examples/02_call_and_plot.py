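"""Call gains/losses and write the four cumulative plots for one cohort.

Segments a simulated cohort in both modes (shared-breakpoint fit and
per-sample CBS), thresholds segment means at theta = 0.2 into {-1, 0, +1},
prints the per-segment gain/loss frequencies, and renders the CS/SW
intensity and frequency figures under ``example_plots/``.
"""

from pathlib import Path

from cumulcnv import (CallingConfig, CBSConfig, CohortSpec, EventSpec,
                      PCFConfig, call_aberrations, cs_frequency_data,
                      cs_intensity_data, render, segment_cohort_sw,
                      segment_genome_cs, sw_frequency_data, sw_intensity_data,
                      synth_bin_cohort)

spec = CohortSpec(n_samples=10, chrom_bins={"1": 100, "2": 100}, noise_sd=0.1,
                  events=[EventSpec("1", 20, 39, strength=0.6, fraction=0.5),
                          EventSpec("2", 50, 79, strength=-0.8, fraction=0.3)],
                  seed=7)
cohort, _ = synth_bin_cohort(spec)
out = Path("example_plots")

cs = segment_genome_cs(cohort, PCFConfig(gamma=1.0))
cs_calls = call_aberrations(cs, cohort, CallingConfig(theta=0.2))
print("CS-mode called regions (gain/loss frequency across the cohort):")
for r in range(len(cs_calls.regions)):
    lab = cs_calls.regions["label"].iloc[r]
    g, l = cs_calls.gain_freq[r], cs_calls.loss_freq[r]
    if g or l:
        print(f"  {lab}: gain {g:.0%}, loss {l:.0%}")

sw = segment_cohort_sw(cohort, CBSConfig(alpha=0.01, n_perm=200, seed=7))
sw_calls = call_aberrations(sw, cohort, CallingConfig(noise_adjust=True))

render(cs_intensity_data(cohort, cs), cohort, out / "cs_intensity.png")
render(cs_frequency_data(cs_calls, cohort), cohort, out / "cs_frequency.png")
render(sw_intensity_data(sw, cohort), cohort, out / "sw_intensity.png")
render(sw_frequency_data(sw_calls, cohort), cohort, out / "sw_frequency.png")
print(f"\nfour figures written under {out}/")
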