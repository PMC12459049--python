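import numpy as np
import pandas as pd
import pytest

from cumulcnv.benchmark import (FREQUENCY_SET, STRENGTH_SET, FocalSimSpec,
                                draw_spec, inject_aberration, mode_concordance,
                                run_monte_carlo, score_detection, _pad_span)
from cumulcnv.calling import CallingConfig, call_aberrations
from cumulcnv.pcf import PCFConfig, segment_genome_cs
from cumulcnv.simulate import CohortSpec, make_arm_table, synth_bin_cohort

from test_calling import flat_bin_matrix, sample_seg, shared_seg


def small_cohort(seed=0, n_samples=6):
    cohort, _ = synth_bin_cohort(CohortSpec(
        n_samples=n_samples, chrom_bins={"1": 60, "2": 40}, seed=seed))
    return cohort


class TestDrawSpec:
    def test_same_seed_same_spec(self):
        cohort = small_cohort()
        a = draw_spec(np.random.default_rng(5), cohort)
        b = draw_spec(np.random.default_rng(5), cohort)
        assert (a.chrom, a.start_bin, a.end_bin, a.frequency, a.strength) == \
            (b.chrom, b.start_bin, b.end_bin, b.frequency, b.strength)
        np.testing.assert_array_equal(a.affected, b.affected)

    def test_frequency_one_affects_every_sample(self):
        cohort = small_cohort()
        for seed in range(30):
            spec = draw_spec(np.random.default_rng(seed), cohort)
            if spec.frequency == 1.0:
                assert spec.affected.size == cohort.n_samples
                return
        pytest.fail("frequency 1.0 never drawn in 30 seeds")

    def test_rounding_of_affected_count(self):
        cohort, _ = synth_bin_cohort(CohortSpec(
            n_samples=60, chrom_bins={"1": 100}, seed=0))
        for seed in range(10):
            spec = draw_spec(np.random.default_rng(seed), cohort)
            assert spec.affected.size == round(spec.frequency * 60)

    def test_draws_come_from_declared_sets(self):
        cohort = small_cohort()
        for seed in range(25):
            spec = draw_spec(np.random.default_rng(seed), cohort)
            assert spec.frequency in FREQUENCY_SET
            assert spec.strength in STRENGTH_SET
            assert spec.n_bins >= 7

    def test_gene_anchor_used_when_available(self):
        cohort = small_cohort()
        gene_bins = {"MYGENE": ("2", 70, 72)}
        spec = draw_spec(np.random.default_rng(1), cohort, gene_bins)
        assert spec.chrom == "2"
        assert spec.start_bin <= 67 and spec.end_bin >= 75  # 3-bin padding


class TestPadding:
    def test_single_bin_anchor_padded_to_seven(self):
        assert _pad_span(30, 30, 0, 99, 3, 7) == (27, 33)

    def test_five_bin_anchor_padded_to_eleven(self):
        a, b = _pad_span(30, 34, 0, 99, 3, 7)
        assert (a, b) == (27, 37) and b - a + 1 == 11

    def test_edge_anchor_shifted_inward(self):
        a, b = _pad_span(0, 0, 0, 99, 3, 7)
        assert a == 0 and b - a + 1 >= 7

    def test_chromosome_too_short_rejected(self):
        with pytest.raises(ValueError):
            _pad_span(1, 1, 0, 3, 3, 7)


class TestInjection:
    def test_only_affected_samples_and_span_touched(self):
        cohort = small_cohort(seed=2)
        spec = FocalSimSpec("1", 10, 16, 0.5, 1.5, np.array([0, 2, 4]))
        out = inject_aberration(cohort, spec)
        delta = out.values - cohort.values
        assert np.allclose(delta[10:17][:, [0, 2, 4]], 1.5)
        delta[10:17, :] = 0
        assert np.allclose(delta, 0)

    def test_zero_strength_is_identity(self):
        cohort = small_cohort(seed=3)
        spec = FocalSimSpec("1", 5, 12, 1.0, 0.0, np.arange(6))
        out = inject_aberration(cohort, spec)
        np.testing.assert_array_equal(out.values, cohort.values)

    def test_span_outside_chromosome_rejected(self):
        cohort = small_cohort()
        spec = FocalSimSpec("1", 50, 70, 1.0, 1.0, np.array([0]))
        with pytest.raises(ValueError):
            inject_aberration(cohort, spec)


class TestScoring:
    def test_exact_span_found_even_with_zero_observed_frequency(self):
        spec = FocalSimSpec("1", 10, 19, 0.2, 0.5, np.array([0]))
        seg = shared_seg([("1", 0, 9), ("1", 10, 19), ("1", 20, 29)],
                         np.zeros((3, 2)), ["a", "b"])
        calls = call_aberrations(seg, flat_bin_matrix(30, 2))
        res = score_detection(seg, calls, spec, gamma=1.0)
        assert res.found and res.observed_frequency == 0.0

    def test_unsegmented_span_not_found(self):
        spec = FocalSimSpec("1", 10, 19, 1.0, 2.0, np.array([0, 1]))
        seg = shared_seg([("1", 0, 29)], np.zeros((1, 2)), ["a", "b"])
        calls = call_aberrations(seg, flat_bin_matrix(30, 2))
        assert not score_detection(seg, calls, spec, gamma=1.0).found

    def test_one_bin_spurious_call_filtered_from_false_positives(self):
        spec = FocalSimSpec("1", 10, 19, 1.0, 2.0, np.array([0, 1]))
        seg = shared_seg([("1", 0, 0), ("1", 1, 9), ("1", 10, 19), ("1", 20, 29)],
                         np.array([[3.0, 3.0], [0, 0], [2, 2], [0.5, 0.0]]),
                         ["a", "b"])
        calls = call_aberrations(seg, flat_bin_matrix(30, 2))
        res = score_detection(seg, calls, spec, gamma=1.0)
        assert res.found
        # the 1-bin segment at 3.0 was dropped by the 2-bin filter; the
        # remaining off-target call (bins 20-29, one gained sample) stays
        assert [lab for lab, _ in res.false_positives] == ["1:20-29"]

    def test_observed_frequency_counts_threshold_exceedance(self):
        spec = FocalSimSpec("1", 10, 19, 0.5, 0.5, np.array([0, 1]))
        seg = shared_seg([("1", 10, 19)], np.array([[0.5, 0.5, 0.1, 0.0]]),
                         ["a", "b", "c", "d"])
        calls = call_aberrations(seg, flat_bin_matrix(30, 4))
        res = score_detection(seg, calls, spec, gamma=1.0)
        assert res.observed_frequency == pytest.approx(0.5)


class TestMonteCarlo:
    def test_detection_monotone_in_gamma_on_fixed_seeds(self):
        spec = CohortSpec(n_samples=20, chrom_bins={"1": 150, "2": 150}, seed=0)
        _, rec = run_monte_carlo(8, [0.5, 2.0, 50.0], spec, seed=42)
        rates = rec.groupby("gamma")["found"].mean()
        assert rates[0.5] >= rates[2.0] >= rates[50.0]

    def test_enormous_gamma_detects_nothing(self):
        spec = CohortSpec(n_samples=10, chrom_bins={"1": 100}, seed=0)
        _, rec = run_monte_carlo(4, [1e6], spec, seed=7)
        assert rec["found"].sum() == 0

    def test_reproducible_given_seed(self):
        spec = CohortSpec(n_samples=10, chrom_bins={"1": 100, "2": 80}, seed=0)
        _, a = run_monte_carlo(4, [1.0], spec, seed=3)
        _, b = run_monte_carlo(4, [1.0], spec, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_summary_stratifies_by_strength_and_frequency(self):
        spec = CohortSpec(n_samples=10, chrom_bins={"1": 120}, seed=0)
        summary, rec = run_monte_carlo(6, [1.0], spec, seed=5)
        assert set(summary.columns) >= {"gamma", "strength", "frequency", "n",
                                        "detected", "detection_rate",
                                        "false_positive_count"}
        assert summary["n"].sum() == len(rec)


class TestConcordance:
    def test_identical_segmentations_correlate_perfectly(self):
        bm = flat_bin_matrix(40, 2)
        arms = make_arm_table({"1": 40})
        means = np.array([[0.5, 0.2], [-0.3, 0.1]])
        cs = shared_seg([("1", 0, 19), ("1", 20, 39)], means, ["a", "b"])
        sw = [sample_seg(s, [("1", 0, 19, means[0, k]), ("1", 20, 39, means[1, k])])
              for k, s in enumerate(["a", "b"])]
        r = mode_concordance(cs, sw, arms, bm)
        assert np.allclose(r, 1.0)

    def test_negated_arm_means_correlate_minus_one(self):
        bm = flat_bin_matrix(40, 1)
        arms = make_arm_table({"1": 40})
        cs = shared_seg([("1", 0, 19), ("1", 20, 39)], [[0.5], [-0.3]], ["a"])
        sw = [sample_seg("a", [("1", 0, 19, -0.5), ("1", 20, 39, 0.3)])]
        r = mode_concordance(cs, sw, arms, bm)
        assert r["a"] == pytest.approx(-1.0)

    def test_three_arm_hand_computed_pearson(self):
        # CS arm means (0.4, 0.0, -0.2), SW arm means (0.5, 0.1, -0.1):
        # r computed independently with the textbook formula
        from cumulcnv.binning import BinMatrix
        from cumulcnv.simulate import make_bin_map
        arms = make_arm_table({"1": 40, "2": 40})  # 2q holds no bins -> skipped
        cs = shared_seg([("1", 0, 19), ("1", 20, 39), ("2", 40, 59)],
                        [[0.4], [0.0], [-0.2]], ["a"])
        sw = [sample_seg("a", [("1", 0, 19, 0.5), ("1", 20, 39, 0.1),
                               ("2", 40, 59, -0.1)])]
        bm = BinMatrix(np.zeros((60, 1)), make_bin_map({"1": 40, "2": 20}), ["a"])
        r = mode_concordance(cs, sw, arms, bm)
        x = np.array([0.4, 0.0, -0.2])
        y = np.array([0.5, 0.1, -0.1])
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
        assert r["a"] == pytest.approx(expected, abs=1e-9)
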