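"""Cohort diagnostics: confusion metrics, ROC/AUC, z-test, power law."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import sevquant as sq
from sevquant.cohortstats import PowerLawModel


def printed_cohort():
    """Counts reproducing the published tallies at cutoff 70:
    204/205 cancer above, 103/106 healthy at or below."""
    cancer = np.full(205, 244.0)
    cancer[0] = 50.0  # the single cancer sample below the cutoff
    healthy = np.full(106, 30.0)
    healthy[:3] = 80.0  # the three healthy samples above it
    counts = np.concatenate([cancer, healthy])
    labels = np.concatenate([np.ones(205, int), np.zeros(106, int)])
    return counts, labels


class TestConfusion:
    def test_published_tallies_give_sensitivity_99_5(self):
        counts, labels = printed_cohort()
        cc = sq.confusion_at_cutoff(counts, labels, 70.0)
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (204, 1, 103, 3)
        assert round(sq.sensitivity(cc), 1) == 99.5
        # computed specificity is 103/106 = 97.2 % to one decimal
        assert round(sq.specificity(cc), 1) == 97.2

    def test_counts_at_cutoff_are_negative_calls(self):
        counts = np.full(10, 70.0)
        labels = np.array([1] * 5 + [0] * 5)
        cc = sq.confusion_at_cutoff(counts, labels, 70.0)
        assert cc.tp == 0 and cc.fp == 0 and cc.fn == 5 and cc.tn == 5

    def test_toy_cohort_matches_hand_enumeration(self):
        counts = np.array([10.0, 80.0, 60.0, 90.0])
        labels = np.array([0, 0, 1, 1])
        cc = sq.confusion_at_cutoff(counts, labels, 70.0)
        assert (cc.tp, cc.fp, cc.tn, cc.fn) == (1, 1, 1, 1)
        assert cc.total == 4

    def test_counts_sum_to_cohort_size_at_every_cutoff(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, 60).astype(float)
        labels = rng.integers(0, 2, 60)
        labels[0], labels[1] = 0, 1
        for cutoff in range(0, 520, 40):
            assert sq.confusion_at_cutoff(counts, labels, cutoff).total == 60

    def test_identities_sensitivity_missrate_specificity_fpr(self):
        cc = sq.ConfusionCounts(tp=17, fp=4, tn=33, fn=6)
        miss = 100.0 * cc.fn / (cc.tp + cc.fn)
        assert sq.sensitivity(cc) + miss == pytest.approx(100.0)
        assert sq.specificity(cc) + 100.0 * sq.fpr(cc) == pytest.approx(100.0)

    def test_zero_denominator_warns_and_is_nan(self):
        cc = sq.ConfusionCounts(tp=0, fp=0, tn=5, fn=0)
        with pytest.warns(UserWarning):
            assert np.isnan(sq.sensitivity(cc))


class TestRoc:
    def test_perfectly_separated_cohort_has_auc_one(self):
        counts = np.array([10.0] * 20 + [900.0] * 20)
        labels = np.array([0] * 20 + [1] * 20)
        assert sq.roc_auc(counts, labels).auc == pytest.approx(1.0)

    def test_permuted_labels_give_null_auc(self):
        rng = np.random.default_rng(1)
        counts = np.rint(rng.normal(200, 80, 2000)).clip(0)
        labels = rng.permutation([0, 1] * 1000)
        auc = sq.roc_auc(counts, labels).auc
        assert abs(auc - 0.5) < 3 * np.sqrt(1 / 12) * np.sqrt(1 / 1000 + 1 / 1000)

    def test_swept_auc_tracks_rank_sum_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            nh, nc = int(rng.integers(30, 120)), int(rng.integers(30, 120))
            df = sq.simulate_cohort(nh, nc, seed=int(rng.integers(2**31)))
            counts = df.post_wash_count.to_numpy(float)
            labels = (df.group_label == "cancer").to_numpy(int)
            curve = sq.roc_auc(counts, labels)
            u = mannwhitneyu(counts[labels == 1], counts[labels == 0]).statistic
            assert abs(curve.auc - u / (nh * nc)) <= 0.01

    def test_tpr_fpr_nonincreasing_in_cutoff(self):
        df = sq.simulate_cohort(80, 80, seed=5)
        curve = sq.roc_auc(df.post_wash_count.to_numpy(float), (df.group_label == "cancer").to_numpy(int))
        assert np.all(np.diff(curve.tpr) <= 1e-12)
        assert np.all(np.diff(curve.fpr) <= 1e-12)

    def test_single_class_cohort_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestProportionTest:
    def test_null_proportion_gives_zero_z(self):
        t = sq.proportion_z_test(0.5, 0.5, 50)
        assert t.z == 0.0
        assert t.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("p,expected_z", [(0.6, 2.0), (0.4, -2.0)])
    def test_known_z_values_and_antisymmetry(self, p, expected_z):
        assert sq.proportion_z_test(p, 0.5, 100).z == pytest.approx(expected_z)

    def test_degenerate_null_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.proportion_z_test(0.5, 1.0, 10)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert sq.pearson_r(x, 2 * x)[0] == pytest.approx(1.0)
        assert sq.pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.pearson_r(np.ones(5), np.arange(5.0))


class TestTumorVolume:
    @pytest.mark.parametrize("l,w,expected", [(2, 1, 1.0), (4, 2, 8.0), (3, 0.01, 0.00015)])
    def test_caliper_formula(self, l, w, expected):
        assert sq.tumor_volume(l, w) == pytest.approx(expected)

    def test_measurement_invariants(self):
        with pytest.raises(sq.ValidationError):
            sq.TumorMeasurement(length_mm=1.0, width_mm=2.0)
        assert sq.TumorMeasurement(4.0, 2.0).volume_mm3 == pytest.approx(8.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.tumor_volume(0.0, 1.0)


class TestPowerLaw:
    def test_eval_at_offset_is_baseline(self):
        assert sq.powerlaw_eval(3.48e-7) == pytest.approx(5.42)

    def test_eval_reference_points(self):
        # frozen from direct evaluation of the default coefficients
        assert sq.powerlaw_eval(0.0) == pytest.approx(22.46, abs=0.01)
        assert sq.powerlaw_eval(8.0) == pytest.approx(135.98, abs=0.01)

    def test_monotone_nondecreasing_above_offset(self):
        x = np.linspace(1e-6, 300, 1000)
        y = sq.powerlaw_eval(x)
        assert np.all(np.diff(y) >= 0)

    def test_recovers_parameters_from_noise_free_data(self):
        x = np.array([0.1, 1.0, 5.0, 10.0, 50.0, 100.0, 200.0])
        y = sq.powerlaw_eval(x)
        fit = sq.powerlaw_fit(x, y)
        assert fit.model.amplitude == pytest.approx(101.7, rel=0.01)
        assert fit.model.exponent == pytest.approx(0.12013, rel=0.01)
        assert fit.model.baseline == pytest.approx(5.42, rel=0.01)
        assert not fit.degenerate

    def test_constant_counts_flagged_degenerate(self):
        x = np.array([0.1, 1.0, 5.0, 10.0, 50.0, 100.0])
        fit = sq.powerlaw_fit(x, np.full(6, 40.0))
        assert fit.degenerate

    def test_noisy_exponent_recovery(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.uniform(0.1, 10, 25), rng.uniform(10, 200, 25)])
        y = sq.powerlaw_eval(x) + rng.normal(0, 10, 50)
        fit = sq.powerlaw_fit(x, y)
        # 3 SE bound estimated from the residual spread
        assert fit.model.exponent == pytest.approx(0.12013, abs=0.05)

    def test_insufficient_span_rejected(self):
        with pytest.raises(sq.ValidationError):
            sq.powerlaw_fit(np.linspace(10, 20, 8), np.linspace(100, 120, 8))
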