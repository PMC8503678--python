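"""Agreement and ROC statistics against hand calculations and oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smearscreen import (ConfusionMatrix, cohens_kappa, compare_auc_paired,
                         confusion_metrics, icc_average_from_f, icc_oneway,
                         kappa_band, roc_curve, split_dataset, youden_optimal)

from .oracles import (anova_icc, bootstrap_se_delta_auc, pairwise_auc,
                      youden_scan)

# Central reconstruction of the published screening row
# (N=5469, sens 0.566, spec 0.913, acc 0.822).
RECONSTRUCTED = ConfusionMatrix(tp=812, fp=351, fn=622, tn=3684)


class TestConfusionMetrics:
    def test_reconstructed_row_arithmetic(self):
        m = confusion_metrics(RECONSTRUCTED)
        assert m.accuracy == pytest.approx(4496 / 5469, abs=1e-12)
        assert m.ppv == pytest.approx(812 / 1163, abs=1e-12)
        assert m.sensitivity == pytest.approx(812 / 1434, abs=1e-12)
        assert m.npv == pytest.approx(3684 / 4306, abs=1e-12)

    def test_perfect_matrix(self):
        m = confusion_metrics(ConfusionMatrix(10, 0, 0, 10))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_flagged_undefined(self):
        m = confusion_metrics(ConfusionMatrix(tp=0, fp=5, fn=0, tn=5))
        assert m.sensitivity is None
        assert m.specificity is not None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 5)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(ConfusionMatrix(50, 0, 0, 50)).kappa == \
            pytest.approx(1.0)

    def test_independence_table(self):
        assert cohens_kappa(ConfusionMatrix(25, 25, 25, 25)).kappa == \
            pytest.approx(0.0, abs=1e-12)

    def test_reconstructed_row_by_hand(self):
        # po = 4496/5469, pe = (1163*1434 + 4306*4035)/5469^2
        r = cohens_kappa(RECONSTRUCTED)
        po = 4496 / 5469
        pe = (1163 * 1434 + 4306 * 4035) / 5469**2
        assert r.kappa == pytest.approx((po - pe) / (1 - pe), abs=1e-12)
        assert r.kappa == pytest.approx(0.510, abs=0.001)

    def test_se_and_ci_match_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        for cm in [RECONSTRUCTED, ConfusionMatrix(30, 10, 5, 55),
                   ConfusionMatrix(8, 2, 3, 7)]:
            r = cohens_kappa(cm)
            sm = sm_kappa(np.array([[cm.tp, cm.fn], [cm.fp, cm.tn]]))
            assert r.kappa == pytest.approx(sm.kappa, abs=1e-10)
            assert r.se == pytest.approx(np.sqrt(sm.var_kappa), rel=1e-6)
            assert r.ci95[0] == pytest.approx(sm.kappa_low, abs=1e-6)
            assert r.ci95[1] == pytest.approx(sm.kappa_upp, abs=1e-6)

    def test_degenerate_margins_flagged(self):
        r = cohens_kappa(ConfusionMatrix(tp=10, fp=0, fn=0, tn=0))
        assert r.kappa is None

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 200)] * 4))
    def test_label_swap_invariance(self, counts):
        tp, fp, fn, tn = counts
        if tp + fp + fn + tn == 0:
            return
        direct = cohens_kappa(ConfusionMatrix(tp, fp, fn, tn)).kappa
        swapped = cohens_kappa(ConfusionMatrix(tn, fn, fp, tp)).kappa
        if direct is None:
            assert swapped is None
        else:
            assert swapped == pytest.approx(direct, abs=1e-12)


class TestKappaBand:
    @pytest.mark.parametrize("kappa,band", [
        (-0.1, "inconsistent"),
        (0.1, "slightly consistent"),
        (0.3, "fair consistent"),
        (0.513, "moderately consistent"),
        (0.7, "substantially consistent"),
        (0.830, "almost consistent"),
        (0.40, "fair consistent"),    # boundary belongs to the lower band
        (0.41, "moderately consistent"),
    ])
    def test_bands(self, kappa, band):
        assert kappa_band(kappa) == band

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            kappa_band(1.01)


class TestIcc:
    def test_identical_raters_give_perfect_average_icc(self):
        table = np.tile(np.array([[1.0], [0.0], [1.0], [0.0], [1.0]]), 3)
        r = icc_oneway(table)
        assert r.icc_average == 1.0
        assert r.icc_single == 1.0

    def test_average_identity_with_f(self):
        rng = np.random.default_rng(1)
        table = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
        r = icc_oneway(table)
        assert r.icc_average == pytest.approx(1.0 - 1.0 / r.f_value,
                                              abs=1e-15)

    def test_small_table_matches_hand_anova(self):
        table = np.array([[7.0, 9.0, 8.0],
                          [4.0, 5.0, 6.0],
                          [9.0, 9.0, 10.0],
                          [2.0, 3.0, 2.0]])
        single, average, f = anova_icc(table)
        r = icc_oneway(table)
        assert r.icc_single == pytest.approx(single, abs=1e-12)
        assert r.icc_average == pytest.approx(average, abs=1e-12)
        assert r.f_value == pytest.approx(f, abs=1e-12)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        table = rng.normal(size=(10, 3)) + 2.0 * rng.normal(size=(10, 1))
        frame = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 3),
            "raters": np.tile(np.arange(3), 10),
            "ratings": table.ravel(),
        })
        icc = pg.intraclass_corr(frame, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")
        r = icc_oneway(table)
        assert r.icc_single == pytest.approx(icc.loc["ICC(1,1)", "ICC"],
                                             abs=1e-9)
        assert r.icc_average == pytest.approx(icc.loc["ICC(1,k)", "ICC"],
                                              abs=1e-9)
        assert r.f_value == pytest.approx(icc.loc["ICC(1,1)", "F"], abs=1e-9)

    def test_zero_variance_flagged(self):
        r = icc_oneway(np.ones((5, 3)))
        assert r.icc_average is None

    def test_icc_from_f_identity(self):
        assert icc_average_from_f(5.791) == pytest.approx(1 - 1 / 5.791)


class TestRoc:
    def test_separable_scores_give_auc_one(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_constant_scores_give_auc_half(self):
        roc = roc_curve([0.5] * 10, [1, 0] * 5)
        assert roc.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            roc = roc_curve(scores, labels)
            assert roc.auc == pytest.approx(pairwise_auc(scores, labels),
                                            abs=1e-12)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(2)
        roc = roc_curve(rng.random(50), rng.integers(0, 2, 50))
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.9], [1, 1])

    def test_hanley_mcneil_se_positive(self):
        roc = roc_curve([0.9, 0.4, 0.3, 0.5, 0.6], [1, 1, 0, 0, 1])
        assert 0.0 < roc.auc < 1.0
        assert roc.se_auc > 0


class TestDeLong:
    def test_identical_scorers(self):
        scores = [0.9, 0.2, 0.7, 0.4]
        labels = [1, 0, 1, 0]
        r = compare_auc_paired(scores, scores, labels)
        assert r.z == 0.0
        assert r.p_two_sided == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a, b = rng.random(40), rng.random(40)
        fwd = compare_auc_paired(a, b, labels)
        rev = compare_auc_paired(b, a, labels)
        assert rev.z == pytest.approx(-fwd.z, abs=1e-12)
        assert rev.p_two_sided == pytest.approx(fwd.p_two_sided, abs=1e-12)

    def test_se_close_to_bootstrap(self):
        rng = np.random.default_rng(12)
        labels = np.array([1] * 14 + [0] * 14)
        signal = labels * 0.8
        a = signal + rng.normal(0, 0.6, 28)
        b = signal + rng.normal(0, 0.9, 28)
        r = compare_auc_paired(a, b, labels)
        boot = bootstrap_se_delta_auc(a, b, labels, n_boot=10_000, seed=5)
        assert r.se_delta == pytest.approx(boot, rel=0.10)


class TestYouden:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        cutoff, j = youden_optimal(roc)
        assert j == 1.0
        assert 0.2 < cutoff <= 0.8

    def test_constant_scores(self):
        roc = roc_curve([0.4] * 8, [1, 0] * 4)
        _, j = youden_optimal(roc)
        assert j == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            scores = np.round(rng.random(20), 2)
            labels = rng.integers(0, 2, 20)
            if labels.min() == labels.max():
                continue
            roc = roc_curve(scores, labels)
            cutoff, j = youden_optimal(roc)
            cut_oracle, j_oracle = youden_scan(scores, labels)
            assert j == pytest.approx(j_oracle, abs=1e-12)
            assert cutoff == pytest.approx(cut_oracle, abs=1e-12)


class TestSplit:
    def test_published_cohort_counts(self):
        train, val = split_dataset(20_748, 0.8, seed=0)
        assert len(train) == 16_598
        assert len(val) == 4_150

    def test_small_example(self):
        train, val = split_dataset(10, 0.8, seed=1)
        assert len(train) == 8 and len(val) == 2

    def test_deterministic_and_seed_sensitive(self):
        t1, v1 = split_dataset(100, 0.8, seed=7)
        t2, v2 = split_dataset(100, 0.8, seed=7)
        t3, _ = split_dataset(100, 0.8, seed=8)
        assert np.array_equal(t1, t2) and np.array_equal(v1, v2)
        assert not np.array_equal(t1, t3)
        assert len(t3) == len(t1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 5000), st.floats(0.0, 1.0),
           st.integers(0, 2**31 - 1))
    def test_conservation_and_disjointness(self, n, fraction, seed):
        train, val = split_dataset(n, fraction, seed)
        assert len(train) + len(val) == n
        assert len(train) == int(np.floor(fraction * n))
        combined = np.concatenate([train, val])
        assert np.array_equal(np.sort(combined), np.arange(n))
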