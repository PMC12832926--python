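import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiopso.exceptions import DomainError
from cardiopso.metrics import (
    ConfusionCounts,
    likelihood_ratios,
    metric_panel,
    roc_auc,
    round_half_up,
    tally_confusion,
)


class TestTallyConfusion:
    def test_one_of_each_cell(self):
        c = tally_confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = tally_confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        t = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        c = tally_confusion(t, p)
        pairs = list(zip(t, p))
        assert c.tp == pairs.count((1, 1))
        assert c.tn == pairs.count((0, 0))
        assert c.fp == pairs.count((0, 1))
        assert c.fn == pairs.count((1, 0))
        assert c.total == 50

    @pytest.mark.parametrize(
        "t, p", [([1, 0], [1]), ([1, 2], [1, 0]), ([], [])]
    )
    def test_invalid_inputs_rejected(self, t, p):
        with pytest.raises(DomainError):
            tally_confusion(t, p)


class TestMetricPanel:
    def test_perfect_classifier(self):
        panel = metric_panel(ConfusionCounts(10, 10, 0, 0))
        for name in ("accuracy", "sensitivity", "specificity", "precision",
                     "f1", "npv", "mcc", "balanced_accuracy", "bm", "mk"):
            assert getattr(panel, name) == pytest.approx(1.0)

    def test_ipso_xgboost_holdout_panel(self):
        # 92-patient held-out panel of the best optimized model
        panel = metric_panel(ConfusionCounts(38, 46, 3, 5))
        assert panel.accuracy == pytest.approx(0.91304, abs=5e-6)
        assert panel.sensitivity == pytest.approx(0.88372, abs=5e-6)
        assert panel.specificity == pytest.approx(0.93878, abs=5e-6)
        assert panel.precision == pytest.approx(0.92683, abs=5e-6)
        assert panel.f1 == pytest.approx(0.90476, abs=5e-6)
        assert panel.npv == pytest.approx(0.90196, abs=5e-6)
        assert panel.mcc == pytest.approx(0.82564, abs=5e-6)
        assert panel.balanced_accuracy == pytest.approx(0.91125, abs=5e-6)

    def test_default_gnb_holdout_panel(self):
        panel = metric_panel(ConfusionCounts(36, 35, 5, 16))
        assert panel.sensitivity == pytest.approx(0.69231, abs=5e-6)
        assert panel.precision == pytest.approx(0.87805, abs=5e-6)
        assert panel.npv == pytest.approx(0.68627, abs=5e-6)

    def test_consistency_identities(self):
        c = ConfusionCounts(17, 23, 4, 9)
        panel = metric_panel(c)
        weighted = (panel.sensitivity * c.n_positive + panel.specificity * c.n_negative) / c.total
        assert panel.accuracy == pytest.approx(weighted)
        assert panel.balanced_accuracy == pytest.approx(
            (panel.sensitivity + panel.specificity) / 2
        )
        assert panel.bm == pytest.approx(panel.sensitivity + panel.specificity - 1)
        assert panel.mk == pytest.approx(panel.precision + panel.npv - 1)

    def test_label_swap_symmetry(self):
        c = ConfusionCounts(17, 23, 4, 9)
        a, b = metric_panel(c), metric_panel(c.swapped())
        assert b.sensitivity == pytest.approx(a.specificity)
        assert b.specificity == pytest.approx(a.sensitivity)
        assert b.precision == pytest.approx(a.npv)
        assert b.npv == pytest.approx(a.precision)
        assert abs(b.mcc) == pytest.approx(abs(a.mcc))

    def test_zero_division_policies(self):
        c = ConfusionCounts(0, 5, 0, 5)  # no positive predictions
        with pytest.raises(DomainError):
            metric_panel(c, zero_division="error")
        panel = metric_panel(c, zero_division="zero-with-flag")
        assert panel.precision == 0.0 and "precision" in panel.flags

    def test_mcc_near_zero_for_independent_predictions(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(200):
            t = rng.integers(0, 2, 200)
            p = rng.permutation(t)
            panel = metric_panel(tally_confusion(t, p), zero_division="zero-with-flag")
            vals.append(panel.mcc)
        assert abs(np.mean(vals)) < 3 * np.std(vals) / math.sqrt(len(vals)) + 0.01

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_panel_ranges(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        panel = metric_panel(ConfusionCounts(tp, tn, fp, fn), zero_division="zero-with-flag")
        for name in ("accuracy", "sensitivity", "specificity", "precision", "f1", "npv"):
            assert 0.0 <= getattr(panel, name) <= 1.0
        for name in ("mcc", "bm", "mk"):
            assert -1.0 - 1e-12 <= getattr(panel, name) <= 1.0 + 1e-12


class TestLikelihoodRatios:
    def test_best_optimized_model(self):
        lrs = likelihood_ratios(ConfusionCounts(38, 46, 3, 5))
        assert round_half_up(lrs.lr_plus, 2) == 14.43
        assert round_half_up(lrs.lr_minus, 4) == 0.1239
        assert round_half_up(lrs.dor, 2) == 116.53

    def test_default_xgboost(self):
        lrs = likelihood_ratios(ConfusionCounts(34, 40, 7, 11))
        assert round_half_up(lrs.lr_plus, 2) == 5.07
        assert round_half_up(lrs.lr_minus, 4) == 0.2872
        assert round_half_up(lrs.dor, 2) == 17.66

    def test_zero_fp_is_infinite_and_flagged(self):
        lrs = likelihood_ratios(ConfusionCounts(5, 5, 0, 5))
        assert math.isinf(lrs.lr_plus) and "lr_plus" in lrs.flags
        assert math.isinf(lrs.dor) and "dor" in lrs.flags

    def test_haldane_correction_is_finite(self):
        lrs = likelihood_ratios(ConfusionCounts(5, 5, 0, 5), haldane=True)
        assert math.isfinite(lrs.dor)

    def test_absent_class_rejected(self):
        with pytest.raises(DomainError):
            likelihood_ratios(ConfusionCounts(0, 5, 5, 0))

    def test_dor_cross_product_identity_exhaustive(self):
        # DOR = LR+/LR- collapses algebraically to (tp*tn)/(fp*fn)
        for tp, tn, fp, fn in itertools.product(range(1, 11), repeat=4):
            lrs = likelihood_ratios(ConfusionCounts(tp, tn, fp, fn))
            assert lrs.dor == pytest.approx((tp * tn) / (fp * fn))
            assert lrs.dor == pytest.approx(lrs.lr_plus / lrs.lr_minus)

    def test_label_swap_inverts_ratios(self):
        c = ConfusionCounts(17, 23, 4, 9)
        a, b = likelihood_ratios(c), likelihood_ratios(c.swapped())
        assert b.lr_plus == pytest.approx(1.0 / a.lr_minus)
        assert b.lr_minus == pytest.approx(1.0 / a.lr_plus)
        assert b.dor == pytest.approx(a.dor)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, fpr, tpr = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_inverted_scores(self):
        auc, *_ = roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert auc == 0.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        t = rng.integers(0, 2, 30)
        t[0], t[1] = 0, 1  # both classes present
        s = np.round(rng.uniform(size=30), 1)  # ties likely
        auc, *_ = roc_auc(s, t)
        pos, neg = s[t == 1], s[t == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([0.1, 0.9], [1, 1])


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(0.91304 * 100, 2, 91.30), (0.125, 2, 0.13), (2.675, 2, 2.68), (116.533, 2, 116.53)],
    )
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected
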