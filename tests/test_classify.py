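import itertools

import numpy as np
import pytest

from dcecad.classify import (
    FFBPN,
    confusion_metrics,
    mcnemar,
    roc_auc,
    smote_balance,
    train_eval_ffbpn,
    train_eval_svm,
)
from dcecad.phantom import separable_feature_clouds


class TestSmoteBalance:
    def _imbalanced(self, rng, n_min=20, n_maj=50):
        X = np.vstack([rng.normal(0, 1, (n_min, 3)), rng.normal(4, 1, (n_maj, 3))])
        y = np.array([1] * n_min + [0] * n_maj)
        return X, y

    def test_balances_class_counts(self, rng):
        X, y = self._imbalanced(rng)
        Xb, yb = smote_balance(X, y, seed=0)
        counts = np.bincount(yb)
        assert counts[0] == counts[1] == 50

    def test_originals_preserved(self, rng):
        X, y = self._imbalanced(rng)
        Xb, yb = smote_balance(X, y, seed=0)
        assert np.array_equal(Xb[: len(X)], X)
        assert np.array_equal(yb[: len(y)], y)

    def test_synthetic_points_lie_on_minority_segments(self, rng):
        X, y = self._imbalanced(rng)
        Xb, yb = smote_balance(X, y, seed=0)
        minority = X[y == 1]
        for s in Xb[len(X):]:
            on_segment = False
            for a, b in itertools.permutations(minority, 2):
                ab = b - a
                t = np.dot(s - a, ab) / np.dot(ab, ab)
                if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(a + t * ab - s) < 1e-9:
                    on_segment = True
                    break
            assert on_segment

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.repeat([0, 1], 10)
        Xb, yb = smote_balance(X, y, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_tiny_minority_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1] + [0] * 9)
        with pytest.raises(ValueError):
            smote_balance(X, y)


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(tp=12, fp=2, tn=10, fn=1)
        assert m.accuracy == pytest.approx(22 / 25)
        assert m.sensitivity == pytest.approx(12 / 13)
        assert m.specificity == pytest.approx(10 / 12)
        assert m.precision == pytest.approx(12 / 14)

    def test_perfect_classifier(self):
        m = confusion_metrics(tp=5, fp=0, tn=5, fn=0)
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision) == (1, 1, 1, 1)

    def test_no_false_negatives_gives_full_sensitivity(self):
        assert confusion_metrics(tp=3, fp=9, tn=1, fn=0).sensitivity == 1.0

    def test_zero_denominators_reported_as_none(self):
        m = confusion_metrics(tp=0, fp=0, tn=4, fn=0)
        assert m.sensitivity is None and m.precision is None
        assert m.specificity == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 0, 1)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == 0.5

    def test_pairwise_ranking_example(self):
        # 3 of the 4 positive-negative pairs correctly ordered
        _, auc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestMcNemar:
    @staticmethod
    def _preds(b, c, n_concordant=30):
        y = np.zeros(b + c + n_concordant, int)
        a_pred = y.copy()
        b_pred = y.copy()
        b_pred[:b] = 1          # A right, B wrong
        a_pred[b : b + c] = 1   # A wrong, B right
        return y, a_pred, b_pred

    @pytest.mark.parametrize(
        "b,c,exact,midp",
        [
            (2, 3, 0.8125, 0.65625),      # SVM vs 6-unit network
            (5, 4, 0.5, 0.376953125),     # SVM vs 10-unit network
        ],
    )
    def test_one_sided_binomial_values(self, b, c, exact, midp):
        y, pa, pb = self._preds(b, c)
        res_e = mcnemar(y, pa, pb, variant="exact-conditional", alternative="A-better")
        res_m = mcnemar(y, pa, pb, variant="mid-p", alternative="A-better")
        assert res_e.p == pytest.approx(exact, abs=1e-6)
        assert res_m.p == pytest.approx(midp, abs=1e-6)
        assert res_e.h == 0 and res_m.h == 0

    def test_exact_at_least_mid_p(self, rng):
        for _ in range(20):
            b, c = rng.integers(0, 8, 2)
            if b + c == 0:
                continue
            y, pa, pb = self._preds(int(b), int(c))
            p_e = mcnemar(y, pa, pb, variant="exact-conditional",
                          alternative="A-better").p
            p_m = mcnemar(y, pa, pb, variant="mid-p", alternative="A-better").p
            assert p_e >= p_m > 0

    def test_exact_conditional_equals_enumeration(self):
        """For n = b + c <= 12 discordant pairs the conditional binomial
        p-value equals direct enumeration over all 2^n discordance
        patterns."""
        for b, c in [(2, 3), (5, 4), (0, 6), (6, 6), (1, 0), (7, 5)]:
            n = b + c
            count_ge = sum(
                1 for bits in itertools.product([0, 1], repeat=n)
                if sum(bits) >= b
            )
            y, pa, pb = self._preds(b, c)
            res = mcnemar(y, pa, pb, variant="exact-conditional",
                          alternative="A-better")
            assert res.p == pytest.approx(count_ge / 2**n, abs=1e-12)
            # mid-p: half the observed statistic's mass
            count_gt = sum(
                1 for bits in itertools.product([0, 1], repeat=n)
                if sum(bits) > b
            )
            count_eq = sum(
                1 for bits in itertools.product([0, 1], repeat=n)
                if sum(bits) == b
            )
            res_m = mcnemar(y, pa, pb, variant="mid-p", alternative="A-better")
            assert res_m.p == pytest.approx(
                (count_gt + 0.5 * count_eq) / 2**n, abs=1e-12
            )

    def test_no_discordance_is_degenerate(self):
        y = np.zeros(10, int)
        res = mcnemar(y, y, y)
        assert res.p == 1.0 and res.h == 0 and res.degenerate

    def test_two_sided_exact_matches_reference(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(2, 9), (8, 3), (5, 5)]:
            y, pa, pb = self._preds(b, c)
            ours = mcnemar(y, pa, pb, variant="exact-conditional",
                           alternative="two-sided").p
            table = [[30, c], [b, 30]]  # discordant cells: (A wrong,B right)=c
            ref = sm_mcnemar(table, exact=True).pvalue
            assert ours == pytest.approx(ref, abs=1e-9)


class TestFFBPN:
    def test_two_output_units_argmax_prediction(self):
        X, y = separable_feature_clouds(n=200, seed=2)
        net = FFBPN(n_hidden=6, seed=0).fit(X, y)
        scores = net.decision_scores(X)
        assert scores.shape == (200,)
        assert np.array_equal(net.predict(X), (scores > 0).astype(int))

    def test_learns_separable_problem(self):
        X, y = separable_feature_clouds(n=200, seed=2)
        net = FFBPN(n_hidden=6, seed=0).fit(X, y)
        assert (net.predict(X) == y).mean() >= 0.95


class TestTrainEval:
    def test_ffbpn_split_sizes_65_15_20(self):
        """n=200 must split 130/30/40 train/validation/test."""
        from sklearn.model_selection import train_test_split

        idx = np.arange(200)
        y = np.repeat([0, 1], 100)
        trv, te = train_test_split(idx, test_size=0.20, stratify=y, random_state=0)
        tr, va = train_test_split(trv, test_size=0.15 / 0.80, stratify=y[trv],
                                  random_state=1)
        assert (len(tr), len(va), len(te)) == (130, 30, 40)

    def test_ffbpn_reports_five_repeats(self):
        X, y = separable_feature_clouds(n=200, seed=2)
        rep, test_idx, pred = train_eval_ffbpn(X, y, hidden_n=6, repeats=5, seed=1)
        assert len(rep.repeats) == 5
        assert len(test_idx) == len(pred) == 40
        assert "accuracy" in rep.mean_metrics

    def test_svm_every_sample_predicted_once(self):
        X, y = separable_feature_clouds(n=150, seed=3)
        rep, y_all, pred = train_eval_svm(X, y, seed=0, tune=False)
        assert len(pred) == len(y)
        n = rep.metrics
        assert n.tp + n.fp + n.tn + n.fn == len(y)

    def test_svm_metric_ranges(self):
        X, y = separable_feature_clouds(n=150, seed=3)
        rep, _, _ = train_eval_svm(X, y, seed=0, tune=False)
        assert 0.9 <= rep.auc <= 1.0
        assert rep.metrics.sensitivity >= 0.9
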