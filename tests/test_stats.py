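"""Statistics battery: logistic recalibration, Hosmer-Lemeshow, AUC, OCC."""

import numpy as np
import pytest
from scipy.special import expit

from icubench.stats import (
    DegenerateDataError,
    SeparationError,
    fit_score_logistic,
    hosmer_lemeshow,
    occ,
    roc_auc,
)


class TestLogistic:
    def test_symmetric_design_gives_or_one(self):
        """Outcome independent of score in a balanced symmetric design."""
        scores = [1, 1, 2, 2, 3, 3, 4, 4] * 10
        outcomes = [0, 1] * 40
        fit = fit_score_logistic(scores, outcomes)
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert fit.odds_ratio == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_mle(self):
        """Slope agrees with an independent nested grid-search MLE."""
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 15, size=20).astype(float)
        outcomes = (rng.random(20) < expit(-2.0 + 0.3 * scores)).astype(int)

        def loglik(a, b):
            eta = a + b * scores
            return float(np.sum(outcomes * eta - np.log1p(np.exp(eta))))

        a_lo, a_hi, b_lo, b_hi = -8.0, 4.0, -2.0, 2.0
        for _ in range(8):  # successive grid refinement
            aa = np.linspace(a_lo, a_hi, 41)
            bb = np.linspace(b_lo, b_hi, 41)
            ll = np.array([[loglik(a, b) for b in bb] for a in aa])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            da, db = aa[1] - aa[0], bb[1] - bb[0]
            a_lo, a_hi = aa[i] - da, aa[i] + da
            b_lo, b_hi = bb[j] - db, bb[j] + db
        fit = fit_score_logistic(scores, outcomes)
        assert fit.slope == pytest.approx((b_lo + b_hi) / 2, abs=1e-3)
        assert fit.or_ci_low <= fit.odds_ratio <= fit.or_ci_high
        assert np.all((fit.predicted > 0) & (fit.predicted < 1))

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_score_logistic([5] * 20, [0, 1] * 10)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_score_logistic(range(20), [0] * 20)

    def test_complete_separation_flagged(self):
        scores = list(range(20))
        outcomes = [0] * 10 + [1] * 10
        with pytest.raises(SeparationError):
            fit_score_logistic(scores, outcomes)


class TestHosmerLemeshow:
    def test_perfect_calibration_in_expectation(self):
        """Observed deaths equal to expected in every group give chi2 ~ 0."""
        p = np.repeat([0.1, 0.2, 0.3, 0.4, 0.5], 10)
        y = np.concatenate([[1] * int(round(q * 10)) + [0] * int(round(10 - q * 10))
                            for q in (0.1, 0.2, 0.3, 0.4, 0.5)])
        res = hosmer_lemeshow(p, y, g=5)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_group_table(self):
        """chi2 equals an independently computed decile group table."""
        rng = np.random.default_rng(11)
        p = np.sort(rng.uniform(0.02, 0.9, 200))
        y = (rng.random(200) < p).astype(int)
        res = hosmer_lemeshow(p, y, g=10)
        # independent spreadsheet-style computation: 10 ordered groups of 20
        chi2 = 0.0
        for k in range(10):
            sl = slice(20 * k, 20 * (k + 1))
            n_g, o, e = 20.0, y[sl].sum(), p[sl].sum()
            chi2 += (o - e) ** 2 / (e * (1 - e / n_g))
        assert res.n_groups == 10
        assert res.df == 8
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, 150)
        y = (rng.random(150) < p).astype(int)
        perm = rng.permutation(150)
        a = hosmer_lemeshow(p, y)
        b = hosmer_lemeshow(p[perm], y[perm])
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 5, [0, 1, 0, 1, 0], g=10)  # n < g
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.0, 0.5] * 10, [0, 1] * 10)  # p not in (0,1)


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_all_ties_is_chance(self):
        res = roc_auc([5] * 10, [0, 1] * 5)
        assert res.auc == 0.5

    def test_pair_enumeration_example(self):
        """Survivors {1,3}, non-survivors {2,4}: 3 of 4 pairs concordant."""
        res = roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_anti_discrimination_reported_as_is(self):
        res = roc_auc([10, 9, 8, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert res.auc == 0.0

    def test_delong_ci_matches_pROC_oracle(self):
        """Frozen oracle: R pROC ci.auc(..., method='delong') on this dataset."""
        scores = [3, 7, 2, 9, 5, 8, 1, 6, 4, 10, 7, 3, 8, 2, 9, 6, 5, 11, 4, 8,
                  12, 3, 7, 10, 6]
        outcome = [0, 1, 0, 1, 0, 1, 0, 0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 0, 0,
                   1, 0, 0, 1, 0]
        res = roc_auc(scores, outcome, ci_method="delong")
        assert res.auc == pytest.approx(0.953333333333, abs=1e-12)
        assert res.ci_low == pytest.approx(0.883170962075, abs=1e-9)
        assert res.ci_high == 1.0  # clipped

    def test_hanley_mcneil_ci_brackets_auc(self):
        res = roc_auc([1, 3, 2, 4, 5, 7, 6, 8], [0, 0, 0, 1, 0, 1, 1, 1],
                      ci_method="hanley-mcneil")
        assert res.ci_low <= res.auc <= res.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_brute_force_equivalence_random(self):
        """Rank AUC equals exhaustive pair counting on random data."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            x = rng.integers(0, 30, n).astype(float)
            y = np.zeros(n, int)
            y[rng.choice(n, size=max(1, n // 5), replace=False)] = 1
            if y.sum() == 0 or y.sum() == n:
                continue
            pos, neg = x[y == 1], x[y == 0]
            brute = np.mean(
                (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert roc_auc(x, y).auc == pytest.approx(brute, abs=1e-12)


class TestOCC:
    def test_all_correct(self):
        assert occ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 100.0

    def test_counting(self):
        p = [0.9] * 45 + [0.1] * 45 + [0.9] * 5 + [0.1] * 5
        y = [1] * 45 + [0] * 45 + [0] * 5 + [1] * 5
        assert occ(p, y) == pytest.approx(90.0)

    def test_rare_event_majority_class(self):
        """All predictions below cutoff: OCC is the survivor fraction x 100."""
        p = [0.05] * 95 + [0.4] * 5
        y = [0] * 95 + [1] * 5
        assert occ(p, y) == pytest.approx(95.0)

    def test_matches_confusion_matrix(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(0, 1, 300)
        y = (rng.random(300) < p).astype(int)
        pred = (p >= 0.5).astype(int)
        assert occ(p, y) == pytest.approx(100 * (1 - np.mean(pred != y)))
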