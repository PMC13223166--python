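"""Cohort statistics: Youden cutoffs, 2x2 measures, logistic and stepwise."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lymphmap.stats import (
    ContingencyTable2x2,
    ForwardStepwiseLogistic,
    YoudenBinarizer,
    chi_square_2x2,
    dichotomize,
    fit_logistic,
    forward_stepwise,
    mann_whitney_u,
    odds_ratio_2x2,
    youden_cutoff,
)


class TestYoudenCutoff:
    def test_perfect_separation(self):
        res = youden_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.threshold == 10 and res.youden_j == pytest.approx(1.0)

    def test_overlapping_groups_brute_force_value(self):
        # candidates {1,4,5,6,7,9}: J maximal (2/3) at 5 and 7; smallest wins
        res = youden_cutoff([1, 4, 6, 5, 7, 9], [0, 0, 0, 1, 1, 1])
        assert res.threshold == 5
        assert res.youden_j == pytest.approx(2 / 3)
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1, abs=1e-12)

    def test_fixed_clinical_cutoff_categorises_above(self):
        assert dichotomize([300.0], 264.5)[0] == 1  # CA125 above-cutoff category
        assert dichotomize([200.0], 264.5)[0] == 0

    def test_one_class_absent_raises(self):
        with pytest.raises(ValueError, match="class"):
            youden_cutoff([1, 2, 3], [1, 1, 1])

    def test_matches_exhaustive_search_on_random_data(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=60)
        y = (rng.random(60) < 0.4).astype(int)
        res = youden_cutoff(v, y)
        n1, n0 = y.sum(), (1 - y).sum()
        best = max(
            ((v >= t) & (y == 1)).sum() / n1 + ((v < t) & (y == 0)).sum() / n0 - 1
            for t in v
        )
        assert res.youden_j == pytest.approx(best, abs=1e-12)


class TestOddsRatio:
    def test_lateralization_counts_match_reported_or(self):
        res = odds_ratio_2x2(ContingencyTable2x2(254, 110, 109, 181))
        assert round(res.odds_ratio, 2) == 3.83
        assert round(res.ci_low, 2) == 2.77
        assert round(res.ci_high, 2) == 5.31

    def test_symmetric_table_gives_unity(self):
        res = odds_ratio_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_haldane_anscombe_zero_cell(self):
        res = odds_ratio_2x2(ContingencyTable2x2(5, 0, 5, 5), correction=True)
        # (5.5 * 5.5) / (5.5 * 0.5) = 11
        assert res.odds_ratio == pytest.approx(11.0)
        assert res.corrected

    def test_zero_cell_without_correction_names_cell(self):
        with pytest.raises(ValueError, match="n01"):
            odds_ratio_2x2(ContingencyTable2x2(5, 0, 5, 5))

    def test_ci_brackets_point_estimate(self):
        res = odds_ratio_2x2(ContingencyTable2x2(20, 15, 8, 30))
        assert res.ci_low < res.odds_ratio < res.ci_high


class TestChiSquare:
    def test_closed_form_value(self):
        stat, _ = chi_square_2x2(ContingencyTable2x2(10, 20, 20, 10))
        assert stat == pytest.approx(20 / 3, abs=1e-9)

    def test_independence_gives_zero(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 20, 20))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_under_swaps(self):
        a = chi_square_2x2(ContingencyTable2x2(7, 13, 21, 9))[0]
        b = chi_square_2x2(ContingencyTable2x2(21, 9, 7, 13))[0]   # row swap
        c = chi_square_2x2(ContingencyTable2x2(13, 7, 9, 21))[0]   # column swap
        assert a == pytest.approx(b) == pytest.approx(c)

    def test_zero_marginal_raises(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2(ContingencyTable2x2(0, 10, 0, 20))


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_give_half(self):
        u, _ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(8.0)  # n^2 / 2

    def test_u_conservation(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=12), rng.normal(1, 1, size=9)
        ua, _ = mann_whitney_u(a, b)
        ub, _ = mann_whitney_u(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestLogistic:
    def test_two_by_two_fit_reproduces_reported_or(self):
        tab = ContingencyTable2x2(254, 110, 109, 181)
        x = np.repeat([0, 0, 1, 1], [tab.n00, tab.n01, tab.n10, tab.n11])
        y = np.repeat([0, 1, 0, 1], [tab.n00, tab.n01, tab.n10, tab.n11])
        fit = fit_logistic(x.reshape(-1, 1), y)
        assert round(float(np.exp(fit.coefficients[1])), 2) == 3.83

    def test_exp_beta_equals_closed_form_or(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            cells = rng.integers(5, 80, 4)
            tab = ContingencyTable2x2(*[int(c) for c in cells])
            x = np.repeat([0, 0, 1, 1], cells)
            y = np.repeat([0, 1, 0, 1], cells)
            fit = fit_logistic(x.reshape(-1, 1), y)
            expected = (cells[3] * cells[0]) / (cells[2] * cells[1])
            assert np.exp(fit.coefficients[1]) == pytest.approx(expected, rel=1e-6)

    def test_balanced_independent_predictor_gives_zero_beta(self):
        x = np.array([0, 0, 1, 1] * 25)
        y = np.array([0, 1, 0, 1] * 25)
        fit = fit_logistic(x.reshape(-1, 1), y)
        assert abs(fit.coefficients[1]) < 1e-6

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 2))
        eta = 0.5 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
        assert np.allclose(fit.standard_errors, ref.bse, atol=1e-4)

    def test_separation_flagged(self):
        x = np.array([0] * 20 + [1] * 20)
        fit = fit_logistic(x.reshape(-1, 1), x)  # outcome == predictor
        assert fit.separation_flag

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones((10, 1)), [0, 1] * 5)


class TestForwardStepwise:
    @staticmethod
    def _planted(seed, n=1000, effect=1.5):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({
            "signal": (rng.random(n) < 0.5).astype(int),
            "noise1": (rng.random(n) < 0.5).astype(int),
            "noise2": (rng.random(n) < 0.5).astype(int),
        })
        eta = -0.5 + effect * X["signal"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return X, y

    def test_selects_exactly_the_planted_predictor(self):
        X, y = self._planted(seed=21)
        res = forward_stepwise(X, y, alpha_in=0.05)
        assert res.selected == ["signal"]

    def test_type_i_error_control_under_pure_noise(self):
        # per-candidate entry probability is ~alpha, so the chance of an
        # intercept-only model is ~(1 - alpha)^k; with one noise candidate
        # it must stay >= 90%, and with three it can only degrade ~alpha
        # per extra candidate
        empty_one = empty_three = 0
        for seed in range(100):
            rng = np.random.default_rng(5000 + seed)
            X = pd.DataFrame((rng.random((1000, 3)) < 0.5).astype(int),
                             columns=["a", "b", "c"])
            y = (rng.random(1000) < 0.4).astype(int)
            if not forward_stepwise(X[["a"]], y, alpha_in=0.05).selected:
                empty_one += 1
            if not forward_stepwise(X, y, alpha_in=0.05).selected:
                empty_three += 1
        assert empty_one >= 90
        assert empty_three >= 75

    def test_alpha_zero_selects_nothing(self):
        X, y = self._planted(seed=3)
        assert forward_stepwise(X, y, alpha_in=0.0).selected == []


class TestEstimators:
    def test_youden_binarizer_transform(self):
        X = pd.DataFrame({"m": [1, 2, 3, 10, 11, 12]})
        y = [0, 0, 0, 1, 1, 1]
        bz = YoudenBinarizer().fit(X, y)
        assert bz.thresholds_[0] == 10
        assert list(bz.transform(X)[:, 0]) == y

    def test_stepwise_estimator_predicts(self):
        X, y = TestForwardStepwise._planted(seed=9)
        est = ForwardStepwiseLogistic(alpha_in=0.05).fit(X, y)
        assert est.selected_ == ["signal"]
        proba = est.predict_proba(X)
        assert proba.shape == (len(X), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
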