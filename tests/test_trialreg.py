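"""Single-trial regression: ranks, OLS exactness, AIC, group inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from toteeg import (SessionConfig, compare_models_aic, coefficient_contrast,
                    fit_trial_regression, generate_trial_table,
                    group_level_test, rank_transform)
from toteeg.trialreg import TINY_P, RegressionFit, fit_trial_regression_maps


def make_table(n=50, seed=0):
    cfg = SessionConfig.null_regime(n_participants=1, trials_per_block=n // 5,
                                    n_blocks=5, seed=seed)
    return generate_trial_table(cfg, 1)


class TestRankTransform:
    def test_simple_order(self):
        assert np.allclose(rank_transform([3.2, 1.1, 7.7]), [2, 1, 3])

    def test_average_ties(self):
        assert np.allclose(rank_transform([5, 5, 9]), [1.5, 1.5, 3])

    def test_missing_stays_missing(self):
        out = rank_transform([2.0, np.nan, 1.0])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [2, 1])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rank_transform([np.nan, np.nan])

    @settings(deadline=None, max_examples=25)
    @given(st.permutations(list(range(8))))
    def test_permutation_equivariance(self, perm):
        base = np.array([0.3, 1.7, -2.0, 5.5, 0.0, 9.1, -0.4, 2.2])
        ranks = rank_transform(base)
        perm = np.asarray(perm)
        assert np.allclose(rank_transform(base[perm]), ranks[perm])


class TestFitTrialRegression:
    def test_exact_linear_model_recovered(self):
        table = make_table(50, seed=1)
        y = 2.0 * rank_transform(table["rt"])
        fit = fit_trial_regression(y, table, include_tot=False, rank_outcome=False)
        assert fit.coefs["rt"] == pytest.approx(2.0, abs=1e-8)
        for name in ("confidence", "difficulty", "accuracy"):
            assert fit.coefs[name] == pytest.approx(0.0, abs=1e-7)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_aic_matches_by_hand_six_trials(self):
        """AIC = n ln(RSS/n) + 2k on a hand-computable 6-trial design."""
        table = pd.DataFrame({
            "participant": 1, "block": 1, "trial_order": range(1, 7),
            "within_block_index": range(1, 7),
            "contrast": [0.075, 0.15, 0.225, 0.3, 0.375, 0.075],
            "stimclass": "number",
            "accuracy": [0, 1, 1, 0, 1, 1], "confidence": [0, 0, 1, 1, 1, 0],
            "rt": [0.9, 0.8, 0.7, 0.75, 0.6, 0.85],
        })
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 1.0])
        fit = fit_trial_regression(y, table, include_tot=False, rank_outcome=False)
        X = np.column_stack([
            np.ones(6), table["confidence"], table["contrast"],
            table["accuracy"], rank_transform(table["rt"])])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = np.sum((y - X @ beta) ** 2)
        k = 4 + 1 + 1  # slopes + intercept + error variance
        assert fit.aic == pytest.approx(6 * np.log(rss / 6) + 2 * k, abs=1e-9)

    def test_adding_constant_changes_only_intercept(self):
        table = make_table(50, seed=2)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(len(table))
        a = fit_trial_regression(y, table, include_tot=True, rank_outcome=False)
        b = fit_trial_regression(y + 11.0, table, include_tot=True, rank_outcome=False)
        assert b.intercept == pytest.approx(a.intercept + 11.0, abs=1e-8)
        for name, val in a.coefs.items():
            assert b.coefs[name] == pytest.approx(val, abs=1e-8)

    def test_constant_predictor_left_undefined(self):
        table = make_table(50, seed=3)
        table["confidence"] = 1  # degenerate: always confident
        y = np.random.default_rng(1).standard_normal(len(table))
        fit = fit_trial_regression(y, table)
        assert np.isnan(fit.coefs["confidence"])
        assert np.isfinite(fit.coefs["rt"])

    def test_noise_outcome_penalises_tot_model(self):
        """For pure noise the extra ToT predictor loses on AIC on average."""
        table = make_table(50, seed=4)
        rng = np.random.default_rng(7)
        deltas = []
        for _ in range(200):
            y = rng.standard_normal(len(table))
            no = fit_trial_regression(y, table, include_tot=False)
            wi = fit_trial_regression(y, table, include_tot=True)
            deltas.append(no.aic - wi.aic)
        assert np.mean(deltas) < 0

    def test_tot_penalty_bound_when_rss_equal(self):
        table = make_table(50, seed=5)
        y = 2.0 * rank_transform(table["rt"])  # perfect fit in both models
        no = fit_trial_regression(y, table, include_tot=False, rank_outcome=False)
        wi = fit_trial_regression(y, table, include_tot=True, rank_outcome=False)
        assert wi.aic >= no.aic - 2.0

    def test_vectorised_maps_agree_with_scalar_path(self):
        table = make_table(50, seed=6)
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((len(table), 3))
        coefs, aic = fit_trial_regression_maps(Y, table, include_tot=True)
        for j in range(3):
            fit = fit_trial_regression(Y[:, j], table, include_tot=True)
            assert aic[j] == pytest.approx(fit.aic, abs=1e-8)
            assert coefs[-1, j] == pytest.approx(fit.coefs["tot"], abs=1e-8)


def _fits_from(values, predictor="rt"):
    fits = []
    for pid, v in enumerate(values, start=1):
        coefs = {"confidence": 0.0, "difficulty": 0.0, "accuracy": 0.0, "rt": v}
        fits.append(RegressionFit(
            participant=pid, outcome="x", model="noToT", intercept=0.0,
            coefs=coefs, resid_var=1.0, n=50, aic=0.0, r_squared=0.5,
            trial_index=np.arange(50)))
    return fits


class TestGroupLevel:
    def test_closed_form_t_statistic(self):
        out = group_level_test(_fits_from([1.0, 2.0, 3.0]), predictors=("rt",))
        row = out.iloc[0]
        assert row["t"] == pytest.approx(2.0 * np.sqrt(3.0))
        assert row["df"] == 2
        assert row["cohen_d"] == pytest.approx(2.0)
        assert row["p"] == pytest.approx(
            2 * stats.t.sf(2.0 * np.sqrt(3.0), 2), abs=1e-12)

    def test_degenerate_zero_variance_signalled(self):
        out = group_level_test(_fits_from([0.7, 0.7, 0.7, 0.7]), predictors=("rt",))
        assert out.iloc[0]["p"] == TINY_P
        assert np.isinf(out.iloc[0]["t"])

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            group_level_test(_fits_from([1.0, 2.0]))

    def test_type_one_error_rate_nominal(self):
        """N(0,1) coefficients, n=36: rejection rate ~ alpha."""
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            t, p = stats.ttest_1samp(rng.standard_normal(36), 0.0)
            hits += p < 0.05
        # same machinery through the package on a subsample of simulations
        out = group_level_test(_fits_from(rng.standard_normal(36)), predictors=("rt",))
        assert 0.03 <= hits / n_sim <= 0.07
        assert 0.0 < out.iloc[0]["p"] <= 1.0

    def test_fdr_is_monotone_in_p(self):
        fits = []
        rng = np.random.default_rng(3)
        for pid in range(1, 13):
            coefs = {"confidence": rng.normal(), "difficulty": rng.normal(),
                     "accuracy": rng.normal(), "rt": 1.0 + 0.1 * rng.normal()}
            fits.append(RegressionFit(pid, "x", "noToT", 0.0, coefs, 1.0, 50,
                                      0.0, 0.5, np.arange(50)))
        out = group_level_test(fits)
        assert (out["p_fdr"] >= out["p"] - 1e-15).all()


class TestModelComparison:
    def test_identical_fits_give_zero_delta(self):
        fits = _fits_from([1.0, 2.0, 3.0])
        cmp = compare_models_aic(fits, fits)
        assert np.allclose(cmp.delta_aic, 0.0)
        assert cmp.t == 0.0 and cmp.p == 1.0

    def test_constant_nonzero_delta_signalled(self):
        a = _fits_from([1.0, 1.0, 1.0, 1.0])
        b = _fits_from([1.0, 1.0, 1.0, 1.0])
        for f in b:
            f.aic = -1.0  # every participant improves by exactly 1
        cmp = compare_models_aic(a, b)
        assert np.allclose(cmp.delta_aic, 1.0)
        assert np.isinf(cmp.t) and cmp.p == TINY_P

    def test_mismatched_participants_rejected(self):
        a = _fits_from([1.0, 2.0, 3.0])
        b = _fits_from([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            compare_models_aic(a, b)

    def test_different_trial_sets_rejected(self):
        a = _fits_from([1.0, 2.0, 3.0])
        b = _fits_from([1.0, 2.0, 3.0])
        b[0].trial_index = np.arange(1, 51)
        with pytest.raises(ValueError):
            compare_models_aic(a, b)


class TestCoefficientContrast:
    def test_identical_models_no_difference(self):
        fits = _fits_from([1.0, 2.0, 3.0])
        out = coefficient_contrast(fits, fits, predictor="rt")
        assert out["mean_diff"] == 0.0 and out["t"] == 0.0

    def test_shifted_coefficients_detected(self):
        a = _fits_from([1.0, 1.2, 0.9, 1.1, 1.0])
        b = _fits_from([0.1, 0.15, 0.05, 0.12, 0.08])
        out = coefficient_contrast(a, b, predictor="rt")
        assert out["mean_diff"] < 0
        assert out["p"] < 0.01
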