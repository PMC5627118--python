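"""Best-subset enumeration, BIC machinery, averaging and AR(1) checks."""

import math

import numpy as np
import pandas as pd
import pytest

from monarch_threats.datagen import reduced_study_config, simulate_dataset
from monarch_threats.modelsel import (
    CandidateFit,
    ModelSet,
    bic,
    confidence_set,
    enumerate_models,
    fit_ar1_gls,
    fit_gompertz,
    fit_gompertz as _fit,
    model_average,
    model_weights,
    rank_models,
    residual_acf,
    variable_importance,
)


def toy_model_set(weights, subsets, coefs=None):
    """Hand-built ModelSet with prescribed weights for derived checks."""
    variables = sorted({v for s in subsets for v in s})
    fits = []
    for i, (w, s) in enumerate(zip(weights, subsets)):
        fits.append(
            CandidateFit(
                subset=tuple(s),
                coefficients=coefs[i] if coefs else dict.fromkeys(s, 0.0),
                intercept=0.0,
                sigma2_hat=1.0,
                loglik=0.0,
                r2=0.0,
                bic=float(i),
                delta_bic=float(i),
                weight=w,
            )
        )
    return ModelSet(fits=fits, variables=variables, n_years=22)


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_vars,min_size,max_size,exact,expected",
        [
            (11, 4, 4, True, 330),
            (3, 1, 2, False, 6),
            (5, 2, 2, True, 10),
        ],
    )
    def test_counts(self, n_vars, min_size, max_size, exact, expected):
        names = [f"v{i}" for i in range(n_vars)]
        subsets = enumerate_models(names, min_size, max_size, exact)
        assert len(subsets) == expected
        assert len(set(subsets)) == expected  # no duplicates

    def test_lexicographic_and_deterministic(self):
        subsets = enumerate_models(["a", "b", "c"], 1, 2)
        assert subsets == [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models([], 1, 1)


class TestGompertzFit:
    def test_noiseless_coefficients_recovered(self):
        config = reduced_study_config(seed=3)
        config = type(config)(**{**vars(config), "noise_sd": 0.0})
        dataset, truth = simulate_dataset(config)
        fit = fit_gompertz(
            dataset.covariates, dataset.response, list(truth.coefficients)
        )
        for name, value in truth.coefficients.items():
            assert fit.coefficients[name] == pytest.approx(value, abs=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self, small_dataset):
        dataset, _ = small_dataset
        subset = list(dataset.covariates.columns[:3])
        fit = fit_gompertz(dataset.covariates, dataset.response, subset)
        Z = dataset.covariates[subset]
        Z = (Z - Z.mean()) / Z.std(ddof=1)
        design = np.column_stack([np.ones(len(Z)), Z.to_numpy()])
        beta = np.linalg.solve(
            design.T @ design, design.T @ dataset.response.to_numpy()
        )
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert np.allclose(list(fit.coefficients.values()), beta[1:], atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, small_dataset):
        dataset, _ = small_dataset
        subset = list(dataset.covariates.columns[:4])
        fit = fit_gompertz(dataset.covariates, dataset.response, subset)
        Z = dataset.covariates[subset]
        Z = ((Z - Z.mean()) / Z.std(ddof=1)).to_numpy()
        assert np.abs(fit.residuals @ Z).max() < 1e-8

    def test_collinear_subset_flagged_singular(self, small_dataset):
        dataset, _ = small_dataset
        frame = dataset.covariates.assign(
            dup=dataset.covariates["climate_0_north_central"]
        )
        fit = fit_gompertz(frame, dataset.response, ["climate_0_north_central", "dup"])
        assert fit.singular
        assert not math.isfinite(fit.bic)


class TestBic:
    @pytest.mark.parametrize(
        "loglik,n_cov,expected",
        [(10.86, 3, -6.26), (6.67, 3, 2.12)],
    )
    def test_printed_convention(self, loglik, n_cov, expected):
        assert bic(loglik, n_cov, 22) == pytest.approx(expected, abs=0.005)

    def test_degenerate_zero(self):
        assert bic(0.0, 3, 1) == 0.0  # k*ln(1)=0 and loglik=0

    def test_nonfinite_loglik_rejected(self):
        with pytest.raises(ValueError):
            bic(math.inf, 2, 22)

    def test_monotone_in_loglik(self):
        assert bic(5.0, 2, 22) > bic(6.0, 2, 22)


class TestWeights:
    def test_single_model(self):
        delta, w = model_weights([3.7])
        assert w[0] == 1.0 and delta[0] == 0.0

    def test_symmetric_pair(self):
        _, w = model_weights([1.0, 1.0])
        assert np.allclose(w, [0.5, 0.5])

    def test_second_weight_from_printed_deltas(self):
        """With the top model at weight 0.919, a model 8.38 BIC units
        behind carries 0.919*exp(-4.19) ~ 0.014."""
        _, w = model_weights([0.0, 8.38])
        scaled = 0.919 * w[1] / w[0]
        assert scaled == pytest.approx(0.014, abs=5e-4)

    def test_sum_to_one_and_nonfinite_excluded(self):
        delta, w = model_weights([2.0, math.inf, 0.0])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[1] == 0.0
        assert delta[2] == 0.0


class TestDerivedQuantities:
    def test_importance_hand_sum(self):
        ms = toy_model_set(
            [0.6, 0.3, 0.1], [("a", "b"), ("b",), ("a", "c")]
        )
        imp = variable_importance(ms)
        assert imp["a"] == pytest.approx(0.7)
        assert imp["b"] == pytest.approx(0.9)
        assert imp["c"] == pytest.approx(0.1)

    def test_importance_bounds(self):
        ms = toy_model_set([1.0], [("a",)])
        imp = variable_importance(ms)
        assert imp["a"] == pytest.approx(1.0)

    def test_average_shrinks_absent_terms(self):
        ms = toy_model_set(
            [0.5, 0.5],
            [("a",), ("b",)],
            coefs=[{"a": 0.4}, {"b": 1.0}],
        )
        avg = model_average(ms)
        assert avg["a"] == pytest.approx(0.2)
        assert avg["b"] == pytest.approx(0.5)

    def test_confidence_set_only_averaging_renormalizes(self):
        ms = toy_model_set(
            [0.8, 0.2],
            [("a",), ("a", "b")],
            coefs=[{"a": 0.5}, {"a": 0.5, "b": 1.0}],
        )
        ms.fits[0].delta_bic, ms.fits[1].delta_bic = 0.0, 20.0
        full = model_average(ms)
        top_only = model_average(ms, within_delta=10.0)
        assert full["b"] == pytest.approx(0.2)
        assert top_only["b"] == pytest.approx(0.0)
        assert top_only["a"] == pytest.approx(0.5)  # weights renormalized

    def test_single_model_average_unchanged(self):
        ms = toy_model_set([1.0], [("a",)], coefs=[{"a": -0.5}])
        assert model_average(ms)["a"] == pytest.approx(-0.5)

    def test_average_bounded_by_importance_times_max(self, small_dataset):
        dataset, _ = small_dataset
        ms = rank_models(
            dataset.covariates, dataset.response,
            list(dataset.covariates.columns[:6]), max_size=2,
        )
        imp = variable_importance(ms)
        avg = model_average(ms)
        for v in ms.variables:
            max_beta = max(
                (abs(f.coefficients.get(v, 0.0)) for f in ms.fits if not f.singular),
                default=0.0,
            )
            assert abs(avg[v]) <= imp[v] * max_beta + 1e-12

    def test_confidence_set_rule(self):
        ms = toy_model_set([0.9, 0.05, 0.05], [("a",), ("b",), ("c",)])
        for f, d in zip(ms.fits, (0.0, 8.38, 12.0)):
            f.delta_bic = d
            f.bic = d
        kept = confidence_set(ms, delta_max=10.0)
        assert [f.subset for f in kept] == [("a",), ("b",)]
        assert len(confidence_set(ms, delta_max=0.0)) == 1
        assert len(confidence_set(ms, delta_max=15.0)) == 3


class TestTableConsistency:
    def test_bic_and_weights_recomputable_end_to_end(self, small_dataset):
        """Stored BIC and weights agree with recomputation from parts."""
        dataset, _ = small_dataset
        ms = rank_models(
            dataset.covariates, dataset.response,
            list(dataset.covariates.columns), max_size=3,
        )
        usable = [f for f in ms.fits if not f.singular]
        for f in usable:
            assert f.bic == pytest.approx(
                bic(f.loglik, len(f.subset), ms.n_years), abs=1e-12
            )
        delta, w = model_weights([f.bic for f in usable])
        assert np.allclose([f.weight for f in usable], w, atol=1e-12)
        assert sum(f.weight for f in usable) == pytest.approx(1.0, abs=1e-12)
        assert all(f.delta_bic >= 0 for f in usable)


class TestResidualAcf:
    def test_lag_zero_is_one(self, small_dataset):
        dataset, _ = small_dataset
        fit = _fit(dataset.covariates, dataset.response,
                   ["trend_0_north_central"])
        report = residual_acf(fit, n_lags=5)
        assert report["acf"].iloc[0] == pytest.approx(1.0)

    def test_alternating_residuals_lag1(self):
        fit = CandidateFit(
            subset=(), coefficients={}, intercept=0.0, sigma2_hat=1.0,
            loglik=0.0, r2=0.0, bic=0.0,
            residuals=np.tile([1.0, -1.0], 50),
        )
        report = residual_acf(fit, n_lags=2)
        assert report["acf"].iloc[1] == pytest.approx(-1.0, abs=0.05)
        assert bool(report["flagged"].iloc[1])

    def test_white_noise_rarely_flagged(self):
        rng = np.random.default_rng(7)
        n_reps, ok = 100, 0
        for _ in range(n_reps):
            fit = CandidateFit(
                subset=(), coefficients={}, intercept=0.0, sigma2_hat=1.0,
                loglik=0.0, r2=0.0, bic=0.0, residuals=rng.normal(size=500),
            )
            report = residual_acf(fit, n_lags=20)
            ok += report["flagged"].iloc[1:].mean() <= 0.10
        assert ok / n_reps >= 0.9

    def test_constant_residuals_rejected(self):
        fit = CandidateFit(
            subset=(), coefficients={}, intercept=0.0, sigma2_hat=0.0,
            loglik=0.0, r2=0.0, bic=0.0, residuals=np.ones(30),
        )
        with pytest.raises(ValueError, match="constant"):
            residual_acf(fit)


class TestAr1Gls:
    def ar1_frame(self, phi, n, seed, beta=0.5):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        eps = np.empty(n)
        eps[0] = rng.normal() * math.sqrt(1.0 / (1.0 - phi**2)) if phi else rng.normal()
        for t in range(1, n):
            eps[t] = phi * eps[t - 1] + rng.normal()
        y = 1.0 + beta * x + eps
        return pd.DataFrame({"x": x}), pd.Series(y)

    def test_loglik_at_phi_zero_nests_ols(self, small_dataset):
        dataset, _ = small_dataset
        from monarch_threats.modelsel import _ar1_loglik

        subset = ["trend_0_north_central", "climate_0_north_central"]
        ols = fit_gompertz(dataset.covariates, dataset.response, subset)
        Z = dataset.covariates[subset]
        Z = ((Z - Z.mean()) / Z.std(ddof=1)).to_numpy()
        design = np.column_stack([np.ones(len(Z)), Z])
        loglik0, *_ = _ar1_loglik(design, dataset.response.to_numpy(), 0.0)
        assert loglik0 == pytest.approx(ols.loglik, abs=1e-8)

    def test_phi_recovery_null(self):
        estimates = []
        for seed in range(40):
            frame, y = self.ar1_frame(0.0, 100, seed)
            fit, _ = fit_ar1_gls(frame, y, ["x"])
            estimates.append(fit.phi)
        assert abs(np.median(estimates)) <= 0.25

    def test_phi_recovery_at_0p6(self):
        estimates = []
        for seed in range(40):
            frame, y = self.ar1_frame(0.6, 200, seed)
            fit, _ = fit_ar1_gls(frame, y, ["x"])
            estimates.append(fit.phi)
        assert abs(np.median(estimates) - 0.6) <= 0.1

    def test_bic_comparison_prefers_ols_for_white_noise(self):
        frame, y = self.ar1_frame(0.0, 80, seed=5)
        _, delta = fit_ar1_gls(frame, y, ["x"])
        assert delta > 0  # extra phi parameter not worth it


class TestRecoveryStudy:
    def test_true_subset_in_confidence_set_and_dominant_importance(self):
        """At the study's n=22, the generating subset stays inside the
        10-unit BIC confidence set and the dominant trend covariate
        out-ranks every inactive variable in importance."""
        truth_subset = (
            "climate_0_north_central",
            "climate_1_north_central",
            "trend_0_north_central",
        )
        in_set, dominant = 0, 0
        n_reps = 50
        for rep in range(n_reps):
            dataset, _ = simulate_dataset(reduced_study_config(seed=5000 + rep))
            ms = rank_models(
                dataset.covariates, dataset.response,
                sorted(dataset.covariates.columns), max_size=4,
            )
            conf = {tuple(sorted(f.subset)) for f in confidence_set(ms, 10.0)}
            in_set += tuple(sorted(truth_subset)) in conf
            imp = variable_importance(ms)
            inactive = [v for v in ms.variables if v not in truth_subset]
            dominant += imp["trend_0_north_central"] > imp[inactive].max()
        assert in_set / n_reps >= 0.8
        assert dominant / n_reps >= 0.9
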