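"""Unit and property tests for the two-stage hurdle model."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from bethedge.hurdle import (
    StageFit,
    compare_submodels,
    fit_binomial_stage,
    fit_yield_stage,
    log_precip,
    observed_to_low_density_yield,
    offset_yield,
    pairwise_wald,
    prepare_hurdle_data,
    reproduction_probability,
    sample_low_density_yield,
    sample_yield_series,
    success_yield,
)

from conftest import make_species


class TestTransforms:
    @pytest.mark.parametrize(
        "P, expected",
        [(0.0, 0.0), (np.e - 1.0, 1.0), (27.0, np.log(28.0))],
    )
    def test_log_precip_values(self, P, expected):
        assert log_precip(P) == pytest.approx(expected, abs=1e-12)

    def test_log_precip_rejects_bad_input(self):
        with pytest.raises(ValueError):
            log_precip(-1.0)
        with pytest.raises(ValueError):
            log_precip(np.nan)

    @given(st.floats(0.0, 1e6), st.floats(0.0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_log_precip_strictly_increasing(self, a, b):
        if a != b:
            lo, hi = min(a, b), max(a, b)
            assert log_precip(lo) < log_precip(hi)

    @pytest.mark.parametrize("Y, expected", [(0.0, 0.5), (0.5, 1.0), (99.5, 100.0)])
    def test_offset_yield(self, Y, expected):
        assert offset_yield(Y) == expected

    def test_offset_yield_rejects_negative(self):
        with pytest.raises(ValueError):
            offset_yield(-0.1)


class TestReproductionProbability:
    def test_flat_logistic_is_half(self):
        sp = make_species(alpha1=0.0, beta1=0.0)
        assert reproduction_probability(sp, 17.3) == pytest.approx(0.5)

    def test_midpoint_at_logistic_root(self, erla):
        # oracle: solve alpha1 + beta1 * x = 0 for the log-precip midpoint
        x_mid = -erla.alpha1 / erla.beta1
        P = np.exp(x_mid) - 1.0
        assert reproduction_probability(erla, P) == pytest.approx(0.5, abs=1e-12)

    def test_pere_at_log_precip_two(self, species10):
        pere = next(sp for sp in species10 if sp.species_code == "PERE")
        P = np.exp(2.0) - 1.0
        assert reproduction_probability(pere, P) == pytest.approx(expit(2.76), rel=1e-12)
        assert reproduction_probability(pere, P) == pytest.approx(0.9405, abs=5e-5)

    @given(st.floats(0.1, 500.0), st.floats(0.2, 500.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_precip_with_positive_slope(self, erla, P1, P2):
        if P1 != P2:
            lo, hi = min(P1, P2), max(P1, P2)
            assert reproduction_probability(erla, lo) < reproduction_probability(erla, hi)
        assert 0.0 < reproduction_probability(erla, P1) < 1.0


class TestSuccessYield:
    def test_flat_regression_is_one(self):
        sp = make_species(log_alpha2=0.0, beta2=0.0)
        assert success_yield(sp, 123.0) == pytest.approx(1.0)

    def test_erla_and_scba_values(self, species10):
        erla = next(sp for sp in species10 if sp.species_code == "ERLA")
        scba = next(sp for sp in species10 if sp.species_code == "SCBA")
        assert success_yield(erla, np.e - 1.0) == pytest.approx(np.exp(1.22), rel=1e-12)
        assert success_yield(scba, np.exp(2.0) - 1.0) == pytest.approx(np.exp(4.22), rel=1e-12)


class TestSampling:
    def test_failure_branch_always_half(self, rng):
        sp = make_species(alpha1=-40.0, beta1=0.0)  # pi = 0
        K = sample_yield_series(sp, np.full(200, 5.0), rng)
        assert np.all(K == 0.5)

    def test_success_branch_deterministic(self, rng):
        sp = make_species(alpha1=40.0, beta1=0.0)  # pi = 1
        P = np.full(50, 5.0)
        K = sample_yield_series(sp, P, rng, residual_sd=0.0)
        assert np.allclose(K, success_yield(sp, 5.0))

    def test_failure_fraction_matches_binomial_error(self, erla, rng):
        P = 4.0
        n = 100_000
        pi = reproduction_probability(erla, P)
        K = sample_yield_series(erla, np.full(n, P), rng)
        fail = np.mean(K == 0.5)
        se = np.sqrt(pi * (1 - pi) / n)
        assert abs(fail - (1 - pi)) < 3 * se

    def test_marginal_mean_mixture(self, erla, rng):
        P = 6.0
        n = 200_000
        K = sample_yield_series(erla, np.full(n, P), rng)
        pi = reproduction_probability(erla, P)
        expected = pi * success_yield(erla, P) + (1 - pi) * 0.5
        assert K.mean() == pytest.approx(expected, rel=0.01)

    def test_scalar_wrapper_reproducible(self, erla):
        a = sample_low_density_yield(erla, 5.0, np.random.default_rng(3))
        b = sample_low_density_yield(erla, 5.0, np.random.default_rng(3))
        assert a == b


class TestObservedToLowDensityYield:
    @pytest.mark.parametrize(
        "Y, N, a, expected",
        [(0.5, 0.0, 0.01, 1.0), (9.5, 100.0, 0.01, 20.0), (0.0, 0.0, 0.01, 0.5)],
    )
    def test_examples(self, Y, N, a, expected):
        assert observed_to_low_density_yield(Y, N, a) == pytest.approx(expected)

    def test_zero_yield_is_failure_at_zero_density(self):
        assert observed_to_low_density_yield(0.0, 0.0, 0.05) < 1.0

    @given(st.floats(0.5, 500.0), st.floats(0.0, 300.0), st.floats(0.001, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_pre_offset(self, K, N, a):
        """Exact inversion when the yield is already on the offset scale."""
        Y = K / (1.0 + a * N)
        back = observed_to_low_density_yield(Y, N, a, yield_is_offset=True)
        assert back == pytest.approx(K, rel=1e-12)


def _simulate_binomial_frame(rng, alpha1, beta1, n, code="SIM"):
    x = rng.uniform(0.5, 3.0, n)
    p = expit(alpha1 + beta1 * x)
    return pd.DataFrame({"species_code": code, "x": x, "success": rng.random(n) < p})


class TestBinomialStage:
    def test_balanced_data_gives_zero_coefficients(self):
        data = pd.DataFrame(
            {
                "species_code": "A",
                "x": [1.0] * 10 + [2.0] * 10,
                "success": [True] * 5 + [False] * 5 + [True] * 5 + [False] * 5,
            }
        )
        fit = fit_binomial_stage(data, "full")
        assert fit.params.to_numpy() == pytest.approx([0.0, 0.0], abs=1e-8)

    def test_parameter_recovery_wald_coverage(self):
        """~95% Wald intervals cover the truth in >= 90% of replicate fits."""
        alpha1, beta1 = -2.0, 2.0
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            data = _simulate_binomial_frame(rng, alpha1, beta1, 500)
            fit = fit_binomial_stage(data, "full")
            se = np.sqrt(np.diag(fit.vcov.to_numpy()))
            b = fit.params.to_numpy()
            ok = (abs(b[0] - alpha1) < 1.96 * se[0]) and (abs(b[1] - beta1) < 1.96 * se[1])
            hits += ok
        assert hits >= 0.90 * n_rep

    def test_nested_loglik_ordering(self, rng):
        frames = [
            _simulate_binomial_frame(rng, -2.0 + 0.3 * i, 2.0 - 0.2 * i, 60, code=f"S{i}")
            for i in range(3)
        ]
        data = pd.concat(frames, ignore_index=True)
        full = fit_binomial_stage(data, "full")
        cs = fit_binomial_stage(data, "common_slope")
        ci = fit_binomial_stage(data, "common_intercept")
        assert full.loglik >= cs.loglik - 1e-8
        assert full.loglik >= ci.loglik - 1e-8

    def test_aic_bic_identities(self, rng):
        data = _simulate_binomial_frame(rng, -1.0, 1.5, 80)
        fit = fit_binomial_stage(data, "full")
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.bic == pytest.approx(fit.k * np.log(fit.n) - 2 * fit.loglik)

    def test_empty_and_degenerate_errors(self):
        with pytest.raises(ValueError):
            fit_binomial_stage(pd.DataFrame(columns=["species_code", "x", "success"]))
        allwin = pd.DataFrame({"species_code": "A", "x": [1.0, 2.0, 3.0], "success": True})
        with pytest.raises(ValueError):
            fit_binomial_stage(allwin)

    def test_separation_warns(self):
        data = pd.DataFrame(
            {
                "species_code": "A",
                "x": [1.0, 1.1, 1.2, 2.0, 2.1, 2.2],
                "success": [False, False, False, True, True, True],
            }
        )
        with pytest.warns(UserWarning, match="separation"):
            fit_binomial_stage(data, "full")


class TestYieldStage:
    def test_two_point_exact_fit(self):
        data = pd.DataFrame(
            {"species_code": "A", "x": [1.0, 2.0], "log_K": [1.0, 3.0], "success": True}
        )
        fit = fit_yield_stage(data, "full")
        assert fit.params["intercept[A]"] == pytest.approx(-1.0, abs=1e-10)
        assert fit.params["slope[A]"] == pytest.approx(2.0, abs=1e-10)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        la2, b2, sd = -0.7, 2.0, 0.5
        x = rng.uniform(0.5, 3.0, 200)
        data = pd.DataFrame(
            {"species_code": "A", "x": x, "log_K": la2 + b2 * x + sd * rng.standard_normal(200)}
        )
        fit = fit_yield_stage(data, "full")
        se = np.sqrt(np.diag(fit.vcov.to_numpy()))
        assert abs(fit.params["intercept[A]"] - la2) < 3 * se[0]
        assert abs(fit.params["slope[A]"] - b2) < 3 * se[1]
        assert fit.residual_sd == pytest.approx(sd, rel=0.2)

    def test_matches_normal_equations(self):
        """OLS coefficients equal the closed-form normal-equations solution."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0.0, 3.0, 50)
        y = 0.3 + 1.7 * x + 0.4 * rng.standard_normal(50)
        data = pd.DataFrame({"species_code": "A", "x": x, "log_K": y})
        fit = fit_yield_stage(data, "full")
        X = np.column_stack([np.ones(50), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.params.to_numpy() == pytest.approx(beta, rel=1e-10)

    def test_rank_deficiency_error(self):
        data = pd.DataFrame({"species_code": "A", "x": [1.0, 1.0, 1.0], "log_K": [1.0, 2.0, 3.0]})
        with pytest.raises(np.linalg.LinAlgError):
            fit_yield_stage(data, "full")


class TestModelComparison:
    def _three_fits(self, seed=0, common_slope=True, n=100):
        rng = np.random.default_rng(seed)
        frames = []
        for i in range(4):
            beta = 2.0 if common_slope else 1.0 + 0.8 * i
            frames.append(
                _simulate_binomial_frame(rng, -3.0 + 0.9 * i, beta, n, code=f"S{i}")
            )
        data = pd.concat(frames, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rare separation in small replicates
            return [
                fit_binomial_stage(data, f)
                for f in ("full", "common_slope", "common_intercept")
            ]

    def test_duplicate_fits_tie(self):
        fits = self._three_fits()
        report = compare_submodels([fits[0], fits[0]])
        assert report["table"]["aic_tie"].all()

    def test_lr_statistic_nonnegative(self):
        report = compare_submodels(self._three_fits())
        assert (report["lr_tests"]["lr_stat"] >= -1e-8).all()

    def test_common_slope_wins_when_true(self):
        """Data generated with one shared slope: common_slope wins AIC mostly."""
        wins = 0
        n_rep = 25
        for rep in range(n_rep):
            fits = self._three_fits(seed=rep, common_slope=True)
            best = compare_submodels(fits)["table"].iloc[0]["model_form"]
            wins += best == "common_slope"
        assert wins > n_rep / 2

    def test_mismatched_data_rejected(self):
        f1 = self._three_fits(seed=1)[0]
        f2 = self._three_fits(seed=2)[0]
        with pytest.raises(ValueError):
            compare_submodels([f1, f2])


class TestPairwiseWald:
    def _fit_with(self, b, V, family="intercept"):
        codes = [f"S{i}" for i in range(len(b))]
        names = [f"{family}[{c}]" for c in codes]
        return StageFit(
            stage="binomial",
            model_form="common_slope",
            params=pd.Series(b, index=names),
            vcov=pd.DataFrame(V, index=names, columns=names),
            loglik=0.0,
            k=len(b),
            n=10,
            species=codes,
        )

    def test_equal_coefficients_give_p_one(self):
        fit = self._fit_with([1.0, 1.0], np.eye(2) * 0.3)
        out = pairwise_wald(fit)
        assert out["z"].iloc[0, 1] == 0.0
        assert out["p"].iloc[0, 1] == pytest.approx(1.0)

    def test_z_two_normal_p(self):
        fit = self._fit_with([2.0, 0.0], np.eye(2) * 0.5)
        out = pairwise_wald(fit)
        assert out["z"].iloc[0, 1] == pytest.approx(2.0)
        assert out["p"].iloc[0, 1] == pytest.approx(0.0455, abs=5e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((4, 4))
        fit = self._fit_with(rng.standard_normal(4), A @ A.T + np.eye(4))
        z = pairwise_wald(fit)["z"].to_numpy()
        assert np.allclose(z, -z.T)

    def test_requires_per_species_family(self):
        fit = self._fit_with([1.0, 2.0], np.eye(2) * 0.1)
        with pytest.raises(ValueError):
            pairwise_wald(fit, family="slope")


class TestPrepareHurdleData:
    def test_success_failure_split_and_logs(self, rng):
        sp = make_species(a=0.02)
        obs = pd.DataFrame(
            {
                "species_code": "TEST",
                "year": [1, 2, 3],
                "precip": [5.0, 2.0, 8.0],
                "seedling_density": [0.0, 50.0, 10.0],
                "observed_yield": [4.5, 0.0, 9.5],
            }
        )
        data = prepare_hurdle_data(obs, [sp])
        # K = (Y + 0.5)(1 + aN): 5.0, 1.0, 12.0
        assert data["K"].to_numpy() == pytest.approx([5.0, 1.0, 12.0])
        assert data["success"].tolist() == [True, True, True]
        assert data["x"].to_numpy() == pytest.approx(np.log1p([5.0, 2.0, 8.0]))

    def test_missing_species_params_rejected(self):
        obs = pd.DataFrame(
            {
                "species_code": "NOPE",
                "year": [1],
                "precip": [5.0],
                "seedling_density": [0.0],
                "observed_yield": [1.0],
            }
        )
        with pytest.raises(KeyError):
            prepare_hurdle_data(obs, [make_species()])
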