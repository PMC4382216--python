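"""Mixed-model fitting, AICc model selection, averaging, and correlations."""

import math

import numpy as np
import pandas as pd
import pytest

import statsmodels.formula.api as smf

from frugitrack.datasets import bat_summary, daily_range_model_set
from frugitrack.models import (
    LmmFit,
    ModelSet,
    aicc,
    akaike_weights,
    all_subsets,
    center_covariates,
    conditional_r2,
    fit_lmm,
    model_average,
    pearson_log_correlation,
    shapiro_normality,
    vif,
)


def _simulate(rng, n_bats=16, n_obs=3, beta0=10.6, beta_dist=3.0,
              sigma_b=0.5, sigma_e=0.6):
    bats = np.repeat([f"b{i:02d}" for i in range(n_bats)], n_obs)
    dist = rng.uniform(0.0, 0.6, n_bats * n_obs)
    dist -= dist.mean()
    y = beta0 + beta_dist * dist + np.repeat(rng.normal(0, sigma_b, n_bats), n_obs) \
        + rng.normal(0, sigma_e, n_bats * n_obs)
    return pd.DataFrame({
        "bat_id": bats, "log_area": y, "disturbance": dist,
        "day": rng.uniform(0, 9, n_bats * n_obs) - 4.5,
        "moon": rng.uniform(0, 1, n_bats * n_obs) - 0.5,
        "sex": np.repeat(rng.integers(0, 2, n_bats), n_obs).astype(float),
    })


class TestCentering:
    def test_example_column(self):
        df = pd.DataFrame({"disturbance": [0.2, 0.4, 0.6], "day": [1.0, 2.0, 3.0],
                           "moon": [0.1, 0.1, 0.4], "sex": [0.0, 1.0, 1.0]})
        out, means = center_covariates(df)
        assert out["disturbance"].to_numpy() == pytest.approx([-0.2, 0.0, 0.2])
        assert means["disturbance"] == pytest.approx(0.4)

    def test_centered_column_unchanged_and_mean_zero(self, rng):
        df = _simulate(rng)
        out, _ = center_covariates(df)
        for t in ("disturbance", "day", "moon", "sex"):
            assert abs(out[t].mean()) < 1e-12
        again, _ = center_covariates(out)
        assert np.allclose(again["disturbance"], out["disturbance"])

    def test_constant_covariate_flagged(self):
        df = pd.DataFrame({"disturbance": [0.2, 0.2, 0.2], "day": [1.0, 2.0, 3.0],
                           "moon": [0.1, 0.2, 0.4], "sex": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="constant"):
            out, _ = center_covariates(df)
        assert (out["sex"] == 0).all()


class TestFitLmm:
    def test_matches_statsmodels_ml(self, rng):
        df = _simulate(rng)
        fit = fit_lmm(df, ("disturbance", "day"))
        ref = smf.mixedlm("log_area ~ disturbance + day", df,
                          groups=df["bat_id"]).fit(reml=False)
        assert fit.beta == pytest.approx(ref.fe_params.to_numpy(), abs=1e-5)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert fit.sigma_b2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-4)
        assert fit.sigma_e2 == pytest.approx(float(ref.scale), abs=1e-4)

    def test_no_group_variance_reduces_to_ols(self, rng):
        df = _simulate(rng, sigma_b=0.0)
        # force zero between-group residual variance exactly
        resid = df["log_area"] - 10.6 - 3.0 * df["disturbance"]
        df["log_area"] -= resid.groupby(df["bat_id"]).transform("mean")
        fit = fit_lmm(df, ("disturbance",))
        assert fit.sigma_b2 <= 1e-6
        X = np.column_stack([np.ones(len(df)), df["disturbance"]])
        ols = np.linalg.lstsq(X, df["log_area"].to_numpy(), rcond=None)[0]
        assert fit.beta == pytest.approx(ols, abs=1e-6)

    def test_duplicating_groups_keeps_coefficients(self, rng):
        """Cloning every group under a fresh label leaves beta unchanged."""
        df = _simulate(rng)
        fit = fit_lmm(df, ("disturbance",))
        clone = df.copy()
        clone["bat_id"] = clone["bat_id"] + "_copy"
        fit2 = fit_lmm(pd.concat([df, clone], ignore_index=True), ("disturbance",))
        assert fit2.beta == pytest.approx(fit.beta, abs=1e-5)

    def test_row_duplication_matches_statsmodels_oracle(self, rng):
        """Row duplication shifts the variance partition; the refit must agree
        with an independent ML implementation on the duplicated data."""
        df = _simulate(rng)
        doubled = pd.concat([df, df], ignore_index=True)
        fit = fit_lmm(doubled, ("disturbance",))
        ref = smf.mixedlm("log_area ~ disturbance", doubled,
                          groups=doubled["bat_id"]).fit(reml=False)
        assert fit.beta == pytest.approx(ref.fe_params.to_numpy(), abs=1e-5)

    def test_likelihood_dominates_ols_boundary(self, rng):
        for _ in range(5):
            df = _simulate(rng, n_bats=8)
            fit = fit_lmm(df, ("disturbance",))
            from frugitrack.models import _profiled
            ll0 = _profiled(df["log_area"].to_numpy(),
                            np.column_stack([np.ones(len(df)), df["disturbance"]]),
                            df["bat_id"].to_numpy(), math.exp(-12))[3]
            assert fit.loglik >= ll0 - 1e-8

    def test_rank_deficient_design_rejected(self, rng):
        df = _simulate(rng)
        df["day"] = df["disturbance"]
        with pytest.raises(np.linalg.LinAlgError):
            fit_lmm(df, ("disturbance", "day"))

    def test_parameter_recovery_short(self, rng):
        est = []
        for _ in range(40):
            df = _simulate(rng, beta_dist=3.0)
            est.append(fit_lmm(df, ("disturbance",)).beta[1])
        assert np.mean(est) == pytest.approx(3.0, abs=0.15)


class TestAicc:
    def test_parameter_count_rules(self, rng):
        df = _simulate(rng)
        assert fit_lmm(df, ()).K == 3                      # intercept-only
        assert fit_lmm(df, ("disturbance",)).K == 4        # one covariate
        assert fit_lmm(df, ("disturbance", "day")).K == 5

    def test_large_n_limit_approaches_aic(self):
        fit = LmmFit(terms=(), beta=np.zeros(1), se=np.zeros(1), sigma_b2=0.1,
                     sigma_e2=1.0, loglik=-100.0, n=10 ** 6,
                     fitted_fixed=np.zeros(2), converged_interior=True)
        aic = -2 * fit.loglik + 2 * fit.K
        assert aicc(fit) - aic < 1e-4

    def test_undefined_for_tiny_n(self):
        fit = LmmFit(terms=(), beta=np.zeros(1), se=np.zeros(1), sigma_b2=0.0,
                     sigma_e2=1.0, loglik=-1.0, n=4,
                     fitted_fixed=np.zeros(4), converged_interior=True)
        with pytest.raises(ValueError):
            aicc(fit)


class TestWeightsAndSubsets:
    def test_printed_candidate_set_weights(self):
        w = akaike_weights(daily_range_model_set()["aicc"])
        assert w == pytest.approx([0.657, 0.343], abs=0.001)
        assert round(w[0], 2) == 0.66 and round(w[1], 2) == 0.34

    def test_equal_aicc_gives_equal_weights(self):
        w = akaike_weights([50.0] * 16)
        assert w == pytest.approx([1 / 16] * 16)

    def test_all_subsets_structure(self, rng):
        df = _simulate(rng)
        mset = all_subsets(df)
        assert len(mset.fits) == 16
        assert mset.weight.sum() == pytest.approx(1.0)
        assert mset.delta.min() == 0.0
        assert mset.order[0] in mset.top_set
        sizes = sorted(len(f.terms) for f in mset.fits)
        assert sizes == sorted(
            [0] + [1] * 4 + [2] * 6 + [3] * 4 + [4])


def _mock_fit(beta, se, terms=("disturbance",)):
    p = len(beta)
    return LmmFit(terms=terms, beta=np.asarray(beta, dtype=float),
                  se=np.asarray(se, dtype=float), sigma_b2=0.0, sigma_e2=1.0,
                  loglik=0.0, n=44, fitted_fixed=np.zeros(4),
                  converged_interior=True)


class TestModelAverage:
    def test_single_model_scope_returns_its_coefficients(self, rng):
        df = _simulate(rng)
        mset = all_subsets(df)
        best = mset.best
        mset.cutoff = 1e-9  # top set collapses to the single best model
        avg = model_average(mset, scope="delta2")
        assert avg.table.loc["(Intercept)", "estimate"] == pytest.approx(best.beta[0])

    def test_equal_weight_spread_variance(self):
        fits = [_mock_fit([0.0, 2.0], [0.0, 0.0]), _mock_fit([0.0, 4.0], [0.0, 0.0])]
        mset = ModelSet(fits=fits, aicc=np.array([10.0, 10.0]),
                        delta=np.zeros(2), weight=np.array([0.5, 0.5]))
        avg = model_average(mset, scope="all", terms=("disturbance",))
        row = avg.table.loc["disturbance"]
        assert row["estimate"] == pytest.approx(3.0)
        assert row["se"] == pytest.approx(1.0)
        assert row["importance"] == pytest.approx(1.0)

    def test_full_mode_shrinks_toward_zero(self, rng):
        df = _simulate(rng)
        mset = all_subsets(df)
        cond = model_average(mset, scope="all", mode="conditional")
        full = model_average(mset, scope="all", mode="full")
        c = cond.table.loc["disturbance", "estimate"]
        f = full.table.loc["disturbance", "estimate"]
        assert abs(f) <= abs(c) + 1e-12


class TestConditionalR2:
    def test_null_model_with_equal_variances(self):
        fit = LmmFit(terms=(), beta=np.array([1.0]), se=np.zeros(1),
                     sigma_b2=0.5, sigma_e2=0.5, loglik=0.0, n=10,
                     fitted_fixed=np.full(10, 1.0), converged_interior=True)
        assert conditional_r2(fit) == pytest.approx(0.5)

    def test_perfect_fixed_fit_limit(self):
        fit = LmmFit(terms=("x",), beta=np.array([0.0, 1.0]), se=np.zeros(2),
                     sigma_b2=0.0, sigma_e2=1e-12, loglik=0.0, n=10,
                     fitted_fixed=np.linspace(0, 9, 10), converged_interior=True)
        assert conditional_r2(fit) == pytest.approx(1.0, abs=1e-9)


class TestVif:
    def test_orthogonal_predictors(self):
        df = pd.DataFrame({"disturbance": [1, 1, -1, -1.0] * 3,
                           "day": [1, -1, 1, -1.0] * 3,
                           "moon": [1, -1, -1, 1.0] * 3})
        out = vif(df, ("disturbance", "day", "moon"))
        assert out.to_numpy() == pytest.approx([1.0, 1.0, 1.0])

    def test_duplicate_predictor_infinite(self, rng):
        df = pd.DataFrame({"disturbance": rng.normal(0, 1, 20)})
        df["day"] = df["disturbance"]
        with pytest.warns(UserWarning, match="collinearity"):
            out = vif(df, ("disturbance", "day"))
        assert math.isinf(out["day"])

    def test_constructed_r2_three_quarters_gives_vif_four(self, rng):
        x1 = rng.normal(0, 1, 400)
        noise = rng.normal(0, 1, 400)
        # orthogonalize the noise against [1, x1], then set var(e) = var(x1)/3
        X = np.column_stack([np.ones(400), x1])
        e = noise - X @ np.linalg.lstsq(X, noise, rcond=None)[0]
        e *= math.sqrt(x1.var() / 3.0) / e.std()
        df = pd.DataFrame({"disturbance": x1, "day": x1 + e})
        out = vif(df, ("disturbance", "day"))
        assert out["day"] == pytest.approx(4.0, rel=1e-6)


class TestPearsonLogCorrelation:
    def test_perfect_negative(self):
        areas = np.exp(np.linspace(1, 3, 10))
        r, lo, hi, p = pearson_log_correlation(areas, -np.log(areas))
        assert r == pytest.approx(-1.0)

    def test_log_base_invariance(self, rng):
        areas = np.exp(rng.normal(2, 1, 16))
        ratios = rng.uniform(0, 1, 16)
        r_e = pearson_log_correlation(areas, ratios, log_base=math.e)[0]
        r_10 = pearson_log_correlation(areas, ratios, log_base=10)[0]
        assert r_e == pytest.approx(r_10, abs=1e-12)

    def test_reference_bats_reproduce_published_association(self):
        df = bat_summary()
        r, lo, hi, p = pearson_log_correlation(df["hr_tot_ha"], df["compactness"])
        assert r == pytest.approx(-0.73, abs=0.005)
        assert p < 0.01

    def test_zero_variance_invalid(self):
        with pytest.raises(ValueError):
            pearson_log_correlation([1.0, 2, 3, 4], [0.5] * 4)


def test_shapiro_smoke(rng):
    p, ok = shapiro_normality(rng.normal(0, 1, 50), alpha=0.2)
    assert 0 <= p <= 1
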