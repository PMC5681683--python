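"""Statistics layer: worked ratio arithmetic, ML fits vs independent
likelihood oracles, AICc selection and model averaging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from foraykit.stats import (
    ModelSpec,
    aicc,
    akaike_weights,
    build_design,
    candidate_set,
    collinearity_screen,
    describe,
    fit_ml,
    model_average,
    one_per_individual,
    pearson_r,
    percent,
    round_half_up,
)


# ---------------------------------------------------------------------------
# independent ZINB likelihood oracle (mean-parametrised NB2 via scipy)


def nb2_logpmf(y, mu, alpha):
    """NB2 log-pmf with Var = mu + alpha*mu^2 (theta = 1/alpha)."""
    theta = 1.0 / alpha
    return sps.nbinom.logpmf(y, theta, theta / (theta + mu))


def zinb_loglik(y, X, beta, alpha, gamma):
    """Zero-inflated NB2 log-likelihood with intercept-only logit zero part."""
    pi = 1.0 / (1.0 + np.exp(-gamma))
    mu = np.exp(X @ beta)
    ll = np.where(
        y == 0,
        np.log(pi + (1 - pi) * np.exp(nb2_logpmf(0, mu, alpha))),
        np.log1p(-pi) + nb2_logpmf(y, mu, alpha),
    )
    return float(ll.sum())


def simulate_zinb(n, beta, alpha, pi, rng, x_loc=3.0):
    x = rng.normal(x_loc, 1.0, n)
    X = np.column_stack([np.ones(n), x])
    mu = np.exp(X @ beta)
    theta = 1.0 / alpha
    y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
    y[rng.random(n) < pi] = 0.0
    return pd.DataFrame({"y": y, "x": x})


# ---------------------------------------------------------------------------


class TestDescriptive:
    def test_percent_worked_ratios(self):
        assert percent(20, 46) == 43.5
        assert percent(25, 54) == 46.3
        assert percent(6, 10) == 60.0
        assert percent(2537, 25000) == 10.1

    def test_percent_rounds_half_up(self):
        assert percent(1, 8) == 12.5
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(-0.125, 2) == -0.13

    def test_percent_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    def test_describe_basic(self):
        d = describe([0, 0, 0, 5])
        assert d.mean == pytest.approx(1.25)
        assert d.median == 0.0
        assert d.sd == pytest.approx(np.std([0, 0, 0, 5], ddof=1))

    def test_describe_single_value(self):
        d = describe([3.0])
        assert d.sd == 0.0 and not d.sd_defined

    def test_describe_sampling_bound(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 3, 10_000)
        d = describe(x)
        assert abs(d.mean - 2) < 3 * 3 / np.sqrt(10_000)

    def test_pearson_exact_and_sampled(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=1000)
        assert abs(pearson_r(x, y) - 0.8) < 0.05

    def test_pearson_constant_errors(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCandidatesAndWeights:
    @pytest.mark.parametrize("p,expected", [(5, 32), (0, 1), (3, 8)])
    def test_candidate_set_size(self, p, expected):
        covs = [f"c{i}" for i in range(p)]
        specs = candidate_set("y", "gaussian_identity", covs)
        assert len(specs) == expected
        assert len({s.covariates for s in specs}) == expected
        assert ModelSpec("y", "gaussian_identity", ()) in specs

    def test_akaike_weights_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.7311, abs=5e-5)
        assert w[1] == pytest.approx(0.2689, abs=5e-5)
        assert w.sum() == pytest.approx(1.0)

    def test_aicc_approaches_aic(self):
        n = 10**6
        for k in range(1, 7):
            assert aicc(-100.0, k, n) - (-2 * -100.0 + 2 * k) < 1e-3


class TestFitML:
    def test_zinb_beats_truth_and_grid_oracle(self):
        """The ML optimum dominates the generating parameters and a coarse
        grid search of the hand-written likelihood."""
        rng = np.random.default_rng(10)
        data = simulate_zinb(400, beta=[1.0, -0.4], alpha=0.5, pi=0.3, rng=rng)
        fit = fit_ml(ModelSpec("y", "zinb", ("x",)), data)
        assert fit.converged
        y = data["y"].values
        X = build_design(data, ("x",)).values
        ll_true = zinb_loglik(y, X, np.array([1.0, -0.4]), 0.5, np.log(0.3 / 0.7))
        assert fit.loglik >= ll_true - 1e-6
        # coarse grid around the truth
        best_grid = -np.inf
        for b0 in np.linspace(0.6, 1.4, 9):
            for b1 in np.linspace(-0.7, -0.1, 9):
                for a in (0.3, 0.5, 0.8):
                    for g in (-1.5, -0.85, -0.4):
                        best_grid = max(
                            best_grid, zinb_loglik(y, X, np.array([b0, b1]), a, g)
                        )
        assert fit.loglik >= best_grid - 0.01

    def test_zinb_loglik_matches_oracle_at_fit(self):
        """statsmodels' ZINB likelihood agrees with the independent scipy
        formulation evaluated at the fitted parameters."""
        rng = np.random.default_rng(11)
        data = simulate_zinb(300, beta=[0.8, -0.3], alpha=0.6, pi=0.25, rng=rng)
        fit = fit_ml(ModelSpec("y", "zinb", ("x",)), data)
        y = data["y"].values
        X = build_design(data, ("x",)).values
        beta_hat = np.array([fit.coef["const"], fit.coef["x"]])
        ll = zinb_loglik(y, X, beta_hat, fit.dispersion, fit.zero_infl_intercept)
        assert ll == pytest.approx(fit.loglik, abs=1e-6)

    def test_zero_inflation_vanishes_nests_nb(self):
        """With pi -> 0 the ZINB likelihood collapses to plain NB (oracle
        identity), and the fitted ZINB matches the NB fit on NB data."""
        rng = np.random.default_rng(12)
        data = simulate_zinb(600, beta=[1.2, 0.3], alpha=0.7, pi=0.0, rng=rng)
        y = data["y"].values
        X = build_design(data, ("x",)).values
        ll_nb_direct = float(nb2_logpmf(y, np.exp(X @ [1.2, 0.3]), 0.7).sum())
        ll_zinb_pi0 = zinb_loglik(y, X, np.array([1.2, 0.3]), 0.7, -40.0)
        assert ll_zinb_pi0 == pytest.approx(ll_nb_direct, abs=1e-8)
        nb = fit_ml(ModelSpec("y", "negbin_log", ("x",)), data)
        zi = fit_ml(ModelSpec("y", "zinb", ("x",)), data)
        assert zi.loglik == pytest.approx(nb.loglik, abs=0.05)

    def test_nb_with_vanishing_dispersion_matches_poisson(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 800)
        y = rng.poisson(np.exp(0.5 + 0.4 * x)).astype(float)
        data = pd.DataFrame({"y": y, "x": x})
        po = fit_ml(ModelSpec("y", "poisson_log", ("x",)), data)
        nb = fit_ml(ModelSpec("y", "negbin_log", ("x",)), data)
        assert nb.coef["x"] == pytest.approx(po.coef["x"], abs=1e-3)
        assert nb.coef["const"] == pytest.approx(po.coef["const"], abs=1e-3)

    def test_gaussian_and_logit_families(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=500)
        data = pd.DataFrame(
            {
                "x": x,
                "yg": 2.0 + 1.5 * x + rng.normal(size=500),
                "yb": (rng.random(500) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float),
            }
        )
        g = fit_ml(ModelSpec("yg", "gaussian_identity", ("x",)), data)
        assert g.coef["x"] == pytest.approx(1.5, abs=0.15)
        assert g.k == 3  # intercept + slope + sigma
        b = fit_ml(ModelSpec("yb", "bernoulli_logit", ("x",)), data)
        assert b.coef["x"] == pytest.approx(0.8, abs=0.3)

    def test_categorical_encoding_reference_levels(self):
        rng = np.random.default_rng(15)
        n = 200
        data = pd.DataFrame(
            {
                "season": rng.choice(["autumn", "spring"], n),
                "status": rng.choice(["dominant", "subordinate"], n),
            }
        )
        data["y"] = 1.0 + 2.0 * (data["season"] == "spring") + rng.normal(0, 0.1, n)
        fit = fit_ml(ModelSpec("y", "gaussian_identity", ("season", "status")), data)
        assert "season_spring" in fit.coef and "status_subordinate" in fit.coef
        assert fit.coef["season_spring"] == pytest.approx(2.0, abs=0.1)

    def test_rank_deficient_design_raises(self):
        data = pd.DataFrame({"y": [1.0, 2, 3, 4], "a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="rank"):
            fit_ml(ModelSpec("y", "gaussian_identity", ("a", "b")), data)


class TestModelAveraging:
    @staticmethod
    def _fits(rng=None, n=120):
        rng = np.random.default_rng(20 if rng is None else rng)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 1.0 + 0.8 * x1 + rng.normal(size=n)
        data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        specs = candidate_set("y", "gaussian_identity", ["x1", "x2"])
        return [fit_ml(s, data) for s in specs]

    def test_weights_sum_to_one(self):
        avg = model_average(self._fits())
        assert sum(avg.weights) == pytest.approx(1.0)

    def test_single_model_average_is_identity(self):
        fits = self._fits()
        best = min(fits, key=lambda f: f.aicc)
        avg = model_average([best])
        for name, b in best.coef.items():
            assert avg.beta[name] == pytest.approx(b)
            assert avg.se[name] == pytest.approx(best.se[name])

    def test_informative_flag_is_zero_exclusion(self):
        avg = model_average(self._fits())
        for name in avg.covariates:
            inside = avg.lci[name] <= 0.0 <= avg.uci[name]
            assert avg.informative[name] == (not inside)
        assert avg.informative[ "x1"]  # strong true effect
        assert not avg.informative["x2"]  # pure noise covariate

    def test_absent_covariate_shrinks_full_average(self):
        """Full averaging pulls a weak term toward zero relative to its
        conditional (within-model) estimate."""
        fits = self._fits()
        avg = model_average(fits)
        with_x2 = [f for f in fits if "x2" in f.coef]
        cond = np.mean([f.coef["x2"] for f in with_x2])
        assert abs(avg.beta["x2"]) <= abs(cond) + 1e-9

    def test_delta_window_strictly_less_than_four(self):
        fits = self._fits()
        best = min(f.aicc for f in fits)
        avg = model_average(fits, delta_max=4.0)
        assert all(f.aicc - best < 4.0 for f in avg.retained)


class TestCollinearityScreen:
    def test_duplicated_covariate_flagged(self):
        rng = np.random.default_rng(30)
        a = rng.normal(size=200)
        data = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=200)})
        rep = collinearity_screen(data, ["a", "b", "c"], threshold_r=0.6)
        assert ("a", "b", pytest.approx(1.0)) in [
            (x, y, r) for x, y, r in rep["flagged"]
        ]

    def test_independent_covariates_clean(self):
        rng = np.random.default_rng(31)
        data = pd.DataFrame(rng.normal(size=(1000, 3)), columns=["a", "b", "c"])
        rep = collinearity_screen(data, ["a", "b", "c"], threshold_r=0.6)
        assert rep["flagged"] == []

    def test_threshold_is_strict(self):
        # r just below the threshold is not flagged
        n = 4
        data = pd.DataFrame({"a": [0.0, 1, 2, 3], "b": [0.0, 1, 2, 2.9]})
        r = abs(pearson_r(data["a"], data["b"], ))
        rep = collinearity_screen(data, ["a", "b"], threshold_r=r + 1e-9)
        assert rep["flagged"] == []


def test_one_per_individual_subsampling():
    table = pd.DataFrame(
        {"individual_id": ["a", "a", "b", "c", "c"], "v": range(5)}
    )
    out = one_per_individual(table, rng=0)
    assert sorted(out["individual_id"]) == ["a", "b", "c"]
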