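"""Descriptive statistics, count-model fitting, AICc selection and model
averaging for the foray analysis.

The inference layer mirrors the standard information-theoretic workflow in
behavioural ecology: fit every fixed-effects combination of a small
covariate set (no interactions), rank by AICc, and average the models
within 4 AICc units of the best one.  Coefficients whose averaged 95%
confidence interval includes zero are flagged uninformative.

Model families are ordinary maximum-likelihood fits delegated to
statsmodels; the zero-inflated negative binomial (ZINB) uses an
intercept-only logit zero part and a log-link NB2 count part:

    P(y = 0) = pi + (1 - pi) * NB(0; mu, theta)
    P(y = k) = (1 - pi) * NB(k; mu, theta),   k > 0
    logit(pi) = gamma0,  log(mu) = X beta,  Var(y|count part) = mu + mu^2/theta

Random effects are deliberately not modelled; repeated deployments of an
individual can instead be subsampled to one per individual (see
``one_per_individual``).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "round_half_up",
    "percent",
    "describe",
    "pearson_r",
    "DescriptiveSummary",
    "ModelSpec",
    "FitResult",
    "AveragedResult",
    "FAMILIES",
    "build_design",
    "fit_ml",
    "candidate_set",
    "fit_candidates",
    "model_average",
    "collinearity_screen",
    "aicc",
    "akaike_weights",
    "one_per_individual",
]

FAMILIES = ("gaussian_identity", "bernoulli_logit", "poisson_log", "negbin_log", "zinb")

#: Treatment-contrast encodings for the categorical covariates; reference
#: levels are autumn, dominant and foray (the printed effects are for
#: spring, subordinate and intra-territorial movement).
CATEGORICAL_LEVELS = {
    "season": ("autumn", "spring"),
    "status": ("dominant", "subordinate"),
    "movement_type": ("foray", "intra"),
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), the rounding used in reports."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        raise ZeroDivisionError("percent undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator, 1)


@dataclass
class DescriptiveSummary:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    sd_defined: bool = True

    def format(self, nd: int = 2) -> str:
        return (
            f"mean ± SD: {round_half_up(self.mean, nd)} ± "
            f"{round_half_up(self.sd, nd)}, median: {round_half_up(self.median, nd)}, "
            f"range: {round_half_up(self.min, nd)}–{round_half_up(self.max, nd)}"
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "median": self.median, "min": self.min, "max": self.max,
        }


def describe(values) -> DescriptiveSummary:
    """Sample statistics (SD with the n-1 denominator).

    A single value has no sample SD; it is reported as 0 with
    ``sd_defined=False``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("describe() needs at least one value")
    sd_defined = arr.size > 1
    return DescriptiveSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if sd_defined else 0.0,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        sd_defined=sd_defined,
    )


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# model specification and design matrices


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, family, covariate subset."""

    response: str
    family: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    def label(self) -> str:
        return " + ".join(self.covariates) if self.covariates else "(intercept)"


def build_design(data: pd.DataFrame, covariates) -> pd.DataFrame:
    """Design matrix with an intercept column ``const`` and treatment-coded
    categorical terms (e.g. ``status`` -> ``status_subordinate``)."""
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            ref, other = CATEGORICAL_LEVELS[cov]
            vals = data[cov].astype(str)
            unknown = set(vals.unique()) - {ref, other}
            if unknown:
                raise ValueError(f"{cov}: unknown level(s) {sorted(unknown)}")
            X[f"{cov}_{other}"] = (vals == other).astype(float)
        else:
            X[cov] = pd.to_numeric(data[cov]).astype(float)
    return X


def term_name(cov: str) -> str:
    """Design-matrix column name of a covariate."""
    if cov in CATEGORICAL_LEVELS:
        return f"{cov}_{CATEGORICAL_LEVELS[cov][1]}"
    return cov


def aicc(loglik: float, k: int, n: int) -> float:
    """AIC corrected for small samples: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    """A fitted model: coefficients, SEs, log-likelihood, AICc.

    ``k`` counts every estimated parameter, including the NB dispersion and
    the zero-inflation intercept where present.  ``coef``/``se`` are keyed
    by design-matrix column name; ``zero_infl_intercept`` is the logit-scale
    gamma of the ZINB zero part (None for other families).
    """

    spec: ModelSpec
    coef: dict[str, float]
    se: dict[str, float]
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    zero_infl_intercept: float | None = None
    dispersion: float | None = None  # NB alpha (=1/theta)
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.spec.label(),
            "family": self.spec.family,
            "coef": self.coef,
            "se": self.se,
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "aicc": self.aicc,
            "converged": self.converged,
            "zero_infl_intercept": self.zero_infl_intercept,
            "dispersion": self.dispersion,
        }


def _hessian_bse(model, params: np.ndarray) -> np.ndarray | None:
    """Standard errors from the observed information (numerical Hessian at
    the optimum); None when the information matrix is not usable.

    When the NB dispersion sits on its boundary (alpha -> 0, the ZIP limit)
    the full information matrix is singular; the regression SEs are then
    taken from the sub-block with the dispersion held at its estimate, and
    the dispersion's own SE is reported as NaN.
    """
    try:
        H = model.hessian(params)
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        if np.isfinite(d).all() and (d > 0).all():
            return np.sqrt(d)
    except Exception:
        pass
    # boundary case: profile out the trailing dispersion parameter
    try:
        from statsmodels.tools.numdiff import approx_hess

        alpha = params[-1]

        def ll_sub(q):
            return model.loglike(np.append(q, alpha))

        H = approx_hess(params[:-1], ll_sub)
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        if not (np.isfinite(d).all() and (d > 0).all()):
            return None
        return np.append(np.sqrt(d), np.nan)
    except Exception:
        return None


def fit_ml(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Maximum-likelihood fit of one candidate model.

    Non-convergence and numerical failures are flagged (``converged=False``)
    rather than raised; rank-deficient designs raise.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

    y = pd.to_numeric(data[spec.response]).astype(float).values
    X = build_design(data, spec.covariates)
    n, p = X.shape
    if np.linalg.matrix_rank(X.values) < p:
        raise ValueError(f"rank-deficient design for model {spec.label()}")

    zero_gamma = None
    alpha = None
    converged = True
    message = ""
    bse_override = None
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            if spec.family == "gaussian_identity":
                res = sm.OLS(y, X).fit()
                k = p + 1  # + residual variance
            elif spec.family == "bernoulli_logit":
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
                k = p
            elif spec.family == "poisson_log":
                res = sm.Poisson(y, X).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
                k = p
            elif spec.family == "negbin_log":
                res = sm.NegativeBinomial(y, X, loglike_method="nb2").fit(
                    disp=0, maxiter=500
                )
                converged = bool(res.mle_retvals.get("converged", True))
                alpha = float(res.params[-1])
                k = p + 1
            elif spec.family == "zinb":
                model = ZeroInflatedNegativeBinomialP(
                    y, X, exog_infl=np.ones((n, 1)), p=2
                )
                res = model.fit(disp=0, maxiter=500)
                converged = bool(res.mle_retvals.get("converged", True))
                if not converged or not np.isfinite(np.asarray(res.bse)).all():
                    # gradient methods can diverge when the zero part is
                    # weakly identified; retry via simplex then polish
                    res_nm = model.fit(disp=0, maxiter=3000, method="nm")
                    try:
                        res2 = model.fit(
                            disp=0, maxiter=500, start_params=res_nm.params
                        )
                    except Exception:
                        res2 = res_nm
                    cand = res2 if np.isfinite(res2.llf) else res_nm
                    if np.isfinite(cand.llf) and (
                        not np.isfinite(res.llf) or cand.llf >= res.llf
                    ):
                        res = cand
                    converged = bool(res.mle_retvals.get("converged", True))
                if not np.isfinite(np.asarray(res.bse)).all():
                    # observed information via the model Hessian when the
                    # default covariance inversion failed
                    bse_override = _hessian_bse(model, np.asarray(res.params))
                    converged = converged and bse_override is not None
                zero_gamma = float(res.params[0])
                alpha = float(res.params[-1])
                k = p + 2  # + zero-inflation intercept + dispersion
            else:  # pragma: no cover
                raise ValueError(spec.family)
            # bse is lazy; force it here so numerical warnings stay suppressed
            params = np.asarray(res.params, dtype=float)
            bse = (
                bse_override
                if bse_override is not None
                else np.asarray(res.bse, dtype=float)
            )
            ll = float(res.llf)
        except (np.linalg.LinAlgError, ValueError, RuntimeError) as e:
            return FitResult(
                spec=spec, coef={}, se={}, loglik=float("nan"), k=0, n=n,
                aicc=float("inf"), converged=False, message=str(e),
            )

    names = list(X.columns)
    if spec.family == "zinb":
        coef = dict(zip(names, params[1: 1 + p]))
        se = dict(zip(names, bse[1: 1 + p]))
    elif spec.family == "negbin_log":
        coef = dict(zip(names, params[:p]))
        se = dict(zip(names, bse[:p]))
    else:
        coef = dict(zip(names, params[:p]))
        se = dict(zip(names, bse[:p]))
    if not np.isfinite(list(se.values())).all():
        converged = False
    return FitResult(
        spec=spec, coef=coef, se=se, loglik=ll, k=k, n=n,
        aicc=aicc(ll, k, n), converged=converged,
        zero_infl_intercept=zero_gamma, dispersion=alpha, message=message,
    )


def candidate_set(response: str, family: str, covariates) -> list[ModelSpec]:
    """All 2^p covariate subsets (no interactions), intercept-only included."""
    covariates = list(covariates)
    if len(covariates) > 8:
        raise ValueError("candidate set limited to <=8 covariates")
    specs = []
    for r in range(len(covariates) + 1):
        for combo in itertools.combinations(covariates, r):
            specs.append(ModelSpec(response=response, family=family, covariates=combo))
    return specs


def fit_candidates(specs, data: pd.DataFrame) -> list[FitResult]:
    return [fit_ml(s, data) for s in specs]


def akaike_weights(aiccs) -> np.ndarray:
    """Normalized exp(-dAICc/2) over a model set."""
    a = np.asarray(aiccs, dtype=float)
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass
class AveragedResult:
    """Full (zero-substitution) model average over the dAICc < 4 set.

    ``table`` rows carry the averaged effect size, its unconditional SE
    (Burnham-Anderson), the Wald 95% CI, and the informativeness flag
    (CI excludes zero).
    """

    covariates: tuple[str, ...]
    beta: dict[str, float]
    se: dict[str, float]
    lci: dict[str, float]
    uci: dict[str, float]
    informative: dict[str, bool]
    weights: list[float] = field(default_factory=list)
    retained: list[FitResult] = field(default_factory=list)
    delta_max: float = 4.0

    def table(self, nd: int = 3) -> pd.DataFrame:
        rows = []
        for name in self.covariates:
            rows.append(
                {
                    "Variable": name,
                    "beta": round_half_up(self.beta[name], nd),
                    "SE": round_half_up(self.se[name], nd),
                    "LCI": round_half_up(self.lci[name], nd),
                    "UCI": round_half_up(self.uci[name], nd),
                    "informative": self.informative[name],
                }
            )
        return pd.DataFrame(rows)


def model_average(fits, delta_max: float = 4.0) -> AveragedResult:
    """Average the converged fits within ``delta_max`` AICc of the best.

    Full averaging: a model lacking a covariate contributes beta = 0 to that
    covariate's average.  Unconditional SE per Burnham-Anderson:
    ``SE = sum_i w_i * sqrt(se_i^2 + (beta_i - beta_avg)^2)``.  95% CI is
    Wald (beta +/- 1.96 SE); a CI containing zero marks the term
    uninformative.
    """
    fits = [f for f in fits if f.converged and np.isfinite(f.aicc)]
    if not fits:
        raise ValueError("no converged fits to average")
    best = min(f.aicc for f in fits)
    retained = sorted(
        (f for f in fits if f.aicc - best < delta_max), key=lambda f: f.aicc
    )
    w = akaike_weights([f.aicc for f in retained])

    terms: list[str] = []
    for f in retained:
        for c in f.coef:
            if c != "const" and c not in terms:
                terms.append(c)
    beta, se, lci, uci, info = {}, {}, {}, {}, {}
    for name in ["const"] + terms:
        b_i = np.array([f.coef.get(name, 0.0) for f in retained])
        s_i = np.array([f.se.get(name, 0.0) for f in retained])
        b_avg = float(np.sum(w * b_i))
        s_avg = float(np.sum(w * np.sqrt(s_i**2 + (b_i - b_avg) ** 2)))
        beta[name] = b_avg
        se[name] = s_avg
        lci[name] = b_avg - 1.96 * s_avg
        uci[name] = b_avg + 1.96 * s_avg
        info[name] = not (lci[name] <= 0.0 <= uci[name])
    return AveragedResult(
        covariates=tuple(["const"] + terms),
        beta=beta, se=se, lci=lci, uci=uci, informative=info,
        weights=[float(x) for x in w], retained=retained, delta_max=delta_max,
    )


def collinearity_screen(data: pd.DataFrame, covariates, threshold_r: float = 0.6):
    """Pairwise |Pearson r| among covariates; pairs with |r| >= threshold are
    flagged.  Categorical covariates enter as their treatment dummies."""
    X = build_design(data, covariates).drop(columns="const")
    corr = X.corr()
    flagged = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold_r:
                flagged.append((a, b, float(r)))
    return {"matrix": corr, "flagged": flagged, "threshold_r": threshold_r}


def one_per_individual(table: pd.DataFrame, rng=None) -> pd.DataFrame:
    """Subsample a covariate table to one deployment per individual (a crude
    alternative to a random intercept for repeated deployments)."""
    rng = np.random.default_rng(rng)
    keep = []
    for _, grp in table.groupby("individual_id", sort=True):
        keep.append(grp.index[rng.integers(0, len(grp))])
    return table.loc[sorted(keep)].reset_index(drop=True)
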