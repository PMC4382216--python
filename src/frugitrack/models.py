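"""Random-intercept models of log daily range with AICc multimodel inference.

The response is the natural log of the daily range (the 95% MCP area of one
six-hour observation session, in m^2).  Candidate fixed effects are the
proportion of degraded forest in the daily range ("disturbance"), the
illuminated moon fraction, the bat's sex, and the sampling day; bat
identity enters as a random intercept to absorb repeated measures.  All
2^4 = 16 fixed-effect subsets are fitted by maximum likelihood, ranked by
the small-sample-corrected AICc, and coefficients are averaged over either
the Delta-2 top set or all models, with unconditional standard errors and
relative variable importance.

The mixed model y = X beta + b_group + eps, b ~ N(0, sigma_b^2),
eps ~ N(0, sigma_e^2) is fitted by profiling: for fixed variance ratio
lambda = sigma_b^2 / sigma_e^2 the GLS coefficients and the residual
variance have closed forms, leaving a one-dimensional concave search over
log lambda.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TERMS",
    "LmmFit",
    "ModelSet",
    "AveragedEstimates",
    "center_covariates",
    "fit_lmm",
    "aicc",
    "all_subsets",
    "model_average",
    "conditional_r2",
    "vif",
    "pearson_log_correlation",
]

#: candidate fixed-effect terms, in canonical order
TERMS = ("disturbance", "day", "moon", "sex")

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)
_PROFILE_TOL = 1e-10


@dataclass
class LmmFit:
    """One ML fit of the random-intercept model for a subset of terms."""

    terms: tuple[str, ...]
    beta: np.ndarray          # intercept first, then `terms` order
    se: np.ndarray            # GLS standard errors of beta
    sigma_b2: float
    sigma_e2: float
    loglik: float
    n: int
    fitted_fixed: np.ndarray  # X beta over the data
    converged_interior: bool

    @property
    def K(self) -> int:
        """Parameter count: intercept + slopes + two variance components."""
        return len(self.beta) + 2

    @property
    def aicc(self) -> float:
        return aicc(self)


def center_covariates(data: pd.DataFrame, terms=TERMS) -> tuple[pd.DataFrame, dict[str, float]]:
    """Subtract the mean from each covariate (sex coded 0/1 first).

    Returns the centered frame and the means used, for back-transformation.
    A constant covariate centers to all-zero and is flagged with a warning.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 records")
    out = data.copy()
    means: dict[str, float] = {}
    for t in terms:
        col = out[t]
        if col.dtype == object or col.dtype == bool:
            col = col.map({"f": 0.0, "m": 1.0, False: 0.0, True: 1.0}).astype(float) \
                if col.dtype == object else col.astype(float)
        col = col.astype(float)
        mu = float(col.mean())
        if col.nunique() == 1:
            warnings.warn(f"covariate {t!r} is constant; centered to all-zero")
        out[t] = col - mu
        means[t] = mu
    return out, means


def _design(data: pd.DataFrame, terms) -> np.ndarray:
    X = np.column_stack([np.ones(len(data))] +
                        [data[t].to_numpy(dtype=float) for t in terms])
    return X


def _profiled(y, X, groups, lam):
    """GLS fit at fixed lambda; returns (beta, cov_unit, sigma_e2, loglik).

    The marginal covariance is sigma_e^2 * V0 with V0 = I + lam * Z Z'
    block-diagonal over groups; (I + lam J)^{-1} = I - lam/(1 + lam n_g) J
    keeps everything closed-form per group.
    """
    n = len(y)
    XtViX = np.zeros((X.shape[1], X.shape[1]))
    XtViy = np.zeros(X.shape[1])
    logdet = 0.0
    blocks = []
    for g in np.unique(groups):
        m = groups == g
        ng = int(m.sum())
        shrink = lam / (1.0 + lam * ng)
        Xg, yg = X[m], y[m]
        Xs = Xg - shrink * Xg.sum(axis=0)
        XtViX += Xg.T @ Xs
        XtViy += Xs.T @ yg
        logdet += math.log1p(lam * ng)
        blocks.append((m, shrink))
    beta = np.linalg.solve(XtViX, XtViy)
    r = y - X @ beta
    rss = 0.0
    for m, shrink in blocks:
        rg = r[m]
        rss += rg @ rg - shrink * rg.sum() ** 2
    sigma_e2 = rss / n
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma_e2) + n + logdet)
    cov_unit = np.linalg.inv(XtViX)  # covariance of beta = sigma_e2 * cov_unit
    return beta, cov_unit, sigma_e2, loglik


def fit_lmm(data: pd.DataFrame, terms=(), response: str = "log_area",
            group: str = "bat_id") -> LmmFit:
    """Maximum-likelihood fit of the random-intercept model.

    Profiles the likelihood over log lambda = log(sigma_b^2 / sigma_e^2) on
    [-12, 12] by bounded scalar minimisation; the GLS coefficients and the
    residual variance are closed-form at each lambda, so the fit is
    deterministic.  A boundary optimum (effectively sigma_b^2 = 0 or a pure
    between-group model) is returned with ``converged_interior=False``.
    """
    y = data[response].to_numpy(dtype=float)
    groups = data[group].to_numpy()
    X = _design(data, terms)
    n, p = X.shape
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    if n <= p + 2:
        raise ValueError("too few observations for the requested terms")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank-deficient")

    def neg_profile(loglam):
        return -_profiled(y, X, groups, math.exp(loglam))[3]

    res = optimize.minimize_scalar(
        neg_profile, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
        options={"xatol": _PROFILE_TOL})
    loglam = float(res.x)
    # accept a boundary if it is strictly better than the interior optimum
    for b in _LOG_LAMBDA_BOUNDS:
        if neg_profile(b) < neg_profile(loglam):
            loglam = b
    interior = _LOG_LAMBDA_BOUNDS[0] + 1e-6 < loglam < _LOG_LAMBDA_BOUNDS[1] - 1e-6
    # a lambda pinned at the lower bound is sigma_b^2 = 0: refit exactly there
    lam = math.exp(loglam) if interior or loglam > 0 else 0.0
    beta, cov_unit, sigma_e2, loglik = _profiled(y, X, groups, lam)
    sigma_b2 = lam * sigma_e2
    return LmmFit(
        terms=tuple(terms),
        beta=beta,
        se=np.sqrt(sigma_e2 * np.diag(cov_unit)),
        sigma_b2=sigma_b2,
        sigma_e2=sigma_e2,
        loglik=loglik,
        n=n,
        fitted_fixed=X @ beta,
        converged_interior=interior,
    )


def aicc(fit: LmmFit) -> float:
    """Small-sample-corrected Akaike information criterion of a fit."""
    n, K = fit.n, fit.K
    if n - K - 1 <= 0:
        raise ValueError("AICc undefined: n <= K + 1")
    return -2.0 * fit.loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def conditional_r2(fit: LmmFit) -> float:
    """Variance explained by fixed plus random effects.

    R2c = (var_f + sigma_b^2) / (var_f + sigma_b^2 + sigma_e^2), with var_f
    the sample variance of the fixed-effect linear predictor.
    """
    var_f = float(np.var(fit.fitted_fixed, ddof=1)) if fit.n > 1 else 0.0
    denom = var_f + fit.sigma_b2 + fit.sigma_e2
    if denom <= 0:
        raise ValueError("zero total variance")
    return (var_f + fit.sigma_b2) / denom


@dataclass
class ModelSet:
    """All-subset ML fits ranked by AICc."""

    fits: list[LmmFit]
    aicc: np.ndarray
    delta: np.ndarray
    weight: np.ndarray
    cutoff: float = 2.0
    order: np.ndarray = field(init=False)

    def __post_init__(self):
        self.order = np.argsort(self.aicc, kind="stable")

    @property
    def top_set(self) -> list[int]:
        """Indices of models within ``cutoff`` AICc of the best."""
        return [i for i in self.order if self.delta[i] <= self.cutoff]

    @property
    def best(self) -> LmmFit:
        return self.fits[int(self.order[0])]

    def summary(self) -> pd.DataFrame:
        rows = []
        w_acc = 0.0
        for i in self.order:
            f = self.fits[i]
            w_acc += self.weight[i]
            rows.append({
                "terms": " + ".join(f.terms) if f.terms else "(intercept)",
                "K": f.K,
                "r2c": conditional_r2(f),
                "aicc": self.aicc[i],
                "delta": self.delta[i],
                "weight": self.weight[i],
                "weight_acc": w_acc,
            })
        return pd.DataFrame(rows)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights exp(-delta/2), normalised to sum to 1."""
    a = np.asarray(aicc_values, dtype=float)
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def all_subsets(data: pd.DataFrame, terms=TERMS, cutoff: float = 2.0,
                response: str = "log_area", group: str = "bat_id") -> ModelSet:
    """Fit every subset of the candidate terms and rank by AICc."""
    fits = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            fits.append(fit_lmm(data, combo, response=response, group=group))
    a = np.array([aicc(f) for f in fits])
    d = a - a.min()
    w = akaike_weights(a)
    return ModelSet(fits=fits, aicc=a, delta=d, weight=w, cutoff=cutoff)


@dataclass
class AveragedEstimates:
    table: pd.DataFrame  # index: (Intercept) + terms; estimate, se, importance, ci
    scope: str
    mode: str


def model_average(mset: ModelSet, scope: str = "delta2", mode: str = "conditional",
                  terms=TERMS, ci_multiplier: float = 1.96) -> AveragedEstimates:
    """Multimodel-averaged coefficients with unconditional standard errors.

    ``scope`` selects the models averaged over: the Delta-2 top set
    (``"delta2"``) or all subset models (``"all"``).  In ``"conditional"``
    mode each term is averaged over the scoped models that contain it (its
    natural average); in ``"full"`` mode absent terms contribute zero.  The
    unconditional SE folds between-model spread into the sampling variance,

        se = sqrt( sum_m w_m (se_m^2 + (beta_m - beta_bar)^2) ),

    and relative importance is the summed Akaike weight of the models
    containing the term over the *full* model set, regardless of scope.
    """
    if scope == "delta2":
        idx = mset.top_set
    elif scope == "all":
        idx = list(range(len(mset.fits)))
    else:
        raise ValueError("scope must be 'delta2' or 'all'")
    if not idx:
        raise ValueError("empty averaging scope")
    w = mset.weight[idx]
    w = w / w.sum()

    rows = []
    for name in ("(Intercept)",) + tuple(terms):
        betas, ses, weights = [], [], []
        for wm, i in zip(w, idx):
            f = mset.fits[i]
            if name == "(Intercept)":
                pos = 0
            elif name in f.terms:
                pos = 1 + f.terms.index(name)
            else:
                if mode == "full":
                    betas.append(0.0)
                    ses.append(0.0)
                    weights.append(wm)
                continue
            betas.append(float(f.beta[pos]))
            ses.append(float(f.se[pos]))
            weights.append(wm)
        importance = float(sum(mset.weight[i] for i, f in enumerate(mset.fits)
                               if name == "(Intercept)" or name in f.terms))
        if not weights:
            rows.append({"term": name, "estimate": np.nan, "se": np.nan,
                         "importance": importance, "ci_low": np.nan,
                         "ci_high": np.nan, "in_scope": False})
            continue
        wv = np.array(weights)
        wv = wv / wv.sum()
        b = np.array(betas)
        s = np.array(ses)
        est = float(wv @ b)
        se = float(np.sqrt(wv @ (s ** 2 + (b - est) ** 2)))
        rows.append({"term": name, "estimate": est, "se": se,
                     "importance": importance,
                     "ci_low": est - ci_multiplier * se,
                     "ci_high": est + ci_multiplier * se,
                     "in_scope": True})
    table = pd.DataFrame(rows).set_index("term")
    return AveragedEstimates(table=table, scope=scope, mode=mode)


def vif(data: pd.DataFrame, terms=TERMS) -> pd.Series:
    """Variance inflation factors: 1/(1 - R^2) of each term on the others.

    Perfect collinearity is reported as +inf with a warning.
    """
    if len(terms) < 2:
        raise ValueError("VIF needs at least 2 terms")
    X = np.column_stack([data[t].to_numpy(dtype=float) for t in terms])
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("too few observations for VIF")
    out = {}
    for j, t in enumerate(terms):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        bhat, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ bhat
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"perfect collinearity involving {t!r}")
            out[t] = math.inf
        else:
            out[t] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def pearson_log_correlation(areas, ratios, log_base: float = math.e):
    """Pearson correlation of log-transformed areas against shape ratios.

    Returns ``(r, ci_low, ci_high, p)`` with a 95% Fisher-z interval
    tanh(atanh r +/- 1.96/sqrt(n-3)) and a two-sided t test on n-2 degrees
    of freedom.  Because the log is an affine change of scale, r does not
    depend on the base.
    """
    a = np.asarray(areas, dtype=float)
    c = np.asarray(ratios, dtype=float)
    if len(a) < 4:
        raise ValueError("need at least 4 pairs")
    if (a <= 0).any():
        raise ValueError("areas must be positive")
    x = np.log(a) / math.log(log_base)
    if np.std(x) == 0 or np.std(c) == 0:
        raise ValueError("zero variance in one of the vectors")
    n = len(a)
    r, p = stats.pearsonr(x, c)
    # Fisher z is undefined at |r| = 1; clamp for the interval only
    z = math.atanh(max(-1 + 1e-15, min(1 - 1e-15, r)))
    half = 1.96 / math.sqrt(n - 3)
    return float(r), math.tanh(z - half), math.tanh(z + half), float(p)


def shapiro_normality(x, alpha: float = 0.2) -> tuple[float, bool]:
    """Shapiro-Wilk normality screen; returns (p, normal-at-alpha)."""
    p = float(stats.shapiro(np.asarray(x, dtype=float)).pvalue)
    return p, p > alpha
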