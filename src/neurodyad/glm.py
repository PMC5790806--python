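"""Dyad-level regression with multi-way cluster-robust inference.

Social distance between dyad members is modeled as a function of their
neural similarity and demographic dissimilarities, either as a
proportional-odds (ordered logistic) regression on the capped distance
category or as a binary logistic regression on a friendship indicator.
Because every subject appears in many dyads, observations are not
independent: standard errors are computed with a two-way cluster-robust
(CGM-style) sandwich that clusters simultaneously on both members of each
dyad,

    V = V_member1 + V_member2 - V_dyad,

each component a B^-1 (sum_g s_g s_g') B^-1 sandwich with cluster-summed
scores s_g and the observed information as bread; the intersection
clusters are the dyads themselves (singletons), so the subtracted term is
the plain heteroskedasticity-robust meat.

Sign convention for the ordered model:  logit P(Y <= k | x) = tau_k - x'b,
so a *negative* b for similarity means more-similar dyads sit at shorter
social distances.  The binary model uses the standard parameterization
logit P(friend = 1 | x) = a + x'b, whose similarity coefficient is
positive under the same effect.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConvergenceError",
    "DyadModelResult",
    "fit_ordered_logit",
    "fit_binary_logit",
    "fit_linear",
    "twoway_cluster_vcov",
    "oneway_cluster_vcov",
    "robust_vcov",
    "lr_test",
    "per_roi_regressions",
    "odds_interpretation",
    "deviation_coded_estimates",
]

MEMBER_COLS = ("subject_i", "subject_j")


class ConvergenceError(RuntimeError):
    """Raised when an MLE fails to converge (including perfect separation)."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclasses.dataclass
class DyadModelResult:
    """Fitted dyad-level model with (optionally clustered) inference.

    ``beta``/``se``/``p`` cover the slope parameters only; ``tau`` holds
    the ordered model's thresholds.  ``vcov`` and ``param_names`` span the
    full parameter vector (slopes first).  ``score_obs`` (n x p) and
    ``bread`` (observed information) are retained so sandwich estimators
    can be recomputed under any clustering.
    """

    model: str
    predictor_names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: float
    n_obs: int
    vcov: np.ndarray
    param_names: tuple[str, ...]
    tau: np.ndarray | None = None
    intercept: float | None = None
    converged: bool = True
    cluster: str = "twoway"
    score_obs: np.ndarray | None = dataclasses.field(default=None, repr=False)
    bread: np.ndarray | None = dataclasses.field(default=None, repr=False)
    member_ids: tuple[np.ndarray, np.ndarray] | None = dataclasses.field(
        default=None, repr=False
    )
    response: str = "distance"

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "p": self.p},
            index=list(self.predictor_names),
        )


# ---------------------------------------------------------------------------
# design-matrix helpers


def _design(
    table: pd.DataFrame, predictors: Sequence[str], standardize: bool
) -> np.ndarray:
    x = table[list(predictors)].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in predictors")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [p for p, s in zip(predictors, sd) if s == 0]
            raise ValueError(f"constant predictor(s) cannot be standardized: {bad}")
        x = (x - x.mean(axis=0)) / sd
    return x


def _wald(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return 2.0 * stats.norm.sf(np.abs(z))


def _psd_clip(v: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((v + v.T) / 2.0)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


# ---------------------------------------------------------------------------
# sandwich variance estimators


def _meat(score_obs: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Sum of outer products of within-cluster score sums."""
    codes, _ = pd.factorize(groups)
    sums = np.zeros((codes.max() + 1, score_obs.shape[1]))
    np.add.at(sums, codes, score_obs)
    return sums.T @ sums


def robust_vcov(result: DyadModelResult) -> np.ndarray:
    """Plain heteroskedasticity-robust (HC0) sandwich."""
    binv = np.linalg.pinv(result.bread)
    return binv @ (result.score_obs.T @ result.score_obs) @ binv


def oneway_cluster_vcov(result: DyadModelResult, groups: np.ndarray) -> np.ndarray:
    binv = np.linalg.pinv(result.bread)
    return binv @ _meat(result.score_obs, np.asarray(groups)) @ binv


def twoway_cluster_vcov(
    result: DyadModelResult,
    member1_ids: Sequence,
    member2_ids: Sequence,
    psd_repair: bool = True,
    small_sample: bool = False,
) -> np.ndarray:
    """Two-way cluster-robust sandwich clustering on both dyad members.

    V = V_{member1} + V_{member2} - V_{intersection}; the intersection of
    the two memberships is the dyad itself.  Negative eigenvalues (the
    subtraction can produce them) are clipped to zero.  ``small_sample``
    applies the G/(G-1) multiplier per component (off by default).
    """
    m1 = np.asarray(member1_ids)
    m2 = np.asarray(member2_ids)
    n = result.score_obs.shape[0]
    if len(m1) != n or len(m2) != n:
        raise ValueError("cluster id vectors must match the number of observations")
    c1, _ = pd.factorize(m1)
    c2, _ = pd.factorize(m2)
    inter = c1.astype(np.int64) * (c2.max() + 1) + c2
    binv = np.linalg.pinv(result.bread)

    def component(groups: np.ndarray) -> np.ndarray:
        v = binv @ _meat(result.score_obs, groups) @ binv
        if small_sample:
            g = len(np.unique(groups))
            v = v * (g / (g - 1)) if g > 1 else v
        return v

    v = component(m1) + component(m2) - component(inter)
    return _psd_clip(v) if psd_repair else v


def _finalize(
    result: DyadModelResult,
    table: pd.DataFrame | None,
    cluster: str,
    n_slopes: int,
) -> DyadModelResult:
    """Attach the requested vcov and Wald inference to a fitted model."""
    if cluster == "twoway":
        if result.member_ids is None:
            raise ValueError("two-way clustering requires dyad member ids")
        v = twoway_cluster_vcov(result, *result.member_ids)
    elif cluster == "robust":
        v = robust_vcov(result)
    elif cluster == "none":
        v = np.linalg.pinv(result.bread)
    else:
        raise ValueError(f"unknown cluster mode {cluster!r}")
    se_all = np.sqrt(np.clip(np.diag(v), 0.0, None))
    result.vcov = v
    result.cluster = cluster
    result.se = se_all[:n_slopes]
    result.p = _wald(result.beta, result.se)
    return result


# ---------------------------------------------------------------------------
# proportional-odds (ordered logistic) model


def _ordered_loglik_parts(theta, x, y_codes, n_cat):
    """Loglik, per-obs natural-parameter scores for the ordered model.

    theta = (beta_1..beta_p, tau_1..tau_{K-1}); y_codes in 0..K-1.
    """
    p = x.shape[1]
    beta, tau = theta[:p], theta[p:]
    eta = x @ beta
    # cut points per observation
    hi = np.where(y_codes < n_cat - 1, tau[np.minimum(y_codes, n_cat - 2)] - eta, np.inf)
    lo = np.where(y_codes > 0, tau[np.maximum(y_codes - 1, 0)] - eta, -np.inf)
    f_hi = special.expit(hi)
    f_lo = special.expit(lo)
    prob = np.clip(f_hi - f_lo, 1e-300, None)
    ll = float(np.log(prob).sum())

    d_hi = f_hi * (1.0 - f_hi)  # logistic pdf; 0 at +/- inf
    d_lo = f_lo * (1.0 - f_lo)
    d_hi = np.where(np.isfinite(hi), d_hi, 0.0)
    d_lo = np.where(np.isfinite(lo), d_lo, 0.0)

    n = x.shape[0]
    score = np.zeros((n, p + n_cat - 1))
    deta = (d_lo - d_hi) / prob
    score[:, :p] = x * deta[:, None]
    rows = np.arange(n)
    mask_hi = y_codes < n_cat - 1
    score[rows[mask_hi], p + y_codes[mask_hi]] += (d_hi / prob)[mask_hi]
    mask_lo = y_codes > 0
    score[rows[mask_lo], p + y_codes[mask_lo] - 1] -= (d_lo / prob)[mask_lo]
    return ll, score


def _numeric_hessian(grad_fn, theta: np.ndarray) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    k = theta.size
    h = 1e-5 * (1.0 + np.abs(theta))
    hess = np.zeros((k, k))
    for j in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        hess[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * h[j])
    return (hess + hess.T) / 2.0


def fit_ordered_logit(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str = "distance",
    standardize: bool = True,
    cluster: str = "twoway",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> DyadModelResult:
    """Proportional-odds MLE, logit P(Y <= k | x) = tau_k - x'b.

    Thresholds are optimized in a log-difference parameterization that
    keeps them ordered, initialized from cumulative category frequencies;
    slopes start at zero.  Convergence requires the natural-parameter
    gradient norm to fall below tolerance; failure (including separation)
    raises :class:`ConvergenceError` with diagnostics.
    """
    x = _design(table, predictors, standardize)
    y_raw = table[response].to_numpy()
    cats = np.unique(y_raw)
    n_cat = len(cats)
    if n_cat < 2:
        raise ValueError("response must have at least 2 occupied categories")
    y = np.searchsorted(cats, y_raw)
    n, p = x.shape
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), x])) < p + 1:
        warnings.warn("design matrix is rank deficient; inference uses a "
                      "pseudo-inverse", stacklevel=2)

    cumfreq = np.cumsum(np.bincount(y, minlength=n_cat))[:-1] / n
    tau0 = special.logit(cumfreq)
    # alpha parameterization: tau_1 = a_1, tau_k = tau_{k-1} + exp(a_k)
    alpha0 = np.concatenate([[tau0[0]], np.log(np.maximum(np.diff(tau0), 1e-8))])
    theta0 = np.concatenate([np.zeros(p), alpha0])

    def to_tau(alpha):
        return np.concatenate([[alpha[0]], alpha[0] + np.cumsum(np.exp(alpha[1:]))])

    def unpack(vec):
        return np.concatenate([vec[:p], to_tau(vec[p:])])

    def negloglik_grad(vec):
        theta = unpack(vec)
        ll, score = _ordered_loglik_parts(theta, x, y, n_cat)
        g_nat = score.sum(axis=0)
        # chain rule into the alpha parameterization
        alpha = vec[p:]
        g_alpha = np.empty_like(alpha)
        g_tau = g_nat[p:]
        g_alpha[0] = g_tau.sum()
        if alpha.size > 1:
            rev = np.cumsum(g_tau[::-1])[::-1]  # sum_{k>=m} g_tau[k]
            g_alpha[1:] = np.exp(alpha[1:]) * rev[1:]
        return -ll, -np.concatenate([g_nat[:p], g_alpha])

    res = optimize.minimize(
        negloglik_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    theta = unpack(res.x)
    ll, score = _ordered_loglik_parts(theta, x, y, n_cat)
    gnorm = float(np.abs(score.sum(axis=0)).max())
    if gnorm > 1e-4 or np.abs(theta[:p]).max(initial=0.0) > 30:
        raise ConvergenceError(
            "ordered logit failed to converge (possible separation)",
            {"grad_norm": gnorm, "beta": theta[:p], "message": res.message},
        )

    def grad_nat(th):
        _, s = _ordered_loglik_parts(th, x, y, n_cat)
        return s.sum(axis=0)

    bread = -_numeric_hessian(grad_nat, theta)
    names = tuple(predictors) + tuple(f"tau_{k+1}" for k in range(n_cat - 1))
    member_ids = None
    if all(c in table.columns for c in MEMBER_COLS):
        member_ids = (
            table[MEMBER_COLS[0]].to_numpy(),
            table[MEMBER_COLS[1]].to_numpy(),
        )
    elif cluster == "twoway":
        cluster = "robust"

    result = DyadModelResult(
        model="ordered_logit",
        predictor_names=tuple(predictors),
        beta=theta[:p],
        se=np.empty(p),
        p=np.empty(p),
        tau=theta[p:],
        loglik=ll,
        n_obs=n,
        vcov=np.empty((p, p)),
        param_names=names,
        score_obs=score,
        bread=bread,
        member_ids=member_ids,
        response=response,
    )
    return _finalize(result, table, cluster, p)


# ---------------------------------------------------------------------------
# binary logistic model


def fit_binary_logit(
    table: pd.DataFrame,
    predictors: Sequence[str],
    response: str = "friend",
    standardize: bool = True,
    cluster: str = "twoway",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> DyadModelResult:
    """Bernoulli MLE, logit P(Y = 1 | x) = a + x'b, by Newton-Raphson.

    The friendship indicator (distance category 1) is the canonical
    response.  Perfect separation is flagged as :class:`ConvergenceError`.
    """
    x = _design(table, predictors, standardize)
    y = table[response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary response must be 0/1")
    if y.min() == y.max():
        raise ValueError("response is constant")
    n, p = x.shape
    design = np.column_stack([x, np.ones(n)])  # slopes first, intercept last
    if np.linalg.matrix_rank(design) < p + 1:
        warnings.warn("design matrix is rank deficient; inference uses a "
                      "pseudo-inverse", stacklevel=2)

    def loglik(th):
        mu = special.expit(design @ th)
        return float(np.sum(y * np.log(np.clip(mu, 1e-300, None))
                            + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None))))

    theta = np.zeros(p + 1)
    theta[-1] = special.logit(y.mean())
    converged = False
    ll_cur = loglik(theta)
    for _ in range(max_iter):
        mu = special.expit(design @ theta)
        grad = design.T @ (y - mu)
        w = mu * (1.0 - mu)
        hess = (design * w[:, None]).T @ design
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(p + 1), grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Hessian in logistic fit") from exc
        # safeguarded ascent: halve the Newton step until loglik improves
        scale = 1.0
        for _ in range(30):
            ll_new = loglik(theta + scale * step)
            if ll_new >= ll_cur - 1e-12:
                break
            scale /= 2.0
        theta = theta + scale * step
        ll_cur = ll_new
        if np.abs(grad).max() < tol and np.abs(scale * step).max() < 1e-8:
            converged = True
            break
    eta = design @ theta
    mu = special.expit(eta)
    if not converged or np.abs(theta).max() > 30:
        raise ConvergenceError(
            "logistic fit failed to converge (possible separation)",
            {"beta": theta[:p], "max_abs_param": float(np.abs(theta).max())},
        )
    ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, None))
                      + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None))))
    score = design * (y - mu)[:, None]
    bread = (design * (mu * (1 - mu))[:, None]).T @ design

    member_ids = None
    if all(c in table.columns for c in MEMBER_COLS):
        member_ids = (
            table[MEMBER_COLS[0]].to_numpy(),
            table[MEMBER_COLS[1]].to_numpy(),
        )
    elif cluster == "twoway":
        cluster = "robust"

    result = DyadModelResult(
        model="binary_logit",
        predictor_names=tuple(predictors),
        beta=theta[:p],
        se=np.empty(p),
        p=np.empty(p),
        tau=None,
        intercept=float(theta[-1]),
        loglik=ll,
        n_obs=n,
        vcov=np.empty((p, p)),
        param_names=tuple(predictors) + ("intercept",),
        score_obs=score,
        bread=bread,
        member_ids=member_ids,
        response=response,
    )
    return _finalize(result, table, cluster, p)


# ---------------------------------------------------------------------------
# linear model (used for deviation-coded similarity contrasts)


def fit_linear(
    table: pd.DataFrame,
    design: np.ndarray,
    response: np.ndarray,
    param_names: Sequence[str],
    cluster: str = "twoway",
) -> DyadModelResult:
    """OLS with the same score/bread interface as the likelihood models.

    Scores are x_i * e_i and the bread is X'X, so all sandwich estimators
    apply unchanged.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    sigma2 = max(float(resid @ resid) / max(n - p, 1), 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)

    member_ids = None
    if all(c in table.columns for c in MEMBER_COLS):
        member_ids = (
            table[MEMBER_COLS[0]].to_numpy(),
            table[MEMBER_COLS[1]].to_numpy(),
        )
    elif cluster == "twoway":
        cluster = "robust"

    result = DyadModelResult(
        model="ols",
        predictor_names=tuple(param_names),
        beta=coef,
        se=np.empty(p),
        p=np.empty(p),
        tau=None,
        loglik=ll,
        n_obs=n,
        vcov=np.empty((p, p)),
        param_names=tuple(param_names),
        score_obs=x * resid[:, None],
        bread=x.T @ x,
        member_ids=member_ids,
        response="similarity",
    )
    return _finalize(result, table, cluster, p)


# ---------------------------------------------------------------------------
# model comparison & multiplicity


def lr_test(full: DyadModelResult, reduced: DyadModelResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested dyad models.

    chi2 = 2 (l_full - l_reduced) against chi-square with df = difference
    in parameter count.
    """
    if full.model != reduced.model or full.response != reduced.response:
        raise ValueError("models must share family and response")
    if full.n_obs != reduced.n_obs:
        raise ValueError("models must be fit to the same data")
    if not set(reduced.predictor_names) <= set(full.predictor_names):
        raise ValueError("reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than the reduced model")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def per_roi_regressions(
    table: pd.DataFrame,
    controls: Sequence[str],
    roi_columns: Sequence[str] | None = None,
    response: str = "distance",
    standardize: bool = True,
    cluster: str = "twoway",
) -> pd.DataFrame:
    """One ordered-logit fit per ROI with BH-FDR across the converged fits.

    Each model regresses social distance on that ROI's z-scored similarity
    plus all controls.  ROIs whose fit fails to converge are retained in
    the output with NaN estimates and excluded from the FDR family (with a
    warning), never silently dropped.
    """
    if roi_columns is None:
        roi_columns = [c for c in table.columns if c.startswith("z_")]
    rows = []
    for col in roi_columns:
        try:
            fit = fit_ordered_logit(
                table, [col, *controls], response=response,
                standardize=standardize, cluster=cluster,
            )
            rows.append(
                {"roi": col.removeprefix("z_"), "beta": fit.beta[0],
                 "se": fit.se[0], "p_raw": fit.p[0], "converged": True}
            )
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"ROI {col}: fit failed ({exc}); excluded from FDR family",
                          stacklevel=2)
            rows.append({"roi": col.removeprefix("z_"), "beta": np.nan,
                         "se": np.nan, "p_raw": np.nan, "converged": False})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    ok = out["converged"].to_numpy()
    if ok.any():
        _, adj, *_ = multipletests(out.loc[ok, "p_raw"], method="fdr_bh")
        out.loc[ok, "p_fdr"] = adj
    return out


def odds_interpretation(beta: float) -> float:
    """Percent change in odds per one-SD predictor increase: 100 (e^b - 1)."""
    return 100.0 * (np.exp(beta) - 1.0)


def deviation_coded_estimates(
    table: pd.DataFrame,
    controls: Sequence[str] = (),
    response: str = "similarity",
    category: str = "distance",
    cluster: str = "twoway",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Deviation-coded category contrasts of composite similarity.

    Linear model of the composite on a full set of category indicators
    plus mean-centered controls; the estimate for category k is its
    adjusted mean minus the unweighted average of the other categories'
    adjusted means, with the CI taken from the two-way clustered vcov.
    """
    cats = np.sort(table[category].unique())
    k = len(cats)
    if k < 2:
        raise ValueError("need at least 2 categories")
    if (table[category].value_counts() < 1).any():
        raise ValueError("empty category")
    dummies = (table[category].to_numpy()[:, None] == cats[None, :]).astype(float)
    names = [f"cat_{c}" for c in cats]
    if controls:
        ctrl = table[list(controls)].to_numpy(dtype=float)
        ctrl = ctrl - ctrl.mean(axis=0)
        design = np.column_stack([dummies, ctrl])
        names = names + list(controls)
    else:
        design = dummies
    fit = fit_linear(table, design, table[response].to_numpy(dtype=float),
                     names, cluster=cluster)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for idx, c in enumerate(cats):
        contrast = np.zeros(len(names))
        contrast[:k] = -1.0 / (k - 1)
        contrast[idx] = 1.0
        est = float(contrast @ fit.beta)
        var = float(contrast @ fit.vcov @ contrast)
        se = np.sqrt(max(var, 0.0))
        rows.append(
            {"category": int(c), "estimate": est, "se": se,
             "ci_low": est - zcrit * se, "ci_high": est + zcrit * se,
             "n": int((table[category] == c).sum())}
        )
    return pd.DataFrame(rows)
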