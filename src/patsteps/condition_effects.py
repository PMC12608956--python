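"""Zero-inflated negative binomial condition-effect model.

The influence of the walking conditions on device step counts is modelled
by a zero-inflated negative binomial (ZINB) regression with the true step
count as exposure and the condition as the only covariate:

    count ~ ZINB(pi_c, mu_c),   mu_c = true_steps * exp(b0 + b_c),
    logit(pi_c) = g0 + g_c,

so the inflation part captures conditions below the device's detection
limit (no steps detected at all) and the count part captures miscounting
above the limit.  Within-participant dependence (each rater walks every
condition twice) is handled by cluster-robust (Huber-White sandwich)
standard errors with participants as clusters, not by random effects.

Reported quantities are marginal means at a true step count of 20,
``E[count | c] = (1 - pi_c) * 20 * exp(b0 + b_c)``, with delta-method
standard errors from the cluster-robust covariance, together with
step-size contrasts within each condition category, category-vs-S
contrasts at matched step sizes, and a global Wald test of equality of
all condition marginal means.

Estimation uses statsmodels' ZINB likelihood with a staged optimisation
(negative-binomial warm start, Nelder-Mead, then BFGS polish).  When the
data contain no zeros the inflation part is unidentifiable and the model
falls back to a plain negative binomial, flagged on the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .protocol import ANALYSIS_CODES, VALID_STEP_SIZES

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE = "S-100"
InflationMode = Literal["condition", "intercept"]


class FitError(RuntimeError):
    """Raised when the condition-effect model cannot be fitted."""


@dataclass
class ZinbFit:
    """Fitted condition-effect model with cluster-robust covariance.

    ``boundary_conditions`` lists conditions whose counts were all zero:
    their maximum-likelihood solution is the boundary (inflation
    probability 1, marginal mean 0) and is separable from the rest of the
    likelihood, so they are reported exactly rather than fitted.
    """

    result: object                       # statsmodels results wrapper
    conditions: list[str]                # fitted levels, reference first
    reference: str
    model_kind: str                      # "zinb" or "nb" (fallback)
    inflation_mode: str                  # "condition", "intercept" or "none"
    n_clusters: int
    n_obs: int
    converged: bool
    cov_matrix: np.ndarray | None = None  # cluster-robust (sandwich)
    boundary_conditions: list[str] = field(default_factory=list)
    true_steps_exposure: float = 20.0
    notes: list[str] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.result.params, dtype=float)

    @property
    def cov(self) -> np.ndarray:
        if self.cov_matrix is not None:
            return self.cov_matrix
        return np.asarray(self.result.cov_params(), dtype=float)

    @property
    def all_conditions(self) -> list[str]:
        """Fitted conditions followed by boundary (all-zero) conditions."""
        return self.conditions + self.boundary_conditions

    def count_coefficients(self) -> dict[str, float]:
        """Log-scale condition effects in the count part (reference = 0)."""
        k = len(self.conditions)
        base = self._count_offset()
        coefs = self.params[base + 1: base + k]
        out = {self.reference: 0.0}
        out.update({c: float(v) for c, v in zip(self.conditions[1:], coefs)})
        return out

    def inflation_probabilities(self) -> dict[str, float]:
        """Zero-inflation probability per condition (boundary ones are 1)."""
        out = {c: 1.0 for c in self.boundary_conditions}
        if self.model_kind == "nb":
            out.update({c: 0.0 for c in self.conditions})
            return out
        k = len(self.conditions)
        g0 = self.params[0]
        if self.inflation_mode == "intercept":
            pi = 1.0 / (1.0 + np.exp(-g0))
            out.update({c: float(pi) for c in self.conditions})
            return out
        etas = np.r_[g0, g0 + self.params[1:k]]
        out.update({c: float(1.0 / (1.0 + np.exp(-e)))
                    for c, e in zip(self.conditions, etas)})
        return out

    def _count_offset(self) -> int:
        """Index of the count-part intercept in the parameter vector."""
        if self.model_kind == "nb":
            return 0
        return 1 if self.inflation_mode == "intercept" else len(self.conditions)

    def overdispersion(self) -> float:
        return float(self.params[-1])


def _design(conditions: pd.Series, levels: list[str]) -> np.ndarray:
    """Intercept + dummy design with the first level as reference."""
    x = np.zeros((len(conditions), len(levels)))
    x[:, 0] = 1.0
    for j, lev in enumerate(levels[1:], start=1):
        x[:, j] = (conditions == lev).to_numpy(dtype=float)
    return x


def fit_zinb(
    trials: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE,
    inflation: InflationMode = "condition",
    true_steps_exposure: float = 20.0,
) -> ZinbFit:
    """Fit the ZINB condition-effect model for one PAT's trials.

    ``trials`` needs columns participant_id, condition, true_steps,
    counted_steps (no missing counts).  The condition factor enters both
    the count and (by default) the inflation component; participants are
    the sandwich clusters.
    """
    df = trials.dropna(subset=["counted_steps"]).copy()
    all_levels = [c for c in ANALYSIS_CODES if c in set(df["condition"])]
    if len(all_levels) < 2:
        raise FitError("need at least two conditions with data")
    notes: list[str] = []

    # conditions with all-zero counts sit on the likelihood boundary
    # (inflation probability 1, marginal mean 0) and are separable from
    # the rest of the model; report them exactly instead of fitting
    zero_by_cond = (df.assign(z=df["counted_steps"] == 0)
                    .groupby("condition")["z"].mean())
    boundary = [c for c in all_levels if zero_by_cond.get(c, 0.0) >= 1.0]
    if boundary:
        notes.append(f"all-zero conditions reported at the boundary "
                     f"(inflation 1): {boundary}")
        logger.info(notes[-1])
        df = df[~df["condition"].isin(boundary)]
    levels = [c for c in all_levels if c not in boundary]
    if reference in levels:
        levels = [reference] + [c for c in levels if c != reference]
    else:
        reference = levels[0]
    if len(levels) < 1:
        raise FitError("no non-degenerate conditions to fit")

    y = df["counted_steps"].to_numpy(dtype=float)
    exposure = df["true_steps"].to_numpy(dtype=float)
    groups = df["participant_id"].to_numpy()
    x = _design(df["condition"], levels)

    if not (y == 0).any():
        notes.append("no zero counts: inflation unidentifiable, "
                     "fell back to plain negative binomial")
        logger.info(notes[-1])
        res, cov, conv = _fit_nb(y, x, exposure, groups)
        return ZinbFit(res, levels, reference, "nb", "none",
                       len(np.unique(groups)), len(df), conv, cov,
                       boundary, true_steps_exposure, notes)

    x_infl = x if inflation == "condition" else x[:, :1]
    res, cov, conv = _fit_zinb_staged(y, x, x_infl, exposure, groups)
    if res is None and inflation == "condition":
        notes.append("ZINB optimisation failed with condition inflation; "
                     "retrying with intercept-only inflation")
        logger.warning(notes[-1])
        inflation = "intercept"
        x_infl = x[:, :1]
        res, cov, conv = _fit_zinb_staged(y, x, x_infl, exposure, groups)
    if res is None:
        raise FitError("ZINB fit did not converge")
    return ZinbFit(res, levels, reference, "zinb", inflation,
                   len(np.unique(groups)), len(df), conv, cov,
                   boundary, true_steps_exposure, notes)


def _cluster_sandwich(model, params: np.ndarray,
                      groups: np.ndarray) -> np.ndarray | None:
    """Huber-White sandwich with participant clusters.

    The bread uses a pseudo-inverse so that flat likelihood directions
    (perfectly separated inflation levels whose probabilities sit at 0)
    do not poison the covariance; the delta-method Jacobian of any
    reported quantity vanishes in those directions.
    """
    try:
        hess = model.hessian(params)
        scores = model.score_obs(params)
    except Exception as exc:
        logger.warning("sandwich computation failed: %s", exc)
        return None
    if not np.isfinite(hess).all() or not np.isfinite(scores).all():
        return None
    bread = np.linalg.pinv(-hess, rcond=1e-10)
    labels, idx = np.unique(groups, return_inverse=True)
    n_g = len(labels)
    meat = np.zeros((len(params), len(params)))
    for g in range(n_g):
        s = scores[idx == g].sum(axis=0)
        meat += np.outer(s, s)
    meat *= n_g / max(n_g - 1, 1)  # standard small-sample cluster factor
    return bread @ meat @ bread


def _fit_nb(y, x, exposure, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = sm.NegativeBinomialP(y, x, exposure=exposure, p=2)
        res = mod.fit(disp=0, maxiter=500)
    cov = _cluster_sandwich(mod, np.asarray(res.params, float), groups)
    if cov is None:
        # degenerate (e.g. zero-variance) data: means remain reportable
        logger.warning("covariance unavailable for NB fit; "
                       "standard errors set to zero")
        cov = np.zeros((len(res.params), len(res.params)))
    return res, cov, bool(res.mle_retvals.get("converged", True))


def _fit_zinb_staged(y, x, x_infl, exposure, groups):
    """NB warm start -> Nelder-Mead -> BFGS -> cluster sandwich."""
    k_infl = x_infl.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos = y > 0
        try:
            nb = sm.NegativeBinomialP(y[pos], x[pos], exposure=exposure[pos], p=2)
            nbres = nb.fit(disp=0, maxiter=500)
            count_start = np.asarray(nbres.params, dtype=float)
        except Exception:
            count_start = np.r_[np.log(max(y[pos].mean(), 1.0) /
                                       exposure[pos].mean()),
                                np.zeros(x.shape[1] - 1), 0.3]
        if not np.isfinite(count_start).all():
            count_start = np.r_[0.0, np.zeros(x.shape[1] - 1), 0.3]
        count_start[-1] = float(np.clip(count_start[-1], 0.02, 5.0))
        zf = float(np.clip((y == 0).mean(), 0.02, 0.95))
        start = np.r_[np.log(zf / (1 - zf)), np.zeros(k_infl - 1), count_start]
        mod = sm.ZeroInflatedNegativeBinomialP(
            y, x, exog_infl=x_infl, exposure=exposure, inflation="logit", p=2)
        try:
            res = mod.fit(start_params=start, method="nm",
                          maxiter=5000, disp=0)
            res = mod.fit(start_params=res.params, method="bfgs",
                          maxiter=1000, disp=0)
        except Exception as exc:  # singular hessian, overflow, ...
            logger.warning("ZINB staged fit raised %s", exc)
            return None, None, False
        params = np.asarray(res.params, dtype=float)
        if not np.isfinite(params).all() or params[-1] <= 0:
            return None, None, False
    cov = _cluster_sandwich(mod, params, groups)
    if cov is None:
        return None, None, False
    return res, cov, bool(res.mle_retvals.get("converged", True))


# ---------------------------------------------------------------------------
# marginal means and contrasts


def _marginal_mean_vector(fit: ZinbFit, params: np.ndarray,
                          true_steps: float) -> np.ndarray:
    """Marginal mean per condition at the given exposure, for any params."""
    k = len(fit.conditions)
    base = fit._count_offset()
    b0 = params[base]
    betas = np.r_[0.0, params[base + 1: base + k]]
    mu = true_steps * np.exp(b0 + betas)
    if fit.model_kind == "nb":
        return mu
    g0 = params[0]
    if fit.inflation_mode == "intercept":
        eta = np.full(k, g0)
    else:
        eta = np.r_[g0, g0 + params[1:k]]
    pi = 1.0 / (1.0 + np.exp(-eta))
    return (1.0 - pi) * mu


def marginal_means(fit: ZinbFit, true_steps: float | None = None) -> pd.DataFrame:
    """Expected counted steps per condition at a fixed true step count.

    Standard errors by the delta method from the cluster-robust
    covariance (numerical Jacobian; the transformation is smooth).
    """
    t = fit.true_steps_exposure if true_steps is None else true_steps
    m, cov_m = _marginal_cov(fit, t)
    se = np.sqrt(np.clip(np.diag(cov_m), 0.0, None))
    return pd.DataFrame({"condition": fit.all_conditions,
                         "marginal_mean": m, "se": se})


def _numeric_jacobian(fun, params: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    f0 = fun(params)
    jac = np.zeros((len(f0), len(params)))
    for j in range(len(params)):
        h = eps * max(1.0, abs(params[j]))
        up, dn = params.copy(), params.copy()
        up[j] += h
        dn[j] -= h
        jac[:, j] = (fun(up) - fun(dn)) / (2 * h)
    return jac


def _marginal_cov(fit: ZinbFit, true_steps: float) -> tuple[np.ndarray, np.ndarray]:
    """Marginal means and delta-method covariance over all conditions.

    Boundary (all-zero) conditions are appended with mean 0 and zero
    variance: their MLE is the exact boundary point.
    """
    params = fit.params
    m = _marginal_mean_vector(fit, params, true_steps)
    jac = _numeric_jacobian(lambda p: _marginal_mean_vector(fit, p, true_steps),
                            params)
    cov = jac @ fit.cov @ jac.T
    nb = len(fit.boundary_conditions)
    if nb:
        m = np.r_[m, np.zeros(nb)]
        full = np.zeros((len(m), len(m)))
        full[:len(cov), :len(cov)] = cov
        cov = full
    return m, cov


def _wald(est: np.ndarray, cov: np.ndarray) -> tuple[float, int, float]:
    """Wald chi-square of H0: est = 0 with a pseudo-inverse for safety."""
    cov = np.atleast_2d(cov)
    est = np.atleast_1d(est)
    rank = np.linalg.matrix_rank(cov, tol=1e-10)
    stat = float(est @ np.linalg.pinv(cov) @ est)
    dof = int(max(rank, 1))
    return stat, dof, float(stats.chi2.sf(stat, dof))


@dataclass
class MarginalContrast:
    """One contrast of marginal mean counted steps (at 20 true steps)."""

    label: str
    estimate: float
    std_error: float
    p_value: float


def contrast_tests(
    fit: ZinbFit, true_steps: float | None = None, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Step-size and category contrasts of marginal means, plus global test.

    Emitted contrasts (when the involved conditions are present):

    * within each category: pairwise step-size differences and, for
      categories with >2 levels (S), a joint Wald test of equality and a
      linear step-size trend;
    * each category vs S at matched step sizes, averaged over the step
      sizes present (e.g. W vs S averaged over 75 % and 40 %);
    * a global Wald test of no difference between any conditions.

    All inference is on the marginal-mean scale via the delta method with
    the cluster-robust covariance and a large-sample normal/chi-square
    reference.
    """
    t = fit.true_steps_exposure if true_steps is None else true_steps
    m, cov_m = _marginal_cov(fit, t)
    conditions = fit.all_conditions
    idx = {c: i for i, c in enumerate(conditions)}
    k = len(conditions)

    def contrast_row(label: str, weights: dict[str, float]) -> MarginalContrast:
        l = np.zeros(k)
        for c, w in weights.items():
            l[idx[c]] = w
        est = float(l @ m)
        se = float(np.sqrt(max(l @ cov_m @ l, 0.0)))
        z = est / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        return MarginalContrast(label, est, se, float(p))

    by_cat: dict[str, list[tuple[int, str]]] = {}
    for c in conditions:
        cat, pct = c.split("-")
        by_cat.setdefault(cat, []).append((int(pct), c))
    for cat in by_cat:
        by_cat[cat].sort(reverse=True)

    rows: list[MarginalContrast] = []
    joint_rows: list[dict] = []

    # within-category step-size effects
    for cat, levels in by_cat.items():
        if len(levels) < 2:
            continue
        for (p_hi, c_hi), (p_lo, c_lo) in zip(levels[:-1], levels[1:]):
            rows.append(contrast_row(f"{cat}: {p_hi}% vs {p_lo}%",
                                     {c_hi: 1.0, c_lo: -1.0}))
        if len(levels) > 2:
            d = np.zeros((len(levels) - 1, k))
            for r, ((_, c_hi), (_, c_lo)) in enumerate(
                    zip(levels[:-1], levels[1:])):
                d[r, idx[c_hi]], d[r, idx[c_lo]] = 1.0, -1.0
            stat, dof, p = _wald(d @ m, d @ cov_m @ d.T)
            joint_rows.append({"label": f"{cat}: equality across step sizes",
                               "statistic": stat, "dof": dof, "p_value": p})
            pcts = np.array([p for p, _ in levels], dtype=float)
            w = pcts - pcts.mean()
            rows.append(contrast_row(
                f"{cat}: linear step-size trend",
                {c: w[i] / 100.0 for i, (_, c) in enumerate(levels)}))

    # category vs S at matched step sizes, averaged over matches
    s_levels = {p: c for p, c in by_cat.get("S", [])}
    for cat, levels in by_cat.items():
        if cat == "S":
            continue
        matched = [(c, s_levels[p]) for p, c in levels if p in s_levels]
        if not matched:
            continue
        w = 1.0 / len(matched)
        weights: dict[str, float] = {}
        for c_cat, c_s in matched:
            weights[c_cat] = weights.get(c_cat, 0.0) + w
            weights[c_s] = weights.get(c_s, 0.0) - w
        rows.append(contrast_row(f"{cat} vs S (matched step sizes)", weights))

    # global test of no difference between any conditions
    d = np.zeros((k - 1, k))
    for r in range(1, k):
        d[r - 1, 0], d[r - 1, r] = 1.0, -1.0
    stat, dof, p_global = _wald(d @ m, d @ cov_m @ d.T)
    global_test = {"label": "all conditions equal", "statistic": stat,
                   "dof": dof, "p_value": p_global,
                   "significant": p_global < alpha}

    table = pd.DataFrame([vars(r) for r in rows])
    table["significant"] = table["p_value"] < alpha
    if joint_rows:
        joints = pd.DataFrame(joint_rows)
        joints["significant"] = joints["p_value"] < alpha
        global_test["joint_tests"] = joints
    return table, global_test
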