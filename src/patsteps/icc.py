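"""Condition-level intraclass correlation via one-way REML.

The quantitative companion to the banded kappa: step-count ratios for one
pairing context are modelled as

    ratio_{cj} = mu + b_c + e_{cj},   b_c ~ N(0, sigma_cond^2),
                                      e_{cj} ~ N(0, sigma_res^2),

with the protocol conditions as random effects.  The ICC
sigma_cond^2 / (sigma_cond^2 + sigma_res^2) measures how much of the ratio
variation is systematic across conditions — i.e. whether the tracker's
detection limits, not noise, drive the differences a rater experiences.

Variance components are estimated by restricted maximum likelihood (REML),
maximising the profiled restricted log-likelihood of the one-way model
directly (the per-group compound-symmetric covariance gives closed-form
determinants and quadratic forms, so no general mixed-model machinery is
needed).  For balanced designs with non-negative ANOVA estimates the REML
solution coincides with the classical one-way ANOVA estimator, which also
serves as the fallback when the numerical optimisation fails.

Reporting rule from the study: the ICC is suppressed when the estimated
random-effect standard deviation is below 0.1 (no meaningful condition
signal to reproduce).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .preprocess import RatioDataset

logger = logging.getLogger(__name__)

#: ICC reporting is omitted below this random-effect SD.
SD_SUPPRESSION_THRESHOLD = 0.1

_LOGV_MIN, _LOGV_MAX = -30.0, 10.0


@dataclass
class IccResult:
    """Variance components and ICC for one pairing context."""

    sigma_condition: float | None
    sigma_residual: float | None
    icc: float | None
    n_obs: int
    n_groups: int
    suppressed: bool = False
    reason: str = ""
    converged: bool = True
    method: str = "reml"


def _group_stats(values: np.ndarray, groups: np.ndarray):
    """Per-group size, sum and sum of squares."""
    labels, idx = np.unique(groups, return_inverse=True)
    n_i = np.bincount(idx).astype(float)
    t_i = np.bincount(idx, weights=values)
    ss_i = np.bincount(idx, weights=values**2)
    return n_i, t_i, ss_i


def _neg_restricted_loglik(
    logvars: np.ndarray, n_i: np.ndarray, t_i: np.ndarray, ss: float
) -> float:
    """-2 x restricted log-likelihood (up to a constant) of the one-way model.

    Uses the compound-symmetry structure: within group i,
    V_i = sr2*I + sc2*J, so log|V_i| and V_i^{-1} are closed-form.
    """
    sc2, sr2 = np.exp(np.clip(logvars, _LOGV_MIN, _LOGV_MAX))
    d_i = sr2 + n_i * sc2
    logdet = float(((n_i - 1) * np.log(sr2)).sum() + np.log(d_i).sum())
    s = float((n_i / d_i).sum())            # X' V^-1 X for X = 1
    xvy = float((t_i / d_i).sum())          # X' V^-1 y
    yvy = (ss - sc2 * float((t_i**2 / d_i).sum())) / sr2
    ypy = yvy - xvy**2 / s                  # residual quadratic form
    return logdet + np.log(s) + ypy


def anova_variance_components(
    values: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Closed-form one-way ANOVA (method-of-moments) variance components.

    For balanced designs with interior solutions this equals REML.  The
    between-group component is truncated at zero.  Unbalanced designs use
    the standard weighted group size n0 = (N - sum n_i^2 / N) / (g - 1).
    """
    n_i, t_i, ss_i = _group_stats(values, groups)
    g = len(n_i)
    n = float(n_i.sum())
    gm = t_i / n_i
    grand = float(t_i.sum() / n)
    ssb = float((n_i * (gm - grand) ** 2).sum())
    ssw = float((ss_i - t_i**2 / n_i).sum())
    msw = ssw / (n - g) if n > g else 0.0
    msb = ssb / (g - 1)
    n0 = (n - float((n_i**2).sum()) / n) / (g - 1)
    sc2 = max(0.0, (msb - msw) / n0)
    return sc2, msw


def fit_condition_icc(
    values: Sequence[float] | np.ndarray,
    groups: Sequence | np.ndarray,
    sd_threshold: float = SD_SUPPRESSION_THRESHOLD,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> IccResult:
    """REML fit of the condition-random-intercept model and its ICC.

    ``values`` are step-count ratios, ``groups`` the condition labels.
    Negative variance estimates are truncated at zero (REML boundary),
    after which the suppression rule (random-effect SD < ``sd_threshold``)
    may fire.  If the optimiser fails, the balanced-design closed form is
    used and flagged in ``method``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    n = len(values)
    g = len(np.unique(groups))
    if g < 2 or n < g + 1:
        return IccResult(None, None, None, n, g, True,
                         "too few groups or observations", converged=False)

    n_i, t_i, ss_i = _group_stats(values, groups)
    ss = float(ss_i.sum())
    sc2_a, sr2_a = anova_variance_components(values, groups)

    if ss - float((t_i**2 / n_i).sum()) < 1e-14 and sc2_a < 1e-14:
        # all values identical: no variance at all
        return IccResult(0.0, 0.0, None, n, g, True,
                         "no variation in ratios", method="degenerate")

    x0 = np.log(np.clip([max(sc2_a, 1e-6), max(sr2_a, 1e-8)], 1e-10, None))
    res = optimize.minimize(
        _neg_restricted_loglik, x0, args=(n_i, t_i, ss),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": maxiter * 10},
    )
    method = "reml"
    if res.success:
        sc2, sr2 = np.exp(np.clip(res.x, _LOGV_MIN, _LOGV_MAX))
        # boundary handling: a component driven to the floor is zero
        if res.x[0] <= _LOGV_MIN + 1e-6 or sc2 < 1e-10:
            sc2 = 0.0
    else:
        logger.warning("REML optimisation failed; using closed-form fallback")
        sc2, sr2 = sc2_a, sr2_a
        method = "anova-fallback"

    sigma_c, sigma_r = float(np.sqrt(sc2)), float(np.sqrt(sr2))
    icc = sc2 / (sc2 + sr2) if (sc2 + sr2) > 0 else None
    if sigma_c < sd_threshold:
        return IccResult(sigma_c, sigma_r, icc, n, g, True,
                         f"random-effect SD {sigma_c:.3f} below {sd_threshold}",
                         converged=res.success, method=method)
    return IccResult(sigma_c, sigma_r, icc, n, g, False, "",
                     converged=res.success, method=method)


# ---------------------------------------------------------------------------
# pairing designs (mirror the agreement module)


def intra_hcp_icc(data: RatioDataset, participant: int, pat: str) -> IccResult:
    """Test-retest ICC for one participant: rounds 1 and 2 grouped by condition."""
    r1 = data.ratios(participant=participant, round=1, pat=pat)
    r2 = data.ratios(participant=participant, round=2, pat=pat)
    m1 = dict(zip(r1["condition"], r1["ratio"]))
    m2 = dict(zip(r2["condition"], r2["ratio"]))
    shared = [c for c in m1 if c in m2]
    if not shared:
        return IccResult(None, None, None, 0, 0, True,
                         "no condition observed in both rounds", converged=False)
    values = np.array([m1[c] for c in shared] + [m2[c] for c in shared])
    groups = np.array(shared + shared)
    return fit_condition_icc(values, groups)


def inter_hcp_icc(
    data: RatioDataset, pat: str,
    round_combos: str = "all",
    pool: bool = False,
) -> tuple[IccResult, pd.DataFrame]:
    """Inter-rater ICC for one PAT.

    Default (``pool=False``): fit the condition-random-effect model for
    each unordered participant pair and round combination, then average
    the non-suppressed ICCs.  ``pool=True`` instead fits one model on all
    ratios of the PAT pooled (alternative reading of the averaging rule).
    """
    participants = data.participants(pat=pat)
    if len(participants) < 2:
        return (IccResult(None, None, None, 0, 0, True,
                          "fewer than two participants", converged=False),
                pd.DataFrame())
    if pool:
        t = data.ratios(pat=pat)
        res = fit_condition_icc(t["ratio"].to_numpy(), t["condition"].to_numpy())
        res.method = "pooled-" + res.method
        return res, pd.DataFrame()

    combos = (
        [(1, 1), (1, 2), (2, 1), (2, 2)] if round_combos == "all"
        else [(1, 2), (2, 1)]
    )
    rows = []
    for pi, pj in itertools.combinations(participants, 2):
        a = data.ratios(participant=pi, pat=pat)
        b = data.ratios(participant=pj, pat=pat)
        for ri, rj in combos:
            ma = dict(zip(a.loc[a["round"] == ri, "condition"],
                          a.loc[a["round"] == ri, "ratio"]))
            mb = dict(zip(b.loc[b["round"] == rj, "condition"],
                          b.loc[b["round"] == rj, "ratio"]))
            shared = [c for c in ma if c in mb]
            if len(shared) < 2:
                rows.append({"participant_a": pi, "participant_b": pj,
                             "round_a": ri, "round_b": rj, "icc": None,
                             "sigma_condition": None, "suppressed": True,
                             "reason": "too few shared conditions"})
                continue
            values = np.array([ma[c] for c in shared] + [mb[c] for c in shared])
            groups = np.array(shared + shared)
            res = fit_condition_icc(values, groups)
            rows.append({"participant_a": pi, "participant_b": pj,
                         "round_a": ri, "round_b": rj, "icc": res.icc,
                         "sigma_condition": res.sigma_condition,
                         "suppressed": res.suppressed, "reason": res.reason})
    breakdown = pd.DataFrame(rows)
    usable = breakdown.loc[~breakdown["suppressed"], "icc"].dropna().astype(float)
    n_supp = int(breakdown["suppressed"].sum())
    if n_supp:
        logger.info("inter-rater ICC %s: %d of %d fits suppressed",
                    pat, n_supp, len(breakdown))
    if usable.empty:
        return (IccResult(None, None, None, 0, 0, True,
                          "all pair/round fits suppressed", converged=False),
                breakdown)
    mean_icc = float(usable.mean())
    total_obs = int(breakdown.loc[~breakdown["suppressed"]].shape[0])
    result = IccResult(
        sigma_condition=float(
            breakdown.loc[~breakdown["suppressed"], "sigma_condition"]
            .dropna().mean()
        ),
        sigma_residual=None,
        icc=mean_icc,
        n_obs=total_obs,
        n_groups=len(participants),
        suppressed=False,
        method="averaged-reml",
    )
    return result, breakdown
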