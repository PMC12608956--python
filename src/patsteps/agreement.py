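"""Banded agreement rates and chance-corrected kappa for step-count ratios.

A step-count ratio near 1 means the tracker detected the steps, near 0
means it detected none, and intermediate values indicate a condition near
the device's detection limit.  Reproducibility of this three-way outcome is
what matters clinically, so instead of treating ratios as fully
quantitative, two ratios observed for the same condition are compared
through a banded weight:

* 1.0 — both ratios tell the same story (both clearly detecting, both
  clearly failing, or both in the unstable middle adjoining the same end);
* 0.5 — one ratio is in the middle band and the other at the opposite end;
* 0.0 — one ratio is above 0.8 and the other below 0.2.

The band edges 0.2 / 0.5 / 0.8 acknowledge that even true ratios of 0 or 1
carry some noise.  The agreement rate of a set of pairs is the average
weight, and it is chance-corrected into a kappa in Cohen's fashion:
``kappa = (P_o - P_e) / (1 - P_e)`` with ``P_e`` the expected weight under
independent band draws from the pair-member marginal distributions.

Two pairing designs are supported: intra-rater (round 1 vs round 2 of the
same participant, pairs matched by condition) and inter-rater (all
participant pairs crossed with all round combinations, averaged).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .preprocess import RatioDataset

logger = logging.getLogger(__name__)


class Band(IntEnum):
    """Partition of the ratio axis at 0.2, 0.5 and 0.8.

    Boundary convention: 0.2 and 0.5 belong to the band above them while
    0.8 belongs to mid_high, so that 0.8 still counts as "between 0.2 and
    0.8" in the full-agreement clause.
    """

    low = 0        # [0, 0.2)
    mid_low = 1    # [0.2, 0.5)
    mid_high = 2   # [0.5, 0.8]
    high = 3       # (0.8, inf)


#: Symmetric 4x4 weight table over band pairs.
WEIGHT_TABLE: np.ndarray = np.array([
    # low  mid_low  mid_high  high
    [1.0,  1.0,     0.5,      0.0],   # low
    [1.0,  1.0,     1.0,      0.5],   # mid_low
    [0.5,  1.0,     1.0,      1.0],   # mid_high
    [0.0,  0.5,     1.0,      1.0],   # high
])

ChanceMarginals = Literal["pair", "pooled"]
RoundCombos = Literal["all", "cross"]

#: Kappa is suppressed when all ratios exceed this (no variation to agree on).
SUPPRESSION_THRESHOLD = 0.5


def band_of(ratio: float) -> Band:
    """Band of a single nonnegative step-count ratio."""
    if ratio < 0:
        raise ValueError(f"step-count ratio must be nonnegative, got {ratio}")
    if ratio < 0.2:
        return Band.low
    if ratio < 0.5:
        return Band.mid_low
    if ratio <= 0.8:
        return Band.mid_high
    return Band.high


def bands_of(ratios: np.ndarray) -> np.ndarray:
    """Vectorised :func:`band_of`."""
    r = np.asarray(ratios, dtype=float)
    if (r < 0).any():
        raise ValueError("step-count ratios must be nonnegative")
    out = np.full(r.shape, Band.high, dtype=np.int64)
    out[r <= 0.8] = Band.mid_high
    out[r < 0.5] = Band.mid_low
    out[r < 0.2] = Band.low
    return out


def pair_weight(ratio_a: float, ratio_b: float) -> float:
    """Agreement weight (0, 0.5 or 1) of two condition-matched ratios."""
    return float(WEIGHT_TABLE[band_of(ratio_a), band_of(ratio_b)])


@dataclass(frozen=True)
class RatioPair:
    """Two step-count ratios observed for the same condition."""

    ratio_a: float
    ratio_b: float
    condition: str = ""
    source_a: str = ""
    source_b: str = ""


@dataclass
class AgreementResult:
    """Observed/chance agreement and kappa for one pairing context."""

    observed_agreement: float | None
    chance_agreement: float | None
    kappa: float | None
    n_pairs: int
    suppressed: bool = False
    reason: str = ""
    label: str | None = None


def _pair_arrays(pairs: Sequence[RatioPair]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([p.ratio_a for p in pairs], dtype=float)
    b = np.array([p.ratio_b for p in pairs], dtype=float)
    return a, b


def agreement_rate(pairs: Sequence[RatioPair]) -> float:
    """Average banded weight over all pairs."""
    if len(pairs) == 0:
        raise ValueError("agreement rate is undefined for an empty pair set")
    a, b = _pair_arrays(pairs)
    return float(WEIGHT_TABLE[bands_of(a), bands_of(b)].mean())


def _band_dist(bands: np.ndarray) -> np.ndarray:
    return np.bincount(bands, minlength=4) / len(bands)


def weighted_kappa(
    pairs: Sequence[RatioPair],
    chance_marginals: ChanceMarginals = "pair",
) -> AgreementResult:
    """Chance-corrected banded agreement of a set of ratio pairs.

    ``chance_marginals`` selects how the expected agreement ``P_e`` is
    formed: ``"pair"`` uses the two pair-member marginal band
    distributions (Cohen's two-rater convention); ``"pooled"`` uses a
    single marginal pooled over both members.

    Kappa is suppressed (per the study's reporting rule) when every ratio
    is above 0.5, and is undefined when the chance agreement is 1.
    """
    n = len(pairs)
    if n == 0:
        return AgreementResult(None, None, None, 0, True, "no pairs")
    a, b = _pair_arrays(pairs)
    if (a > SUPPRESSION_THRESHOLD).all() and (b > SUPPRESSION_THRESHOLD).all():
        return AgreementResult(
            None, None, None, n, True,
            f"all step count ratios above {SUPPRESSION_THRESHOLD}",
        )
    ba, bb = bands_of(a), bands_of(b)
    p_o = float(WEIGHT_TABLE[ba, bb].mean())
    if chance_marginals == "pair":
        da, db = _band_dist(ba), _band_dist(bb)
    elif chance_marginals == "pooled":
        da = db = _band_dist(np.concatenate([ba, bb]))
    else:
        raise ValueError(f"unknown chance_marginals policy {chance_marginals!r}")
    p_e = float(da @ WEIGHT_TABLE @ db)
    if p_e >= 1.0 - 1e-12:
        return AgreementResult(
            p_o, p_e, None, n, True, "degenerate marginals (chance agreement 1)"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(p_o, p_e, kappa, n, False, "",
                           label=landis_koch_label(kappa))


def landis_koch_label(kappa: float) -> str:
    """Verbal label for a kappa value (cut-offs 0.2, 0.4, 0.6, 0.8)."""
    if kappa <= 0.0:
        return "poor"
    if kappa <= 0.2:
        return "slight"
    if kappa <= 0.4:
        return "fair"
    if kappa <= 0.6:
        return "moderate"
    if kappa <= 0.8:
        return "substantial"
    return "almost perfect"


# ---------------------------------------------------------------------------
# pairing designs


def intra_hcp_pairs(
    data: RatioDataset, participant: int, pat: str
) -> list[RatioPair]:
    """Round-1 vs round-2 ratio pairs of one participant, matched by condition."""
    r1 = data.ratios(participant=participant, round=1, pat=pat)
    r2 = data.ratios(participant=participant, round=2, pat=pat)
    m1 = dict(zip(r1["condition"], r1["ratio"]))
    m2 = dict(zip(r2["condition"], r2["ratio"]))
    shared = [c for c in m1 if c in m2]
    if not shared:
        logger.info(
            "participant %s / %s: no condition observed in both rounds",
            participant, pat,
        )
    return [
        RatioPair(m1[c], m2[c], condition=c,
                  source_a=f"P{participant}R1", source_b=f"P{participant}R2")
        for c in shared
    ]


def intra_hcp_kappa(
    data: RatioDataset, participant: int, pat: str,
    chance_marginals: ChanceMarginals = "pair",
) -> AgreementResult:
    """Intra-rater (test-retest) kappa for one participant and PAT."""
    return weighted_kappa(intra_hcp_pairs(data, participant, pat),
                          chance_marginals=chance_marginals)


def _cross_pairs(
    data: RatioDataset, pat: str,
    pi: int, ri: int, pj: int, rj: int,
) -> list[RatioPair]:
    a = data.ratios(participant=pi, round=ri, pat=pat)
    b = data.ratios(participant=pj, round=rj, pat=pat)
    ma = dict(zip(a["condition"], a["ratio"]))
    mb = dict(zip(b["condition"], b["ratio"]))
    return [
        RatioPair(ma[c], mb[c], condition=c,
                  source_a=f"P{pi}R{ri}", source_b=f"P{pj}R{rj}")
        for c in ma if c in mb
    ]


def inter_hcp_kappa(
    data: RatioDataset, pat: str,
    chance_marginals: ChanceMarginals = "pair",
    round_combos: RoundCombos = "all",
) -> tuple[AgreementResult, pd.DataFrame]:
    """Inter-rater kappa for one PAT, averaged over participant pairs.

    For every unordered participant pair {i, j} and every round
    combination (r_i, r_j) — all four by default, or only the cross-round
    combinations (1,2)/(2,1) with ``round_combos="cross"`` — a kappa is
    computed from the condition-matched ratio pairs.  The headline value
    is the unweighted mean of the non-suppressed kappas; the full
    per-combination breakdown is returned for diagnostics.
    """
    participants = data.participants(pat=pat)
    if len(participants) < 2:
        return (
            AgreementResult(None, None, None, 0, True,
                            "fewer than two participants"),
            pd.DataFrame(),
        )
    combos = (
        [(1, 1), (1, 2), (2, 1), (2, 2)] if round_combos == "all"
        else [(1, 2), (2, 1)]
    )
    rows = []
    for pi, pj in itertools.combinations(participants, 2):
        for ri, rj in combos:
            pairs = _cross_pairs(data, pat, pi, ri, pj, rj)
            res = weighted_kappa(pairs, chance_marginals=chance_marginals)
            rows.append({
                "participant_a": pi, "participant_b": pj,
                "round_a": ri, "round_b": rj,
                "n_pairs": res.n_pairs,
                "observed_agreement": res.observed_agreement,
                "chance_agreement": res.chance_agreement,
                "kappa": res.kappa,
                "suppressed": res.suppressed,
                "reason": res.reason,
            })
    breakdown = pd.DataFrame(rows)
    usable = breakdown.loc[~breakdown["suppressed"], "kappa"].astype(float)
    n_supp = int(breakdown["suppressed"].sum())
    if n_supp:
        logger.info(
            "inter-rater %s: %d of %d pair/round combinations suppressed",
            pat, n_supp, len(breakdown),
        )
    if usable.empty:
        return (
            AgreementResult(None, None, None, 0, True,
                            "all pair/round combinations suppressed"),
            breakdown,
        )
    mean_kappa = float(usable.mean())
    obs = breakdown.loc[~breakdown["suppressed"], "observed_agreement"]
    chance = breakdown.loc[~breakdown["suppressed"], "chance_agreement"]
    result = AgreementResult(
        observed_agreement=float(obs.mean()),
        chance_agreement=float(chance.mean()),
        kappa=mean_kappa,
        n_pairs=int(breakdown.loc[~breakdown["suppressed"], "n_pairs"].sum()),
        suppressed=False,
        label=landis_koch_label(mean_kappa),
    )
    return result, breakdown
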