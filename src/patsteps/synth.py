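"""Synthetic trial-data generator mirroring the analysis model.

Generates step-count records with the statistical structure the analysis
assumes, so every downstream stage (cleaning, agreement, ICC, condition
effects) can be exercised and validated by parameter recovery without the
study's raw data.

The outcome model per trial x PAT is a zero-inflated negative binomial,
matching the condition-effect analysis: with probability ``zero_prob`` the
device fails to detect any step (count 0); otherwise the count is negative
binomial with mean ``true_steps * mean_ratio * participant_effect`` and
NB2 overdispersion ``dispersion`` (variance mu + dispersion * mu^2).  On
top of that:

* a multiplicative log-normal participant effect, shared across conditions
  within a PAT, models rater-level heterogeneity;
* an occasional additive Poisson overcount burst lets ratios exceed 1.5,
  as observed for pocket- and wrist-worn trackers;
* an ``off_by_one`` flag reproduces the sole sensor's behaviour of
  consistently counting one step short (a half step at start and end);
* the true step count jitters around the intended 20 (19/21 with small
  probability), since raters cannot be forced to exactly 20 steps.

Scenario labels classify each PAT x condition cell into the three outcome
regimes the protocol aims to expose: ``detectable`` (ratio near 1),
``undetectable`` (ratio near 0) and ``near_limit`` (unstable ratios).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .preprocess import PATS, TRIAL_COLUMNS
from .protocol import PROTOCOL_ORDER, ConditionError


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class DetectionScenario:
    """Outcome regime of one PAT under one condition.

    ``count_model`` selects the non-inflated count distribution:
    ``"nb"`` (negative binomial, mean true*mean_ratio*effect, NB2
    overdispersion ``dispersion``) for unstable regimes, or
    ``"binomial"`` (each true step detected independently with
    probability mean_ratio*effect, capped at 1) for near-perfect sensors,
    whose counts are far less variable than a Poisson floor allows.
    """

    label: str
    zero_prob: float
    mean_ratio: float
    dispersion: float
    overcount_prob: float = 0.0
    overcount_scale: float = 0.8
    count_model: str = "nb"

    def __post_init__(self) -> None:
        if self.count_model not in ("nb", "binomial"):
            raise ConfigError(f"unknown count_model {self.count_model!r}")
        if not 0.0 <= self.zero_prob <= 1.0:
            raise ConfigError(f"zero_prob must be in [0,1], got {self.zero_prob}")
        if self.mean_ratio < 0:
            raise ConfigError(f"mean_ratio must be nonnegative, got {self.mean_ratio}")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be positive, got {self.dispersion}")
        if not 0.0 <= self.overcount_prob <= 1.0:
            raise ConfigError(
                f"overcount_prob must be in [0,1], got {self.overcount_prob}")
        if self.overcount_scale <= 0:
            raise ConfigError(
                f"overcount_scale must be positive, got {self.overcount_scale}")
        if self.label == "detectable":
            if self.zero_prob > 0.05 or not 0.85 <= self.mean_ratio <= 1.05:
                raise ConfigError(
                    "detectable scenario requires zero_prob <= 0.05 and "
                    f"mean_ratio in [0.85, 1.05]; got {self}")
        elif self.label == "undetectable":
            if self.zero_prob < 0.90:
                raise ConfigError(
                    f"undetectable scenario requires zero_prob >= 0.90; got {self}")
        elif self.label == "near_limit":
            if not 0.05 < self.zero_prob < 0.90:
                raise ConfigError(
                    f"near_limit scenario requires zero_prob in (0.05, 0.90); got {self}")
        else:
            raise ConfigError(f"unknown scenario label {self.label!r}")


def detectable(mean_ratio: float = 1.0, zero_prob: float = 0.01,
               dispersion: float = 0.005, count_model: str = "binomial",
               **kw) -> DetectionScenario:
    return DetectionScenario("detectable", zero_prob, mean_ratio, dispersion,
                             count_model=count_model, **kw)


def undetectable(zero_prob: float = 0.95, mean_ratio: float = 0.4,
                 dispersion: float = 0.4, **kw) -> DetectionScenario:
    return DetectionScenario("undetectable", zero_prob, mean_ratio, dispersion, **kw)


def near_limit(zero_prob: float = 0.4, mean_ratio: float = 0.65,
               dispersion: float = 0.4, **kw) -> DetectionScenario:
    return DetectionScenario("near_limit", zero_prob, mean_ratio, dispersion, **kw)


#: Default jitter of the performed (true) step count around the intended 20.
DEFAULT_TRUE_STEP_JITTER: dict[int, float] = {19: 0.05, 20: 0.90, 21: 0.05}


@dataclass
class SyntheticConfig:
    """Full specification of a simulated study."""

    n_participants: int
    pat_profiles: dict[str, dict[str, DetectionScenario]]
    participant_effect_sd: float | dict[str, float] = 0.0
    true_step_jitter: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_STEP_JITTER))
    off_by_one: frozenset[str] = frozenset()
    seed: int = 0
    # missingness hooks emulating real-study data loss
    failed_participants: dict[str, frozenset[int]] = field(default_factory=dict)
    missing_round1_participants: frozenset[int] = frozenset()
    slipper_participants: frozenset[int] | None = None  # None = everyone

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        for pat, profile in self.pat_profiles.items():
            if pat not in PATS:
                raise ConfigError(f"unknown PAT {pat!r}; expected one of {PATS}")
            for code in profile:
                if code not in PROTOCOL_ORDER:
                    raise ConditionError(
                        f"profile for {pat!r} uses unknown condition code {code!r}")
        total = sum(self.true_step_jitter.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("true_step_jitter probabilities must sum to 1")
        if any(v < 0 for v in self.true_step_jitter.values()):
            raise ConfigError("true_step_jitter probabilities must be nonnegative")

    def effect_sd(self, pat: str) -> float:
        if isinstance(self.participant_effect_sd, Mapping):
            return float(self.participant_effect_sd.get(pat, 0.0))
        return float(self.participant_effect_sd)


def _nb_draw(rng: np.random.Generator, mu: float, dispersion: float) -> int:
    """NB2 draw with mean mu and variance mu + dispersion * mu^2."""
    if mu <= 0:
        return 0
    if dispersion < 1e-8:
        return int(rng.poisson(mu))
    k = 1.0 / dispersion
    return int(rng.negative_binomial(k, k / (k + mu)))


def simulate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate one full study; bit-exact for a fixed seed.

    Returns a trial table with one row per participant x round(2) x
    condition-in-profile x PAT.  All four PATs of a trial share the same
    true step count (they were worn simultaneously); detection failures
    are independent across PATs.  Missingness hooks leave the row in
    place with an empty device count.
    """
    rng = np.random.default_rng(config.seed)
    pats = [p for p in PATS if p in config.pat_profiles]
    if not pats:
        raise ConfigError("config defines no PAT profiles")
    # union of condition codes, in protocol order, per PAT kept separate
    jit_vals = np.array(sorted(config.true_step_jitter), dtype=int)
    jit_probs = np.array([config.true_step_jitter[v] for v in jit_vals])

    effects = {
        pat: np.exp(rng.normal(0.0, config.effect_sd(pat),
                               size=config.n_participants))
        for pat in pats
    }

    rows: list[tuple] = []
    for part in range(1, config.n_participants + 1):
        for rnd in (1, 2):
            round_missing = rnd == 1 and part in config.missing_round1_participants
            for code in PROTOCOL_ORDER:
                relevant = [p for p in pats if code in config.pat_profiles[p]]
                if not relevant:
                    continue
                true_steps = int(rng.choice(jit_vals, p=jit_probs))
                slipper_missing = (
                    code in ("L-75", "L-40")
                    and config.slipper_participants is not None
                    and part not in config.slipper_participants
                )
                for pat in relevant:
                    failed = part in config.failed_participants.get(pat, ())
                    if round_missing or slipper_missing or failed:
                        rows.append((part, rnd, code, pat, true_steps,
                                     None, False))
                        continue
                    sc = config.pat_profiles[pat][code]
                    if rng.random() < sc.zero_prob:
                        count = 0
                    else:
                        eff = effects[pat][part - 1]
                        if sc.count_model == "binomial":
                            p = min(1.0, sc.mean_ratio * eff)
                            count = int(rng.binomial(true_steps, p))
                        else:
                            mu = true_steps * sc.mean_ratio * eff
                            count = _nb_draw(rng, mu, sc.dispersion)
                        if sc.overcount_prob > 0 and rng.random() < sc.overcount_prob:
                            count += int(rng.poisson(sc.overcount_scale * true_steps))
                    if pat in config.off_by_one:
                        count = max(0, count - 1)
                    rows.append((part, rnd, code, pat, true_steps, count, False))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["counted_steps"] = df["counted_steps"].astype("Float64")
    return df


def preset_study_like(seed: int = 0, n_participants: int = 14) -> SyntheticConfig:
    """A configuration emulating the observed behaviour of the four PATs.

    * sole: near-perfect detection everywhere, minus one step per walk;
    * knee: near-perfect detection, but the companion app failed for 9 of
      the 14 participants (no data at all);
    * trouser: strongly step-size-dependent detection — undetectable at
      25-40 % step size, near the detection limit at 75 %, with crutches
      shifting detection further down; occasional overcount bursts;
    * wrist: mild condition effects but strong participant-level
      heterogeneity, plus occasional overcounts.

    The study's data-loss quirks are reproduced: round 1 of participant 1
    is unusable and only four participants brought slippers.  No
    distributional parameters were reported for any sensor; the values
    here are illustrative and chosen to land in the documented regimes.
    """
    rng = np.random.default_rng(seed)

    sole = {code: detectable(1.0, zero_prob=0.0)
            for code in PROTOCOL_ORDER}
    knee = {code: detectable(0.99, zero_prob=0.01)
            for code in PROTOCOL_ORDER}

    trouser: dict[str, DetectionScenario] = {}
    wrist: dict[str, DetectionScenario] = {}
    for code in PROTOCOL_ORDER:
        cat, pct = code.split("-")
        pct = int(pct)
        if cat == "W":  # crutches hit the trouser sensor hardest
            trouser[code] = (near_limit(0.55, 0.45, overcount_prob=0.02)
                             if pct == 75 else undetectable(0.95, 0.3))
        elif pct >= 100:
            trouser[code] = detectable(0.95, zero_prob=0.02, dispersion=0.05,
                                       count_model="nb", overcount_prob=0.02)
        elif pct == 75:
            trouser[code] = near_limit(0.35, 0.7, overcount_prob=0.03)
        else:  # 25-40 % step size: below the detection limit
            trouser[code] = undetectable(0.93, 0.35)
        if pct >= 75:
            wrist[code] = detectable(0.95, zero_prob=0.03, dispersion=0.08,
                                     count_model="nb", overcount_prob=0.02)
        else:
            wrist[code] = near_limit(0.25, 0.8, dispersion=0.3,
                                     overcount_prob=0.02)

    participants = np.arange(1, n_participants + 1)
    knee_failed = frozenset(
        int(p) for p in rng.choice(participants, size=min(9, n_participants),
                                   replace=False))
    slipper = frozenset(
        int(p) for p in rng.choice(participants, size=min(4, n_participants),
                                   replace=False))
    return SyntheticConfig(
        n_participants=n_participants,
        pat_profiles={"sole": sole, "knee": knee,
                      "trouser": trouser, "wrist": wrist},
        participant_effect_sd={"sole": 0.0, "knee": 0.01,
                               "trouser": 0.15, "wrist": 0.35},
        off_by_one=frozenset({"sole"}),
        seed=seed,
        failed_participants={"knee": knee_failed},
        missing_round1_participants=frozenset({1}),
        slipper_participants=slipper,
    )


# ---------------------------------------------------------------------------
# plain-text config round-trip


def config_to_yaml(config: SyntheticConfig, path: str | Path) -> None:
    doc = {
        "n_participants": config.n_participants,
        "participant_effect_sd": config.participant_effect_sd,
        "true_step_jitter": {int(k): float(v)
                             for k, v in config.true_step_jitter.items()},
        "off_by_one": sorted(config.off_by_one),
        "seed": config.seed,
        "failed_participants": {k: sorted(v)
                                for k, v in config.failed_participants.items()},
        "missing_round1_participants": sorted(config.missing_round1_participants),
        "slipper_participants": (None if config.slipper_participants is None
                                 else sorted(config.slipper_participants)),
        "pat_profiles": {
            pat: {code: {"label": sc.label, "zero_prob": sc.zero_prob,
                         "mean_ratio": sc.mean_ratio,
                         "dispersion": sc.dispersion,
                         "overcount_prob": sc.overcount_prob,
                         "overcount_scale": sc.overcount_scale,
                         "count_model": sc.count_model}
                  for code, sc in profile.items()}
            for pat, profile in config.pat_profiles.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> SyntheticConfig:
    doc = yaml.safe_load(Path(path).read_text())
    profiles = {
        pat: {code: DetectionScenario(**sc) for code, sc in profile.items()}
        for pat, profile in doc["pat_profiles"].items()
    }
    return SyntheticConfig(
        n_participants=doc["n_participants"],
        pat_profiles=profiles,
        participant_effect_sd=doc.get("participant_effect_sd", 0.0),
        true_step_jitter={int(k): float(v)
                          for k, v in doc.get(
                              "true_step_jitter", DEFAULT_TRUE_STEP_JITTER
                          ).items()},
        off_by_one=frozenset(doc.get("off_by_one", [])),
        seed=int(doc.get("seed", 0)),
        failed_participants={k: frozenset(v) for k, v in
                             doc.get("failed_participants", {}).items()},
        missing_round1_participants=frozenset(
            doc.get("missing_round1_participants", [])),
        slipper_participants=(None if doc.get("slipper_participants") is None
                              else frozenset(doc["slipper_participants"])),
    )
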