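"""Trial-record I/O, study exclusion rules and step-count ratios.

The unit of observation is one 20-step walk by one participant under one
condition, read off one physical activity tracker (PAT).  Records arrive as
delimited text with one row per trial x PAT:

    participant_id,round,condition,pat,true_steps,counted_steps,repeated

``counted_steps`` is left empty when the device produced no reading (e.g.
the knee-sensor app failures); an explicit 0 is data — the device counted
no steps — never missingness.

Cleaning applies the study rules: slipper conditions are dropped entirely
(too few participants brought slippers), records without a device reading
are dropped with a logged reason, and implausibly large ratios are flagged
but retained (overcounting is a real device behaviour).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .protocol import PROTOCOL_ORDER, SLIPPER_CODES, ConditionError

logger = logging.getLogger(__name__)

PATS: tuple[str, ...] = ("sole", "knee", "trouser", "wrist")

TRIAL_COLUMNS = [
    "participant_id", "round", "condition", "pat",
    "true_steps", "counted_steps", "repeated",
]

#: Ratios above this are flagged (not dropped) in the cleaning report.
RATIO_FLAG_CAP = 3.0


class DataError(ValueError):
    """Raised for structurally invalid trial data."""


@dataclass(frozen=True)
class TrialRecord:
    """One 20-step walk under one condition, seen by one PAT."""

    participant_id: int
    round: int
    condition_code: str
    pat: str
    true_steps: int
    counted_steps: int | None
    repeated: bool = False

    def __post_init__(self) -> None:
        if self.condition_code not in PROTOCOL_ORDER:
            raise ConditionError(
                f"unknown condition code {self.condition_code!r}"
            )
        if self.pat not in PATS:
            raise DataError(f"unknown PAT {self.pat!r}; expected one of {PATS}")
        if self.round not in (1, 2):
            raise DataError(f"round must be 1 or 2, got {self.round}")
        if self.true_steps <= 0:
            raise DataError(f"true_steps must be positive, got {self.true_steps}")


def compute_ratio(record: TrialRecord) -> float:
    """Step-count ratio: device count divided by the true step count."""
    if record.counted_steps is None:
        raise DataError("cannot compute a ratio for a missing device reading")
    if record.true_steps <= 0:
        raise DataError(f"true_steps must be positive, got {record.true_steps}")
    return record.counted_steps / record.true_steps


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        (r.participant_id, r.round, r.condition_code, r.pat,
         r.true_steps, r.counted_steps, r.repeated)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["counted_steps"] = df["counted_steps"].astype("Float64")
    return df


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial CSV; tolerates comma and semicolon dialects."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "repeated"]
    if missing:
        raise DataError(f"trial file {path} lacks required columns: {missing}")
    if "repeated" not in df.columns:
        df["repeated"] = False
    df = df[TRIAL_COLUMNS].copy()
    df["participant_id"] = df["participant_id"].astype(int)
    df["round"] = df["round"].astype(int)
    df["true_steps"] = df["true_steps"].astype(int)
    df["counted_steps"] = df["counted_steps"].astype("Float64")
    df["repeated"] = df["repeated"].astype(bool)
    bad = sorted(set(df["condition"]) - set(PROTOCOL_ORDER))
    if bad:
        raise DataError(f"unknown condition codes in {path}: {bad}")
    bad_pat = sorted(set(df["pat"]) - set(PATS))
    if bad_pat:
        raise DataError(f"unknown PATs in {path}: {bad_pat}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as comma-separated text."""
    df.to_csv(path, index=False)


@dataclass
class CleaningReport:
    """Bookkeeping of every exclusion applied during cleaning."""

    n_input: int = 0
    n_retained: int = 0
    dropped_slipper: int = 0
    dropped_missing_count: int = 0
    flagged_high_ratio: int = 0
    missing_by_pat: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.dropped_slipper + self.dropped_missing_count

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "dropped_slipper": self.dropped_slipper,
            "dropped_missing_count": self.dropped_missing_count,
            "flagged_high_ratio": self.flagged_high_ratio,
            "missing_by_pat": dict(self.missing_by_pat),
        }


@dataclass
class RatioDataset:
    """Cleaned step-count-ratio table.

    ``table`` has columns participant_id, round, condition, pat,
    true_steps, counted_steps, ratio; keys
    (participant_id, round, condition, pat) are unique and contain no
    slipper conditions.
    """

    table: pd.DataFrame
    provenance: str = "observed"
    report: CleaningReport = field(default_factory=CleaningReport)

    def ratios(
        self,
        participant: int | None = None,
        round: int | None = None,
        pat: str | None = None,
        condition: str | None = None,
    ) -> pd.DataFrame:
        t = self.table
        if participant is not None:
            t = t[t["participant_id"] == participant]
        if round is not None:
            t = t[t["round"] == round]
        if pat is not None:
            t = t[t["pat"] == pat]
        if condition is not None:
            t = t[t["condition"] == condition]
        return t

    def participants(self, pat: str | None = None) -> list[int]:
        return sorted(self.ratios(pat=pat)["participant_id"].unique())


def clean_dataset(
    records: pd.DataFrame | Iterable[TrialRecord],
    provenance: str = "observed",
    flag_cap: float = RATIO_FLAG_CAP,
) -> RatioDataset:
    """Apply the study exclusion rules and compute step-count ratios.

    Idempotent: re-cleaning the retained trial rows changes nothing.
    Every dropped record is counted in the returned report, never
    silently discarded.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    df = records.copy()
    report = CleaningReport(n_input=len(df))

    slipper = df["condition"].isin(SLIPPER_CODES)
    report.dropped_slipper = int(slipper.sum())
    df = df[~slipper]

    missing = df["counted_steps"].isna()
    report.dropped_missing_count = int(missing.sum())
    report.missing_by_pat = (
        df.loc[missing, "pat"].value_counts().to_dict()
    )
    df = df[~missing].copy()

    if (df["true_steps"] <= 0).any():
        raise DataError("true_steps must be positive for all retained records")

    dup = df.duplicated(["participant_id", "round", "condition", "pat"])
    if dup.any():
        raise DataError(
            f"{int(dup.sum())} duplicate (participant, round, condition, pat) keys"
        )

    df["ratio"] = df["counted_steps"].astype(float) / df["true_steps"]
    report.flagged_high_ratio = int((df["ratio"] > flag_cap).sum())
    if report.flagged_high_ratio:
        logger.warning(
            "%d ratios above %.1f retained but flagged",
            report.flagged_high_ratio, flag_cap,
        )
    report.n_retained = len(df)
    logger.info(
        "cleaning: %d records in, %d retained, %d slipper rows dropped, "
        "%d missing device readings dropped",
        report.n_input, report.n_retained,
        report.dropped_slipper, report.dropped_missing_count,
    )
    return RatioDataset(table=df.reset_index(drop=True), provenance=provenance,
                        report=report)
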