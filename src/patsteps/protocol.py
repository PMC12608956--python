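"""The 14-condition low-impact-gait protocol.

A health care professional (HCP) walks 20 steps under each of 14 conditions
that mimic the gait of patients recovering from knee surgery.  Conditions
combine four factors: intended step size (25/40/75/100 % of normal),
walking direction (straight, 90° turn, zigzag, 360° circle), use of a
walking aid (forearm crutches) and footwear (street shoes vs. slippers).
Only 14 of the 64 possible factor combinations are part of the protocol;
they are performed in a fixed order, starting from normal gait and
progressively reducing impact.

Condition codes (e.g. ``"S-75"``) are the single source of truth used in
all data files: the leading letter is the condition *category* and the
number the intended step size in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache


class Direction(str, Enum):
    straight = "straight"
    turn90 = "turn90"
    zigzag = "zigzag"
    circle360 = "circle360"


class Footwear(str, Enum):
    street = "street"
    slipper = "slipper"


#: Category letter -> (direction, walking aid, footwear) semantics.
#: S/T/Z/C vary the walking direction with street shoes and no aid,
#: W adds forearm crutches (straight line), L swaps to slippers (straight).
CATEGORY_SEMANTICS: dict[str, tuple[Direction, bool, Footwear]] = {
    "S": (Direction.straight, False, Footwear.street),
    "T": (Direction.turn90, False, Footwear.street),
    "Z": (Direction.zigzag, False, Footwear.street),
    "C": (Direction.circle360, False, Footwear.street),
    "W": (Direction.straight, True, Footwear.street),
    "L": (Direction.straight, False, Footwear.slipper),
}

#: Kinematic detail kept as plain metadata, not modelled.
DIRECTION_NOTES: dict[Direction, str] = {
    Direction.straight: "straight line",
    Direction.turn90: "right turn by 90 degrees after 10 steps",
    Direction.zigzag: "90 degree shifts after 5, 10 and 15 steps, starting left",
    Direction.circle360: "360 degree circle clockwise",
}

#: Protocol order of the 14 condition codes.
PROTOCOL_ORDER: tuple[str, ...] = (
    "S-100", "S-75", "S-40", "S-25",
    "T-75", "Z-75", "C-75",
    "T-40", "Z-40", "C-40",
    "W-75", "W-40",
    "L-75", "L-40",
)

VALID_STEP_SIZES = (25, 40, 75, 100)

#: Slipper conditions, excluded from all analyses after cleaning.
SLIPPER_CODES: tuple[str, ...] = ("L-75", "L-40")

#: The 12 analysis conditions remaining after the slipper exclusion.
ANALYSIS_CODES: tuple[str, ...] = tuple(
    c for c in PROTOCOL_ORDER if c not in SLIPPER_CODES
)


class ConditionError(ValueError):
    """Raised for malformed or unknown condition codes."""


@dataclass(frozen=True)
class ConditionSpec:
    """One walking condition of the protocol.

    ``standard`` is False for user-defined extensions built through
    :func:`make_condition`; only the 14 protocol conditions are standard.
    """

    code: str
    step_size_pct: int
    direction: Direction
    walking_aid: bool
    footwear: Footwear
    sequence_index: int
    standard: bool = field(default=True, compare=False)

    @property
    def category(self) -> str:
        """Leading category letter of the code (S, T, Z, C, W or L)."""
        return self.code.split("-", 1)[0]


def _split_code(code: str) -> tuple[str, int]:
    parts = code.split("-")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ConditionError(
            f"malformed condition code {code!r}: expected <letter>-<percent>"
        )
    letter, num = parts
    try:
        pct = int(num)
    except ValueError:
        raise ConditionError(
            f"malformed condition code {code!r}: step size {num!r} is not an integer"
        ) from None
    return letter, pct


def make_condition(code: str, sequence_index: int = 0) -> ConditionSpec:
    """Permissive constructor for user-defined conditions.

    Accepts any known category letter and step size; conditions outside the
    14-code protocol are flagged ``standard=False`` so downstream reports
    can mark them as extensions.
    """
    letter, pct = _split_code(code)
    if letter not in CATEGORY_SEMANTICS:
        raise ConditionError(
            f"unknown condition category {letter!r} in code {code!r}; "
            f"known categories: {sorted(CATEGORY_SEMANTICS)}"
        )
    if pct not in VALID_STEP_SIZES:
        raise ConditionError(
            f"unknown step size {pct} in code {code!r}; "
            f"valid step sizes: {VALID_STEP_SIZES}"
        )
    direction, aid, footwear = CATEGORY_SEMANTICS[letter]
    return ConditionSpec(
        code=code,
        step_size_pct=pct,
        direction=direction,
        walking_aid=aid,
        footwear=footwear,
        sequence_index=sequence_index,
        standard=code in PROTOCOL_ORDER,
    )


@lru_cache(maxsize=1)
def build_protocol() -> tuple[ConditionSpec, ...]:
    """The 14 protocol conditions in performance order (pure function)."""
    return tuple(
        make_condition(code, sequence_index=i + 1)
        for i, code in enumerate(PROTOCOL_ORDER)
    )


def parse_condition(code: str) -> ConditionSpec:
    """Parse one of the 14 protocol codes; reject anything else.

    Use :func:`make_condition` for non-standard extensions.
    """
    if code not in PROTOCOL_ORDER:
        # raise a precise error: malformed vs. merely non-protocol
        letter, pct = _split_code(code)
        raise ConditionError(
            f"condition code {code!r} is not one of the 14 protocol conditions"
        )
    return build_protocol()[PROTOCOL_ORDER.index(code)]


def condition_category(code: str) -> str:
    """Category letter of a condition code (validates the code)."""
    return parse_condition(code).category
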