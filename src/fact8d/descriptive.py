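"""FACT-8D descriptive system and the FACT-G -> FACT-8D mapping.

The FACT-8D describes health by eight HRQL dimensions (pain, fatigue, nausea,
sleep, work, support, sadness, worry), each on five severity levels
(1 = "Not at all" ... 5 = "Very much"), giving 5**8 = 390,625 states.
Each dimension is sourced from one FACT-G item (two for support), scored 0-4.
Sleep, work and support items are positively framed in the FACT-G, so their
scores are reversed; support takes the *best* of its two items (max score).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "FACTG_ITEMS",
    "N_LEVELS",
    "N_STATES",
    "Dimension",
    "DIMENSION_TABLE",
    "HealthState",
    "MissingItemError",
    "map_response_to_state",
    "enumerate_states",
    "read_factg_responses",
    "states_to_frame",
]

DIMENSIONS = ("pain", "fatigue", "nausea", "sleep", "work", "support", "sadness", "worry")
FACTG_ITEMS = ("GP4", "GP1", "GP2", "GF5", "GF1", "GS2", "GS3", "GE1", "GE6")
N_LEVELS = 5
N_STATES = N_LEVELS ** len(DIMENSIONS)  # 390,625


@dataclass(frozen=True)
class Dimension:
    """One FACT-8D dimension and its FACT-G source item(s).

    ``polarity`` is "direct" when a higher item score means a worse level,
    "reversed" when the source item is positively framed (sleep, work,
    support) and must be reverse-scored.
    """

    code: str
    polarity: str  # "direct" | "reversed"
    source_items: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.polarity not in ("direct", "reversed"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


DIMENSION_TABLE: dict[str, Dimension] = {
    "pain": Dimension("pain", "direct", ("GP4",)),
    "fatigue": Dimension("fatigue", "direct", ("GP1",)),
    "nausea": Dimension("nausea", "direct", ("GP2",)),
    "sleep": Dimension("sleep", "reversed", ("GF5",)),
    "work": Dimension("work", "reversed", ("GF1",)),
    "support": Dimension("support", "reversed", ("GS2", "GS3")),
    "sadness": Dimension("sadness", "direct", ("GE1",)),
    "worry": Dimension("worry", "direct", ("GE6",)),
}


class MissingItemError(ValueError):
    """Raised when a FACT-G response lacks an item needed for mapping."""


@dataclass(frozen=True)
class HealthState:
    """A FACT-8D health state: one level in 1..5 per dimension."""

    levels: Mapping[str, int]

    def __post_init__(self) -> None:
        lv = dict(self.levels)
        missing = set(DIMENSIONS) - set(lv)
        if missing:
            raise ValueError(f"missing dimensions: {sorted(missing)}")
        extra = set(lv) - set(DIMENSIONS)
        if extra:
            raise ValueError(f"unknown dimensions: {sorted(extra)}")
        for dim, level in lv.items():
            if not (isinstance(level, (int, np.integer)) and 1 <= level <= N_LEVELS):
                raise ValueError(f"{dim}: level {level!r} not an integer in 1..{N_LEVELS}")
            lv[dim] = int(level)
        object.__setattr__(self, "levels", lv)

    def __getitem__(self, dim: str) -> int:
        return self.levels[dim]

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(self.levels[d] for d in DIMENSIONS)

    @classmethod
    def from_tuple(cls, levels: tuple[int, ...]) -> "HealthState":
        return cls(dict(zip(DIMENSIONS, levels)))

    @classmethod
    def full_health(cls) -> "HealthState":
        return cls({d: 1 for d in DIMENSIONS})

    @classmethod
    def worst(cls) -> "HealthState":
        return cls({d: N_LEVELS for d in DIMENSIONS})


def map_response_to_state(response: Mapping[str, int | None]) -> HealthState:
    """Map a complete 9-item FACT-G response to a FACT-8D health state.

    Direct dimensions: level = score + 1. Reversed single-item dimensions:
    level = (4 - score) + 1. Support: level = (4 - max(GS2, GS3)) + 1, i.e.
    the best available support, whether from family or friends.

    Raises
    ------
    MissingItemError
        If any of the nine items is absent or None; no imputation is done.
    """
    scores: dict[str, int] = {}
    for item in FACTG_ITEMS:
        val = response.get(item)
        if val is None or (isinstance(val, float) and pd.isna(val)):
            raise MissingItemError(f"FACT-G item {item} is missing; cannot map to a state")
        val = int(val)
        if not 0 <= val <= 4:
            raise ValueError(f"FACT-G item {item} score {val} outside 0..4")
        scores[item] = val

    levels: dict[str, int] = {}
    for dim, meta in DIMENSION_TABLE.items():
        if dim == "support":
            score = max(scores["GS2"], scores["GS3"])
        else:
            score = scores[meta.source_items[0]]
        if meta.polarity == "direct":
            levels[dim] = score + 1
        else:
            levels[dim] = (4 - score) + 1
    return HealthState(levels)


def enumerate_states() -> Iterator[HealthState]:
    """Yield all 5**8 health states once, in lexicographic order over
    (pain, fatigue, nausea, sleep, work, support, sadness, worry).

    States are built through a trusted fast path (enumeration cannot
    produce an invalid level, and per-state validation would dominate the
    cost of a full sweep)."""
    for combo in itertools.product(range(1, N_LEVELS + 1), repeat=len(DIMENSIONS)):
        state = HealthState.__new__(HealthState)
        object.__setattr__(state, "levels", dict(zip(DIMENSIONS, combo)))
        yield state


def read_factg_responses(path) -> pd.DataFrame:
    """Read FACT-G item responses from CSV (one row per respondent, columns
    named by item code; an optional leading id column is preserved)."""
    df = pd.read_csv(path)
    missing_cols = set(FACTG_ITEMS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"response file lacks item columns: {sorted(missing_cols)}")
    return df


def states_to_frame(states: list[HealthState]) -> pd.DataFrame:
    """One column per dimension, one row per state."""
    return pd.DataFrame([s.levels for s in states], columns=list(DIMENSIONS))
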