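"""The 133 contiguous month sets and the pooled reference library.

A harvest hypothesis is a subset of the 12 calendar months.  With 12
possible start months and 12 possible durations there are 144 raw
start x duration combinations, but the twelve 12-month sets pool to
the same data, leaving 133 unique contiguous month sets.  They are
numbered duration-major: indices 1-12 are the one-month sets
(January..December), 13-24 the two-month sets (starting
January..December, wrapping December-January), and so on through the
twelve 11-month sets; index 133 is the single full-year set.

Wraparound runs (e.g. November-March) are first-class; ``start_month``
is the first month of the run in harvest order, not the smallest
calendar number.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import pandas as pd

from .demography import SizeSample, pool_samples

__all__ = [
    "MonthSet",
    "ReferenceLibrary",
    "N_MONTH_SETS",
    "N_RAW_COMBINATIONS",
    "MONTH_ABBR",
    "enumerate_month_sets",
    "month_set_from_index",
    "index_from_months",
    "grid_coordinates",
    "build_reference_library",
    "month_set_table",
]

N_MONTH_SETS = 133
N_RAW_COMBINATIONS = 144  # 12 starts x 12 durations, before collapsing the full year

MONTH_ABBR = [
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
]


def _wrap(month: int) -> int:
    return (month - 1) % 12 + 1


def _contiguous_start(months: frozenset[int]) -> Optional[int]:
    """Start month of the single modular run formed by ``months``, else None."""
    if len(months) == 12:
        return 1  # full year: every month is a start; January by convention
    starts = [m for m in months if _wrap(m - 1) not in months]
    if len(starts) != 1:
        return None
    start = starts[0]
    run = {_wrap(start + k) for k in range(len(months))}
    return start if run == set(months) else None


@dataclass(frozen=True)
class MonthSet:
    """A subset of the calendar months hypothesised as the harvest window."""

    months: frozenset[int]

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError("MonthSet must be non-empty")
        if not all(1 <= m <= 12 for m in self.months):
            raise ValueError(f"months must lie in 1-12: {sorted(self.months)}")

    @property
    def duration(self) -> int:
        return len(self.months)

    @property
    def start_month(self) -> Optional[int]:
        return _contiguous_start(self.months)

    @property
    def contiguous(self) -> bool:
        return self.start_month is not None

    @property
    def canonical_index(self) -> Optional[int]:
        start = self.start_month
        if start is None:
            return None
        if self.duration == 12:
            return N_MONTH_SETS
        return (self.duration - 1) * 12 + start

    def ordered_months(self) -> list[int]:
        """Member months in harvest order (run order for contiguous sets)."""
        start = self.start_month
        if start is not None:
            return [_wrap(start + k) for k in range(self.duration)]
        return sorted(self.months)

    @property
    def label(self) -> str:
        return "-".join(MONTH_ABBR[m - 1] for m in self.ordered_months())

    def __repr__(self) -> str:
        idx = self.canonical_index
        tag = f"#{idx} " if idx is not None else ""
        return f"MonthSet({tag}{self.label})"


def month_set_from_index(i: int) -> MonthSet:
    """The contiguous month set carrying canonical index ``i`` (1-133)."""
    if not 1 <= i <= N_MONTH_SETS:
        raise ValueError(f"canonical index must be 1-{N_MONTH_SETS}, got {i}")
    if i == N_MONTH_SETS:
        return MonthSet(frozenset(range(1, 13)))
    duration = (i - 1) // 12 + 1
    start = i - (duration - 1) * 12
    return MonthSet(frozenset(_wrap(start + k) for k in range(duration)))


def index_from_months(months: Iterable[int]) -> Optional[int]:
    """Canonical 1-133 index of a month set, or None if non-contiguous."""
    return MonthSet(frozenset(months)).canonical_index


@lru_cache(maxsize=1)
def _all_sets() -> tuple[MonthSet, ...]:
    return tuple(month_set_from_index(i) for i in range(1, N_MONTH_SETS + 1))


def enumerate_month_sets() -> tuple[MonthSet, ...]:
    """All 133 month sets in canonical (duration-major) order."""
    return _all_sets()


def grid_coordinates(i: int) -> tuple[int, int]:
    """(start_month, duration) heatmap coordinates of canonical index ``i``.

    Index 133 maps to (January, 12); the January start there is a
    display convention only, since the full-year set has no start.
    """
    ms = month_set_from_index(i)
    return ms.start_month, ms.duration


@dataclass
class ReferenceLibrary:
    """Cross-year monthly reference SFDs and their 133 pooled month-set SFDs."""

    monthly: dict[int, SizeSample]
    pooled: dict[int, SizeSample]
    metadata: dict

    def __post_init__(self) -> None:
        if len(self.pooled) != N_MONTH_SETS:
            raise ValueError(
                f"reference library must hold {N_MONTH_SETS} pooled SFDs, "
                f"got {len(self.pooled)}"
            )


def build_reference_library(
    monthly: Mapping[int, SizeSample], metadata: Optional[dict] = None
) -> ReferenceLibrary:
    """Pool the 12 monthly reference SFDs into the 133 month-set SFDs.

    Every calendar month must be present with at least one specimen;
    the design assumes full monthly coverage and a missing month is
    reported by name.
    """
    missing = [MONTH_ABBR[m - 1] for m in range(1, 13) if m not in monthly]
    if missing:
        raise ValueError(
            "reference library requires all 12 months; missing: " + ", ".join(missing)
        )
    pooled = {}
    for ms in enumerate_month_sets():
        i = ms.canonical_index
        parts = [monthly[m] for m in ms.ordered_months()]
        pooled[i] = pool_samples(parts, label=f"set-{i:03d}[{ms.label}]")
    return ReferenceLibrary(
        monthly=dict(monthly), pooled=pooled, metadata=dict(metadata or {})
    )


def month_set_table() -> pd.DataFrame:
    """The 133 canonical sets as a table: index, start_month, duration, months."""
    rows = []
    for ms in enumerate_month_sets():
        start, duration = grid_coordinates(ms.canonical_index)
        rows.append(
            {
                "index": ms.canonical_index,
                "start_month": start,
                "duration": duration,
                "months": ms.label,
            }
        )
    return pd.DataFrame(rows)
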