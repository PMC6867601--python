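"""Reading and writing the measurement CSV schema and result exports.

Measurement tables have one row per specimen:
``specimen_id, shell_height_mm, source, month, year, unit, level,
elevation_m`` with empty cells for inapplicable fields.  All exports
are plain CSV; run metadata goes in a JSON manifest.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .comparisons import PairwiseTable
from .demography import Measurement
from .models import MatchDistribution, SimilarityProfile
from .month_sets import N_MONTH_SETS, grid_coordinates, month_set_from_index

__all__ = [
    "CSV_COLUMNS",
    "read_measurements",
    "write_measurements",
    "profile_frame",
    "grid_matrix",
    "pairwise_frame",
]

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "specimen_id",
    "shell_height_mm",
    "source",
    "month",
    "year",
    "unit",
    "level",
    "elevation_m",
]


class MalformedTableError(ValueError):
    """The measurement table cannot be used (schema or bulk-corruption)."""


def _opt_int(value: str) -> Optional[int]:
    return int(value) if value not in ("", None) else None


def _opt_float(value: str) -> Optional[float]:
    return float(value) if value not in ("", None) else None


def read_measurements(
    path: str | Path,
    expected_source: Optional[str] = None,
    max_malformed_frac: float = 0.05,
) -> list[Measurement]:
    """Parse a measurement CSV into validated records.

    Malformed rows are collected and logged with their line numbers and
    excluded; if more than ``max_malformed_frac`` of rows are malformed
    the whole table is rejected.  A missing required column is always a
    hard error, as is a record whose source contradicts
    ``expected_source``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise MalformedTableError(
                f"{path}: missing required columns {missing}"
            )
        records: list[Measurement] = []
        bad: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = Measurement(
                    shell_height=float(row["shell_height_mm"]),
                    source=row["source"],
                    month=_opt_int(row["month"]),
                    year=_opt_int(row["year"]),
                    unit=row["unit"] or None,
                    level=row["level"] or None,
                    elevation=_opt_float(row["elevation_m"]),
                    specimen_id=row["specimen_id"] or None,
                )
            except (ValueError, TypeError) as exc:
                bad.append((lineno, str(exc)))
                continue
            if expected_source is not None and rec.source != expected_source:
                raise MalformedTableError(
                    f"{path}:{lineno}: expected source {expected_source!r}, "
                    f"got {rec.source!r}"
                )
            records.append(rec)
    total = len(records) + len(bad)
    if bad:
        for lineno, msg in bad:
            logger.warning("%s:%d: malformed row skipped (%s)", path, lineno, msg)
        if total == 0 or len(bad) / total > max_malformed_frac:
            raise MalformedTableError(
                f"{path}: {len(bad)} of {total} rows malformed"
            )
    return records


def write_measurements(records: Sequence[Measurement], path: str | Path) -> None:
    """Write records in the standard measurement CSV schema."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.specimen_id or "",
                    f"{r.shell_height:.2f}",
                    r.source,
                    r.month if r.month is not None else "",
                    r.year if r.year is not None else "",
                    r.unit or "",
                    r.level or "",
                    r.elevation if r.elevation is not None else "",
                ]
            )


def profile_frame(
    profile: SimilarityProfile, model: Optional[MatchDistribution] = None
) -> pd.DataFrame:
    """A 133-row table of a similarity profile keyed by canonical index,
    with grid coordinates and (optionally) the match relative frequencies."""
    rows = []
    for i in range(1, N_MONTH_SETS + 1):
        start, duration = grid_coordinates(i)
        row = {
            "index": i,
            "start_month": start,
            "duration": duration,
            "months": month_set_from_index(i).label,
            "similarity": profile.value(i),
        }
        if model is not None:
            row["match_rel_freq"] = float(model.relative[i - 1])
        rows.append(row)
    return pd.DataFrame(rows)


def grid_matrix(values_by_index: np.ndarray) -> pd.DataFrame:
    """Reshape a 133-vector onto the 12 x 12 start-month x duration grid.

    Rows are start months, columns durations 1-12; the duration-12
    column is populated only at the January row (display convention for
    the collapsed full-year set); other cells of that column are NaN.
    """
    values_by_index = np.asarray(values_by_index, dtype=float)
    if values_by_index.shape != (N_MONTH_SETS,):
        raise ValueError("expected one value per canonical index")
    grid = np.full((12, 12), np.nan)
    for i in range(1, N_MONTH_SETS + 1):
        start, duration = grid_coordinates(i)
        grid[start - 1, duration - 1] = values_by_index[i - 1]
    return pd.DataFrame(
        grid,
        index=[f"start_{m:02d}" for m in range(1, 13)],
        columns=[f"dur_{d:02d}" for d in range(1, 13)],
    )


def pairwise_frame(table: PairwiseTable) -> pd.DataFrame:
    """Pairwise-test table in the published column order."""
    df = table.data.copy()
    return df[
        [
            "test",
            "p",
            "statistic",
            "first_sample",
            "second_sample",
            "significant",
            "significant_bonferroni",
        ]
    ]
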