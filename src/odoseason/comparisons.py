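"""Pairwise homogeneity testing of archaeological SFD samples.

Pairwise Kolmogorov-Smirnov (distribution shape) and two-group
Kruskal-Wallis (median/location) tests over all unordered pairs of
samples, with a per-family Bonferroni correction, plus the
pooling-strategy machinery (vertical by excavation unit versus
horizontal by elevation bin) and the interannual consistency
diagnostic for the monthly reference surveys.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .demography import (
    Measurement,
    SizeSample,
    ks_distance,
    ks_two_sample_test,
    kruskal_wallis_test,
)

__all__ = [
    "PairwiseTable",
    "pairwise_table",
    "table_from_pvalues",
    "proportion_indistinguishable",
    "year_consistency",
    "pool_archaeological",
]

logger = logging.getLogger(__name__)

TEST_KS = "Kolmogorov-Smirnov Test"
TEST_KW = "Kruskal-Wallis Test"
_TEST_ALIASES = {
    "ks": TEST_KS,
    TEST_KS: TEST_KS,
    "kw": TEST_KW,
    TEST_KW: TEST_KW,
}


@dataclass
class PairwiseTable:
    """All-pairs test results with per-family Bonferroni flags.

    ``m`` is the number of unordered pairs (the per-family comparison
    count); the Bonferroni threshold is ``alpha / m``.
    """

    data: pd.DataFrame  # test, p, statistic, first_sample, second_sample, flags
    alpha: float
    m: int

    def family(self, test: str) -> pd.DataFrame:
        name = _TEST_ALIASES.get(test)
        if name is None:
            raise ValueError(f"unknown test family {test!r}")
        return self.data[self.data["test"] == name]


def _flag(df: pd.DataFrame, alpha: float, m: int) -> pd.DataFrame:
    df = df.copy()
    df["significant"] = df["p"] < alpha
    df["significant_bonferroni"] = df["p"] < alpha / m
    return df


def pairwise_table(
    samples: Sequence[SizeSample], alpha: float = 0.05
) -> PairwiseTable:
    """KS and Kruskal-Wallis tests over all unordered pairs of samples."""
    if len(samples) < 2:
        raise ValueError("pairwise_table requires at least two samples")
    for s in samples:
        if s.n < 2:
            raise ValueError(f"sample {s.label!r} has n={s.n} < 2")
    pairs = list(itertools.combinations(samples, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        d, p_ks = ks_two_sample_test(a, b)
        rows.append((TEST_KS, p_ks, d, a.label, b.label))
    for a, b in pairs:
        h, p_kw = kruskal_wallis_test(a, b)
        rows.append((TEST_KW, p_kw, h, a.label, b.label))
    df = pd.DataFrame(
        rows, columns=["test", "p", "statistic", "first_sample", "second_sample"]
    )
    return PairwiseTable(data=_flag(df, alpha, m), alpha=alpha, m=m)


def table_from_pvalues(
    records: pd.DataFrame, alpha: float = 0.05
) -> PairwiseTable:
    """Build a PairwiseTable from already-computed test results.

    ``records`` needs columns test, p, statistic, first_sample,
    second_sample; used to push published p-values through the same
    Bonferroni machinery as freshly computed ones.  The comparison
    count m is taken per family and must agree across families.
    """
    required = {"test", "p", "statistic", "first_sample", "second_sample"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    counts = records.groupby("test").size()
    if counts.nunique() != 1:
        raise ValueError("test families must have equal comparison counts")
    m = int(counts.iloc[0])
    df = records[sorted(required, key=list(records.columns).index)].copy()
    return PairwiseTable(data=_flag(df, alpha, m), alpha=alpha, m=m)


def proportion_indistinguishable(
    t: PairwiseTable, test: str, corrected: bool = True
) -> float:
    """Percentage of pairwise comparisons that are not significant.

    With ``corrected=True`` the Bonferroni-adjusted flags are counted;
    the corrected proportion can only be larger or equal.
    """
    fam = t.family(test)
    if fam.empty:
        raise ValueError(f"no rows for test family {test!r}")
    col = "significant_bonferroni" if corrected else "significant"
    return float(100.0 * (~fam[col]).sum() / len(fam))


def year_consistency(
    by_year: Mapping[tuple[int, int], SizeSample]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Between-year departures of monthly SFDs versus sample size.

    For every month sampled in two different years, the pairwise
    |difference in median size|, the Kolmogorov-Smirnov D, and the
    smaller of the two sample sizes are tabulated.  Returns the table
    and the Spearman rank correlation of each departure measure against
    min(n): under sampling-noise-driven departures the correlations are
    negative (small samples disagree most).
    """
    months: dict[int, list[tuple[int, SizeSample]]] = {}
    for (month, year), sample in by_year.items():
        months.setdefault(int(month), []).append((int(year), sample))
    rows = []
    for month, entries in sorted(months.items()):
        for (ya, sa), (yb, sb) in itertools.combinations(sorted(entries), 2):
            rows.append(
                {
                    "month": month,
                    "year_a": ya,
                    "year_b": yb,
                    "abs_median_diff": abs(
                        float(np.median(sa.heights)) - float(np.median(sb.heights))
                    ),
                    "ks_d": ks_distance(sa, sb),
                    "min_n": min(sa.n, sb.n),
                }
            )
    if len(rows) < 3:
        raise ValueError(
            "year_consistency requires at least 3 months shared across years"
        )
    table = pd.DataFrame(rows)
    correlations = {}
    for measure in ("abs_median_diff", "ks_d"):
        rho = stats.spearmanr(table[measure], table["min_n"]).statistic
        correlations[measure] = float(rho)
    return table, correlations


def pool_archaeological(
    measurements: Sequence[Measurement],
    mode: str = "vertical",
    elevation_breaks: tuple[float, float] = (2.4, 2.7),
) -> list[SizeSample]:
    """Pool archaeological records by excavation unit or by elevation slice.

    Vertical mode produces one sample per unit (each analytically
    time-averaged over the whole deposit); horizontal mode produces
    three elevation-bin samples with lower-inclusive intervals
    [-inf, b0), [b0, b1), [b1, inf).  Records without an elevation are
    excluded from horizontal pooling only, with a logged count.
    """
    arch = [r for r in measurements if r.source == "archaeological"]
    if not arch:
        raise ValueError("no archaeological records to pool")
    if mode == "vertical":
        groups: dict[str, list[float]] = {}
        for r in arch:
            groups.setdefault(r.unit, []).append(r.shell_height)
        return [
            SizeSample(unit, hs, provenance=f"pooled by unit over {len(hs)} records")
            for unit, hs in sorted(groups.items())
        ]
    if mode != "horizontal":
        raise ValueError(f"unknown pooling mode {mode!r}")
    b0, b1 = elevation_breaks
    if not b0 < b1:
        raise ValueError("elevation_breaks must be increasing")
    bins = {
        f"below-{b0}": [],
        f"{b0}-{b1}": [],
        f"above-{b1}": [],
    }
    labels = list(bins)
    skipped = 0
    for r in arch:
        if r.elevation is None:
            skipped += 1
            continue
        if r.elevation < b0:
            bins[labels[0]].append(r.shell_height)
        elif r.elevation < b1:
            bins[labels[1]].append(r.shell_height)
        else:
            bins[labels[2]].append(r.shell_height)
    if skipped:
        logger.warning(
            "horizontal pooling excluded %d records without elevation", skipped
        )
    return [
        SizeSample(label, hs, provenance=f"pooled by elevation bin {label} (m)")
        for label, hs in bins.items()
        if hs
    ]
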