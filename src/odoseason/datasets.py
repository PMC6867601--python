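"""Published comparison data for the St. Catherines Shell Ring odostomes.

The study that introduced this estimation framework reported pairwise
homogeneity tests among six archaeological samples (three pooled
vertically by excavation unit, three pooled horizontally by elevation
slice).  The printed test results are embedded here so the Bonferroni
reanalysis can be run without the original measurement data, which is
distributed separately.
"""

from __future__ import annotations

import pandas as pd

from .comparisons import TEST_KS, TEST_KW, PairwiseTable, table_from_pvalues

__all__ = ["published_pairwise_results", "PUBLISHED_ALPHA"]

PUBLISHED_ALPHA = 0.05

# (p, statistic, first_sample, second_sample, significant,
#  significant_bonferroni) as printed; flags are retained for
# cross-checking the recomputed ones, not consumed by the reanalysis.
_KS_ROWS = [
    (0.0558, 0.145, "2.1", "2.4", False, False),
    (0.0010, 0.203, "2.1", "2.7", True, True),
    (0.0331, 0.171, "2.1", "281-W83S2", True, False),
    (0.0004, 0.219, "2.1", "784N811E", True, True),
    (0.9767, 0.050, "2.1", "789N801E", False, False),
    (0.0933, 0.120, "2.4", "2.7", False, False),
    (0.8131, 0.072, "2.4", "281-W83S2", False, False),
    (0.0665, 0.129, "2.4", "784N811E", False, False),
    (0.1423, 0.112, "2.4", "789N801E", False, False),
    (0.4292, 0.095, "2.7", "281-W83S2", False, False),
    (0.9967, 0.038, "2.7", "784N811E", False, False),
    (0.0006, 0.188, "2.7", "789N801E", True, True),
    (0.2191, 0.116, "281-W83S2", "784N811E", False, False),
    (0.0201, 0.166, "281-W83S2", "789N801E", True, False),
    (0.0002, 0.203, "784N811E", "789N801E", True, True),
]

_KW_ROWS = [
    (0.0302, 4.698, "2.1", "2.4", True, False),
    (0.0011, 10.709, "2.1", "2.7", True, True),
    (0.0057, 7.643, "2.1", "281-W83S2", True, False),
    (0.0003, 12.893, "2.1", "784N811E", True, True),
    (0.9701, 0.001, "2.1", "789N801E", False, False),
    (0.2113, 1.562, "2.4", "2.7", False, False),
    (0.4634, 0.538, "2.4", "281-W83S2", False, False),
    (0.1021, 2.672, "2.4", "784N811E", False, False),
    (0.0174, 5.658, "2.4", "789N801E", True, False),
    (0.5897, 0.291, "2.7", "281-W83S2", False, False),
    (0.6701, 0.181, "2.7", "784N811E", False, False),
    (0.0004, 12.735, "2.7", "789N801E", True, True),
    (0.3553, 0.854, "281-W83S2", "784N811E", False, False),
    (0.0031, 8.771, "281-W83S2", "789N801E", True, True),
    (0.0001, 15.204, "784N811E", "789N801E", True, True),
]


def published_records() -> pd.DataFrame:
    """The printed pairwise test rows, including the printed flags."""
    rows = []
    for test, data in ((TEST_KS, _KS_ROWS), (TEST_KW, _KW_ROWS)):
        for p, stat, a, b, sig, bonf in data:
            rows.append(
                {
                    "test": test,
                    "p": p,
                    "statistic": stat,
                    "first_sample": a,
                    "second_sample": b,
                    "published_significant": sig,
                    "published_significant_bonferroni": bonf,
                }
            )
    return pd.DataFrame(rows)


def published_pairwise_results(alpha: float = PUBLISHED_ALPHA) -> PairwiseTable:
    """The published pairwise tests with significance flags recomputed
    from the printed p-values under the per-family Bonferroni rule."""
    return table_from_pvalues(published_records(), alpha=alpha)
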