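"""Bootstrap null-model inference of harvest season and duration.

The estimation strategy is a resampling classifier.  Each of the 133
reference month-set SFDs defines a "null model": the distribution,
over B bootstrap replicates drawn from that reference at the
archaeological sample size n, of which of the 133 references each
replicate matches best under the Kolmogorov-Smirnov D distance.  The
same match distribution is built for the archaeological sample itself,
and the null model most similar to it (Jaccard, Sorensen or
Bray-Curtis similarity over the 133 match frequencies) identifies the
best-supported harvest window.

Because every bootstrap replicate of a reference takes values on that
reference's own support, best-match classification is vectorised: all
reference ECDFs are tabulated once on the union support grid, a
bootstrap replicate is a multinomial draw over grid points, and D to
every reference is a row-wise max of absolute ECDF differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .demography import SizeSample, ks_distance, pool_samples
from .month_sets import (
    N_MONTH_SETS,
    MonthSet,
    ReferenceLibrary,
    enumerate_month_sets,
    month_set_from_index,
)

__all__ = [
    "MatchDistribution",
    "NullModelSuite",
    "SimilarityProfile",
    "HarvestEstimate",
    "MatchClassifier",
    "best_match",
    "build_null_model",
    "build_null_suite",
    "sample_match_model",
    "similarity",
    "estimate_harvest",
    "discontinuous_variants",
    "evaluate_month_combination",
]

SIMILARITY_METHODS = ("jaccard", "sorensen", "bray_curtis")

# substream layout under the master seed: child 0 -> sample match model,
# child i (1..133) -> null model i; gapped combinations get keyed streams.
_N_CHILDREN = N_MONTH_SETS + 1
_GAPPED_STREAM_KEY = 0x6D6F6E74  # namespace tag for non-contiguous month sets


@dataclass
class MatchDistribution:
    """Counts of best-match outcomes over the 133 month-set indices."""

    counts: np.ndarray  # shape (133,), counts[i-1] for canonical index i
    B: int
    n: int
    origin: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_MONTH_SETS,):
            raise ValueError("counts must cover the 133 canonical indices")
        if self.B < 1 or int(self.counts.sum()) != self.B:
            raise ValueError("match counts must sum to B >= 1")

    @property
    def relative(self) -> np.ndarray:
        return self.counts / self.B

    @property
    def presence(self) -> np.ndarray:
        return self.counts >= 1

    def modal_index(self) -> int:
        """Most frequent match (lowest canonical index on ties)."""
        return int(np.argmax(self.counts)) + 1


@dataclass
class NullModelSuite:
    """One null model per reference month set, at a fixed sample size."""

    models: dict[int, MatchDistribution]
    n: int
    B: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.models) != N_MONTH_SETS:
            raise ValueError("suite must contain 133 null models")


@dataclass
class SimilarityProfile:
    """Similarity of one sample's match model to each of the 133 null models."""

    method: str
    values: np.ndarray  # shape (133,), values[i-1] for canonical index i

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_MONTH_SETS,):
            raise ValueError("profile must cover the 133 canonical indices")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("similarities must lie in [0, 1]")

    def value(self, index: int) -> float:
        return float(self.values[index - 1])

    def best_indices(self) -> list[int]:
        """Canonical indices attaining the profile maximum (ties reported)."""
        top = self.values.max()
        return [int(i) + 1 for i in np.flatnonzero(self.values == top)]


@dataclass
class HarvestEstimate:
    """Per-method best month set(s) with the full similarity profiles."""

    label: str
    n: int
    B: int
    seed: int
    profiles: dict[str, SimilarityProfile]
    best: dict[str, list[int]]
    sample_model: MatchDistribution

    def best_set(self, method: str) -> MonthSet:
        return month_set_from_index(self.best[method][0])


class MatchClassifier:
    """Vectorised KS best-match classifier against the 133 pooled references.

    ``extra_support`` must include the heights of any sample that will
    be classified or bootstrapped but is not part of the library, so
    that the evaluation grid contains every ECDF jump point and the
    computed D values are exact.
    """

    def __init__(
        self, lib: ReferenceLibrary, extra_support: Iterable[float] = ()
    ) -> None:
        parts = [lib.monthly[m].heights for m in sorted(lib.monthly)]
        extra = np.asarray(list(extra_support), dtype=float)
        if extra.size:
            parts.append(extra)
        self.grid = np.unique(np.concatenate(parts))
        m = self.grid.size
        self.ref_cdf = np.empty((N_MONTH_SETS, m))
        for i in range(1, N_MONTH_SETS + 1):
            h = lib.pooled[i].heights
            self.ref_cdf[i - 1] = np.searchsorted(h, self.grid, side="right") / h.size

    def _grid_weights(self, heights: np.ndarray) -> np.ndarray:
        """Empirical probabilities of a sample over the grid points."""
        idx = np.searchsorted(self.grid, heights)
        if np.any(idx >= self.grid.size) or np.any(self.grid[idx] != heights):
            raise ValueError(
                "sample heights missing from classifier grid; rebuild the "
                "classifier with extra_support covering this sample"
            )
        counts = np.bincount(idx, minlength=self.grid.size)
        return counts / counts.sum()

    def classify(self, heights: np.ndarray) -> int:
        """Best-matching canonical index for one sample (lowest index on ties)."""
        h = np.sort(np.asarray(heights, dtype=float))
        e = np.searchsorted(h, self.grid, side="right") / h.size
        d = np.abs(self.ref_cdf - e).max(axis=1)
        return int(np.argmin(d)) + 1

    def bootstrap_match_counts(
        self,
        source_heights: np.ndarray,
        n: int,
        B: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Match counts of B bootstrap replicates (size n) of a source sample.

        A replicate is a draw with replacement from the source, i.e. a
        multinomial draw over its empirical distribution on the grid;
        its ECDF is the normalised cumulative sum of those counts.
        """
        p = self._grid_weights(np.asarray(source_heights, dtype=float))
        draws = rng.multinomial(n, p, size=B)
        ecdfs = np.cumsum(draws, axis=1) / n
        best = np.zeros(B, dtype=np.int64)
        dmin = np.abs(ecdfs - self.ref_cdf[0]).max(axis=1)
        for j in range(1, N_MONTH_SETS):
            d = np.abs(ecdfs - self.ref_cdf[j]).max(axis=1)
            better = d < dmin  # strict: ties stay at the lowest index
            best[better] = j
            dmin[better] = d[better]
        return np.bincount(best, minlength=N_MONTH_SETS)


def best_match(s: SizeSample, lib: ReferenceLibrary) -> int:
    """Canonical index of the reference SFD with the lowest D to ``s``.

    Ties are broken deterministically toward the lowest canonical index.
    """
    clf = MatchClassifier(lib, extra_support=s.heights)
    return clf.classify(s.heights)


def _child_rng(master_seed: int, child: int) -> np.random.Generator:
    children = np.random.SeedSequence(master_seed).spawn(_N_CHILDREN)
    return np.random.default_rng(children[child])


def _gapped_rng(master_seed: int, months: frozenset[int]) -> np.random.Generator:
    bitmask = sum(1 << (m - 1) for m in months)
    return np.random.default_rng(
        np.random.SeedSequence((master_seed, _GAPPED_STREAM_KEY, bitmask))
    )


def build_null_model(
    i: int,
    lib: ReferenceLibrary,
    n: int,
    B: int,
    rng_seed: int,
    _classifier: Optional[MatchClassifier] = None,
) -> MatchDistribution:
    """Null model for reference month set ``i``: the match distribution of
    B bootstrap replicates of its pooled SFD at sample size ``n``.

    Each null model draws from its own substream of the master seed, so
    a single model can be rebuilt in isolation and still agree with the
    corresponding entry of a full suite built under the same seed.
    """
    if n < 1 or B < 1:
        raise ValueError("n and B must be >= 1")
    clf = _classifier if _classifier is not None else MatchClassifier(lib)
    rng = _child_rng(rng_seed, i)
    counts = clf.bootstrap_match_counts(lib.pooled[i].heights, n, B, rng)
    return MatchDistribution(counts=counts, B=B, n=n, origin=f"null model for set {i}")


def build_null_suite(
    lib: ReferenceLibrary,
    n: int,
    B: int,
    rng_seed: int,
    _classifier: Optional[MatchClassifier] = None,
) -> NullModelSuite:
    """All 133 null models at sample size ``n`` (133 x B classifier calls)."""
    clf = _classifier if _classifier is not None else MatchClassifier(lib)
    models = {
        i: build_null_model(i, lib, n, B, rng_seed, _classifier=clf)
        for i in range(1, N_MONTH_SETS + 1)
    }
    return NullModelSuite(models=models, n=n, B=B, seed=rng_seed)


def sample_match_model(
    s: SizeSample,
    lib: ReferenceLibrary,
    B: int,
    rng_seed: int,
    _classifier: Optional[MatchClassifier] = None,
) -> MatchDistribution:
    """Match distribution of B bootstrap replicates of a sample at its own n."""
    clf = (
        _classifier
        if _classifier is not None
        else MatchClassifier(lib, extra_support=s.heights)
    )
    rng = _child_rng(rng_seed, 0)
    counts = clf.bootstrap_match_counts(s.heights, s.n, B, rng)
    return MatchDistribution(
        counts=counts, B=B, n=s.n, origin=f"sample {s.label}"
    )


def similarity(p: MatchDistribution, q: MatchDistribution, method: str) -> float:
    """Similarity of two match distributions in [0, 1].

    Presence-absence indices treat any index matched at least once as
    present; Bray-Curtis is computed on relative match frequencies so
    distributions with unequal B remain comparable (identical to raw
    counts when B agrees).
    """
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown similarity method {method!r}")
    if p.B < 1 or q.B < 1:
        raise ValueError("similarity requires non-degenerate match distributions")
    if method == "bray_curtis":
        pf, qf = p.relative, q.relative
        return float(1.0 - np.abs(pf - qf).sum() / (pf + qf).sum())
    a, b = p.presence, q.presence
    inter = int(np.sum(a & b))
    if method == "jaccard":
        union = int(np.sum(a | b))
        return inter / union
    return 2 * inter / (int(a.sum()) + int(b.sum()))  # sorensen


def estimate_harvest(
    s: SizeSample,
    lib: ReferenceLibrary,
    B: int = 2000,
    methods: Sequence[str] = SIMILARITY_METHODS,
    rng_seed: int = 0,
) -> HarvestEstimate:
    """Full harvest-time estimate for one archaeological sample.

    Builds the 133-model null suite at the sample's n, the sample's own
    match model, and one similarity profile per requested method; the
    per-method best month set(s) are the profile argmax (ties reported).
    """
    unknown = [m for m in methods if m not in SIMILARITY_METHODS]
    if unknown:
        raise ValueError(f"unknown similarity methods: {unknown}")
    clf = MatchClassifier(lib, extra_support=s.heights)
    suite = build_null_suite(lib, s.n, B, rng_seed, _classifier=clf)
    model = sample_match_model(s, lib, B, rng_seed, _classifier=clf)
    profiles = {}
    best = {}
    for method in methods:
        values = np.array(
            [
                similarity(model, suite.models[i], method)
                for i in range(1, N_MONTH_SETS + 1)
            ]
        )
        prof = SimilarityProfile(method=method, values=values)
        profiles[method] = prof
        best[method] = prof.best_indices()
    return HarvestEstimate(
        label=s.label,
        n=s.n,
        B=B,
        seed=rng_seed,
        profiles=profiles,
        best=best,
        sample_model=model,
    )


def discontinuous_variants(best: MonthSet) -> list[MonthSet]:
    """Non-contiguous sub-windows of a best continuous month set.

    All subsets of the window's months of size >= 2 that contain at
    least one gap.  Windows shorter than 3 months have none.
    """
    if not best.contiguous:
        raise ValueError("discontinuous_variants expects a contiguous month set")
    months = best.ordered_months()
    k = len(months)
    out = []
    for mask in range(1, 1 << k):
        subset = frozenset(months[j] for j in range(k) if mask >> j & 1)
        if len(subset) < 2:
            continue
        ms = MonthSet(subset)
        if not ms.contiguous:
            out.append(ms)
    out.sort(key=lambda ms: (ms.duration, tuple(sorted(ms.months))))
    return out


def evaluate_month_combination(
    months: MonthSet,
    s: SizeSample,
    lib: ReferenceLibrary,
    B: int,
    method: str,
    rng_seed: int,
) -> float:
    """Similarity between a sample's match model and the null model of an
    arbitrary (possibly gapped) month combination.

    The combination's pooled SFD is bootstrapped at the sample's n and
    classified against the standard 133 references — the reference
    space is never enlarged; gapped candidates are evaluated post hoc.
    Contiguous combinations reuse the canonical per-model substream, so
    they reproduce the corresponding profile entry of
    :func:`estimate_harvest` under the same master seed.
    """
    missing = [m for m in months.months if m not in lib.monthly]
    if missing:
        raise ValueError(f"months missing from the reference library: {missing}")
    clf = MatchClassifier(lib, extra_support=s.heights)
    idx = months.canonical_index
    if idx is not None:
        rng = _child_rng(rng_seed, idx)
        source = lib.pooled[idx]
    else:
        rng = _gapped_rng(rng_seed, months.months)
        source = pool_samples(
            [lib.monthly[m] for m in months.ordered_months()],
            label=f"combo[{months.label}]",
        )
    counts = clf.bootstrap_match_counts(source.heights, s.n, B, rng)
    null = MatchDistribution(
        counts=counts, B=B, n=s.n, origin=f"null model for {months.label}"
    )
    model = sample_match_model(s, lib, B, rng_seed, _classifier=clf)
    return similarity(model, null, method)
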