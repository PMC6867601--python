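"""Empirical size-frequency distribution (SFD) machinery.

Shell-height samples and their empirical cumulative distributions
(ogives), the two-sample Kolmogorov-Smirnov D distance that serves as
the matching metric throughout the package, rank-based homogeneity
tests, pooling, and minimum-size trimming.

Shell height is the maximum shell dimension, measured from the apex to
the abapical end, in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Measurement",
    "SizeSample",
    "Ecdf",
    "ks_distance",
    "ks_two_sample_test",
    "kruskal_wallis_test",
    "pool_samples",
    "trim_min_size",
    "monthly_pool",
    "ogive",
]


@dataclass(frozen=True)
class Measurement:
    """A single measured specimen with its provenance.

    Recent (live-collected) specimens carry the survey month and year;
    archaeological specimens carry the excavation unit, an arbitrary
    10 cm level label, and an elevation in metres relative to the site
    datum.  A missing elevation only excludes the record from
    horizontal (elevation-bin) pooling.
    """

    shell_height: float
    source: str  # "recent" | "archaeological"
    month: Optional[int] = None
    year: Optional[int] = None
    unit: Optional[str] = None
    level: Optional[str] = None
    elevation: Optional[float] = None
    specimen_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.shell_height) or self.shell_height <= 0:
            raise ValueError(
                f"shell_height must be positive and finite, got {self.shell_height!r}"
            )
        if self.source not in ("recent", "archaeological"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "recent":
            if self.month is None or self.year is None:
                raise ValueError("recent records require month and year")
            if not 1 <= int(self.month) <= 12:
                raise ValueError(f"month must be 1-12, got {self.month!r}")
        else:
            if self.unit is None:
                raise ValueError("archaeological records require a unit label")


class SizeSample:
    """An SFD sample: a labelled multiset of shell heights (mm).

    Heights are stored sorted ascending so two samples with equal
    multisets compare equal regardless of input order.
    """

    __slots__ = ("label", "heights", "provenance")

    def __init__(
        self,
        label: str,
        heights: Iterable[float],
        provenance: str = "",
    ) -> None:
        h = np.sort(np.asarray(list(heights), dtype=float))
        if h.size == 0:
            raise ValueError(f"sample {label!r} is empty")
        if not np.all(np.isfinite(h)) or np.any(h <= 0):
            raise ValueError(f"sample {label!r} has non-positive or non-finite heights")
        self.label = label
        self.heights = h
        self.heights.setflags(write=False)
        self.provenance = provenance

    @property
    def n(self) -> int:
        return int(self.heights.size)

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SizeSample):
            return NotImplemented
        return self.heights.shape == other.heights.shape and bool(
            np.array_equal(self.heights, other.heights)
        )

    def __hash__(self) -> int:  # multiset identity
        return hash(self.heights.tobytes())

    def __repr__(self) -> str:
        return f"SizeSample({self.label!r}, n={self.n})"


@dataclass(frozen=True)
class Ecdf:
    """Empirical CDF on the distinct observed heights.

    ``cumulative`` holds fractions in (0, 1] at each support point;
    it is strictly increasing and ends at exactly 1.
    """

    support: np.ndarray
    cumulative: np.ndarray

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        idx = np.searchsorted(self.support, x, side="right")
        padded = np.concatenate([[0.0], self.cumulative])
        return padded[idx]


def ogive(s: SizeSample) -> Ecdf:
    """Cumulative relative frequency curve of a sample's shell heights."""
    support, counts = np.unique(s.heights, return_counts=True)
    cumulative = np.cumsum(counts) / s.n
    cumulative[-1] = 1.0  # guard against accumulated rounding
    return Ecdf(support=support, cumulative=cumulative)


def ks_distance(a: SizeSample, b: SizeSample) -> float:
    """Kolmogorov-Smirnov D between two SFDs.

    The maximum absolute difference between the two empirical relative
    cumulative frequency distributions, evaluated over the union of
    observed heights with ties merged.  0 means identical distributions;
    1 means completely non-overlapping ones.
    """
    grid = np.union1d(a.heights, b.heights)
    fa = np.searchsorted(a.heights, grid, side="right") / a.n
    fb = np.searchsorted(b.heights, grid, side="right") / b.n
    return float(np.abs(fa - fb).max())


def ks_two_sample_test(a: SizeSample, b: SizeSample) -> tuple[float, float]:
    """Two-sample KS test: (D, asymptotic p-value).

    Symmetric in argument order.  p-values use the asymptotic
    distribution; for the small samples of this application they are
    approximate and feed only significance flags.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("ks_two_sample_test requires n >= 2 in both samples")
    d = ks_distance(a, b)
    en = np.sqrt(a.n * b.n / (a.n + b.n))
    p = stats.kstwobign.sf(d * en)
    return d, float(min(1.0, max(0.0, p)))


def kruskal_wallis_test(a: SizeSample, b: SizeSample) -> tuple[float, float]:
    """Two-group Kruskal-Wallis H with tie correction; p from chi-square (1 df).

    Degenerate case where every value in both samples is identical is
    defined as H = 0, p = 1.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("kruskal_wallis_test requires n >= 2 in both samples")
    combined = np.concatenate([a.heights, b.heights])
    if np.all(combined == combined[0]):
        # all observations tied across both groups
        return 0.0, 1.0
    h, p = stats.kruskal(a.heights, b.heights)
    return float(h), float(p)


def pool_samples(samples: Sequence[SizeSample], label: str) -> SizeSample:
    """Multiset union of samples; n is additive; provenance records the chain."""
    if len(samples) == 0:
        raise ValueError("pool_samples requires at least one sample")
    heights = np.concatenate([s.heights for s in samples])
    provenance = "pooled[" + " + ".join(s.label for s in samples) + "]"
    return SizeSample(label, heights, provenance=provenance)


def trim_min_size(s: SizeSample, cutoff: float = 1.6) -> SizeSample:
    """Drop specimens below ``cutoff`` mm (boundary value retained).

    Mirrors the removal of recent specimens finer than the coarsest
    archaeological screen mesh.  An empty result is an error: the
    trimmed sample would be unusable.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    kept = s.heights[s.heights >= cutoff]
    if kept.size == 0:
        raise ValueError(f"trimming {s.label!r} at {cutoff} mm leaves no specimens")
    return SizeSample(
        s.label,
        kept,
        provenance=f"{s.provenance} | trimmed >= {cutoff} mm".strip(" |"),
    )


def monthly_pool(recent: Sequence[Measurement]) -> dict[int, SizeSample]:
    """Pool recent records into cross-year monthly samples.

    Returns a mapping month (1-12) -> SizeSample; months with no
    specimens are simply absent (downstream library construction
    reports them).
    """
    by_month: dict[int, list[float]] = {}
    years: dict[int, set[int]] = {}
    for rec in recent:
        if rec.source != "recent" or rec.month is None:
            raise ValueError("monthly_pool expects recent records with months")
        by_month.setdefault(int(rec.month), []).append(rec.shell_height)
        years.setdefault(int(rec.month), set()).add(int(rec.year))
    out = {}
    for month in sorted(by_month):
        yrs = ",".join(str(y) for y in sorted(years[month]))
        out[month] = SizeSample(
            f"month-{month:02d}",
            by_month[month],
            provenance=f"recent surveys pooled across years {yrs}",
        )
    return out


def measurements_to_sample(
    records: Sequence[Measurement], label: str, provenance: str = ""
) -> SizeSample:
    """Collect the heights of a record set into a single sample."""
    return SizeSample(label, [r.shell_height for r in records], provenance=provenance)
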