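"""Synthetic odostome demography: monthly surveys and time-averaged harvests.

The generator emulates the life history that makes the snail a
seasonality proxy: a single late-spring spawning event per year, a
fixed ~12-month lifespan with abrupt cohort replacement, and saturating
(von Bertalanffy-type) growth with lognormal between-individual rate
heterogeneity, so that dispersion of the size-frequency distribution
grows as the cohort ages.  Sizes receive Gaussian measurement noise and
are rounded to the 0.02 mm caliper precision.

Every random draw comes from a substream keyed on (master seed, year,
month), so a one-month, one-year harvest reproduces the corresponding
monthly survey exactly under the same seed, and harvests accumulated
over many years share per-year spawn-timing and growth-rate
fluctuations coherently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .demography import Measurement, SizeSample, monthly_pool
from .month_sets import MonthSet, ReferenceLibrary, build_reference_library

__all__ = [
    "DemographyParams",
    "HarvestScenario",
    "size_at_age",
    "simulate_monthly_survey",
    "simulate_harvest",
    "make_reference_fixture",
]

MM_PRECISION = 0.02  # caliper measurement precision
WEEKS_PER_MONTH = 4.345

# substream namespace tags
_KEY_YEAR = 1
_KEY_GROWTH_YEAR = 2
_KEY_ASSIGN = 3
_KEY_DRAW = 4


@dataclass(frozen=True)
class DemographyParams:
    """Life-history and observation parameters of the synthetic population.

    Defaults describe the study system: spawning once a year in May,
    death of the outgoing cohort within twelve months (so May is the
    one bimodal month, with old and new cohorts co-occurring), rapid
    early growth decelerating toward an asymptote a little above the
    largest observed shells (~6.2 mm).
    """

    spawn_month: int = 5
    spawn_sd_weeks: float = 0.0  # interannual spawn-timing jitter
    lifespan_months: float = 12.0
    settlement_size: float = 0.3  # mm at age 0
    asymptotic_size: float = 6.4  # mm
    growth_rate: float = 0.25  # per month
    growth_cv: float = 0.18  # between-individual CV of growth rate
    measurement_sd: float = 0.05  # mm observation noise

    def __post_init__(self) -> None:
        if not 1 <= self.spawn_month <= 12:
            raise ValueError("spawn_month must be 1-12")
        if min(
            self.lifespan_months,
            self.settlement_size,
            self.asymptotic_size,
            self.growth_rate,
        ) <= 0:
            raise ValueError("demography parameters must be positive")
        if self.growth_cv < 0 or self.spawn_sd_weeks < 0 or self.measurement_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.asymptotic_size <= self.settlement_size:
            raise ValueError("asymptotic_size must exceed settlement_size")


@dataclass(frozen=True)
class HarvestScenario:
    """A true harvest window and its time-averaging depth.

    ``n_years`` is the number of accumulation years mixed into one
    archaeological sample; ``growth_jitter_sd`` is the lognormal sd of
    a per-year multiplier on the growth rate (environmental
    fluctuation between years).
    """

    month_set: MonthSet
    n: int
    n_years: int = 1
    within_set_weights: Optional[tuple[float, ...]] = None
    growth_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.n_years < 1:
            raise ValueError("n and n_years must be >= 1")
        if self.growth_jitter_sd < 0:
            raise ValueError("growth_jitter_sd must be non-negative")
        if self.within_set_weights is not None:
            w = np.asarray(self.within_set_weights, dtype=float)
            if w.size != self.month_set.duration or np.any(w < 0) or w.sum() <= 0:
                raise ValueError(
                    "within_set_weights must be non-negative, one per member month"
                )

    def month_probabilities(self) -> np.ndarray:
        if self.within_set_weights is None:
            return np.full(self.month_set.duration, 1.0 / self.month_set.duration)
        w = np.asarray(self.within_set_weights, dtype=float)
        return w / w.sum()


def size_at_age(
    p: DemographyParams, age_months: float, individual_rate: Optional[float] = None
) -> float:
    """Expected shell height at a given age under the saturating growth curve.

    height(a) = s0 + (A - s0) * (1 - exp(-k a)); strictly increasing in
    both age and the individual growth rate k.
    """
    if age_months < 0:
        raise ValueError("age_months must be non-negative")
    k = p.growth_rate if individual_rate is None else individual_rate
    span = p.asymptotic_size - p.settlement_size
    return float(p.settlement_size + span * (1.0 - np.exp(-k * age_months)))


def _seq(seed: int, *key: int) -> np.random.Generator:
    # keys may be small negative ints (e.g. years before the epoch used
    # in a scenario); SeedSequence entropy must be non-negative
    shifted = tuple(int(k) + (1 << 20) for k in key)
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + shifted))


def _spawn_offset(p: DemographyParams, seed: int, year: int) -> float:
    """This year's spawn-timing deviation from spawn_month, in months."""
    if p.spawn_sd_weeks == 0:
        return 0.0
    rng = _seq(seed, _KEY_YEAR, year)
    return float(rng.normal(0.0, p.spawn_sd_weeks / WEEKS_PER_MONTH))


def _growth_multiplier(sd: float, seed: int, year: int) -> float:
    """This year's multiplicative growth-rate fluctuation (lognormal, mean 1)."""
    if sd == 0:
        return 1.0
    rng = _seq(seed, _KEY_GROWTH_YEAR, year)
    sigma = np.sqrt(np.log1p(sd**2))
    return float(np.exp(rng.normal(-sigma**2 / 2.0, sigma)))


def _round_mm(x: np.ndarray) -> np.ndarray:
    units = np.round(x / MM_PRECISION)
    return np.maximum(units, 1.0) * MM_PRECISION


def _draw_sizes(
    p: DemographyParams,
    month: int,
    year: int,
    n: int,
    seed: int,
    growth_jitter_sd: float = 0.0,
) -> np.ndarray:
    """Sizes of n specimens alive at survey time (month, year).

    The survey falls at the integer month mark; a cohort spawned in
    year y is aged t - (12 y + spawn_month + jitter_y) and is alive for
    ages in [0, lifespan].  At the spawn month itself, with zero
    jitter, the outgoing cohort (age == lifespan) and the incoming one
    (age 0) co-occur, producing the characteristic bimodal window;
    individuals are split evenly between co-occurring cohorts.
    """
    t = 12.0 * year + month
    cohorts = []  # (age, birth_year)
    for by in (year - 2, year - 1, year):
        age = t - (12.0 * by + p.spawn_month + _spawn_offset(p, seed, by))
        if 0.0 <= age <= p.lifespan_months:
            cohorts.append((age, by))
    if not cohorts:
        # jitter opened a gap between cohorts; fall back to the nearest
        # one with its age clipped to the live range
        candidates = []
        for by in (year - 2, year - 1, year):
            age = t - (12.0 * by + p.spawn_month + _spawn_offset(p, seed, by))
            clipped = min(max(age, 0.0), p.lifespan_months)
            candidates.append((abs(age - clipped), clipped, by))
        _, age, by = min(candidates)
        cohorts = [(age, by)]
    rng = _seq(seed, _KEY_DRAW, year, month)
    which = rng.integers(len(cohorts), size=n)
    sigma = np.sqrt(np.log1p(p.growth_cv**2)) if p.growth_cv > 0 else 0.0
    rate_factor = (
        np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=n)) if sigma > 0 else np.ones(n)
    )
    sizes = np.empty(n)
    for c, (age, by) in enumerate(cohorts):
        mask = which == c
        if not np.any(mask):
            continue
        k = p.growth_rate * rate_factor[mask]
        k = k * _growth_multiplier(growth_jitter_sd, seed, by)
        span = p.asymptotic_size - p.settlement_size
        sizes[mask] = p.settlement_size + span * (1.0 - np.exp(-k * age))
    if p.measurement_sd > 0:
        sizes = sizes + rng.normal(0.0, p.measurement_sd, size=n)
    return _round_mm(sizes)


def simulate_monthly_survey(
    p: DemographyParams,
    months: Sequence[tuple[int, int]],
    n_per_month: int,
    rng_seed: int,
) -> list[Measurement]:
    """Recent census records for a sequence of (month, year) surveys."""
    if n_per_month < 1:
        raise ValueError("n_per_month must be >= 1")
    records = []
    for month, year in months:
        sizes = _draw_sizes(p, month, year, n_per_month, rng_seed)
        for j, h in enumerate(sizes):
            records.append(
                Measurement(
                    shell_height=float(h),
                    source="recent",
                    month=month,
                    year=year,
                    specimen_id=f"R{year}{month:02d}-{j:04d}",
                )
            )
    return records


def simulate_harvest(
    p: DemographyParams, sc: HarvestScenario, rng_seed: int
) -> SizeSample:
    """A time-averaged archaeological sample from a known harvest window.

    Each specimen draws an accumulation year (uniform over n_years) and
    a harvest month (by the scenario's within-window weights), then a
    size from the cohort alive in that month of that year.  The true
    scenario rides along in the sample's provenance string and is never
    consumed by the estimator.
    """
    assign = _seq(rng_seed, _KEY_ASSIGN)
    member = sc.month_set.ordered_months()
    years = assign.integers(0, sc.n_years, size=sc.n)
    months = assign.choice(member, p=sc.month_probabilities(), size=sc.n)
    heights = np.empty(sc.n)
    for year in np.unique(years):
        for month in np.unique(months[years == year]):
            mask = (years == year) & (months == month)
            heights[mask] = _draw_sizes(
                p,
                int(month),
                int(year),
                int(mask.sum()),
                rng_seed,
                growth_jitter_sd=sc.growth_jitter_sd,
            )
    return SizeSample(
        label=f"synthetic-harvest[{sc.month_set.label}]",
        heights=heights,
        provenance=(
            f"simulated truth={sc.month_set.label} n_years={sc.n_years} "
            f"spawn_sd_weeks={p.spawn_sd_weeks} growth_jitter_sd={sc.growth_jitter_sd} "
            f"seed={rng_seed}"
        ),
    )


def make_reference_fixture(
    p: DemographyParams,
    years: int = 2,
    n_per_month: int = 100,
    rng_seed: int = 0,
    start_year: int = 2006,
) -> tuple[list[Measurement], ReferenceLibrary]:
    """A multi-year monthly census and the reference library built from it.

    Emulates the 24-consecutive-month survey design (July of the first
    year through June two years later when ``years=2``): ``12 * years``
    monthly samples, pooled across years into 12 monthly reference SFDs
    and their 133 month-set SFDs.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    schedule = []
    month, year = 7, start_year
    for _ in range(12 * years):
        schedule.append((month, year))
        month += 1
        if month > 12:
            month, year = 1, year + 1
    records = simulate_monthly_survey(p, schedule, n_per_month, rng_seed)
    monthly = monthly_pool(records)
    lib = build_reference_library(
        monthly,
        metadata={
            "source": f"synthetic census {schedule[0]}..{schedule[-1]}",
            "n_per_month": n_per_month,
            "years": years,
            "seed": rng_seed,
            "trim_mm": None,
        },
    )
    return records, lib
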