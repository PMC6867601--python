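# Methods

## The estimator

The package infers the season and duration of shellfish harvest from
the size-frequency distribution (SFD) of *Boonea impressa* shell
heights in an archaeological sample. The snail's annual life cycle —
one late-spring spawning event, death of the outgoing cohort within
about twelve months — makes its SFD a proxy for the calendar months
over which specimens were gathered.

The hypothesis space is the set of contiguous month windows: 12 start
months × 12 durations = 144 combinations, collapsing to 133 unique
month sets because all twelve 12-month windows pool identical data.
Sets are numbered duration-major (all one-month sets January→December,
then all two-month sets, and so on; #133 is the full year). Wraparound
windows such as November–March are ordinary members; the full-year set
is displayed at the January row of the 12 × 12 start × duration grid
purely by convention.

For an archaeological sample of size *n*, each reference month set *i*
yields a *null model*: the distribution, over *B* bootstrap replicates
of size *n* drawn from reference SFD *i*, of the best-matching
reference index under the two-sample Kolmogorov–Smirnov distance
*D* = sup|F₁ − F₂| (evaluated over the union of observed heights with
ties merged; no jittering). The archaeological sample's own match
distribution is built the same way and compared with each null model
by Jaccard, Sørensen (presence–absence, a month set counting as
"present" if matched in at least one replicate) or Bray–Curtis
similarity (computed on relative match frequencies, so models with
unequal *B* remain comparable). The null model with the highest
similarity is the harvest estimate; the full 133-value similarity
profile is retained, because the shape of the profile (e.g. uniformly
near-zero similarity for summer-inclusive sets) carries the
interpretable signal.

Discontinuous harvest hypotheses are handled post hoc: the gapped
subsets (size ≥ 2, at least one internal gap) of the best continuous
window are scored by the same procedure, classified against the
standard 133 references — the reference space is never enlarged, and
no exhaustive search over all 2¹² month subsets is attempted.

## Numerical and design choices

- **Tie-breaking.** Best-match classification breaks ties toward the
  lowest canonical index. This is deterministic and keeps every null
  model reproducible from (library, n, B, seed) alone.
- **Seeding.** A master seed spawns one substream per null model
  (children 1–133) and one for the sample's match model (child 0), so
  any single model can be rebuilt in isolation and still agree with
  the full suite. Gapped combinations draw from streams keyed on the
  month bitmask.
- **Vectorised classification.** All 133 reference ECDFs are tabulated
  once on the grid of distinct observed heights; a bootstrap replicate
  of a library member is a multinomial draw over grid points, and the
  KS distance to every reference is a row-wise maximum of absolute
  ECDF differences. The grid always contains every jump point of both
  distributions being compared, so the computed *D* is exact, not a
  discretisation.
- **KS p-values** (pairwise homogeneity table only) use the limiting
  Kolmogorov distribution without finite-sample correction; they feed
  only the significance flags. The Kruskal–Wallis test is the
  two-group form with the standard tie correction; the degenerate case
  of all observations tied is defined as H = 0, p = 1.
- **Bonferroni.** Each test family (KS, Kruskal–Wallis) is corrected
  separately, with m = C(k, 2) comparisons per family (m = 15 for the
  six published samples).
- **Trimming.** The minimum-size trim retains heights ≥ cutoff
  (boundary kept); default cutoff 1.6 mm, the coarsest archaeological
  screen mesh.
- **Elevation bins.** Horizontal pooling uses lower-inclusive
  intervals [−∞, 2.4), [2.4, 2.7), [2.7, ∞) metres relative to site
  datum; records without elevation are excluded from horizontal
  pooling only, with a logged count.
- **B.** The default is B = 2000 bootstrap replicates per model.
  Tests and the acceptance script use B = 300 (and unit tests
  B = 40–60), a fidelity/runtime trade-off: with 133 models × 133
  references per replicate the full-scale analysis is expensive, and
  the match signatures are already stable at a few hundred replicates
  for the synthetic library sizes used.

## The synthetic demography generator

The generator exists so every stage of the pipeline can be exercised
against a known truth. It emulates:

- one spawning event per year (default May), with optional interannual
  spawn-timing jitter (`spawn_sd_weeks`, Gaussian, default 0);
- deterministic cohort replacement: the outgoing cohort is present
  through its twelfth month (so the spawn month is the one bimodal
  month, split evenly between outgoing and incoming cohorts) and gone
  the month after;
- saturating growth h(a) = s₀ + (A − s₀)(1 − e^(−k a)) with
  settlement size s₀ = 0.3 mm, asymptote A = 6.4 mm and rate
  k = 0.25/month, calibrated once so the maximum generated shell
  height over a large census falls near the ~6.2 mm maximum observed
  in both recent and archaeological material;
- lognormal between-individual variation of the growth rate
  (CV = 0.18), which makes SFD dispersion grow from early summer into
  fall and winter;
- measurement: Gaussian noise (sd 0.05 mm) and rounding to the 0.02 mm
  caliper precision;
- harvest scenarios: each specimen draws an accumulation year (uniform
  over `n_years`), a month within the true window (uniform by
  default), and a size from the cohort alive then; per-year spawn and
  growth-rate fluctuations are shared coherently across specimens of
  the same year. The true scenario travels in the sample's provenance
  string and is never read by the estimator.

All draws come from substreams keyed on (seed, year, month), so a
one-month single-year harvest is bit-identical to the corresponding
monthly survey under the same seed — the consistency contract the
tests assert exactly.

The reference fixture mirrors the two-year monthly census design
(24 consecutive surveys, July through June two years later) pooled
across years; 100 specimens per survey is the study-scale default in
the acceptance runs, 25–30 in unit tests.

What the generator does **not** emulate: recruitment-pulse abundance
(monthly sample sizes are constant, so the fraction of sub-1.6 mm
specimens is smaller than real spring surveys show), background
mortality within a cohort, growth seasonality beyond the saturating
curve, spatial structure of infestation, and taphonomic size bias.
Passing recovery tests therefore demonstrate that the estimator works
when its demographic assumptions hold, not that real assemblages meet
those assumptions.

## Problem sizes and expected behaviour

The acceptance computations run at n = 250 specimens, B = 300
replicates on a 100-per-survey synthetic library. Under those
conditions about 98% of the 133 null models are modally self-matching;
20/20 simulated December–March harvests are recovered with overlapping
windows; summer-only month sets score below the best estimate in every
run; and a one-month December harvest time-averaged over 50 years with
~1 month of spawn jitter is estimated at a median duration of ~3
months — the duration-inflation mechanism that cautions against
reading multi-month estimates from time-averaged deposits literally.

## Known limitations

- The estimator assumes the recent reference populations and the
  archaeological populations share growth and spawning schedules;
  violations bias estimates in ways the package cannot detect.
- Similarity profiles depend on B through the presence threshold of
  the Jaccard/Sørensen indices (any count ≥ 1); B is therefore
  recorded in every output.
- The published archaeological estimates themselves (e.g. a
  December–March window for one excavation-unit sample) require the
  externally distributed measurement data; the package reproduces the
  machinery and its behaviour on synthetic truth, and reanalyses the
  published pairwise-test table, but does not ship those measurements.
- Month-set #52 is April–August under the duration-major numbering
  used here; one published figure caption labels it March–July. The
  worked numbering examples (#1, #34, #59) are treated as normative.
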