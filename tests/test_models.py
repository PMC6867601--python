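import numpy as np
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis

from odoseason import (
    MatchDistribution,
    MonthSet,
    N_MONTH_SETS,
    SizeSample,
    best_match,
    build_null_model,
    build_null_suite,
    build_reference_library,
    discontinuous_variants,
    estimate_harvest,
    evaluate_month_combination,
    ks_distance,
    month_set_from_index,
    sample_match_model,
    similarity,
)


def dist(counts, n=10, origin="test"):
    counts = np.asarray(counts)
    full = np.zeros(N_MONTH_SETS, dtype=int)
    full[: counts.size] = counts
    return MatchDistribution(counts=full, B=int(full.sum()), n=n, origin=origin)


class TestSimilarity:
    def test_identical_distributions_are_unit_similar(self):
        p = dist([3, 2, 1])
        for method in ("jaccard", "sorensen", "bray_curtis"):
            assert similarity(p, p, method) == pytest.approx(1.0)

    def test_disjoint_supports_are_zero_similar(self):
        p, q = dist([3, 0, 0]), dist([0, 2, 2])
        for method in ("jaccard", "sorensen", "bray_curtis"):
            assert similarity(p, q, method) == pytest.approx(0.0)

    def test_hand_evaluated_closed_forms(self):
        # presence (1,1,0) vs (1,1,1): |A∩B|=2, |A∪B|=3, |A|+|B|=5;
        # relative freqs (2/3,1/3,0) vs (1/4,1/4,1/2): Σ|p-q|=1, Σ(p+q)=2
        p, q = dist([2, 1, 0]), dist([1, 1, 2])
        assert similarity(p, q, "jaccard") == pytest.approx(2 / 3)
        assert similarity(p, q, "sorensen") == pytest.approx(4 / 5)
        assert similarity(p, q, "bray_curtis") == pytest.approx(0.5)

    def test_bray_curtis_matches_scipy_on_relative_frequencies(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = dist(rng.integers(0, 5, size=10) + 1)
            q = dist(rng.integers(0, 5, size=10) + 1)
            ours = similarity(p, q, "bray_curtis")
            theirs = 1.0 - scipy_braycurtis(p.relative, q.relative)
            assert ours == pytest.approx(theirs)

    def test_symmetry(self):
        p, q = dist([5, 0, 2, 1]), dist([1, 1, 0, 4])
        for method in ("jaccard", "sorensen", "bray_curtis"):
            assert similarity(p, q, method) == similarity(q, p, method)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            similarity(dist([1]), dist([1]), "euclidean")

    def test_all_zero_distribution_rejected(self):
        with pytest.raises(ValueError):
            MatchDistribution(
                counts=np.zeros(N_MONTH_SETS, dtype=int), B=0, n=1, origin="bad"
            )


class TestMatchDistribution:
    def test_counts_must_sum_to_b(self):
        counts = np.zeros(N_MONTH_SETS, dtype=int)
        counts[4] = 7
        with pytest.raises(ValueError):
            MatchDistribution(counts=counts, B=9, n=5, origin="bad")

    def test_modal_index_tie_breaks_low(self):
        counts = np.zeros(N_MONTH_SETS, dtype=int)
        counts[[9, 29]] = 5
        d = MatchDistribution(counts=counts, B=10, n=5, origin="tie")
        assert d.modal_index() == 10


class TestBestMatch:
    def test_exact_library_member_matches_itself(self, small_lib):
        s = small_lib.pooled[7]
        assert best_match(s, small_lib) == 7

    def test_identical_references_tie_break_to_one(self):
        base = SizeSample("m", [1.0, 2.0, 3.0])
        lib = build_reference_library({m: base for m in range(1, 13)})
        probe = SizeSample("probe", [1.0, 2.5])
        assert best_match(probe, lib) == 1

    def test_agrees_with_exhaustive_loop(self, small_lib):
        rng = np.random.default_rng(17)
        for _ in range(100):
            probe = SizeSample(
                "probe", rng.uniform(0.3, 6.4, size=rng.integers(5, 40))
            )
            expected = min(
                range(1, N_MONTH_SETS + 1),
                key=lambda i: (ks_distance(probe, small_lib.pooled[i]), i),
            )
            assert best_match(probe, small_lib) == expected


class TestNullModels:
    B = 50

    def test_counts_conserved(self, small_lib):
        model = build_null_model(34, small_lib, n=40, B=self.B, rng_seed=3)
        assert int(model.counts.sum()) == self.B == model.B

    def test_reproducible_and_isolated(self, small_lib):
        suite = build_null_suite(small_lib, n=40, B=self.B, rng_seed=3)
        assert len(suite.models) == N_MONTH_SETS
        alone = build_null_model(59, small_lib, n=40, B=self.B, rng_seed=3)
        assert np.array_equal(alone.counts, suite.models[59].counts)
        again = build_null_suite(small_lib, n=40, B=self.B, rng_seed=3)
        for i in (1, 59, 133):
            assert np.array_equal(suite.models[i].counts, again.models[i].counts)

    def test_different_seeds_differ(self, small_lib):
        a = build_null_model(12, small_lib, n=40, B=self.B, rng_seed=3)
        b = build_null_model(12, small_lib, n=40, B=self.B, rng_seed=4)
        assert not np.array_equal(a.counts, b.counts)

    def test_sample_model_concentrates_near_source(self, small_lib):
        s = small_lib.pooled[34]  # October-December
        model = sample_match_model(s, small_lib, B=200, rng_seed=5)
        assert int(model.counts.sum()) == 200
        modal = month_set_from_index(model.modal_index())
        assert modal.months & {10, 11, 12}


class TestEstimateHarvest:
    def test_best_attains_profile_max(self, small_lib):
        s = small_lib.pooled[27]
        est = estimate_harvest(s, small_lib, B=60, rng_seed=9)
        for method, prof in est.profiles.items():
            best = est.best[method]
            assert prof.value(best[0]) == prof.values.max()
            assert best == prof.best_indices()
            assert prof.values.shape == (N_MONTH_SETS,)

    def test_recovers_source_window(self, small_lib):
        # a sample drawn exactly from the March-May reference should
        # estimate a window overlapping March-May
        s = small_lib.pooled[27]
        est = estimate_harvest(s, small_lib, B=60, rng_seed=9)
        for method in est.best:
            months = month_set_from_index(est.best[method][0]).months
            assert months & {3, 4, 5}


class TestDiscontinuousVariants:
    def test_dec_march_includes_dec_feb_mar(self):
        variants = discontinuous_variants(month_set_from_index(48))
        assert frozenset({12, 2, 3}) in {v.months for v in variants}

    def test_jan_april_includes_feb_apr(self):
        best = MonthSet(frozenset({1, 2, 3, 4}))
        assert frozenset({2, 4}) in {v.months for v in discontinuous_variants(best)}

    @pytest.mark.parametrize("index", [37, 40, 48])  # 4-month windows
    def test_four_month_window_has_five_variants(self, index):
        variants = discontinuous_variants(month_set_from_index(index))
        assert len(variants) == 5
        for v in variants:
            assert not v.contiguous and v.duration >= 2
            assert v.months < month_set_from_index(index).months

    def test_counts_match_subset_enumeration(self):
        # 2^d - d - 1 subsets of size >= 2, minus d(d-1)/2 contiguous runs
        for d in (2, 3, 5, 6):
            best = month_set_from_index((d - 1) * 12 + 1)
            expected = (2**d - d - 1) - d * (d - 1) // 2
            assert len(discontinuous_variants(best)) == expected

    def test_short_windows_have_none(self):
        assert discontinuous_variants(month_set_from_index(13)) == []


class TestEvaluateMonthCombination:
    def test_contiguous_reproduces_profile_entry(self, small_lib):
        s = small_lib.pooled[40]
        est = estimate_harvest(s, small_lib, B=60, methods=("bray_curtis",), rng_seed=21)
        value = evaluate_month_combination(
            month_set_from_index(48), s, small_lib, 60, "bray_curtis", 21
        )
        assert value == pytest.approx(est.profiles["bray_curtis"].value(48))

    def test_full_year_equals_entry_133(self, small_lib):
        s = small_lib.pooled[40]
        est = estimate_harvest(s, small_lib, B=60, methods=("jaccard",), rng_seed=21)
        value = evaluate_month_combination(
            month_set_from_index(133), s, small_lib, 60, "jaccard", 21
        )
        assert value == pytest.approx(est.profiles["jaccard"].value(133))

    def test_gapped_combination_deterministic(self, small_lib):
        s = small_lib.pooled[48]
        gapped = MonthSet(frozenset({12, 2, 3}))
        a = evaluate_month_combination(gapped, s, small_lib, 60, "bray_curtis", 21)
        b = evaluate_month_combination(gapped, s, small_lib, 60, "bray_curtis", 21)
        assert a == b and 0.0 <= a <= 1.0

    def test_missing_month_rejected(self, small_lib):
        incomplete = {m: s for m, s in small_lib.monthly.items()}
        s = small_lib.pooled[1]
        lib2 = build_reference_library(incomplete)
        lib2.monthly.pop(4)
        with pytest.raises(ValueError):
            evaluate_month_combination(
                MonthSet(frozenset({4, 6})), s, lib2, 20, "jaccard", 0
            )
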