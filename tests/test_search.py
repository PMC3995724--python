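import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuescope import (
    CandidateSubset,
    LossConfig,
    SyntheticSpec,
    candidate_tissues,
    correlation_profile,
    extend_to_organs,
    generate,
    loss,
    parse_sample_id,
    rank_tissues,
    sample_subsets,
    search_best_subset,
    search_over_k,
)
from tissuescope.search import RankEntry, SubsetSearchResult, TissueRanking

from conftest import make_matrix


def brute_force_best(mirna_id, targets, mirna_matrix, mrna_matrix, k, a, candidates):
    """Independent oracle: enumerate every k-subset via the scalar path."""
    best = None
    for combo in itertools.combinations(sorted(candidates), k):
        profile = correlation_profile(mirna_id, targets, mirna_matrix, mrna_matrix, CandidateSubset(combo))
        value = loss(profile, a)
        key = (value, tuple(sorted(combo)))
        if best is None or key < best:
            best = key
    return best


class TestCandidateTissues:
    def test_all_above_cutoff(self, small_sample_ids):
        matrix = make_matrix(["mir-x"], small_sample_ids, np.full((1, 6), 9.0))
        assert candidate_tissues("mir-x", matrix, 7.25) == small_sample_ids

    def test_strict_cutoff(self, small_sample_ids):
        values = np.array([[7.25, 8.0, 7.0, 9.0, 7.26, 6.0]])
        matrix = make_matrix(["mir-x"], small_sample_ids, values)
        assert candidate_tissues("mir-x", matrix, 7.25) == [
            small_sample_ids[1], small_sample_ids[3], small_sample_ids[4]
        ]

    def test_too_few_candidates_error(self, small_sample_ids):
        values = np.array([[9.0, 9.0, 5.0, 5.0, 5.0, 5.0]])
        matrix = make_matrix(["mir-x"], small_sample_ids, values)
        with pytest.raises(ValueError, match="above cutoff"):
            candidate_tissues("mir-x", matrix, 7.25, k_min=3)


class TestSampleSubsets:
    def test_exhaustive_enumerates_all_combinations(self, small_sample_ids):
        subsets = list(sample_subsets(small_sample_ids, 3, M=10, seed=0, mode="exhaustive"))
        assert len(subsets) == math.comb(6, 3)
        assert len(set(s.sample_ids for s in subsets)) == math.comb(6, 3)

    @pytest.mark.parametrize("mode", ["random", "exhaustive", "auto"])
    def test_full_set_when_k_equals_n(self, small_sample_ids, mode):
        subsets = list(sample_subsets(small_sample_ids, 6, M=3, seed=0, mode=mode))
        assert all(s.sample_ids == tuple(sorted(small_sample_ids)) for s in subsets)

    def test_same_seed_identical_stream(self, small_sample_ids):
        a = [s.sample_ids for s in sample_subsets(small_sample_ids, 3, M=50, seed=9, mode="random")]
        b = [s.sample_ids for s in sample_subsets(small_sample_ids, 3, M=50, seed=9, mode="random")]
        assert a == b

    def test_nested_streams_share_prefix(self, small_sample_ids):
        short = [s.sample_ids for s in sample_subsets(small_sample_ids, 3, M=20, seed=9, mode="random")]
        long = [s.sample_ids for s in sample_subsets(small_sample_ids, 3, M=200, seed=9, mode="random")]
        assert long[:20] == short

    def test_random_draws_are_uniform_over_combinations(self):
        # chi-square over all C(5,2)=10 subsets at M=2000
        ids = ["T_colon_1", "T_colon_2", "T_colon_3", "N_colon_1", "N_colon_2"]
        draws = [s.sample_ids for s in sample_subsets(ids, 2, M=2000, seed=1, mode="random")]
        from collections import Counter

        counts = Counter(draws)
        assert set(counts) == set(tuple(sorted(c)) for c in itertools.combinations(ids, 2))
        chi2 = sum((c - 200) ** 2 / 200 for c in counts.values())
        # df=9, 99.9% quantile ~ 27.9
        assert chi2 < 27.9

    def test_seeded_mode_includes_seed_tissues(self, small_sample_ids):
        seeds = small_sample_ids[:2]
        for subset in sample_subsets(small_sample_ids, 4, M=30, seed=3, mode="seeded", seed_tissues=seeds):
            assert set(seeds) <= set(subset.sample_ids)

    def test_seed_tissues_outside_universe_error(self, small_sample_ids):
        with pytest.raises(ValueError, match="not in candidate universe"):
            list(sample_subsets(small_sample_ids, 3, M=5, seed=0, mode="seeded", seed_tissues=["T_liver_1"]))

    def test_k_larger_than_universe_error(self, small_sample_ids):
        with pytest.raises(ValueError):
            list(sample_subsets(small_sample_ids, 7, M=5, seed=0, mode="random"))


class TestSearchBestSubset:
    def test_exhaustive_recovers_constructed_planted_subset(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, planted = planted_instance
        config = LossConfig(a=0.4, M=10, k_min=3, k_max=4, rng_seed=0)
        result = search_best_subset(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 4, config,
            mode="exhaustive", candidates=mirna_matrix.sample_ids,
        )
        assert result.best_subset.sample_ids == tuple(sorted(planted))
        assert result.best_loss == pytest.approx(-0.4)  # lower bound -a attained
        assert result.n_evaluated == math.comb(8, 4)
        # oracle confirms it is the unique minimizer
        oracle_loss, oracle_ids = brute_force_best(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 4, 0.4, mirna_matrix.sample_ids
        )
        assert oracle_ids == result.best_subset.sample_ids
        assert result.best_loss == pytest.approx(oracle_loss)

    def test_agrees_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(21)
        for trial in range(4):
            spec = SyntheticSpec(
                n_tissues=9, n_mirnas=1, targets_per_mirna=5, planted_subset_size=4,
                beta=1.5, noise_sd=0.6, seed=int(rng.integers(2**31)),
            )
            mirna_matrix, mrna_matrix, catalog, _ = generate(spec)
            config = LossConfig(a=0.4, M=10_000, k_min=3, k_max=4, rng_seed=trial)
            result = search_best_subset(
                "syn-mir-1", catalog.targets("syn-mir-1"), mirna_matrix, mrna_matrix, 4, config,
                mode="exhaustive", candidates=mirna_matrix.sample_ids,
            )
            oracle_loss, oracle_ids = brute_force_best(
                "syn-mir-1", catalog.targets("syn-mir-1"), mirna_matrix, mrna_matrix, 4, 0.4,
                mirna_matrix.sample_ids,
            )
            assert result.best_subset.sample_ids == oracle_ids
            assert result.best_loss == pytest.approx(oracle_loss, abs=1e-12)

    def test_random_with_full_coverage_equals_exhaustive(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, _ = planted_instance
        config = LossConfig(a=0.4, M=5000, k_min=3, k_max=4, rng_seed=1)
        random_result = search_best_subset(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 4, config,
            mode="random", candidates=mirna_matrix.sample_ids,
        )
        exhaustive_result = search_best_subset(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 4, config,
            mode="exhaustive", candidates=mirna_matrix.sample_ids,
        )
        assert random_result.best_subset == exhaustive_result.best_subset
        assert random_result.n_evaluated == 5000

    def test_auto_switches_to_exhaustive_when_feasible(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, _ = planted_instance
        config = LossConfig(a=0.4, M=100, k_min=3, k_max=4, rng_seed=0)
        result = search_best_subset(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 4, config,
            candidates=mirna_matrix.sample_ids,
        )
        assert result.mode == "exhaustive" and result.n_evaluated == 70

    def test_k_equals_universe(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, _ = planted_instance
        config = LossConfig(a=0.4, M=10, k_min=3, k_max=8, rng_seed=0)
        result = search_best_subset(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 8, config,
            candidates=mirna_matrix.sample_ids,
        )
        assert result.best_subset.sample_ids == tuple(sorted(mirna_matrix.sample_ids))
        profile = correlation_profile(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, result.best_subset
        )
        assert result.best_loss == pytest.approx(loss(profile, 0.4))

    def test_determinism_bit_identical(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, _ = planted_instance
        config = LossConfig(a=0.4, M=300, k_min=3, k_max=5, rng_seed=13)
        runs = [
            search_best_subset(
                "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 5, config,
                mode="random", candidates=mirna_matrix.sample_ids,
            )
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_best_loss_non_increasing_in_M(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, _ = planted_instance
        losses = []
        for M in (10, 40, 160, 640):
            config = LossConfig(a=0.4, M=M, k_min=3, k_max=5, rng_seed=99)
            result = search_best_subset(
                "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 5, config,
                mode="random", candidates=mirna_matrix.sample_ids,
            )
            losses.append(result.best_loss)
        assert all(b <= a + 1e-15 for a, b in zip(losses, losses[1:]))

    def test_coupon_collector_hit_rate(self):
        # C(8,3) = 56 <= 10,000; random mode with M = 3 C ln C finds the
        # exhaustive optimum in >= 95% of seeds
        spec = SyntheticSpec(n_tissues=8, n_mirnas=1, targets_per_mirna=4, planted_subset_size=3,
                             beta=1.5, noise_sd=0.5, seed=77)
        mirna_matrix, mrna_matrix, catalog, _ = generate(spec)
        targets = catalog.targets("syn-mir-1")
        C = math.comb(8, 3)
        M = int(3 * C * math.log(C))
        exhaustive = search_best_subset(
            "syn-mir-1", targets, mirna_matrix, mrna_matrix, 3,
            LossConfig(a=0.4, M=M, k_min=3, k_max=3, rng_seed=0),
            mode="exhaustive", candidates=mirna_matrix.sample_ids,
        )
        hits = 0
        for seed in range(100):
            config = LossConfig(a=0.4, M=M, k_min=3, k_max=3, rng_seed=seed)
            result = search_best_subset(
                "syn-mir-1", targets, mirna_matrix, mrna_matrix, 3, config,
                mode="random", candidates=mirna_matrix.sample_ids,
            )
            hits += result.best_subset == exhaustive.best_subset
        assert hits >= 95


class TestSearchOverK:
    def test_returns_one_result_per_k_and_global_best(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, planted = planted_instance
        config = LossConfig(a=0.4, M=500, k_min=3, k_max=6, rng_seed=2)
        results, best = search_over_k(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, config,
            candidates=mirna_matrix.sample_ids,
        )
        assert [r.k for r in results] == [3, 4, 5, 6]
        assert best.best_loss == min(r.best_loss for r in results)

    def test_k_min_equals_k_max_matches_single_search(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, _ = planted_instance
        config = LossConfig(a=0.4, M=500, k_min=4, k_max=4, rng_seed=5)
        results, best = search_over_k(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, config,
            candidates=mirna_matrix.sample_ids,
        )
        assert len(results) == 1 and best == results[0]
        single = search_best_subset(
            "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, 4, config,
            candidates=mirna_matrix.sample_ids,
        )
        assert best.best_subset == single.best_subset

    def test_k_max_beyond_universe_error(self, planted_instance):
        mirna_matrix, mrna_matrix, catalog, _ = planted_instance
        config = LossConfig(a=0.4, M=10, k_min=3, k_max=9, rng_seed=0)
        with pytest.raises(ValueError, match="k_max"):
            search_over_k(
                "mir-x", catalog.targets("mir-x"), mirna_matrix, mrna_matrix, config,
                candidates=mirna_matrix.sample_ids,
            )


def dummy_result(sample_ids, k=None):
    subset = CandidateSubset(sample_ids)
    profile_stub = None
    return SubsetSearchResult(
        mirna_id="mir-x", k=k or subset.n_A, best_subset=subset, best_loss=0.0,
        profile=profile_stub, n_evaluated=1, mode="exhaustive",
    )


class TestRankTissues:
    def test_hand_count_with_ties(self):
        results = [
            dummy_result(["T_colon_1", "T_colon_2"]),
            dummy_result(["T_colon_1", "N_colon_1"]),
            dummy_result(["T_colon_1", "T_colon_2", "T_lung_1"]),
        ]
        ranking = rank_tissues(results)
        assert [(e.sample_id, e.occurrence_count, e.rank) for e in ranking.entries] == [
            ("T_colon_1", 3, 1),
            ("T_colon_2", 2, 2),
            ("N_colon_1", 1, 3),
            ("T_lung_1", 1, 4),
        ]

    def test_single_result_all_counts_one(self):
        ranking = rank_tissues([dummy_result(["T_colon_1", "T_lung_1"])])
        assert all(e.occurrence_count == 1 for e in ranking.entries)

    @given(
        subsets=st.lists(
            st.sets(
                st.sampled_from([f"T_colon_{i}" for i in range(1, 9)]), min_size=2, max_size=6
            ),
            min_size=1,
            max_size=10,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_count_conservation_and_deterministic_order(self, subsets):
        results = [dummy_result(sorted(s)) for s in subsets]
        ranking = rank_tissues(results)
        assert sum(e.occurrence_count for e in ranking.entries) == sum(len(s) for s in subsets)
        counts = [e.occurrence_count for e in ranking.entries]
        assert counts == sorted(counts, reverse=True)
        ids = [e.sample_id for e in ranking.entries]
        # equal counts ordered lexicographically; ranks are 1..n
        for e1, e2 in zip(ranking.entries, ranking.entries[1:]):
            if e1.occurrence_count == e2.occurrence_count:
                assert e1.sample_id < e2.sample_id
        assert [e.rank for e in ranking.entries] == list(range(1, len(ids) + 1))
        assert rank_tissues(results) == ranking


class TestExtendToOrgans:
    @pytest.fixture
    def annotated(self):
        sample_ids = [
            "T_prostate_1", "T_prostate_2", "T_breast_1", "T_breast_2",
            "N_breast_1", "T_uterus_1", "N_uterus_1", "T_colon_1",
        ]
        values = np.array([[9.0, 9.0, 9.0, 6.0, 9.0, 9.0, 9.0, 9.0]])
        matrix = make_matrix(["mir-x"], sample_ids, values)
        return matrix, [parse_sample_id(s) for s in sample_ids]

    def test_extends_to_organ_status_classes_then_filters(self, annotated):
        matrix, samples = annotated
        selected = CandidateSubset(["T_prostate_1", "T_breast_1"])
        extended = extend_to_organs(selected, samples, "mir-x", matrix, cutoff=7.25)
        # classes: (prostate, tumor) and (breast, tumor); T_breast_2 dropped (6.0 < 7.25)
        assert extended.sample_ids == ("T_breast_1", "T_prostate_1", "T_prostate_2")

    def test_cutoff_minus_infinity_keeps_whole_classes(self, annotated):
        matrix, samples = annotated
        selected = CandidateSubset(["T_prostate_1", "T_breast_1", "N_breast_1",
                                    "T_uterus_1", "N_uterus_1", "T_colon_1"])
        extended = extend_to_organs(selected, samples, "mir-x", matrix, cutoff=-np.inf)
        assert set(extended.sample_ids) == {s.sample_id for s in samples}

    def test_fixed_point_when_selected_covers_classes(self, annotated):
        matrix, samples = annotated
        selected = CandidateSubset(["T_prostate_1", "T_prostate_2"])
        assert extend_to_organs(selected, samples, "mir-x", matrix, cutoff=7.25) == selected

    def test_empty_extension_error(self, annotated):
        matrix, samples = annotated
        low = make_matrix(["mir-x"], [s.sample_id for s in samples], np.full((1, 8), 5.0))
        selected = CandidateSubset(["T_prostate_1", "T_prostate_2"])
        with pytest.raises(ValueError, match="above cutoff"):
            extend_to_organs(selected, samples, "mir-x", low, cutoff=7.25)
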