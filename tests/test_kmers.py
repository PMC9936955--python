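"""K-mer selection: FPR model, alignment/DTW kernels, filters, evolution."""

import itertools

import numpy as np
import pytest

from sigmer.kmers import (
    FprConfig,
    LibraryDesignConfig,
    abundance_percentile_filter,
    check_library_constraints,
    choose_k,
    dtw_distance,
    evolve_kmer_library,
    expected_hits,
    expected_occurrences,
    false_positive_rate,
    fpr_table,
    p_at_least_one,
    passes_homopolymer_filter,
    select_discriminative_kmers,
    smith_waterman,
)
from sigmer.seqio import InputError, KmerProfile
from sigmer.sim import make_pore_model, random_sequence


class TestFprModel:
    def test_expected_occurrences_printed_value(self):
        assert expected_occurrences(30_000, 8) == pytest.approx(0.91552734375, abs=1e-12)

    def test_expected_occurrences_quarter_per_k(self):
        for L in (0, 1_000, 30_000):
            assert expected_occurrences(L, 9) == pytest.approx(expected_occurrences(L, 8) / 4)

    def test_p_at_least_one_closed_form_and_limits(self):
        assert p_at_least_one(0, 8) == 0.0
        assert p_at_least_one(30_000, 8) == pytest.approx(1 - np.exp(-0.91552734375))
        grid = [p_at_least_one(L, 8) for L in (10, 100, 1_000, 10_000, 10**5)]
        assert all(b > a for a, b in zip(grid, grid[1:]))
        assert 0.95 < grid[-1] < 1.0

    def test_expected_hits_linear_in_library(self):
        assert expected_hits(1_500, 8, 0) == 0.0
        assert expected_hits(1_500, 8, 300) == pytest.approx(3 * expected_hits(1_500, 8, 100))
        assert expected_hits(1_500, 8, 1_500) == pytest.approx(
            1_500 * (1 - np.exp(-1_500 * 2 * 4.0 ** -8))
        )

    def test_fpr_edge_cases(self):
        assert false_positive_rate(FprConfig(8, 30_000, 1_500, 0)) == 1.0
        assert false_positive_rate(FprConfig(8, 0, 1_500, 1_500)) == 0.0

    def test_fpr_decreasing_in_target_length(self):
        fprs = [
            false_positive_rate(FprConfig(8, 30_000, lt, 1_500))
            for lt in (300, 600, 1_500, 30_000)
        ]
        assert all(b < a for a, b in zip(fprs, fprs[1:]))

    def test_k8_k9_beat_k6_on_representative_grid(self):
        table = fpr_table([6, 8, 9]).set_index(["k", "L_read", "L_target"])["fpr"]
        for lr in (30_000, 50_000):
            for lt in (600, 1_500, 30_000):
                assert table[8, lr, lt] <= table[6, lr, lt]
                assert table[9, lr, lt] <= table[6, lr, lt]

    def test_choose_k(self):
        assert choose_k([7])[0] == 7
        best, table = choose_k(range(5, 11))
        assert best in (8, 9)
        assert ((table["fpr"] >= 0) & (table["fpr"] <= 1)).all()

    def test_invalid_config(self):
        with pytest.raises(InputError):
            FprConfig(0, 100, 100, 10)


def sw_oracle(a, b, match=1, mismatch=-1, gap=-4):
    """Independent Smith-Waterman oracle via Biopython's aligner."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    score = aligner.score(a, b)
    return max(0, int(score))


class TestSmithWaterman:
    def test_perfect_match(self):
        assert smith_waterman("ACGTACGT", "ACGTACGT") == 8

    def test_no_positive_alignment(self):
        assert smith_waterman("AAAAAAAA", "CCCCCCCC") == 0

    def test_near_match_agrees_with_oracle(self):
        a, b = "ACGTACGT", "ACGTTCGT"
        assert smith_waterman(a, b) == sw_oracle(a, b)

    def test_random_pairs_match_oracle_and_symmetry(self):
        rng = np.random.default_rng(5)
        kmers = ["".join("ACGT"[c] for c in rng.integers(0, 4, 6)) for _ in range(40)]
        for a, b in itertools.combinations(kmers, 2):
            s = smith_waterman(a, b)
            assert s == sw_oracle(a, b)
            assert s == smith_waterman(b, a)


def dtw_recursive(s1, s2):
    """Reference implementation by direct recursion."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return float("inf")
        cost = (s1[i - 1] - s2[j - 1]) ** 2
        return cost + min(d(i - 1, j), d(i, j - 1), d(i - 1, j - 1))

    return d(len(s1), len(s2))


class TestDtw:
    def test_identical_is_zero(self):
        assert dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset_hand_value(self):
        assert dtw_distance([0, 0, 0], [2, 2, 2]) == pytest.approx(12.0)

    def test_matches_recursive_reference(self, rng):
        for _ in range(100):
            n, m = rng.integers(1, 9, 2)
            a = tuple(rng.normal(size=n).round(3))
            b = tuple(rng.normal(size=m).round(3))
            assert dtw_distance(a, b) == pytest.approx(dtw_recursive(a, b))
            assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            dtw_distance([], [1.0])


class TestHomopolymerFilter:
    @pytest.mark.parametrize(
        "kmer,ok",
        [
            ("GGGGACGT", False),  # 4 G in a row
            ("AAAAACGT", False),  # 5 A in a row
            ("AAAACGTC", True),   # 4 A allowed
            ("CCCTAGGG", True),   # runs of 3 allowed
            ("ACGTACGT", True),
            ("TTTTTACG", False),
        ],
    )
    def test_single_base_rule(self, kmer, ok):
        assert passes_homopolymer_filter(kmer) is ok

    def test_combined_group_switch(self):
        # GCGC has a {G,C}-group run of 4 but no single-base run over 1
        assert passes_homopolymer_filter("GCGCACGT")
        assert not passes_homopolymer_filter("GCGCACGT", combine_groups=True)


class TestPercentileFilter:
    def test_all_equal_retained(self):
        cands = ["AC", "GT", "CA"]
        kept = abundance_percentile_filter(cands, [], counts={m: 3 for m in cands})
        assert kept == cands

    def test_outer_deciles_dropped(self):
        cands = [f"k{i}" for i in range(100)]
        counts = {m: i for i, m in enumerate(cands)}
        kept = abundance_percentile_filter(cands, [], counts=counts)
        assert len(kept) == 80
        assert kept[0] == "k10" and kept[-1] == "k89"

    def test_absent_candidate_dropped(self):
        cands = [f"k{i}" for i in range(100)]
        counts = {m: i + 5 for i, m in enumerate(cands)}
        counts["k0"] = 0  # unique minimum, below the 10th percentile
        assert "k0" not in abundance_percentile_filter(cands, [], counts=counts)

    def test_one_sided_mode_keeps_rare(self):
        cands = [f"k{i}" for i in range(100)]
        counts = {m: i for i, m in enumerate(cands)}
        kept = abundance_percentile_filter(cands, [], counts=counts, two_sided=False)
        assert "k0" in kept and "k99" not in kept


class TestDiscriminativeSelection:
    def _profiles(self, t_counts, b_counts_list, k=2):
        target = KmerProfile(k, dict(t_counts), canonical=False, source_label="t")
        bgs = [KmerProfile(k, dict(b), canonical=False) for b in b_counts_list]
        return target, bgs

    def test_private_kmer_ranks_first(self):
        t, bgs = self._profiles(
            {"AA": 50, "AC": 10, "AG": 10},
            [{"AC": 10, "AG": 10}, {"AC": 11, "AG": 9}],
        )
        assert select_discriminative_kmers(t, bgs, 1) == ["AA"]

    def test_absent_only_from_target_selected(self):
        t, bgs = self._profiles(
            {"AC": 10, "AG": 10},
            [{"AA": 50, "AC": 10, "AG": 10}, {"AA": 48, "AC": 10, "AG": 10}],
        )
        assert "AA" in select_discriminative_kmers(t, bgs, 2)

    def test_no_signal_gives_deterministic_order(self):
        t, bgs = self._profiles({"AA": 5, "AC": 5}, [{"AA": 5, "AC": 5}])
        first = select_discriminative_kmers(t, bgs, 2)
        assert first == select_discriminative_kmers(t, bgs, 2) == ["AA", "AC"]

    def test_size_errors(self):
        t, bgs = self._profiles({"AA": 1}, [{"AA": 1}])
        with pytest.raises(InputError):
            select_discriminative_kmers(t, bgs, 5)


class TestEvolveLibrary:
    @pytest.fixture(scope="class")
    def small_result(self):
        pore = make_pore_model(seed=2, model_k=4)
        refs = [random_sequence(1_000, 100 + i) for i in range(10)]
        cfg = LibraryDesignConfig(n_kmers=6, k=8, seed=3)
        return cfg, pore, refs, evolve_kmer_library(cfg, pore, refs)

    def test_output_satisfies_hard_constraints(self, small_result):
        cfg, pore, refs, result = small_result
        assert result.feasible and len(result.kmers) == 6
        audit = check_library_constraints(result.kmers, cfg, refs, result.percentile_bounds)
        assert audit["sw_ok"].all()
        assert audit["homopolymer_ok"].all()
        assert audit["percentile_ok"].all()

    def test_mean_pairwise_dtw_non_decreasing(self, small_result):
        *_, result = small_result
        trace = result.dtw_trace
        assert len(trace) == 11  # init + 10 rounds
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_deterministic(self, small_result):
        cfg, pore, refs, result = small_result
        again = evolve_kmer_library(cfg, pore, refs)
        assert again.kmers == result.kmers

    def test_mutation_schedule_validation(self):
        with pytest.raises(InputError):
            LibraryDesignConfig(mutation_schedule=(5, 5, 4), rounds=10)
        with pytest.raises(InputError):
            LibraryDesignConfig(mutation_schedule=(1,) * 9 + (5,), rounds=10)

    def test_infeasible_n_kmers(self):
        pore = make_pore_model(seed=2, model_k=4)
        cfg = LibraryDesignConfig(n_kmers=300, k=4, seed=1)
        with pytest.raises(InputError):
            evolve_kmer_library(cfg, pore, ["ACGT" * 50])
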