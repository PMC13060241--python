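import numpy as np
import pytest

from bcar.aligner import (
    MATCH,
    DELETE,
    INSERT,
    AlignParams,
    align_pair,
    match_score,
    merge_aligned,
    order_by_consensus_similarity,
    progressive_align,
    score_path,
)
from bcar.consensus import call_consensus
from bcar.evidence import merge_without_alignment, read_to_evidence

from helpers import (
    brute_force_align_score,
    enumerate_paths_score,
    make_read,
    random_read,
    single_read_unit_vectors,
)

UNBANDED = AlignParams(band_width=1000)


class TestMatchScore:
    def test_identical_columns_score_smax(self):
        col = read_to_evidence(make_read("A", 40)).column(0)
        assert match_score(col, col, AlignParams()) == pytest.approx(1.0)

    def test_identical_low_q_columns_still_parallel(self):
        col = read_to_evidence(make_read("A", 10)).column(0)
        assert match_score(col, col, AlignParams()) == pytest.approx(1.0)

    def test_confident_conflict_scores_near_smin(self):
        a = read_to_evidence(make_read("A", 90)).column(0)
        c = read_to_evidence(make_read("C", 90)).column(0)
        assert match_score(a, c, AlignParams()) == pytest.approx(-1.0, abs=1e-4)


class TestAlignPair:
    def test_identity_alignment(self):
        arr = read_to_evidence(make_read("ACGTACGTAC", 40))
        path = align_pair(arr, arr)
        assert (path.codes == MATCH).all()
        assert path.score == pytest.approx(10.0)

    def test_single_deletion_placed_correctly(self):
        a = read_to_evidence(make_read("ACGT", 40))
        b = read_to_evidence(make_read("AGT", 40))
        path = align_pair(a, b, UNBANDED)
        steps = list(path.steps())
        deletes = [s for s in steps if s[0] == DELETE]
        assert deletes == [(DELETE, 1, None)]  # the 'C' column
        assert path.score == pytest.approx(
            brute_force_align_score(single_read_unit_vectors(make_read("ACGT", 40)),
                                    single_read_unit_vectors(make_read("AGT", 40))),
            abs=1e-9)

    def test_dp_equals_path_enumeration_small_pairs(self, rng):
        """Unbanded DP == exhaustive global path enumeration (lengths <= 8)."""
        for _ in range(80):
            ra = random_read(rng, int(rng.integers(1, 9)))
            rb = random_read(rng, int(rng.integers(1, 9)))
            got = align_pair(read_to_evidence(ra), read_to_evidence(rb),
                             UNBANDED).score
            want = brute_force_align_score(single_read_unit_vectors(ra),
                                           single_read_unit_vectors(rb))
            assert got == pytest.approx(want, abs=1e-9)

    def test_memoized_oracle_agrees_with_literal_enumeration(self, rng):
        for _ in range(20):
            ua = single_read_unit_vectors(random_read(rng, int(rng.integers(1, 5))))
            ub = single_read_unit_vectors(random_read(rng, int(rng.integers(1, 5))))
            assert brute_force_align_score(ua, ub) == pytest.approx(
                enumerate_paths_score(ua, ub), abs=1e-12)

    def test_banded_equals_unbanded_for_small_length_differences(self, rng):
        for _ in range(20):
            L = int(rng.integers(40, 80))
            ra = random_read(rng, L)
            rb = random_read(rng, L + int(rng.integers(-3, 4)))
            a, b = read_to_evidence(ra), read_to_evidence(rb)
            banded = align_pair(a, b, AlignParams(band_width=16)).score
            full = align_pair(a, b, AlignParams(band_width=200)).score
            assert banded == pytest.approx(full, abs=1e-9)

    def test_score_symmetric_under_swap(self, rng):
        for _ in range(10):
            a = read_to_evidence(random_read(rng, int(rng.integers(5, 30))))
            b = read_to_evidence(random_read(rng, int(rng.integers(5, 30))))
            assert align_pair(a, b, UNBANDED).score == pytest.approx(
                align_pair(b, a, UNBANDED).score, abs=1e-9)

    def test_path_indices_monotonic_and_score_reproducible(self, rng):
        a = read_to_evidence(random_read(rng, 30))
        b = read_to_evidence(random_read(rng, 27))
        path = align_pair(a, b, UNBANDED)
        i_seen = j_seen = -1
        for op, i, j in path.steps():
            if i is not None:
                assert i == i_seen + 1
                i_seen = i
            if j is not None:
                assert j == j_seen + 1
                j_seen = j
        assert (i_seen, j_seen) == (len(a) - 1, len(b) - 1)
        assert score_path(a, b, path, UNBANDED) == pytest.approx(path.score,
                                                                 abs=1e-9)

    def test_empty_array_rejected(self):
        arr = read_to_evidence(make_read("A", 30))
        import dataclasses
        empty = dataclasses.replace(arr, loglik=arr.loglik[:0],
                                    gap_count=arr.gap_count[:0],
                                    coverage=arr.coverage[:0])
        with pytest.raises(ValueError):
            align_pair(arr, empty)

    def test_free_end_gaps_do_not_penalize_truncation(self):
        a = read_to_evidence(make_read("ACGTACGT", 40))
        b = read_to_evidence(make_read("GTACGT", 40))  # missing 2-base prefix
        params = AlignParams(band_width=50, free_end_gaps=True)
        path = align_pair(a, b, params)
        assert path.score == pytest.approx(6.0)  # 6 matches, free leading gap
        assert score_path(a, b, path, params) == pytest.approx(6.0)


class TestMergeAligned:
    def test_identical_arrays(self):
        a = read_to_evidence(make_read("ACGT", 40))
        path = align_pair(a, a)
        merged = merge_aligned(a, a, path)
        assert len(merged) == 4
        assert (merged.coverage == 2).all()
        assert (merged.gap_count == 0).all()
        assert merged.n_reads == 2

    def test_interior_deletion_gap_evidence(self):
        a = read_to_evidence(make_read("ACGT", 40))
        b = read_to_evidence(make_read("AGT", 40))
        merged = merge_aligned(a, b, align_pair(a, b, UNBANDED))
        assert len(merged) == 4
        assert list(merged.gap_count) == [0, 1, 0, 0]
        assert list(merged.coverage) == [2, 2, 2, 2]

    def test_overhang_contributes_nothing(self):
        a = read_to_evidence(make_read("ACGTAC", 40))
        b = read_to_evidence(make_read("ACGT", 40))
        merged = merge_aligned(a, b, align_pair(a, b, UNBANDED))
        # b never observed the last two columns: no gap or coverage charge
        assert list(merged.coverage)[-2:] == [1, 1]
        assert list(merged.gap_count)[-2:] == [0, 0]

    def test_n_reads_additivity(self, rng):
        a = progressive_align([random_read(rng, 12, rid=f"r{i}") for i in range(3)])
        b = read_to_evidence(random_read(rng, 12))
        merged = merge_aligned(a, b, align_pair(a, b, UNBANDED))
        assert merged.n_reads == 4

    def test_invalid_path_rejected(self):
        from bcar.aligner import AlignmentPath
        a = read_to_evidence(make_read("ACGT", 40))
        b = read_to_evidence(make_read("AC", 40))
        bad = AlignmentPath(codes=np.array([0, 0], dtype=np.int8), score=0.0)
        with pytest.raises(ValueError):
            merge_aligned(a, b, bad)


class TestProgressiveAlign:
    def test_single_read_is_its_own_array(self):
        read = make_read("ACGTA", 33)
        arr = progressive_align([read])
        ref = read_to_evidence(read)
        assert np.allclose(arr.loglik, ref.loglik)
        assert arr.n_reads == 1

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_identical_reads_stack_cleanly(self, k):
        read = make_read("ACGTACGTACGTACGT", 35)
        arr = progressive_align([read] * k)
        assert (arr.coverage == k).all()
        assert (arr.gap_count == 0).all()
        rec = call_consensus(arr, "BC")
        assert rec.bases == read.bases

    def test_ordering_prefers_consensus_like_reads(self):
        good = make_read("ACGTACGTAC", 30, rid="good")
        outlier = make_read("TTTTTTTTTT", 30, rid="bad")
        short = make_read("ACG", 30, rid="short")  # < half consensus: last
        order = order_by_consensus_similarity([outlier, good, good, short])
        assert order[-1] == 3
        assert order[0] in (1, 2)

    def test_recovers_truth_from_indel_reads(self, rng):
        """10 reads of a 100-mer at 1% indel rate reconstruct the truth."""
        from bcar.simulate import SimConfig, _mutate
        from bcar.evidence import indices_to_seq
        failures = 0
        trials = 30
        for t in range(trials):
            true_idx = rng.integers(0, 4, 100).astype(np.int8)
            reads = []
            for k in range(10):
                mut, *_ = _mutate(true_idx, 0.0, 0.01, rng)
                reads.append(make_read(indices_to_seq(mut), 40, rid=f"r{k}"))
            rec = call_consensus(progressive_align(reads), "BC")
            if rec.bases != indices_to_seq(true_idx):
                failures += 1
        assert failures <= 1
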