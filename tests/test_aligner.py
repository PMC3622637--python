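"""Candidate collection, filtration, ranking, and sliding-window reuse."""

import bisect
import math
from collections import Counter

import numpy as np
import pytest

import permalign as pa
from permalign.aligner import FORWARD, REVERSE, default_stride
from permalign.index import ComparisonCounter


def naive_candidates(read, indexes, params):
    """Independent re-execution of the search on explicit permuted strings."""
    hits = Counter()
    strands = [(FORWARD, read)]
    if params.strand_mode == "both":
        strands.append((REVERSE, pa.reverse_complement(read)))
    for ix in indexes[: params.j]:
        keys = [ix.key(int(p)) for p in ix.order]
        for strand, seq in strands:
            q = ix.permutation.apply(seq)
            rank = bisect.bisect_left(keys, q)
            lo, hi = max(0, rank - params.k), min(len(keys), rank + params.k + 1)
            for p in ix.order[lo:hi]:
                hits[(int(p), strand)] += 1
    return hits


def plant_mismatches(seq, positions, rng):
    codes = list(seq)
    for pos in positions:
        old = codes[pos]
        codes[pos] = rng.choice([c for c in "ACGT" if c != old])
    return "".join(codes)


@pytest.fixture(scope="module")
def params():
    return pa.SearchParams(j=4, k=5, max_report=5)


class TestCollectCandidates:
    def test_exact_read_gets_full_hit_count(self, small_library, params):
        ixs = pa.build_indexes(small_library, params.j, seed=5)
        pos = int(small_library.positions[37])
        cands = pa.collect_candidates(small_library.mmer(pos), ixs, params)
        assert cands.hits[(pos, FORWARD)] == params.j

    def test_zero_iterations_empty_set(self, small_library):
        ixs = pa.build_indexes(small_library, 1, seed=5)
        cands = pa.collect_candidates(small_library.mmer(0), ixs, pa.SearchParams(j=0))
        assert len(cands) == 0

    def test_matches_naive_reexecution(self, small_library, params, rng):
        ixs = pa.build_indexes(small_library, params.j, seed=5)
        for _ in range(10):
            read = "".join("ACGT"[c] for c in rng.integers(0, 4, small_library.m))
            got = pa.collect_candidates(read, ixs, params)
            assert got.hits == naive_candidates(read, ixs, params)

    def test_size_bound_and_hit_count_bound(self, small_library, params, rng):
        ixs = pa.build_indexes(small_library, params.j, seed=5)
        read = "".join("ACGT"[c] for c in rng.integers(0, 4, small_library.m))
        cands = pa.collect_candidates(read, ixs, params)
        assert len(cands) <= params.j * (2 * params.k + 1) * 2
        assert all(1 <= c <= params.j for c in cands.hits.values())

    def test_wrong_length_rejected(self, small_library, params):
        ixs = pa.build_indexes(small_library, params.j, seed=5)
        with pytest.raises(ValueError):
            pa.collect_candidates("A" * (small_library.m + 3), ixs, params)


class TestFilterByHits:
    def test_min_hits_one_is_identity(self):
        c = pa.CandidateSet(hits=Counter({(3, "+"): 2, (9, "-"): 1}))
        assert pa.filter_by_hits(c, 1).hits == c.hits

    def test_threshold_above_j_empties(self, small_library, params):
        ixs = pa.build_indexes(small_library, params.j, seed=5)
        cands = pa.collect_candidates(small_library.mmer(0), ixs, params)
        assert len(pa.filter_by_hits(cands, params.j + 1)) == 0

    def test_recount_oracle(self, small_library, params, rng):
        ixs = pa.build_indexes(small_library, params.j, seed=5)
        read = plant_mismatches(small_library.mmer(100), [2, 7], rng)
        cands = pa.collect_candidates(read, ixs, params)
        kept = pa.filter_by_hits(cands, 2)
        assert kept.hits == {k: c for k, c in cands.hits.items() if c >= 2}


class TestRankCandidates:
    def test_true_position_wins_at_distance_zero(self, small_library, params):
        pos = int(small_library.positions[50])
        cands = pa.CandidateSet(hits=Counter({(pos, FORWARD): 2, (0, FORWARD): 1}))
        res = pa.rank_candidates(small_library.mmer(pos), cands, small_library, params)
        assert res.best == (pos, FORWARD, 0, 2)

    def test_empty_set_is_unaligned(self, small_library, params):
        res = pa.rank_candidates(small_library.mmer(0), pa.CandidateSet(), small_library, params)
        assert res.status == "unaligned" and res.best is None

    def test_best_equals_bruteforce_argmin_over_set(self, small_library, params, rng):
        for _ in range(10):
            read = "".join("ACGT"[c] for c in rng.integers(0, 4, small_library.m))
            picks = rng.choice(small_library.positions, size=20, replace=False)
            cands = pa.CandidateSet(hits=Counter({(int(p), FORWARD): 1 for p in picks}))
            res = pa.rank_candidates(read, cands, small_library, params)
            brute = min(pa.hamming_distance(read, small_library.mmer(int(p))) for p in picks)
            assert res.best.distance == brute

    def test_reported_sorted_and_truncated(self, small_library, rng):
        read = "".join("ACGT"[c] for c in rng.integers(0, 4, small_library.m))
        picks = rng.choice(small_library.positions, size=30, replace=False)
        cands = pa.CandidateSet(hits=Counter({(int(p), FORWARD): 1 for p in picks}))
        res = pa.rank_candidates(read, cands, small_library, pa.SearchParams(max_report=3))
        assert len(res.reported) == 3
        dists = [a.distance for a in res.reported]
        assert dists == sorted(dists)
        assert res.best.distance == dists[0]
        assert all(p for p in res.ties)


class TestAlignRead:
    def test_error_free_reads_align_to_origin(self, toy_library, toy_indexes):
        params = pa.SearchParams(j=1, k=1)
        for pos in toy_library.positions[:50:5]:
            res = pa.align_read(toy_library.mmer(int(pos)), toy_indexes, toy_library, params)
            assert res.aligned and res.best.distance == 0
            assert (int(pos), FORWARD) in res.ties

    def test_reverse_complement_reads_found_on_minus_strand(self, toy_library, toy_indexes):
        params = pa.SearchParams(j=2, k=5)
        pos = int(toy_library.positions[1234])
        read = pa.reverse_complement(toy_library.mmer(pos))
        res = pa.align_read(read, toy_indexes, toy_library, params)
        assert res.best == (pos, REVERSE, 0, 2)

    def test_best_distance_never_beats_full_scan(self, small_library, rng):
        ixs = pa.build_indexes(small_library, 4, seed=5)
        params = pa.SearchParams(j=4, k=5, strand_mode="forward")
        windows = small_library.windows(small_library.positions)
        for _ in range(10):
            read = plant_mismatches(small_library.mmer(int(rng.choice(small_library.positions))),
                                    rng.choice(small_library.m, 2, replace=False), rng)
            res = pa.align_read(read, ixs, small_library, params)
            q = pa.seqcore.encode(read)
            global_min = int((windows != q[None, :]).sum(axis=1).min())
            assert res.best.distance >= global_min

    def test_monotone_in_j_and_k(self, small_library, rng):
        """More permutations or wider neighborhoods never lose candidates."""
        ixs = pa.build_indexes(small_library, 6, seed=5)
        read = plant_mismatches(small_library.mmer(77), [1, 5, 9], rng)
        small = pa.collect_candidates(read, ixs, pa.SearchParams(j=3, k=4))
        big_j = pa.collect_candidates(read, ixs, pa.SearchParams(j=6, k=4))
        big_k = pa.collect_candidates(read, ixs, pa.SearchParams(j=3, k=9))
        assert set(small.hits) <= set(big_j.hits)
        assert set(small.hits) <= set(big_k.hits)

    def test_comparison_budget_per_read(self, toy_library, toy_indexes):
        """O(J (log N + K)) M-mer comparisons per aligned read."""
        params = pa.SearchParams(j=8, k=20)
        counter = ComparisonCounter()
        read = toy_library.mmer(int(toy_library.positions[500]))
        pa.align_read(read, toy_indexes, toy_library, params, counter=counter)
        n = toy_library.size
        strands = 2
        budget = params.j * strands * (math.ceil(math.log2(n)) + 1 + (2 * params.k + 1))
        assert counter.count <= budget

    def test_deterministic_across_runs(self, small_library):
        ixs = pa.build_indexes(small_library, 4, seed=5)
        params = pa.SearchParams(j=4, k=5)
        read = small_library.mmer(11)
        a = pa.align_read(read, ixs, small_library, params)
        b = pa.align_read(read, ixs, small_library, params)
        assert (a.best, a.ties, a.reported) == (b.best, b.ties, b.reported)


class TestSlidingWindow:
    def test_single_window_equals_collect_candidates(self, small_library):
        ix = pa.build_index(small_library, pa.random_permutation(small_library.m, 9))
        params = pa.SearchParams(j=1, k=4)
        read = small_library.mmer(42)
        assert (pa.sliding_window_search(read, ix, params).hits
                == pa.collect_candidates(read, [ix], params).hits)

    def test_exact_long_read_double_votes(self, small_library):
        ix = pa.build_index(small_library, pa.random_permutation(small_library.m, 9))
        params = pa.SearchParams(j=1, k=2, strand_mode="forward")
        m = small_library.m
        pos = 60
        read = pa.seqcore.decode(small_library.codes[pos : pos + 2 * m])
        cands = pa.sliding_window_search(read, ix, params, stride=m)
        assert cands.hits[(pos, FORWARD)] == 2

    def test_matches_naive_per_window_rerun(self, small_library, rng):
        ix = pa.build_index(small_library, pa.random_permutation(small_library.m, 9))
        params = pa.SearchParams(j=1, k=3, strand_mode="forward")
        m = small_library.m
        read = "".join("ACGT"[c] for c in rng.integers(0, 4, m + 7))
        stride = default_stride(m)
        keys = [ix.key(int(p)) for p in ix.order]
        expect = Counter()
        offsets = list(range(0, len(read) - m + 1, stride))
        if offsets[-1] != len(read) - m:
            offsets.append(len(read) - m)
        for o in offsets:
            q = ix.permutation.apply(read[o : o + m])
            rank = bisect.bisect_left(keys, q)
            lo, hi = max(0, rank - params.k), min(len(keys), rank + params.k + 1)
            for p in ix.order[lo:hi]:
                if int(p) - o >= 0:
                    expect[(int(p) - o, FORWARD)] += 1
        assert pa.sliding_window_search(read, ix, params, stride=stride).hits == expect

    def test_short_read_rejected(self, small_library):
        ix = pa.build_index(small_library, pa.random_permutation(small_library.m, 9))
        with pytest.raises(ValueError):
            pa.sliding_window_search("ACGT", ix, pa.SearchParams())

    def test_long_read_end_to_end_alignment(self, toy_library, toy_indexes):
        m = toy_library.m
        pos = int(toy_library.positions[4000])
        read = pa.seqcore.decode(toy_library.codes[pos : pos + 3 * m])
        res = pa.align_read_windows(read, toy_indexes, toy_library,
                                    pa.SearchParams(j=4, k=5))
        assert res.best.position == pos and res.best.distance == 0


def test_align_reads_batch_dispatch(toy_library, toy_indexes):
    m = toy_library.m
    pos = int(toy_library.positions[100])
    reads = [
        ("exact", toy_library.mmer(pos)),
        ("long", pa.seqcore.decode(toy_library.codes[pos : pos + 2 * m])),
        ("short", "ACGT"),
    ]
    out = pa.align_reads(reads, toy_indexes, toy_library, pa.SearchParams(j=2, k=3))
    assert out[0].best.position == pos
    assert out[1].best.position == pos
    assert out[2].status == "unaligned"
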