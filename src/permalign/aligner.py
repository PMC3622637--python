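"""Candidate search, hit-count filtration, and Hamming ranking.

Search (one read, J indexes): permute the read with each index's
permutation, binary-search its lexicographical position, and union the
surrounding ``2K+1`` entries into the candidate set, counting how many
lookups proposed each position (the hit count).  Filtration keeps
candidates with enough hits; ranking computes the Hamming distance of the
read against each surviving reference M-mer and reports the closest ones.

Indexes are forward-strand only; each read is searched both as-is and
reverse-complemented, and candidates carry the strand label.  A single
index can also be reused as if it were several: a sliding window takes
contiguous M-long substrings of a longer read, searches each, and votes for
the window-adjusted start position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .index import ComparisonCounter, PermutedIndex, ReferenceLibrary, lexicographic_position, neighborhood
from .seqcore import N_CODE, decode, encode, reverse_complement_codes

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the randomized search.

    j: number of permuted indexes used per read.
    k: neighborhood half-width; each lookup proposes up to 2k+1 entries.
    min_hits: coarse filter — candidates proposed by fewer lookups are dropped.
    max_report: alignments reported per read.
    strand_mode: "both" (default) or "forward".
    """

    j: int = 8
    k: int = 20
    min_hits: int = 1
    max_report: int = 5
    strand_mode: str = "both"

    def __post_init__(self):
        if self.j < 0 or self.k < 0:
            raise ValueError("j and k must be >= 0")
        if self.min_hits < 1 or self.max_report < 1:
            raise ValueError("min_hits and max_report must be >= 1")
        if self.strand_mode not in ("both", "forward"):
            raise ValueError("strand_mode must be 'both' or 'forward'")

    @property
    def strands(self) -> tuple[str, ...]:
        return (FORWARD, REVERSE) if self.strand_mode == "both" else (FORWARD,)


@dataclass
class CandidateSet:
    """Candidate (position, strand) pairs with their hit counts."""

    hits: Counter = field(default_factory=Counter)

    def add(self, positions, strand: str):
        self.hits.update((int(p), strand) for p in positions)

    def __len__(self) -> int:
        return len(self.hits)

    def __contains__(self, key) -> bool:
        return key in self.hits

    def items(self):
        return self.hits.items()


class ReportedAlignment(NamedTuple):
    position: int
    strand: str
    distance: int
    hit_count: int


@dataclass
class AlignmentResult:
    """Ranked outcome for one read.

    ``reported`` is sorted by (distance asc, hit count desc, position asc,
    forward before reverse) and truncated to ``max_report``; ``ties`` lists
    every evaluated candidate at the best distance.
    """

    read_id: str
    read: str
    status: str  # "aligned" | "unaligned"
    best: ReportedAlignment | None = None
    ties: list = field(default_factory=list)
    reported: list = field(default_factory=list)

    @property
    def aligned(self) -> bool:
        return self.status == "aligned"


def _read_codes(read) -> np.ndarray:
    return encode(read) if isinstance(read, str) else np.asarray(read, dtype=np.uint8)


def collect_candidates(read, indexes, params: SearchParams,
                       counter: ComparisonCounter | None = None) -> CandidateSet:
    """Union of the j neighborhoods of the permuted read (per strand)."""
    codes = _read_codes(read)
    if params.j > 0:
        if not indexes:
            raise ValueError("no indexes supplied")
        if params.j > len(indexes):
            raise ValueError(f"j={params.j} exceeds the {len(indexes)} available indexes")
        if codes.size != indexes[0].m:
            raise ValueError(
                f"read length {codes.size} != m={indexes[0].m}; "
                "use sliding_window_search for longer reads"
            )
    cands = CandidateSet()
    oriented = {FORWARD: codes}
    if REVERSE in params.strands:
        oriented[REVERSE] = reverse_complement_codes(codes)
    for ix in indexes[: params.j]:
        for strand in params.strands:
            q = oriented[strand][ix.permutation.order]
            rank = lexicographic_position(ix, q, counter=counter)
            cands.add(neighborhood(ix, rank, params.k), strand)
    return cands


def filter_by_hits(cands: CandidateSet, min_hits: int) -> CandidateSet:
    """Keep candidates proposed by at least ``min_hits`` lookups."""
    if min_hits < 1:
        raise ValueError("min_hits must be >= 1")
    if min_hits == 1:
        return cands
    kept = Counter({k: c for k, c in cands.items() if c >= min_hits})
    return CandidateSet(hits=kept)


def rank_candidates(read, cands: CandidateSet, lib: ReferenceLibrary,
                    params: SearchParams, read_id: str = "read",
                    counter: ComparisonCounter | None = None) -> AlignmentResult:
    """Hamming-rank the candidates against the reference.

    The strand-appropriate orientation of the read is compared with the
    reference window at each candidate start; candidates whose window would
    run off the reference (possible only for window-adjusted votes from
    sliding-window search) are dropped.
    """
    codes = _read_codes(read)
    read_str = read if isinstance(read, str) else decode(codes)
    length = codes.size
    evaluated: list[ReportedAlignment] = []
    by_strand: dict[str, list] = {}
    for (pos, strand), hit in sorted(cands.items()):
        if 0 <= pos <= lib.n - length:
            by_strand.setdefault(strand, []).append((pos, hit))
    oriented = {FORWARD: codes, REVERSE: reverse_complement_codes(codes)}
    for strand, entries in by_strand.items():
        starts = np.array([p for p, _ in entries], dtype=np.int64)
        windows = lib.windows(starts, length)
        q = oriented[strand]
        dists = np.count_nonzero(
            (windows != q[None, :]) | (windows == N_CODE) | (q[None, :] == N_CODE), axis=1
        )
        if counter is not None:
            counter.tick(len(entries))
        for (pos, hit), d in zip(entries, dists):
            evaluated.append(ReportedAlignment(pos, strand, int(d), hit))
    if not evaluated:
        return AlignmentResult(read_id=read_id, read=read_str, status="unaligned")
    evaluated.sort(key=lambda a: (a.distance, -a.hit_count, a.position, a.strand == REVERSE))
    best = evaluated[0]
    ties = [(a.position, a.strand) for a in evaluated if a.distance == best.distance]
    return AlignmentResult(
        read_id=read_id,
        read=read_str,
        status="aligned",
        best=best,
        ties=ties,
        reported=evaluated[: params.max_report],
    )


def align_read(read, indexes, lib: ReferenceLibrary, params: SearchParams,
               read_id: str = "read",
               counter: ComparisonCounter | None = None) -> AlignmentResult:
    """Search + filter + rank for one read whose length equals m."""
    cands = collect_candidates(read, indexes, params, counter=counter)
    cands = filter_by_hits(cands, params.min_hits)
    return rank_candidates(read, cands, lib, params, read_id=read_id, counter=counter)


def default_stride(m: int) -> int:
    return max(1, m // 2)


def sliding_window_search(read, index: PermutedIndex, params: SearchParams,
                         stride: int | None = None,
                         counter: ComparisonCounter | None = None) -> CandidateSet:
    """Reuse one index for a read longer than m via sliding windows.

    Each m-long window at offset ``o`` is permuted and searched, and every
    neighborhood hit votes for read start ``hit - o``; hit counts accumulate
    across windows, so a single index behaves almost like several.
    """
    codes = _read_codes(read)
    m = index.m
    if codes.size < m:
        raise ValueError(f"read length {codes.size} < m={m}")
    if stride is None:
        stride = default_stride(m)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    last = codes.size - m
    offsets = list(range(0, last + 1, stride))
    if offsets[-1] != last:
        offsets.append(last)  # final window clamped to end at the read's last character
    cands = CandidateSet()
    oriented = {FORWARD: codes}
    if REVERSE in params.strands:
        oriented[REVERSE] = reverse_complement_codes(codes)
    for strand in params.strands:
        oc = oriented[strand]
        for o in offsets:
            q = oc[o : o + m][index.permutation.order]
            rank = lexicographic_position(index, q, counter=counter)
            hits = neighborhood(index, rank, params.k).astype(np.int64) - o
            cands.add(hits[hits >= 0], strand)
    return cands


def align_read_windows(read, indexes, lib: ReferenceLibrary, params: SearchParams,
                       stride: int | None = None, read_id: str = "read",
                       counter: ComparisonCounter | None = None) -> AlignmentResult:
    """Align a read of length >= m using sliding windows over each index."""
    merged = CandidateSet()
    if params.j > len(indexes):
        raise ValueError(f"j={params.j} exceeds the {len(indexes)} available indexes")
    for ix in indexes[: params.j]:
        part = sliding_window_search(read, ix, params, stride=stride, counter=counter)
        merged.hits.update(part.hits)
    merged = filter_by_hits(merged, params.min_hits)
    return rank_candidates(read, merged, lib, params, read_id=read_id, counter=counter)


def align_reads(reads, indexes, lib: ReferenceLibrary, params: SearchParams,
                stride: int | None = None) -> list[AlignmentResult]:
    """Batch alignment; dispatches on read length (== m exact, > m windowed)."""
    m = lib.m
    out = []
    for read_id, seq in reads:
        if len(seq) < m:
            out.append(AlignmentResult(read_id=read_id, read=seq, status="unaligned"))
        elif len(seq) == m:
            out.append(align_read(seq, indexes, lib, params, read_id=read_id))
        else:
            out.append(align_read_windows(seq, indexes, lib, params,
                                          stride=stride, read_id=read_id))
    return out
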