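"""Reference M-mer library and randomly permuted sorted-array indexes.

The reference genome ``W`` is viewed as its ``N - M + 1`` overlapping
substrings of length ``M`` (the "library"), each identified by its start
position.  A :class:`PermutedIndex` pairs one random permutation of the M
positions with an array of library start positions sorted by the *permuted*
M-mer.  Permuted M-mers are never stored: they are materialized on demand
from the reference and the permutation, so an index costs one integer per
library position plus the permutation itself.

Lookup primitives follow the sorted-dictionary picture: the lexicographical
position of a query (binary search, leftmost-insertion semantics), the
``2K+1``-wide neighborhood around it, the prefix neighborhood (all entries
sharing an ``l``-long permuted prefix), and the resolution length (the
shortest prefix shared by at most ``K`` entries).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import cmp_to_key

import numpy as np

from .seqcore import N_CODE, Permutation, decode, encode

INDEX_FORMAT_VERSION = 1

# Lexicographic order of the library is A < C < G < T (codes 0..3);
# N never occurs in a library M-mer, by construction.


class ComparisonCounter:
    """Counts M-mer comparison operations for complexity contracts."""

    def __init__(self):
        self.count = 0

    def tick(self, n: int = 1):
        self.count += n


@dataclass(frozen=True)
class ReferenceLibrary:
    """Reference string plus the start positions of its N-free M-mers."""

    codes: np.ndarray = field(repr=False)
    m: int
    positions: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        """Reference length."""
        return int(self.codes.size)

    @property
    def size(self) -> int:
        """Number of library M-mers."""
        return int(self.positions.size)

    def mmer_codes(self, pos: int) -> np.ndarray:
        return self.codes[pos : pos + self.m]

    def mmer(self, pos: int) -> str:
        return decode(self.mmer_codes(pos))

    def has_position(self, pos: int) -> bool:
        i = int(np.searchsorted(self.positions, pos))
        return i < self.positions.size and int(self.positions[i]) == int(pos)

    def windows(self, starts: np.ndarray, length: int | None = None) -> np.ndarray:
        """Gather the reference windows starting at ``starts`` as a 2-d array."""
        length = self.m if length is None else int(length)
        starts = np.asarray(starts, dtype=np.int64)
        return self.codes[starts[:, None] + np.arange(length)[None, :]]


def build_library(w, m: int) -> ReferenceLibrary:
    """List every N-free M-mer start position of the reference, ascending."""
    codes = encode(w) if isinstance(w, str) else np.asarray(w, dtype=np.uint8)
    if m < 1:
        raise ValueError("m must be >= 1")
    if codes.size < m:
        raise ValueError(f"reference length {codes.size} < m={m}")
    n_cum = np.concatenate(([0], np.cumsum(codes == N_CODE, dtype=np.int64)))
    n_in_window = n_cum[m:] - n_cum[: codes.size - m + 1]
    positions = np.nonzero(n_in_window == 0)[0].astype(np.int64)
    return ReferenceLibrary(codes=codes, m=m, positions=positions)


@dataclass(frozen=True)
class PermutedIndex:
    """One permutation plus library positions sorted by permuted M-mer.

    Ties (duplicate M-mers) are broken by ascending genome position.
    """

    permutation: Permutation
    library: ReferenceLibrary
    order: np.ndarray = field(repr=False)
    seed: int | None = None

    @property
    def m(self) -> int:
        return self.library.m

    def key_bytes(self, pos: int) -> bytes:
        """The permuted M-mer at library position ``pos``, as code bytes."""
        return self.library.codes[pos + self.permutation.order].tobytes()

    def key(self, pos: int) -> str:
        return decode(self.library.codes[pos + self.permutation.order])


def _packed_key_words(lib: ReferenceLibrary, perm: Permutation) -> np.ndarray:
    """Permuted M-mers packed 2 bits/base into uint64 words, one row per word.

    Valid because library M-mers never contain N (codes are < 4).
    """
    positions = lib.positions
    n_words = -(-lib.m // 32)
    words = np.empty((n_words, positions.size), dtype=np.uint64)
    for w in range(n_words):
        cols = perm.order[w * 32 : (w + 1) * 32]
        acc = np.zeros(positions.size, dtype=np.uint64)
        shift = 62
        for c in cols:
            acc |= lib.codes[positions + int(c)].astype(np.uint64) << np.uint64(shift)
            shift -= 2
        words[w] = acc
    return words


def build_index(
    lib: ReferenceLibrary,
    perm: Permutation,
    seed: int | None = None,
    counter: ComparisonCounter | None = None,
) -> PermutedIndex:
    """Sort the library by permuted M-mer without materializing the strings.

    The default path packs each permuted M-mer into ceil(M/32) 64-bit words
    and radix-sorts them (``np.lexsort``, stable, so duplicate M-mers keep
    ascending genome position).  With ``counter`` given, a comparison sort is
    used instead and every M-mer comparison is counted — the instrumented
    path for the O(n log n) construction contract.
    """
    if perm.m != lib.m:
        raise ValueError(f"permutation length {perm.m} != library m {lib.m}")
    if counter is not None:
        def cmp(a: int, b: int) -> int:
            counter.tick()
            ka = lib.codes[a + perm.order].tobytes()
            kb = lib.codes[b + perm.order].tobytes()
            return -1 if ka < kb else (1 if ka > kb else (a > b) - (a < b))

        order = np.array(sorted(lib.positions.tolist(), key=cmp_to_key(cmp)), dtype=np.int64)
    else:
        words = _packed_key_words(lib, perm)
        order = lib.positions[np.lexsort(words[::-1])]
    return PermutedIndex(permutation=perm, library=lib, order=order, seed=seed)


def _query_bytes(index: PermutedIndex, q) -> bytes:
    codes = encode(q) if isinstance(q, str) else np.asarray(q, dtype=np.uint8)
    if codes.size != index.m:
        raise ValueError(f"query length {codes.size} != m={index.m}")
    return codes.tobytes()


def _bisect(index: PermutedIndex, q_prefix: bytes, l: int, right: bool,
            counter: ComparisonCounter | None = None) -> int:
    """Leftmost rank whose l-long key prefix is >= (or > with right=True) q_prefix."""
    order = index.order
    lo, hi = 0, order.size
    while lo < hi:
        mid = (lo + hi) // 2
        if counter is not None:
            counter.tick()
        k = index.key_bytes(int(order[mid]))[:l]
        if k < q_prefix or (right and k == q_prefix):
            lo = mid + 1
        else:
            hi = mid
    return lo


def lexicographic_position(index: PermutedIndex, q,
                           counter: ComparisonCounter | None = None) -> int:
    """Rank at which the (already permuted) query sits or would be inserted.

    Leftmost-insertion semantics: the count of entries strictly less than
    ``q``; if ``q`` is present, the rank of its first occurrence.  Uses
    O(log N) M-mer comparisons.
    """
    qb = _query_bytes(index, q)
    return _bisect(index, qb, index.m, right=False, counter=counter)


def neighborhood(index: PermutedIndex, rank: int, k: int) -> np.ndarray:
    """Genome positions at sorted-array ranks rank-K .. rank+K, clamped."""
    if not 0 <= rank <= index.order.size:
        raise ValueError(f"rank {rank} out of range")
    if k < 0:
        raise ValueError("k must be >= 0")
    lo = max(0, rank - k)
    hi = min(index.order.size, rank + k + 1)
    return index.order[lo:hi]


def prefix_neighborhood(index: PermutedIndex, q, l: int,
                        counter: ComparisonCounter | None = None) -> np.ndarray:
    """All entries whose permuted M-mer shares the query's l-long prefix."""
    if not 0 <= l <= index.m:
        raise ValueError(f"prefix length {l} out of range for m={index.m}")
    qb = _query_bytes(index, q)[:l]
    lo = _bisect(index, qb, l, right=False, counter=counter)
    hi = _bisect(index, qb, l, right=True, counter=counter)
    return index.order[lo:hi]


def _prefix_count(index: PermutedIndex, qb: bytes, l: int) -> int:
    p = qb[:l]
    return _bisect(index, p, l, right=True) - _bisect(index, p, l, right=False)


def resolution_length(index: PermutedIndex, i: int, k: int) -> int:
    """Smallest L whose L-long permuted prefix is shared by <= K entries.

    Returns the sentinel ``m + 1`` when even the full M-mer is shared by
    more than K entries (duplicate M-mers in the reference).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not index.library.has_position(i):
        raise ValueError(f"position {i} is not a library position")
    qb = index.key_bytes(int(i))
    if _prefix_count(index, qb, index.m) > k:
        return index.m + 1
    # prefix count is nonincreasing in L: binary search the first L with count <= k
    lo, hi = 0, index.m
    while lo < hi:
        mid = (lo + hi) // 2
        if _prefix_count(index, qb, mid) <= k:
            hi = mid
        else:
            lo = mid + 1
    return lo


def reference_checksum(lib: ReferenceLibrary) -> str:
    return hashlib.sha256(lib.codes.tobytes()).hexdigest()


def save_indexes(path, indexes, seed: int | None = None) -> None:
    """Persist a set of indexes over one library.

    Stores a versioned JSON header (m, seed, reference checksum, permutations
    in 1-based manifest form) plus the order arrays — never the permuted
    strings, which are rebuilt from reference + permutation on load.
    """
    indexes = list(indexes)
    if not indexes:
        raise ValueError("no indexes to save")
    lib = indexes[0].library
    header = {
        "version": INDEX_FORMAT_VERSION,
        "m": lib.m,
        "seed": seed,
        "reference_sha256": reference_checksum(lib),
        "permutations": [list(ix.permutation.to_one_based()) for ix in indexes],
        "index_seeds": [ix.seed for ix in indexes],
    }
    np.savez(
        path,
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        orders=np.stack([ix.order for ix in indexes]),
    )


def load_indexes(path, lib: ReferenceLibrary) -> list[PermutedIndex]:
    """Load indexes saved by :func:`save_indexes`, verifying the reference."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        orders = data["orders"]
    if header["version"] != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format version {header['version']}")
    if header["m"] != lib.m:
        raise ValueError(f"index m={header['m']} != library m={lib.m}")
    if header["reference_sha256"] != reference_checksum(lib):
        raise ValueError("reference checksum mismatch: index built from a different reference")
    return [
        PermutedIndex(
            permutation=Permutation.from_one_based(code),
            library=lib,
            order=np.asarray(order, dtype=np.int64),
            seed=ix_seed,
        )
        for code, order, ix_seed in zip(header["permutations"], orders, header["index_seeds"])
    ]


def build_indexes(lib: ReferenceLibrary, j: int, seed: int) -> list[PermutedIndex]:
    """Build ``j`` independent random-permutation indexes from a master seed."""
    if j < 0:
        raise ValueError("j must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(j):
        sub = int(rng.integers(0, 2**31 - 1))
        perm = Permutation(np.random.default_rng(sub).permutation(lib.m))
        out.append(build_index(lib, perm, seed=sub))
    return out
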