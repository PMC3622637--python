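"""DNA string primitives: alphabet encoding, random permutations, Hamming distance.

Sequences are plain Python strings over ``A C G T N`` at the API surface and
``numpy.uint8`` code arrays internally (A=0, C=1, G=2, T=3, N=4, so that the
lexicographic order A < C < G < T is the numeric order and N sorts last).
All internal coordinates are 0-based half-open; 1-based positions appear only
in user-facing output and in the permutation manifest format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGTN"
N_CODE = np.uint8(4)

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# A<->T, C<->G, N->N
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes; unknown characters become N."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to an uppercase DNA string."""
    return _DECODE[codes].tobytes().decode("ascii")


def normalize(seq: str) -> str:
    """Case-fold to uppercase and map any non-ACGTN character to N."""
    return decode(encode(seq))


def reverse_complement(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return decode(_COMPLEMENT[encode(seq)][::-1])


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1]


def hamming_distance(a, b) -> int:
    """Number of mismatching positions between equal-length strings.

    N mismatches every character, including another N, so masked regions
    never match anything spuriously.
    """
    x = encode(a) if isinstance(a, str) else np.asarray(a, dtype=np.uint8)
    y = encode(b) if isinstance(b, str) else np.asarray(b, dtype=np.uint8)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    return int(np.count_nonzero((x != y) | (x == N_CODE) | (y == N_CODE)))


@dataclass(frozen=True)
class Permutation:
    """A bijection on the positions of an m-long string (gather convention).

    ``order[j]`` is the 0-based *source* position whose character lands at
    output position ``j``: ``apply(s)[j] == s[order[j]]``.
    """

    order: np.ndarray = field(repr=False)

    def __post_init__(self):
        order = np.asarray(self.order, dtype=np.int64)
        object.__setattr__(self, "order", order)
        if order.ndim != 1 or order.size < 1:
            raise ValueError("permutation must be a nonempty 1-d array")
        if not np.array_equal(np.sort(order), np.arange(order.size)):
            raise ValueError("order is not a bijection on 0..m-1")

    @property
    def m(self) -> int:
        return int(self.order.size)

    def apply(self, s):
        """Permute a string (or code array) of length m."""
        if isinstance(s, str):
            codes = encode(s)
            if codes.size != self.m:
                raise ValueError(f"string length {codes.size} != m={self.m}")
            return decode(codes[self.order])
        s = np.asarray(s, dtype=np.uint8)
        if s.size != self.m:
            raise ValueError(f"string length {s.size} != m={self.m}")
        return s[self.order]

    def destination(self, pos: int) -> int:
        """Where the character at 0-based input position ``pos`` lands."""
        if not 0 <= pos < self.m:
            raise ValueError(f"position {pos} out of range for m={self.m}")
        return int(np.nonzero(self.order == pos)[0][0])

    def inverse(self) -> "Permutation":
        inv = np.empty(self.m, dtype=np.int64)
        inv[self.order] = np.arange(self.m)
        return Permutation(inv)

    @classmethod
    def identity(cls, m: int) -> "Permutation":
        return cls(np.arange(m))

    @classmethod
    def from_one_based(cls, code) -> "Permutation":
        """Build from a 1-based source-position code, e.g. the manifest format."""
        return cls(np.asarray(code, dtype=np.int64) - 1)

    def to_one_based(self) -> tuple:
        return tuple(int(v) + 1 for v in self.order)


def random_permutation(m: int, seed: int) -> Permutation:
    """A uniformly random permutation of m positions (seeded Fisher–Yates)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed)
    return Permutation(rng.permutation(m))


def apply_permutation(perm: Permutation, s):
    return perm.apply(s)


def permute_position(perm: Permutation, pos: int) -> int:
    """0-based output position of the character at 0-based input ``pos``."""
    return perm.destination(pos)


def write_manifest(path, permutations, seed=None) -> None:
    """Write permutations as plain text: one comma-separated 1-based code
    per line, after a header line recording m and the master seed."""
    perms = list(permutations)
    if not perms:
        raise ValueError("no permutations to write")
    m = perms[0].m
    if any(p.m != m for p in perms):
        raise ValueError("permutations have mixed lengths")
    with open(path, "w") as fh:
        fh.write(f"# m={m} seed={'NA' if seed is None else int(seed)}\n")
        for p in perms:
            fh.write(",".join(str(v) for v in p.to_one_based()) + "\n")


def read_manifest(path):
    """Read a permutation manifest; returns (permutations, m, seed or None)."""
    perms = []
    m = seed = None
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("manifest missing header line")
        for tok in header.lstrip("#").split():
            key, _, val = tok.partition("=")
            if key == "m":
                m = int(val)
            elif key == "seed":
                seed = None if val == "NA" else int(val)
        for line in fh:
            line = line.strip()
            if not line:
                continue
            perms.append(Permutation.from_one_based([int(v) for v in line.split(",")]))
    if m is None or any(p.m != m for p in perms):
        raise ValueError("manifest permutations inconsistent with header m")
    return perms, m, seed
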