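"""Synthetic genomes and wgsim-style reads with per-read ground truth.

The generator emulates the standard resequencing simulation: a random
uniform reference, a sampled haplotype carrying point variants (a stated
fraction of which are single-base indels), and reads drawn uniformly from
either strand of the haplotype with independent per-base sequencing errors.
Ground truth records the reference coordinate of each read's origin (mapped
back through the variant list), which is what "aligned to the correct
original location" is scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqcore import N_CODE, decode, encode, reverse_complement_codes


@dataclass(frozen=True)
class SimulationConfig:
    """Generation parameters (defaults: length-100 reads, 0.1% mutation rate,
    15% indel fraction, 2% per-base sequencing error)."""

    genome_length: int = 1_000_000
    n_reads: int = 10_000
    read_length: int = 100
    mutation_rate: float = 0.001
    indel_fraction: float = 0.15
    error_rate: float = 0.02
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    seed: int = 0

    def __post_init__(self):
        for name in ("mutation_rate", "indel_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.genome_length, self.read_length, self.n_reads) < 1:
            raise ValueError("lengths and counts must be positive")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class Variant:
    kind: str  # "sub" | "ins" | "del"
    ref_pos: int  # 0-based reference coordinate of the affected base
    ref_base: str
    alt_base: str  # substituted base, inserted base, or "" for a deletion


@dataclass(frozen=True)
class Haplotype:
    """A mutated copy of the reference with a coordinate map back to it."""

    codes: np.ndarray = field(repr=False)
    hap2ref: np.ndarray = field(repr=False)  # per-haplotype-base reference coord
    variants: tuple = ()

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    def __len__(self) -> int:
        return int(self.codes.size)


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    position: int  # 0-based reference coordinate of the read's leftmost base
    strand: str
    n_errors: int = 0


def generate_genome(n: int, seed: int) -> str:
    """I.i.d. uniform A/C/G/T reference of length n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))


def mutate_haplotype(genome, mutation_rate: float, indel_fraction: float,
                     seed: int) -> Haplotype:
    """Plant variants on a copy of the reference.

    Each base is independently a variant site with probability
    ``mutation_rate``; a site is a substitution with probability
    ``1 - indel_fraction``, otherwise a single-base insertion or deletion
    with equal odds (insertions are placed after the site's base).
    """
    if not 0 <= mutation_rate <= 1 or not 0 <= indel_fraction <= 1:
        raise ValueError("rates must be in [0, 1]")
    ref = encode(genome) if isinstance(genome, str) else np.asarray(genome, dtype=np.uint8)
    n = ref.size
    rng = np.random.default_rng(seed)
    sites = np.nonzero(rng.random(n) < mutation_rate)[0]
    kind_draw = rng.random(sites.size)
    sub_alt = (ref[sites] + rng.integers(1, 4, size=sites.size, dtype=np.uint8)) % 4
    ins_base = rng.integers(0, 4, size=sites.size, dtype=np.uint8)

    seq_parts, map_parts, variants = [], [], []
    prev = 0
    for idx, site in enumerate(sites):
        site = int(site)
        seq_parts.append(ref[prev:site])
        map_parts.append(np.arange(prev, site, dtype=np.int64))
        r = kind_draw[idx]
        ref_base = decode(ref[site : site + 1])
        if r < 1.0 - indel_fraction:  # substitution
            seq_parts.append(sub_alt[idx : idx + 1])
            map_parts.append(np.array([site], dtype=np.int64))
            variants.append(Variant("sub", site, ref_base, decode(sub_alt[idx : idx + 1])))
        elif r < 1.0 - indel_fraction / 2:  # insertion after this base
            seq_parts.append(ref[site : site + 1])
            seq_parts.append(ins_base[idx : idx + 1])
            map_parts.append(np.array([site, site], dtype=np.int64))
            variants.append(Variant("ins", site, ref_base, decode(ins_base[idx : idx + 1])))
        else:  # deletion
            variants.append(Variant("del", site, ref_base, ""))
        prev = site + 1
    seq_parts.append(ref[prev:])
    map_parts.append(np.arange(prev, n, dtype=np.int64))
    return Haplotype(
        codes=np.concatenate(seq_parts),
        hap2ref=np.concatenate(map_parts),
        variants=tuple(variants),
    )


def _as_haplotype(hap) -> Haplotype:
    if isinstance(hap, Haplotype):
        return hap
    codes = encode(hap) if isinstance(hap, str) else np.asarray(hap, dtype=np.uint8)
    return Haplotype(codes=codes, hap2ref=np.arange(codes.size, dtype=np.int64))


def _apply_errors(codes: np.ndarray, error_rate: float, rng) -> tuple[np.ndarray, int]:
    if error_rate <= 0:
        return codes, 0
    mask = rng.random(codes.size) < error_rate
    if not mask.any():
        return codes, 0
    out = codes.copy()
    shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
    out[mask] = (out[mask] + shift) % 4
    return out, int(mask.sum())


def sample_reads(hap, config: SimulationConfig):
    """Uniform-start, uniform-strand reads with per-base errors.

    Returns ``(reads, truths)`` where reads are ``(id, sequence)`` pairs and
    truth positions are reference coordinates of each read's leftmost base.
    """
    h = _as_haplotype(hap)
    L = config.read_length
    if L > len(h):
        raise ValueError(f"read_length {L} exceeds haplotype length {len(h)}")
    rng = np.random.default_rng(config.seed)
    starts = rng.integers(0, len(h) - L + 1, size=config.n_reads)
    rev = rng.random(config.n_reads) < 0.5
    reads, truths = [], []
    for i in range(config.n_reads):
        s = int(starts[i])
        frag = h.codes[s : s + L]
        strand = "-" if rev[i] else "+"
        oriented = reverse_complement_codes(frag) if rev[i] else frag
        seq, n_err = _apply_errors(oriented, config.error_rate, rng)
        rid = f"read{i}"
        reads.append((rid, decode(seq)))
        truths.append(TruthRecord(rid, int(h.hap2ref[s]), strand, n_err))
    return reads, truths


def sample_pairs(hap, config: SimulationConfig):
    """Forward/reverse mate pairs with Normal start-to-start separation.

    The separation between the two mates' start positions is drawn from
    Normal(insert_mean, insert_sd), truncated positive and clipped so the
    pair fits the haplotype.  Each pair is emitted in either order (which
    mate is read 1) with equal probability; layout is always
    forward-then-reverse on the reference.
    """
    h = _as_haplotype(hap)
    L = config.read_length
    if L > len(h):
        raise ValueError(f"read_length {L} exceeds haplotype length {len(h)}")
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    inserts = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n)).astype(np.int64)
    inserts = np.clip(inserts, 1, len(h) - L)
    pairs, truths = [], []
    for i in range(n):
        ins = int(inserts[i])
        s1 = int(rng.integers(0, len(h) - L - ins + 1))
        s2 = s1 + ins
        fwd = h.codes[s1 : s1 + L]
        rev = reverse_complement_codes(h.codes[s2 : s2 + L])
        fwd, e_f = _apply_errors(fwd, config.error_rate, rng)
        rev, e_r = _apply_errors(rev, config.error_rate, rng)
        rid = f"pair{i}"
        t_f = TruthRecord(rid + "/f", int(h.hap2ref[s1]), "+", e_f)
        t_r = TruthRecord(rid + "/r", int(h.hap2ref[s2]), "-", e_r)
        if rng.random() < 0.5:
            pairs.append((rid, decode(fwd), decode(rev)))
            truths.append((t_f, t_r))
        else:
            pairs.append((rid, decode(rev), decode(fwd)))
            truths.append((t_r, t_f))
    return pairs, truths


@dataclass(frozen=True)
class EvaluationReport:
    n_total: int
    n_excluded: int
    n_aligned: int
    n_correct: int
    tolerance: int

    @property
    def n_scored(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def percent_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_scored if self.n_scored else 0.0


def _hits_truth(candidates, truth: TruthRecord, tolerance: int) -> bool:
    return any(
        strand == truth.strand and abs(pos - truth.position) <= tolerance
        for pos, strand in candidates
    )


def evaluate(results, truths, tolerance: int = 5, reference=None) -> EvaluationReport:
    """Fraction of reads with some reported alignment at the true origin.

    A read is correct when any reported alignment lies on the truth strand
    within ``tolerance`` positions of the truth start.  When ``reference``
    is given, reads whose truth window contains N are excluded from the
    denominator.
    """
    truth_by_id = {t.read_id: t for t in truths}
    if len(truth_by_id) != len(truths):
        raise ValueError("duplicate read ids in truth records")
    ref_codes = None
    if reference is not None:
        ref_codes = encode(reference) if isinstance(reference, str) else np.asarray(reference, dtype=np.uint8)
    n_excluded = n_aligned = n_correct = 0
    for res in results:
        truth = truth_by_id.get(res.read_id)
        if truth is None:
            raise ValueError(f"no truth record for read id {res.read_id!r}")
        if ref_codes is not None:
            w = ref_codes[truth.position : truth.position + len(res.read)]
            if (w == N_CODE).any():
                n_excluded += 1
                continue
        if res.aligned:
            n_aligned += 1
            if _hits_truth([(a.position, a.strand) for a in res.reported], truth, tolerance):
                n_correct += 1
    return EvaluationReport(n_total=len(results), n_excluded=n_excluded,
                           n_aligned=n_aligned, n_correct=n_correct, tolerance=tolerance)


def evaluate_pairs(pair_results, pair_truths, tolerance: int = 5) -> EvaluationReport:
    """Pairs with BOTH primary mate alignments at their true origins."""
    n_aligned = n_correct = 0
    for pr, (t1, t2) in zip(pair_results, pair_truths, strict=True):
        p1, p2 = pr.primary1, pr.primary2
        if p1 is None or p2 is None:
            continue
        n_aligned += 1
        ok1 = p1.strand == t1.strand and abs(p1.position - t1.position) <= tolerance
        ok2 = p2.strand == t2.strand and abs(p2.position - t2.position) <= tolerance
        if ok1 and ok2:
            n_correct += 1
    return EvaluationReport(n_total=len(pair_results), n_excluded=0,
                           n_aligned=n_aligned, n_correct=n_correct, tolerance=tolerance)
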