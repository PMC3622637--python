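"""Paired-end alignment with indel-tolerant mate rescue.

Mates are first aligned independently by the Hamming search.  If some pair
of reasonable candidates is concordant — opposite strands in the expected
forward/reverse layout with a start-to-start separation inside the insert
bounds — the best such pair (smallest summed distance) is reported.
Otherwise the better-aligned mate anchors a rescue: the expected window of
the reference around the anchor is scanned for the position minimizing the
edit distance of the full mate, so a single indel that wrecks the Hamming
search still yields the correct locus.

Edit distances are unit-cost and banded: only alignment paths that stay
within ``band`` diagonals of the main diagonal are considered, which is
exact whenever the true distance is at most ``band`` (and an upper bound
otherwise).  With ``band=0`` the distance degenerates to the Hamming
distance at the same offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .aligner import (
    FORWARD,
    REVERSE,
    AlignmentResult,
    ReportedAlignment,
    SearchParams,
    align_read,
    align_read_windows,
)
from .index import ReferenceLibrary
from .seqcore import N_CODE, encode, reverse_complement_codes

_INF = 1 << 30


@dataclass(frozen=True)
class PairedParams:
    """Concordance and rescue settings.

    insert_min/insert_max bound the distance between the two mates' start
    positions on the reference; orientation "fr" expects the forward-strand
    mate to the left of the reverse-strand mate (Illumina layout).
    rescue_band is the indel budget (DP band half-width); a rescued mate is
    accepted when its edit distance is at most max_rescue_distance.
    reasonable_fraction caps the Hamming distance (as a fraction of read
    length) for a candidate to take part in concordance or anchor a rescue.
    """

    insert_min: int = 0
    insert_max: int = 1000
    orientation: str = "fr"
    rescue_band: int = 5
    max_rescue_distance: int = 10
    reasonable_fraction: float = 0.1
    rescue: bool = True

    def __post_init__(self):
        if not 0 <= self.insert_min <= self.insert_max:
            raise ValueError("need 0 <= insert_min <= insert_max")
        if self.rescue_band < 0 or self.max_rescue_distance < 0:
            raise ValueError("rescue_band and max_rescue_distance must be >= 0")
        if self.orientation != "fr":
            raise ValueError("only 'fr' orientation is supported")

    def reasonable(self, distance: int, read_length: int) -> bool:
        return distance <= math.ceil(self.reasonable_fraction * read_length)


@dataclass(frozen=True)
class RescueOutcome:
    accepted: bool
    position: int | None = None
    strand: str | None = None
    distance: int | None = None
    transcript: str | None = None


@dataclass
class PairedResult:
    """Outcome for one pair: per-mate results plus the pair-level call."""

    r1: AlignmentResult
    r2: AlignmentResult
    status: str  # "concordant" | "one-rescued" | "discordant" | "unaligned"
    primary1: ReportedAlignment | None = None
    primary2: ReportedAlignment | None = None
    rescued_mate: int | None = None
    rescue: RescueOutcome | None = None


def _codes(s) -> np.ndarray:
    return encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.uint8)


def _sub_cost(a: np.uint8, b: np.uint8) -> int:
    return int(a != b or a == N_CODE or b == N_CODE)


def bounded_edit_distance(a, b, band: int):
    """Banded global edit distance with a transcript.

    Returns ``(distance, transcript)`` where the transcript is an extended
    CIGAR over ``= X I D`` (I consumes a character of ``a``, D of ``b``).
    Exact whenever the true distance is at most ``band``; otherwise the
    returned value is an upper bound, and when the length difference alone
    exceeds the band no path exists and ``(len(a)+len(b), None)`` is
    returned.
    """
    if band < 0:
        raise ValueError("band must be >= 0")
    x, y = _codes(a), _codes(b)
    la, lb = x.size, y.size
    if abs(la - lb) > band:
        return la + lb, None
    dp = np.full((la + 1, lb + 1), _INF, dtype=np.int64)
    op = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up(I), 2 left(D)
    dp[0, 0] = 0
    for j in range(1, min(lb, band) + 1):
        dp[0, j] = j
        op[0, j] = 2
    for i in range(1, la + 1):
        jlo, jhi = max(0, i - band), min(lb, i + band)
        for j in range(jlo, jhi + 1):
            if j == 0:
                dp[i, 0] = i
                op[i, 0] = 1
                continue
            best = dp[i - 1, j - 1] + _sub_cost(x[i - 1], y[j - 1])
            choice = 0
            up = dp[i - 1, j] + 1
            if up < best:
                best, choice = up, 1
            left = dp[i, j - 1] + 1
            if left < best:
                best, choice = left, 2
            dp[i, j] = best
            op[i, j] = choice
    dist = int(dp[la, lb])
    if dist >= _INF:
        return la + lb, None
    # traceback
    ops = []
    i, j = la, lb
    while i > 0 or j > 0:
        c = op[i, j]
        if c == 0 and i > 0 and j > 0:
            ops.append("=" if _sub_cost(x[i - 1], y[j - 1]) == 0 else "X")
            i, j = i - 1, j - 1
        elif c == 1:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    cigar = []
    for o in ops:
        if cigar and cigar[-1][1] == o:
            cigar[-1][0] += 1
        else:
            cigar.append([1, o])
    return dist, "".join(f"{n}{o}" for n, o in cigar)


def _semiglobal_scores(q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Edit distances of q against every end position in t, start free.

    Row-vectorized DP: entry j of the returned array is the minimum edit
    distance of q against any substring of t ending at position j.
    """
    lt = t.size
    idx = np.arange(lt + 1, dtype=np.int64)
    prev = np.zeros(lt + 1, dtype=np.int64)
    for qc in q:
        sub = ((t != qc) | (t == N_CODE) | (qc == N_CODE)).astype(np.int64)
        cand = np.empty(lt + 1, dtype=np.int64)
        cand[0] = prev[0] + 1
        np.minimum(prev[:-1] + sub, prev[1:] + 1, out=cand[1:])
        # resolve left-gap dependency: cur[j] = min_{j'<=j} cand[j'] + (j-j')
        prev = np.minimum.accumulate(cand - idx) + idx
    return prev


def rescue_mate(anchor_position: int, anchor_strand: str, mate,
                lib: ReferenceLibrary, params: PairedParams) -> RescueOutcome:
    """Scan the expected reference window for the mate of an anchored read.

    The full mate (oriented opposite to the anchor) is slid over the window
    by an exhaustive semi-global DP; the minimizing end position is refined
    to a start position and transcript with the banded global DP.  The
    rescue is accepted when the edit distance is at most
    ``max_rescue_distance``.
    """
    q = _codes(mate)
    lq = q.size
    band = params.rescue_band
    if anchor_strand == FORWARD:
        s_lo = anchor_position + params.insert_min
        s_hi = anchor_position + params.insert_max
        q = reverse_complement_codes(q)
        strand = REVERSE
    else:
        s_lo = anchor_position - params.insert_max
        s_hi = anchor_position - params.insert_min
        strand = FORWARD
    w0 = max(0, s_lo - band)
    w1 = min(lib.n, s_hi + lq + band)
    if w1 - w0 < max(1, lq - band):
        return RescueOutcome(accepted=False)
    window = lib.codes[w0:w1]
    scores = _semiglobal_scores(q, window)
    end = int(np.argmin(scores))
    d = int(scores[end])
    if d > params.max_rescue_distance:
        return RescueOutcome(accepted=False)
    # refine: among plausible starts for this end, take the best global fit
    best = None
    for start in range(max(0, end - lq - d), min(end, end - lq + d) + 1):
        tlen = end - start
        dist, transcript = bounded_edit_distance(q, window[start:end], band=max(d, abs(tlen - lq)))
        if transcript is None:
            continue
        if best is None or dist < best[0]:
            best = (dist, start, transcript)
    if best is None or best[0] > params.max_rescue_distance:
        return RescueOutcome(accepted=False)
    dist, start, transcript = best
    return RescueOutcome(accepted=True, position=w0 + start, strand=strand,
                         distance=dist, transcript=transcript)


def _align_one(read, indexes, lib, params: SearchParams, read_id: str) -> AlignmentResult:
    if len(read) == lib.m:
        return align_read(read, indexes, lib, params, read_id=read_id)
    return align_read_windows(read, indexes, lib, params, read_id=read_id)


def _concordant_pairs(res1: AlignmentResult, res2: AlignmentResult,
                      len1: int, len2: int, params: PairedParams):
    """All concordant (a1, a2) combos among reasonable reported candidates."""
    combos = []
    for a1 in res1.reported:
        if not params.reasonable(a1.distance, len1):
            continue
        for a2 in res2.reported:
            if not params.reasonable(a2.distance, len2):
                continue
            if a1.strand == a2.strand:
                continue
            fwd, rev = (a1, a2) if a1.strand == FORWARD else (a2, a1)
            sep = rev.position - fwd.position
            if params.insert_min <= sep <= params.insert_max:
                combos.append((a1, a2))
    return combos


def align_pair(r1, r2, indexes, lib: ReferenceLibrary, search_params: SearchParams,
               paired_params: PairedParams, read_id: str = "pair") -> PairedResult:
    """Align a mate pair: independent search, concordance, then rescue."""
    res1 = _align_one(r1, indexes, lib, search_params, read_id=read_id + "/1")
    res2 = _align_one(r2, indexes, lib, search_params, read_id=read_id + "/2")
    combos = _concordant_pairs(res1, res2, len(r1), len(r2), paired_params)
    if combos:
        a1, a2 = min(
            combos,
            key=lambda c: (c[0].distance + c[1].distance,
                           c[0].position, c[1].position, c[0].strand == REVERSE),
        )
        return PairedResult(r1=res1, r2=res2, status="concordant", primary1=a1, primary2=a2)
    if paired_params.rescue:
        # anchor on the better-aligned mate; try its candidates by ascending distance
        order = []
        for mate_no, res, length in ((1, res1, len(r1)), (2, res2, len(r2))):
            if res.aligned and paired_params.reasonable(res.best.distance, length):
                order.append((res.best.distance, mate_no, res))
        order.sort()
        for _, mate_no, res in order:
            other = r2 if mate_no == 1 else r1
            for cand in res.reported:
                if not paired_params.reasonable(cand.distance, len(res.read)):
                    continue
                out = rescue_mate(cand.position, cand.strand, other, lib, paired_params)
                if out.accepted:
                    rescued_no = 2 if mate_no == 1 else 1
                    primary = {mate_no: cand,
                               rescued_no: ReportedAlignment(out.position, out.strand,
                                                             out.distance, 0)}
                    return PairedResult(r1=res1, r2=res2, status="one-rescued",
                                        primary1=primary[1], primary2=primary[2],
                                        rescued_mate=rescued_no, rescue=out)
    if not res1.aligned and not res2.aligned:
        status = "unaligned"
    else:
        status = "discordant"
    return PairedResult(r1=res1, r2=res2, status=status,
                        primary1=res1.best, primary2=res2.best)
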