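"""Standard-format I/O: FASTA references, FASTQ reads, SAM output.

Multi-sequence references are concatenated into one coordinate space with
runs of N between sequences (at least as long as the M-mer length, so no
library M-mer can span two sequences); a :class:`ReferenceMap` translates
concatenated coordinates back to (sequence name, offset).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import pysam
from Bio import SeqIO

from . import __version__
from .seqcore import normalize, reverse_complement

DEFAULT_SPACER = 500


@dataclass(frozen=True)
class ReferenceMap:
    """Sequence names, lengths, and offsets into the concatenated coordinates."""

    entries: tuple  # of (name, length, offset), offsets strictly increasing

    def __post_init__(self):
        offsets = [off for _, _, off in self.entries]
        if offsets != sorted(set(offsets)):
            raise ValueError("offsets must be strictly increasing")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def to_reference(self, concat_pos: int) -> tuple[str, int]:
        """Map a concatenated coordinate to (sequence name, 0-based offset)."""
        for name, length, offset in reversed(self.entries):
            if concat_pos >= offset:
                if concat_pos >= offset + length:
                    break  # falls in a spacer
                return name, concat_pos - offset
        raise ValueError(f"position {concat_pos} is not inside any sequence")

    def to_concat(self, name: str, pos: int) -> int:
        for n, length, offset in self.entries:
            if n == name:
                if not 0 <= pos < length:
                    raise ValueError(f"position {pos} out of range for {name}")
                return offset + pos
        raise ValueError(f"unknown sequence {name!r}")


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path, spacer: int = DEFAULT_SPACER) -> tuple[str, ReferenceMap]:
    """Read a FASTA file into one concatenated, normalized string.

    Sequences are case-folded, non-ACGTN characters become N, and records
    are joined with ``spacer`` Ns (choose spacer >= the M-mer length).
    """
    with _open_text(path) as fh:
        first = fh.readline()
        lineno = 1
        while first and not first.strip():
            first = fh.readline()
            lineno += 1
        if not first or not first.startswith(">"):
            raise ValueError(f"{path}: malformed FASTA at line {lineno}: expected '>'")
    with _open_text(path) as fh:
        records = [(rec.id, normalize(str(rec.seq))) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    parts, entries, offset = [], [], 0
    for i, (name, seq) in enumerate(records):
        if i > 0:
            parts.append("N" * spacer)
            offset += spacer
        parts.append(seq)
        entries.append((name, len(seq), offset))
        offset += len(seq)
    return "".join(parts), ReferenceMap(entries=tuple(entries))


def read_fastq(path):
    """Stream (id, sequence, quality-string) from a FASTQ file (plain or gzip)."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.strip():
                continue
            if not header.startswith("@"):
                raise ValueError(f"{path}: malformed FASTQ at line {lineno}")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            lineno += 3
            if not qual or not plus.startswith("+"):
                raise ValueError(f"{path}: truncated FASTQ record at line {lineno}")
            seq, qual = seq.strip(), qual.strip()
            if len(seq) != len(qual):
                raise ValueError(f"{path}: sequence/quality length mismatch at line {lineno}")
            yield header[1:].split()[0], normalize(seq), qual


def _strip_mate_suffix(rid: str) -> str:
    return rid[:-2] if rid.endswith(("/1", "/2")) else rid


def read_fastq_paired(path1, path2):
    """Iterate two FASTQ files in lockstep, checking id consistency."""
    it1, it2 = read_fastq(path1), read_fastq(path2)
    for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2, strict=True):
        if _strip_mate_suffix(id1) != _strip_mate_suffix(id2):
            raise ValueError(f"pair id mismatch: {id1!r} vs {id2!r}")
        yield (_strip_mate_suffix(id1), s1, s2)


def write_fasta(path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_fastq(path, reads) -> None:
    """Write (id, sequence) pairs with constant placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def _sam_header(reference_map: ReferenceMap, extra_pg: str = "") -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length, _ in reference_map.entries],
            "PG": [{"ID": "permalign", "PN": "permalign", "VN": __version__,
                    **({"CL": extra_pg} if extra_pg else {})}],
        }
    )


_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "=": 7, "X": 8}


def transcript_to_cigartuples(transcript: str):
    """Parse an extended-CIGAR transcript (ops = X I D) into pysam tuples."""
    out, num = [], ""
    for ch in transcript:
        if ch.isdigit():
            num += ch
        else:
            out.append((_CIGAR_CODE[ch], int(num)))
            num = ""
    return out


def _segment(header, result, alignment, reference_map, secondary=False,
             cigartuples=None):
    seg = pysam.AlignedSegment(header)
    seg.query_name = result.read_id
    if alignment is None:
        seg.flag = 4
        seg.query_sequence = result.read
        return seg
    name, local = reference_map.to_reference(alignment.position)
    seg.reference_id = reference_map.names.index(name)
    seg.reference_start = local
    seg.flag = (16 if alignment.strand == "-" else 0) | (256 if secondary else 0)
    seg.mapping_quality = 255
    seq = result.read if alignment.strand == "+" else reverse_complement(result.read)
    seg.query_sequence = seq
    seg.cigartuples = cigartuples or [(0, len(seq))]
    seg.set_tag("NM", int(alignment.distance))
    return seg


def write_sam(results, reference_map: ReferenceMap, path, command_line: str = "") -> None:
    """Write single-end alignment results as SAM.

    The best alignment is primary; further reported alignments (up to the
    search's max_report) are flagged secondary.  Hamming alignments get a
    full-length match CIGAR and an NM tag holding the distance.
    """
    header = _sam_header(reference_map, command_line)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for res in results:
            if not res.aligned:
                out.write(_segment(header, res, None, reference_map))
                continue
            out.write(_segment(header, res, res.best, reference_map))
            for aln in res.reported[1:]:
                if (aln.position, aln.strand) == (res.best.position, res.best.strand):
                    continue
                out.write(_segment(header, res, aln, reference_map, secondary=True))


def write_sam_paired(pair_results, reference_map: ReferenceMap, path,
                     command_line: str = "") -> None:
    """Write paired results as SAM with mate fields and inferred insert size."""
    header = _sam_header(reference_map, command_line)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pr in pair_results:
            proper = pr.status in ("concordant", "one-rescued")
            chosen = (pr.primary1, pr.primary2)
            for mate_no, (res, aln) in enumerate(zip((pr.r1, pr.r2), chosen), start=1):
                cig = None
                if pr.rescue is not None and pr.rescued_mate == mate_no:
                    cig = transcript_to_cigartuples(pr.rescue.transcript)
                seg = _segment(header, res, aln, reference_map, cigartuples=cig)
                seg.query_name = _strip_mate_suffix(seg.query_name)
                seg.flag |= 1 | (64 if mate_no == 1 else 128)
                if proper:
                    seg.flag |= 2
                other = chosen[2 - mate_no]
                if other is None:
                    seg.flag |= 8
                else:
                    oname, olocal = reference_map.to_reference(other.position)
                    seg.next_reference_id = reference_map.names.index(oname)
                    seg.next_reference_start = olocal
                    if other.strand == "-":
                        seg.flag |= 32
                    if aln is not None:
                        seg.template_length = other.position - aln.position
                out.write(seg)


def read_sam_alignments(path):
    """Collapse a SAM file to {read id: [(reference name, 0-based pos, strand)]}."""
    hits: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            lst = hits.setdefault(seg.query_name, [])
            if seg.is_unmapped:
                continue
            lst.append((seg.reference_name, seg.reference_start,
                        "-" if seg.is_reverse else "+"))
    return hits


def write_truth_table(path, truths, chrom: str) -> None:
    """Tab-separated truth: id, chrom, 1-based position, strand, planted edits."""
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\tstrand\tedits\n")
        for t in truths:
            fh.write(f"{t.read_id}\t{chrom}\t{t.position + 1}\t{t.strand}\t{t.n_errors}\n")


def read_truth_table(path):
    """Read a truth table back as (id, chrom, 0-based pos, strand) tuples."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: missing truth-table header")
        for line in fh:
            rid, chrom, pos, strand, _ = line.rstrip("\n").split("\t")
            out.append((rid, chrom, int(pos) - 1, strand))
    return out
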