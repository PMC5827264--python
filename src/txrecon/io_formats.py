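"""Readers and writers for the external formats the pipeline touches.

All coordinate-convention conversion happens here and nowhere else: GTF,
SAM and tabular alignment hits are 1-based inclusive on disk and become
0-based half-open in memory; the writers apply the inverse.  Minus-strand
subject hits (``s_start > s_end`` in the 12-column tabular format) are
normalised to ``(min, max)`` plus an explicit strand at parse time so that
downstream interval algebra can assume ``start < end``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AlignmentHit",
    "ReadPairRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_hits_tab",
    "write_hits_tab",
    "read_sam_min",
    "cigar_reference_blocks",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence, 0-based."""

    sequence_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.sequence_id != other.sequence_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """An exon-structured transcript on one sequence and strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    source: str = "."

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        seqids = {e.sequence_id for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seqids) != 1 or len(strands) != 1:
            raise ValueError(
                f"transcript {self.transcript_id} mixes sequences/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )

    @property
    def sequence_id(self) -> str:
        return self.exons[0].sequence_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.sequence_id, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass(frozen=True)
class AlignmentHit:
    """One record of the 12-column tabular pairwise-alignment format.

    ``q_start``/``q_end`` and ``s_start``/``s_end`` keep the on-disk 1-based
    inclusive convention but are normalised so start <= end; the subject
    strand implied by a descending subject range is stored explicitly.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 1
    q_end: int = 1
    s_start: int = 1
    s_end: int = 1
    evalue: float = 0.0
    bitscore: float = 0.0
    subject_strand: str = "+"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end")
        if self.s_start > self.s_end:
            raise ValueError("s_start > s_end after normalisation")
        if self.aln_length < 1:
            raise ValueError("aln_length < 1")

    @classmethod
    def from_coords(cls, *args, **kwargs) -> "AlignmentHit":
        """Build a hit from raw file coordinates, normalising a descending
        subject range to (min, max) + minus strand."""
        hit = cls.__new__(cls)
        fields = dict(
            zip(
                (
                    "query_id", "subject_id", "pct_identity", "aln_length",
                    "mismatches", "gap_opens", "q_start", "q_end",
                    "s_start", "s_end", "evalue", "bitscore",
                ),
                args,
            )
        )
        fields.update(kwargs)
        s_start, s_end = fields.get("s_start", 1), fields.get("s_end", 1)
        if s_start > s_end:
            fields["s_start"], fields["s_end"] = s_end, s_start
            fields["subject_strand"] = "-"
        else:
            fields.setdefault("subject_strand", "+")
        return cls(**fields)

    @property
    def query_interval(self) -> GenomicInterval:
        return GenomicInterval(self.query_id, self.q_start - 1, self.q_end)

    @property
    def subject_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.subject_id, self.s_start - 1, self.s_end, self.subject_strand
        )


@dataclass
class ReadPairRecord:
    """Both mates of one sequenced fragment, joined by query name."""

    query_name: str
    flag1: int
    flag2: int
    ref1: str
    ref2: str
    pos1: int  # 1-based leftmost, as in SAM
    pos2: int
    mapq1: int = 0
    mapq2: int = 0
    cigar1: str | None = None
    cigar2: str | None = None

    def __post_init__(self) -> None:
        if not (self.flag1 & 0x1 and self.flag2 & 0x1):
            raise ValueError(f"{self.query_name}: both mates must be paired (0x1)")
        first = (self.flag1 & 0x40, self.flag2 & 0x40)
        second = (self.flag1 & 0x80, self.flag2 & 0x80)
        if sorted(bool(x) for x in first) != [False, True] or sorted(
            bool(x) for x in second
        ) != [False, True]:
            raise ValueError(
                f"{self.query_name}: exactly one first-in-pair (0x40) and one "
                "second-in-pair (0x80) mate required"
            )

    @property
    def is_duplicate(self) -> bool:
        return bool((self.flag1 | self.flag2) & 0x400)

    @property
    def is_multimapped(self) -> bool:
        return bool((self.flag1 | self.flag2) & 0x100)

    @property
    def is_mapped(self) -> bool:
        return not ((self.flag1 | self.flag2) & 0x4)

    @property
    def is_chimeric(self) -> bool:
        return self.ref1 != self.ref2

    def mate_blocks(self, mate: int, default_read_length: int = 50) -> list[GenomicInterval]:
        """Reference intervals covered by one mate (0-based half-open).

        Uses the CIGAR when present (N/D splits respected for N); falls
        back to ``[pos, pos + default_read_length)``.
        """
        flag, ref, pos, cigar = (
            (self.flag1, self.ref1, self.pos1, self.cigar1)
            if mate == 1
            else (self.flag2, self.ref2, self.pos2, self.cigar2)
        )
        if flag & 0x4:
            return []
        start0 = pos - 1
        if cigar in (None, "*"):
            return [GenomicInterval(ref, start0, start0 + default_read_length)]
        return [
            GenomicInterval(ref, s, e)
            for s, e in cigar_reference_blocks(cigar, start0)
        ]


def cigar_reference_blocks(cigar: str, start0: int) -> list[tuple[int, int]]:
    """Aligned reference blocks from a CIGAR string, splitting on N (introns)."""
    blocks: list[tuple[int, int]] = []
    pos = start0
    block_start = start0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "M=XD":
            pos += n
        elif ch == "N":
            if pos > block_start:
                blocks.append((block_start, pos))
            pos += n
            block_start = pos
        elif ch in "ISHP":
            pass
        else:
            raise FormatError(f"unsupported CIGAR operation {ch!r} in {cigar}")
    if pos > block_start:
        blocks.append((block_start, pos))
    return blocks


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{sequence_id: sequence}`` preserving case."""
    _validate_fasta_headers(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def _validate_fasta_headers(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {stripped[:30]!r}"
                )
            return


def write_fasta(
    records: dict[str, str], path: str | os.PathLike, line_width: int = 60
) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ (Phred+33) into ``(read_id, sequence, qualities)`` tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])))
    return out


def write_fastq(
    reads: list[tuple[str, str, list[int]]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for read_id, seq, quals in reads:
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = list(quals)
            fh.write(rec.format("fastq"))


# ---------------------------------------------------------------------------
# GTF (Cufflinks dialect: gene_id + transcript_id attributes)

def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse exon features of a 9-column GTF into transcript models.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    sources: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            feat = feature_from_line(line, dialect=None)
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise FormatError(
                    f"{path}: line {lineno}: missing mandatory gene_id/"
                    "transcript_id attribute"
                )
            tid = attrs["transcript_id"][0]
            interval = GenomicInterval(
                cols[0], feat.start - 1, feat.end, feat.strand if feat.strand in "+-" else "."
            )
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            exons[tid].append(interval)
            genes[tid] = attrs["gene_id"][0]
            sources[tid] = cols[1]
    return [
        TranscriptModel(tid, genes[tid], exons[tid], source=sources[tid])
        for tid in order
    ]


def write_gtf(models: list[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in models:
            for exon in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        (
                            exon.sequence_id,
                            t.source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand if exon.strand != "." else ".",
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# 12-column tabular alignment hits (BLAST outfmt 6 layout)

def read_hits_tab(path: str | os.PathLike) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                hits.append(
                    AlignmentHit.from_coords(
                        cols[0],
                        cols[1],
                        float(cols[2]),
                        int(cols[3]),
                        int(cols[4]),
                        int(cols[5]),
                        int(cols[6]),
                        int(cols[7]),
                        int(cols[8]),
                        int(cols[9]),
                        float(cols[10]),
                        float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_hits_tab(hits: list[AlignmentHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            s_start, s_end = (
                (h.s_end, h.s_start) if h.subject_strand == "-" else (h.s_start, h.s_end)
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                        h.aln_length, h.mismatches, h.gap_opens,
                        h.q_start, h.q_end, s_start, s_end,
                        f"{h.evalue:.2g}", f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Minimal SAM

def read_sam_min(
    path: str | os.PathLike,
) -> tuple[list[ReadPairRecord], list[str]]:
    """Join primary SAM records into read pairs by query name.

    Returns ``(pairs, orphans)`` where orphans lists query names whose mate
    was never seen; orphans are reported, never silently dropped.  Chimeric
    pairs (mates on different references) are retained.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[ReadPairRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name in pending:
                mate = pending.pop(rec.query_name)
                r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
                pairs.append(
                    ReadPairRecord(
                        query_name=rec.query_name,
                        flag1=r1.flag,
                        flag2=r2.flag,
                        ref1=r1.reference_name or "*",
                        ref2=r2.reference_name or "*",
                        pos1=r1.reference_start + 1 if r1.reference_start >= 0 else 0,
                        pos2=r2.reference_start + 1 if r2.reference_start >= 0 else 0,
                        mapq1=r1.mapping_quality,
                        mapq2=r2.mapping_quality,
                        cigar1=r1.cigarstring,
                        cigar2=r2.cigarstring,
                    )
                )
            else:
                pending[rec.query_name] = rec
    return pairs, sorted(pending)
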