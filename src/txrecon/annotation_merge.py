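"""Merge two gene annotation models into one guide annotation.

Two genes are *identical* when they sit on the same sequence and strand
and their transcripts' intron chains match exactly as multisets
(single-exon transcripts match when their exons overlap by at least 1 bp).
Identical genes are retrieved only once; genes unique to either input are
carried through; overlapping-but-different ("discordant") genes are
resolved by keeping the gene with the larger total exonic length — the
computable proxy for "best coverage" — with ties going to the first
annotation.  Every resolution is recorded in a decision log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import GenomicInterval, TranscriptModel

__all__ = [
    "GeneGroup",
    "intron_chain",
    "genes_identical",
    "merge_annotations",
    "group_by_gene",
    "exonic_length",
]


@dataclass
class GeneGroup:
    gene_id: str
    transcripts: list[TranscriptModel]
    source: str = "."

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ValueError(f"gene {self.gene_id}: transcript with foreign gene_id")

    @property
    def sequence_id(self) -> str:
        return self.transcripts[0].sequence_id

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.sequence_id, start, end, self.strand)


def group_by_gene(models: list[TranscriptModel], source: str = ".") -> list[GeneGroup]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    order: list[str] = []
    for t in models:
        if t.gene_id not in by_gene:
            by_gene[t.gene_id] = []
            order.append(t.gene_id)
        by_gene[t.gene_id].append(t)
    return [GeneGroup(g, by_gene[g], source=source) for g in order]


def intron_chain(t: TranscriptModel) -> list[GenomicInterval]:
    """Intervals strictly between consecutive exons; empty for single-exon."""
    return [
        GenomicInterval(t.sequence_id, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
        if b.start > a.end
    ]


def exonic_length(gene: GeneGroup) -> int:
    """Length of the union of all the gene's exons."""
    intervals = sorted(
        (e.start, e.end) for t in gene.transcripts for e in t.exons
    )
    total = 0
    cur_start, cur_end = None, None
    for s, e in intervals:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def _chain_key(t: TranscriptModel) -> tuple:
    return tuple((i.start, i.end) for i in intron_chain(t))


def genes_identical(a: GeneGroup, b: GeneGroup) -> bool:
    if a.sequence_id != b.sequence_id or a.strand != b.strand:
        return False
    multi_a = sorted(_chain_key(t) for t in a.transcripts if len(t.exons) > 1)
    multi_b = sorted(_chain_key(t) for t in b.transcripts if len(t.exons) > 1)
    if multi_a != multi_b:
        return False
    single_a = sorted(
        (t.exons[0] for t in a.transcripts if len(t.exons) == 1),
        key=lambda e: (e.start, e.end),
    )
    single_b = sorted(
        (t.exons[0] for t in b.transcripts if len(t.exons) == 1),
        key=lambda e: (e.start, e.end),
    )
    if len(single_a) != len(single_b):
        return False
    # greedy positional matching: each single-exon transcript must overlap
    # its rank-matched counterpart by >= 1 bp
    return all(x.overlaps(y) for x, y in zip(single_a, single_b))


def _overlapping(a: GeneGroup, b: GeneGroup) -> bool:
    """Discordance candidate: >= 1 bp exonic overlap on the same strand."""
    if a.sequence_id != b.sequence_id or a.strand != b.strand:
        return False
    exons_a = [e for t in a.transcripts for e in t.exons]
    exons_b = [e for t in b.transcripts for e in t.exons]
    return any(x.overlaps(y) for x in exons_a for y in exons_b)


def merge_annotations(
    a_genes: list[GeneGroup], b_genes: list[GeneGroup]
) -> tuple[list[GeneGroup], list[dict]]:
    """Merge annotation A with annotation B.

    Returns the merged gene list plus a decision log with one entry per
    identical-gene collapse and per discordant-gene resolution.
    """
    log: list[dict] = []
    dropped_a: set[int] = set()
    dropped_b: set[int] = set()

    for j, b in enumerate(b_genes):
        for i, a in enumerate(a_genes):
            if i in dropped_a or j in dropped_b:
                continue
            if genes_identical(a, b):
                dropped_b.add(j)
                log.append(
                    {
                        "decision": "identical",
                        "kept": a.gene_id,
                        "kept_source": "A",
                        "dropped": b.gene_id,
                        "dropped_source": "B",
                    }
                )
            elif _overlapping(a, b):
                len_a, len_b = exonic_length(a), exonic_length(b)
                if len_b > len_a:
                    dropped_a.add(i)
                    winner, loser, ws = b.gene_id, a.gene_id, "B"
                else:
                    dropped_b.add(j)
                    winner, loser, ws = a.gene_id, b.gene_id, "A"
                log.append(
                    {
                        "decision": "discordant",
                        "kept": winner,
                        "kept_source": ws,
                        "dropped": loser,
                        "dropped_source": "A" if ws == "B" else "B",
                        "exonic_length_a": len_a,
                        "exonic_length_b": len_b,
                    }
                )

    merged = [g for i, g in enumerate(a_genes) if i not in dropped_a]
    merged += [g for j, g in enumerate(b_genes) if j not in dropped_b]
    return merged, log
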