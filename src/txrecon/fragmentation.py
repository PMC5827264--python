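"""Gene-fragmentation correction.

De novo assembled contigs are compared to the genome-guided gene
candidates; a contig is assigned to a candidate when an alignment hit with
identity strictly above 90% contributes at least 40 bp of the contig not
already covered by previously accepted hits.  Uncovered contig regions of
at least 400 bp are extracted as novel sequence.  Contigs placed on the
genome are classified relative to a candidate's exon features (missed
internal exon, 5'/3' extension), and candidates are classified by where
their parts live: a single location, multiple ordered chromosomes,
multiple unplaced contigs, or a mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import AlignmentHit, GenomicInterval

DEFAULT_MIN_IDENTITY = 90.0   # strict: identity must exceed this
DEFAULT_MIN_NOVEL_BP = 40     # inclusive: novel coverage of at least this
DEFAULT_MIN_REGION_BP = 400   # inclusive: uncovered regions of at least this
DEFAULT_VICINITY_BP = 10_000

ORDERED = "ordered"
UNPLACED = "unplaced"
ARTIFICIAL = "artificial"

__all__ = [
    "CoverageMap",
    "ContigAssignment",
    "GeneCandidate",
    "coverage_union",
    "assign_contig",
    "uncovered_regions",
    "classify_genomic_placement",
    "fragmentation_class",
    "gather_parts",
]


@dataclass
class CoverageMap:
    """Disjoint sorted covered intervals on one target's own coordinates."""

    target_id: str
    target_length: int
    covered: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.covered = _merge_intervals(self.covered)
        if self.covered:
            if self.covered[0][0] < 0 or self.covered[-1][1] > self.target_length:
                raise ValueError(
                    f"{self.target_id}: coverage outside [0, {self.target_length})"
                )

    @property
    def covered_bp(self) -> int:
        return sum(e - s for s, e in self.covered)

    def novel_bp(self, start: int, end: int) -> int:
        """Bases of [start, end) not yet covered."""
        novel = end - start
        for s, e in self.covered:
            if s >= end:
                break
            novel -= max(0, min(e, end) - max(s, start))
        return novel

    def add(self, start: int, end: int) -> int:
        """Add an interval; returns the number of newly covered bases."""
        novel = self.novel_bp(start, end)
        self.covered = _merge_intervals(self.covered + [(start, end)])
        return novel

    def complement(self) -> list[tuple[int, int]]:
        gaps = []
        prev = 0
        for s, e in self.covered:
            if s > prev:
                gaps.append((prev, s))
            prev = e
        if prev < self.target_length:
            gaps.append((prev, self.target_length))
        return gaps


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class ContigAssignment:
    contig_id: str
    gene_candidate_id: str
    supporting_hits: list[AlignmentHit]
    novel_bp: int


@dataclass
class GeneCandidate:
    """A predicted gene whose parts may span several chromosomes/contigs."""

    candidate_id: str
    parts: list[tuple[str, GenomicInterval]]
    chrom_class: dict[str, str] = field(default_factory=dict)
    name: str | None = None
    biotype: str | None = None

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"candidate {self.candidate_id} has no parts")
        for seq_id, _ in self.parts:
            self.chrom_class.setdefault(seq_id, ORDERED)

    @property
    def sequence_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for seq_id, _ in self.parts:
            seen.setdefault(seq_id)
        return list(seen)


def coverage_union(hits: list[AlignmentHit], axis: str = "query") -> CoverageMap:
    """Union of hit intervals on the query or subject axis."""
    if axis not in ("query", "subject"):
        raise ValueError(f"axis must be 'query' or 'subject', got {axis!r}")
    ids = {h.query_id if axis == "query" else h.subject_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"mixed {axis} ids in coverage_union: {sorted(ids)}")
    target_id = next(iter(ids)) if ids else ""
    intervals = [
        (h.q_start - 1, h.q_end) if axis == "query" else (h.s_start - 1, h.s_end)
        for h in hits
    ]
    length = max((e for _, e in intervals), default=0)
    return CoverageMap(target_id, length, intervals)


def _hit_order(h: AlignmentHit) -> tuple:
    # deterministic processing: best bitscore first, then best evalue,
    # then subject id lexicographically
    return (-h.bitscore, h.evalue, h.subject_id, h.s_start)


def assign_contig(
    contig_id: str,
    hits: list[AlignmentHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_novel_bp: int = DEFAULT_MIN_NOVEL_BP,
    contig_length: int | None = None,
    axis: str = "query",
) -> tuple[list[ContigAssignment], CoverageMap]:
    """Assign a contig to gene candidates by sequential novel coverage.

    Hits are processed in descending bitscore order; a hit is accepted when
    its identity strictly exceeds ``min_identity`` and it contributes at
    least ``min_novel_bp`` bases not covered by previously accepted hits
    (novelty measured on the contig/query axis by default).  Returns one
    assignment per gene candidate with accepted hits, plus the final
    contig coverage map.
    """
    for h in hits:
        if h.query_id != contig_id:
            raise ValueError(f"hit query {h.query_id!r} != contig {contig_id!r}")
    if contig_length is None:
        contig_length = max((h.q_end for h in hits), default=0)
    cov = CoverageMap(contig_id, contig_length)
    subject_cov: dict[str, CoverageMap] = {}
    accepted: dict[str, list[AlignmentHit]] = {}
    novel: dict[str, int] = {}
    for h in sorted(hits, key=_hit_order):
        if not h.pct_identity > min_identity:
            continue
        if axis == "query":
            gain = cov.novel_bp(h.q_start - 1, h.q_end)
        else:
            scov = subject_cov.setdefault(
                h.subject_id, CoverageMap(h.subject_id, 10**12)
            )
            gain = scov.novel_bp(h.s_start - 1, h.s_end)
        if gain < min_novel_bp:
            continue
        cov.add(h.q_start - 1, h.q_end)
        if axis == "subject":
            subject_cov[h.subject_id].add(h.s_start - 1, h.s_end)
        accepted.setdefault(h.subject_id, []).append(h)
        novel[h.subject_id] = novel.get(h.subject_id, 0) + gain
    assignments = [
        ContigAssignment(contig_id, subj, accepted[subj], novel[subj])
        for subj in sorted(accepted)
    ]
    return assignments, cov


def uncovered_regions(
    target_length: int,
    cov: CoverageMap,
    min_len: int = DEFAULT_MIN_REGION_BP,
    sequence: str | None = None,
) -> list[GenomicInterval]:
    """Maximal uncovered runs of at least ``min_len`` bp, sorted.

    Runs touching either end of the target qualify.  When the target
    sequence is supplied, ambiguous bases (N) inside a run do not count
    toward its length — gap filler cannot masquerade as novel sequence.
    """
    if cov.target_length != target_length:
        cov = CoverageMap(cov.target_id, target_length, list(cov.covered))
    out = []
    for s, e in cov.complement():
        effective = e - s
        if sequence is not None:
            effective -= sum(1 for b in sequence[s:e] if b in "Nn")
        if effective >= min_len:
            out.append(GenomicInterval(cov.target_id or "target", s, e))
    return out


def classify_genomic_placement(
    contig_hits_on_genome: list[AlignmentHit],
    candidate_features: list[GenomicInterval],
    vicinity_bp: int = DEFAULT_VICINITY_BP,
) -> str:
    """Place a contig relative to a candidate's exon features.

    Returns ``internal_exon`` when the contig's genomic footprint lies
    strictly between two consecutive features (a missed exon),
    ``five_prime_extension`` / ``three_prime_extension`` when it lies
    within ``vicinity_bp`` of the first / last exon in transcriptional
    order (strand-aware: for a minus-strand candidate the first exon is
    the rightmost), and ``unplaced`` otherwise.
    """
    if not contig_hits_on_genome or not candidate_features:
        return "unplaced"
    feats = sorted(candidate_features, key=lambda f: f.start)
    seq_id = feats[0].sequence_id
    strand = feats[0].strand
    on_seq = [h for h in contig_hits_on_genome if h.subject_id == seq_id]
    if not on_seq:
        return "unplaced"
    lo = min(h.s_start - 1 for h in on_seq)
    hi = max(h.s_end for h in on_seq)
    for a, b in zip(feats, feats[1:]):
        if lo >= a.end and hi <= b.start:
            return "internal_exon"
    left_gap_ok = hi <= feats[0].start and feats[0].start - hi <= vicinity_bp
    right_gap_ok = lo >= feats[-1].end and lo - feats[-1].end <= vicinity_bp
    if strand == "-":
        if right_gap_ok:
            return "five_prime_extension"
        if left_gap_ok:
            return "three_prime_extension"
    else:
        if left_gap_ok:
            return "five_prime_extension"
        if right_gap_ok:
            return "three_prime_extension"
    return "unplaced"


def fragmentation_class(candidate: GeneCandidate) -> str:
    """One of single_location / multi_ordered / multi_unplaced / mixed."""
    seq_ids = candidate.sequence_ids
    if len(seq_ids) == 1:
        return "single_location"
    classes = {candidate.chrom_class[s] for s in seq_ids}
    if classes == {ORDERED}:
        return "multi_ordered"
    if classes == {UNPLACED}:
        return "multi_unplaced"
    return "mixed"


def gather_parts(
    assignments: list[ContigAssignment],
    candidates: dict[str, GeneCandidate],
    contig_locations: dict[str, list[tuple[str, GenomicInterval]]],
    contig_class: dict[str, str] | None = None,
) -> tuple[dict[str, GeneCandidate], list[dict]]:
    """Append assigned contigs' genomic locations to their candidates.

    ``contig_locations`` maps contig_id to its genomic placement(s);
    ``contig_class`` optionally tags each location's sequence as ordered/
    unplaced/artificial.  A contig assigned to more than one candidate is
    recorded in the conflicts report and still appended to each (never
    silently resolved).  Candidate identity is never split or merged.
    """
    conflicts: list[dict] = []
    by_contig: dict[str, list[str]] = {}
    for a in assignments:
        by_contig.setdefault(a.contig_id, []).append(a.gene_candidate_id)
    for contig_id, cand_ids in by_contig.items():
        if len(set(cand_ids)) > 1:
            conflicts.append(
                {"contig_id": contig_id, "candidates": sorted(set(cand_ids))}
            )
    for a in assignments:
        cand = candidates.get(a.gene_candidate_id)
        if cand is None:
            continue
        existing = {(s, iv.start, iv.end) for s, iv in cand.parts}
        for seq_id, interval in contig_locations.get(a.contig_id, []):
            key = (seq_id, interval.start, interval.end)
            if key in existing:
                continue
            cand.parts.append((seq_id, interval))
            existing.add(key)
            if contig_class and seq_id in contig_class:
                cand.chrom_class[seq_id] = contig_class[seq_id]
            else:
                cand.chrom_class.setdefault(seq_id, UNPLACED)
    return candidates, conflicts
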