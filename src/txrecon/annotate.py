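"""Tiered gene naming and biotype classification of gene candidates.

Naming cascade: (1) nucleotide hits against bird transcript databases —
identity strictly above 90% for chicken, at least 75% for other birds,
with both query and subject covered on at least 50% of their length;
(2) protein hits against mammal databases — homology of at least 30% and
query coverage of at least 50%, accessions mapped to gene names through a
static table.  Unnamed candidates are then classified by their longest
predicted open reading frame and protein-feature evidence into putative
protein / uncharacterized protein / ncRNA; named candidates matching a
miscellaneous keyword (rRNA, spliceosomal RNA, pseudogene) are set aside
as miscellaneous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io_formats import AlignmentHit, GenomicInterval
from .fragmentation import CoverageMap

CHICKEN_MIN_IDENTITY = 90.0   # strict >
BIRD_MIN_IDENTITY = 75.0      # inclusive >=
MIN_BIDIR_COV = 50.0          # inclusive >=
MIN_PROT_HOMOLOGY = 30.0      # inclusive >=
MIN_PROT_COV = 50.0           # inclusive >=
MIN_ORF_AA = 100              # inclusive >=
DEFAULT_MISC_KEYWORDS = (
    "rRNA", "ribosomal RNA", "snRNA", "spliceosom", "pseudogene",
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

__all__ = [
    "OpenReadingFrame",
    "AnnotationEvidence",
    "BiotypeCall",
    "bidirectional_coverage",
    "assign_name_nt",
    "assign_name_prot",
    "find_orfs",
    "classify_biotype",
    "coverage_vs_reference",
    "name_concordance",
]


@dataclass(frozen=True)
class OpenReadingFrame:
    candidate_id: str
    frame: int
    interval: GenomicInterval   # nucleotide coords on the candidate
    length_aa: int
    completeness: str  # complete | five_prime_partial | three_prime_partial

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0/1/2, got {self.frame}")
        if self.length_aa < 1:
            raise ValueError("ORF must encode at least one amino acid")


@dataclass
class AnnotationEvidence:
    candidate_id: str
    nt_hits: list[tuple[AlignmentHit, str]] = field(default_factory=list)  # (hit, taxon)
    prot_hits: list[AlignmentHit] = field(default_factory=list)
    prot_homology: dict[int, float] = field(default_factory=dict)  # index -> % positives
    orfs: list[OpenReadingFrame] = field(default_factory=list)
    has_domain: bool = False
    has_signal_peptide: bool = False
    has_tm_domain: bool = False
    mapped_gene_names: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class BiotypeCall:
    candidate_id: str
    biotype: str  # protein_coding_named | putative_protein | uncharacterized_protein | ncRNA | miscellaneous
    name: str | None
    evidence_tier: str

    def __post_init__(self) -> None:
        named = self.biotype in ("protein_coding_named", "miscellaneous")
        if named != (self.name is not None):
            raise ValueError(
                f"{self.candidate_id}: name must be present iff biotype is "
                "protein_coding_named or miscellaneous"
            )


# ---------------------------------------------------------------------------
# coverage helpers

def _union_bp(intervals: list[tuple[int, int]], length: int) -> int:
    if not intervals:
        return 0
    cov = CoverageMap("x", max(length, max(e for _, e in intervals)), intervals)
    return cov.covered_bp


def bidirectional_coverage(
    candidate_len: int, subject_len: int, hits: list[AlignmentHit]
) -> tuple[float, float]:
    """Union coverage of the query and of the subject, as percentages."""
    q = _union_bp([(h.q_start - 1, h.q_end) for h in hits], candidate_len)
    s = _union_bp([(h.s_start - 1, h.s_end) for h in hits], subject_len)
    q_pct = 100.0 * q / candidate_len if candidate_len else 0.0
    s_pct = 100.0 * s / subject_len if subject_len else 0.0
    return q_pct, s_pct


# ---------------------------------------------------------------------------
# naming tiers

def assign_name_nt(
    candidate_id: str,
    candidate_len: int,
    nt_hits: list[tuple[AlignmentHit, str]],
    subject_lengths: dict[str, int],
    subject_names: dict[str, str],
    chicken_min_id: float = CHICKEN_MIN_IDENTITY,
    bird_min_id: float = BIRD_MIN_IDENTITY,
    min_bidir_cov: float = MIN_BIDIR_COV,
) -> tuple[tuple[str, str] | None, bool]:
    """Nucleotide naming tier.

    A subject gene qualifies when its best-identity hit passes the taxon
    threshold (chicken: strictly above ``chicken_min_id``; other birds: at
    least ``bird_min_id``) and the union of its hits covers at least
    ``min_bidir_cov`` percent of *both* the candidate and the subject.
    Among qualifying gene names the highest total bitscore wins; two or
    more distinct surviving names raise the discordance flag (manual
    review queue for chimeric/fused candidates).

    Returns ``((name, tier) | None, discordant)``.
    """
    by_subject: dict[str, list[tuple[AlignmentHit, str]]] = {}
    for hit, taxon in nt_hits:
        by_subject.setdefault(hit.subject_id, []).append((hit, taxon))
    name_scores: dict[str, float] = {}
    for subject_id, entries in sorted(by_subject.items()):
        hits = [h for h, _ in entries]
        qualifying = [
            h
            for h, taxon in entries
            if (taxon == "chicken" and h.pct_identity > chicken_min_id)
            or (taxon == "other_bird" and h.pct_identity >= bird_min_id)
        ]
        if not qualifying:
            continue
        q_cov, s_cov = bidirectional_coverage(
            candidate_len, subject_lengths.get(subject_id, 0), hits
        )
        if q_cov < min_bidir_cov or s_cov < min_bidir_cov:
            continue
        name = subject_names.get(subject_id, subject_id)
        name_scores[name] = name_scores.get(name, 0.0) + sum(
            h.bitscore for h in qualifying
        )
    if not name_scores:
        return None, False
    best = max(sorted(name_scores), key=lambda n: name_scores[n])
    return (best, "nt"), len(name_scores) > 1


def assign_name_prot(
    candidate_id: str,
    prot_hits: list[AlignmentHit],
    homology: dict[int, float],
    coverage: dict[int, float],
    accession_map: dict[str, str],
    min_homology: float = MIN_PROT_HOMOLOGY,
    min_cov: float = MIN_PROT_COV,
) -> tuple[tuple[str, str] | None, list[str]]:
    """Protein naming tier, for candidates the nucleotide tier left unnamed.

    ``homology`` and ``coverage`` give, per hit index, the percentage of
    positives and the candidate length coverage.  Accessions without a
    mapping are ignored with a warning entry.  Returns
    ``((name, tier) | None, warnings)``.
    """
    name_scores: dict[str, float] = {}
    warned: list[str] = []
    for i, hit in enumerate(prot_hits):
        if homology.get(i, 0.0) < min_homology:
            continue
        if coverage.get(i, 0.0) < min_cov:
            continue
        name = accession_map.get(hit.subject_id)
        if name is None:
            warned.append(f"unmapped protein accession {hit.subject_id}")
            continue
        name_scores[name] = name_scores.get(name, 0.0) + hit.bitscore
    if not name_scores:
        return None, warned
    best = max(sorted(name_scores), key=lambda n: name_scores[n])
    return (best, "prot"), warned


# ---------------------------------------------------------------------------
# ORF prediction

def find_orfs(
    sequence: str, candidate_id: str = "", strand_specific: bool = True
) -> list[OpenReadingFrame]:
    """Maximal ORFs in the three forward frames (forward-only when strand
    specific, matching a stranded library).

    Reports complete ORFs (first ATG after the previous stop, through the
    stop), 3'-partial ORFs running off the sequence end (from the first
    ATG of the last open segment) and 5'-partial ORFs starting at the
    sequence edge before any stop.  Amino-acid length excludes the stop
    codon.  Sorted by length descending.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    frames = [0, 1, 2]
    orfs: list[OpenReadingFrame] = []
    strands = [seq] if strand_specific else [seq, _revcomp(seq)]
    for strand_seq in strands:
        for frame in frames:
            orfs.extend(_scan_frame(strand_seq, frame, candidate_id))
    return sorted(orfs, key=lambda o: (-o.length_aa, o.frame, o.interval.start))


def _scan_frame(seq: str, frame: int, candidate_id: str) -> list[OpenReadingFrame]:
    """One maximal ORF per stop-free codon segment.

    A segment qualifies as an ORF only when it contains an ATG or ends at
    a stop codon.  A qualifying segment touching the 5' edge is read from
    the edge (complete when it starts with ATG and ends at a stop,
    5'-partial otherwise); an interior segment is read from its first ATG
    (complete when stop-terminated, 3'-partial when it runs off the end).
    """
    codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
    orfs = []
    seg_start = 0
    at_edge = True  # no stop seen upstream of the current segment
    for idx in range(len(codons) + 1):
        at_end = idx == len(codons)
        if not at_end and codons[idx] not in STOP_CODONS:
            continue
        seg = codons[seg_start:idx]
        atg = next((k for k, c in enumerate(seg) if c == "ATG"), None)
        orf_start = None
        if at_edge and seg and (atg is not None or not at_end):
            orf_start = seg_start  # open at the 5' edge: read from frame start
            complete = atg == 0 and not at_end
        elif not at_edge and atg is not None:
            orf_start = seg_start + atg
            complete = not at_end
        if orf_start is not None:
            aa = idx - orf_start
            if aa >= 1:
                if complete:
                    kind = "complete"
                elif at_end and orf_start == seg_start + (atg or 0) and atg is not None:
                    kind = "three_prime_partial"
                else:
                    kind = "five_prime_partial"
                if at_edge and at_end and atg != 0:
                    kind = "five_prime_partial"
                orfs.append(_mk_orf(candidate_id, frame, orf_start, idx, aa, kind))
        seg_start = idx + 1
        at_edge = False
    return orfs


def _mk_orf(
    candidate_id: str, frame: int, codon_start: int, codon_end: int, aa: int, kind: str
) -> OpenReadingFrame:
    nt_start = frame + 3 * codon_start
    nt_end = frame + 3 * codon_end
    return OpenReadingFrame(
        candidate_id, frame, GenomicInterval(candidate_id or "seq", nt_start, nt_end, "+"),
        aa, kind,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# biotype cascade

def classify_biotype(
    evidence: AnnotationEvidence,
    name: str | None,
    misc_keywords: tuple[str, ...] = DEFAULT_MISC_KEYWORDS,
    min_orf_aa: int = MIN_ORF_AA,
) -> BiotypeCall:
    """Decision cascade producing exactly one biotype per candidate.

    1. named and the name matches a miscellaneous keyword -> miscellaneous;
    2. named otherwise -> protein_coding_named;
    3. unnamed, longest ORF >= ``min_orf_aa`` aa, protein-feature evidence
       (domain, signal peptide or transmembrane domain) -> putative_protein;
    4. unnamed, longest ORF >= ``min_orf_aa`` aa, no feature evidence ->
       uncharacterized_protein;
    5. otherwise -> ncRNA.
    """
    cid = evidence.candidate_id
    if name is not None:
        if any(re.search(kw, name, re.IGNORECASE) for kw in misc_keywords):
            return BiotypeCall(cid, "miscellaneous", name, "misc_keyword")
        return BiotypeCall(cid, "protein_coding_named", name, "named")
    longest = max((o.length_aa for o in evidence.orfs), default=0)
    if longest >= min_orf_aa:
        if evidence.has_domain or evidence.has_signal_peptide or evidence.has_tm_domain:
            return BiotypeCall(cid, "putative_protein", None, "orf_with_domain")
        return BiotypeCall(cid, "uncharacterized_protein", None, "orf_no_domain")
    return BiotypeCall(cid, "ncRNA", None, "short_orf")


# ---------------------------------------------------------------------------
# comparison against a reference annotation

def coverage_vs_reference(
    candidate_len: int, ref_hits: list[AlignmentHit]
) -> tuple[float, str]:
    """Union length-coverage of the candidate by reference gene hits, and
    its bin: ``zero`` (no hits at all), ``below_50`` or ``at_least_50``."""
    if not ref_hits:
        return 0.0, "zero"
    covered = _union_bp([(h.q_start - 1, h.q_end) for h in ref_hits], candidate_len)
    pct = 100.0 * covered / candidate_len if candidate_len else 0.0
    return pct, ("at_least_50" if pct >= 50.0 else "below_50")


def name_concordance(
    candidate_name: str | None,
    ref_hits_with_names: list[tuple[AlignmentHit, str | None, float]],
    min_len_cov: float = 50.0,
    synonyms: dict[str, str] | None = None,
) -> str:
    """Compare the candidate's assigned name with reference gene names.

    ``ref_hits_with_names`` carries (hit, reference gene name or None,
    candidate length coverage %).  Only hits covering at least
    ``min_len_cov`` percent qualify; the best (highest bitscore) such
    hit decides: ``concordant`` when names match case-insensitively after
    applying the synonym table, ``matched_undefined`` when the reference
    gene has no symbol, ``discordant`` otherwise, ``no_match`` when no
    hit qualifies.
    """
    qualifying = [
        (hit, ref_name)
        for hit, ref_name, cov in ref_hits_with_names
        if cov >= min_len_cov
    ]
    if not qualifying:
        return "no_match"
    best_hit, best_name = max(qualifying, key=lambda x: x[0].bitscore)
    if best_name is None or best_name == "":
        return "matched_undefined"
    syn = synonyms or {}
    canon = lambda n: syn.get(n.upper(), n.upper())
    if candidate_name is not None and canon(candidate_name) == canon(best_name):
        return "concordant"
    return "discordant"
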