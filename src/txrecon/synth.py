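"""Deterministic toy-world generator and fixture oracles.

Emulates the study design every other module is tested against: a
fragmented draft genome (ordered chromosomes, unplaced contigs, N gaps),
multi-isoform genes whose sequence may be partly or wholly absent from
the genome, strand-specific 50-bp paired-end reads with a 150-bp insert
(fr-firststrand chemistry), and tabular alignment-hit tables consistent
with the toy sequences.  All generators are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AlignmentHit, GenomicInterval, TranscriptModel

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = "ACGT"

__all__ = [
    "ToyWorldConfig",
    "GeneTruth",
    "ReadPairTruth",
    "ToyWorld",
    "make_toy_world",
    "make_isoforms",
    "simulate_read_pairs",
    "pairs_to_sam",
    "toy_align",
    "write_sam",
]


@dataclass
class ToyWorldConfig:
    """Study conditions for the toy world.

    Read geometry follows the sequencing design (50-bp mates, 150-bp
    insert, fr-firststrand); structural fractions default to values that
    exercise every fragmentation class and biotype at small scale.
    """

    n_ordered_chromosomes: int = 2
    n_unplaced_contigs: int = 4
    n_genes: int = 12
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exon_length_range: tuple[int, int] = (200, 400)
    intron_length_range: tuple[int, int] = (100, 300)
    exons_per_gene: tuple[int, int] = (3, 6)
    fraction_fragmented: float = 0.25
    fraction_missing_from_genome: float = 0.2
    read_length: int = 50
    insert_size: int = 150
    library: str = "fr-firststrand"
    low_quality_fraction: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("fraction_fragmented", "fraction_missing_from_genome",
                     "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("isoforms_per_gene", "exon_length_range",
                     "intron_length_range", "exons_per_gene"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive range")

    @property
    def fragment_length(self) -> int:
        return 2 * self.read_length + self.insert_size


@dataclass
class GeneTruth:
    """Everything known by construction about one toy gene."""

    gene_id: str
    name: str | None
    biotype: str
    exon_seqs: list[str]
    # (sequence_id, genomic start) per exon; None when absent from the genome
    exon_locs: list[tuple[str, int] | None]
    isoforms: dict[str, list[int]] = field(default_factory=dict)
    strand: str = "+"

    @property
    def supertranscript(self) -> str:
        present = sorted({i for idx in self.isoforms.values() for i in idx})
        return "".join(self.exon_seqs[i] for i in present)

    @property
    def isoform_seqs(self) -> dict[str, str]:
        return {
            iso: "".join(self.exon_seqs[i] for i in idx)
            for iso, idx in self.isoforms.items()
        }

    @property
    def hidden_exons(self) -> list[int]:
        return [i for i, loc in enumerate(self.exon_locs) if loc is None]

    @property
    def visible_seqids(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.exon_locs:
            if loc is not None:
                seen.setdefault(loc[0])
        return list(seen)


@dataclass
class ReadPairTruth:
    pair_id: str
    transcript_id: str
    gene_id: str
    frag_start: int  # on the transcript
    frag_end: int
    low_quality_mate: int  # 0 = none, 1, 2, or 3 = both


@dataclass
class ToyWorld:
    config: ToyWorldConfig
    genome: dict[str, str]
    chrom_class: dict[str, str]  # sequence_id -> ordered | unplaced
    candidate_models: list[TranscriptModel]  # genome-guided truth annotation
    genes: dict[str, GeneTruth]


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _max_open_stretch(seq: str) -> int:
    """Longest stop-free stretch (nt) over the three forward frames,
    counting from the sequence edge as open."""
    best = 0
    for frame in range(3):
        run = 0
        for i in range(frame, len(seq) - 2, 3):
            if seq[i : i + 3] in STOP_CODONS:
                best = max(best, run)
                run = 0
            else:
                run += 3
        best = max(best, run)
    return best


def _noncoding_seq(rng: np.random.Generator, length: int, max_orf_nt: int = 240) -> str:
    """Random sequence whose longest stop-free forward stretch stays well
    below the 100-codon ORF threshold."""
    for _ in range(200):
        seq = _random_seq(rng, length)
        if _max_open_stretch(seq) < max_orf_nt:
            return seq
    raise RuntimeError("could not draw a non-coding sequence; length too large")


def _coding_mrna(rng: np.random.Generator, total_len: int, orf_aa: int = 120) -> str:
    """mRNA with a clean embedded ORF: stop-terminated 5' UTR without ATG,
    ATG + ``orf_aa - 1`` sense codons + stop, noncoding 3' UTR."""
    orf_nt = 3 * orf_aa + 3
    utr5_len = max(9, (total_len - orf_nt) // 3)
    utr3_len = total_len - orf_nt - utr5_len
    utr5 = _noncoding_seq(rng, utr5_len - 3).replace("ATG", "ATC") + "TAA"
    codons = []
    while len(codons) < orf_aa - 1:
        c = _random_seq(rng, 3)
        if c not in STOP_CODONS and c != "ATG":
            codons.append(c)
    utr3 = _noncoding_seq(rng, max(utr3_len, 9))
    return utr5 + "ATG" + "".join(codons) + "TAA" + utr3


# ---------------------------------------------------------------------------
# toy world

_BIOTYPE_CYCLE = (
    "protein_coding_named",
    "protein_coding_named",
    "ncRNA",
    "protein_coding_named",
    "uncharacterized_protein",
    "protein_coding_named",
    "putative_protein",
    "ncRNA",
    "protein_coding_named",
    "miscellaneous",
)


def make_toy_world(config: ToyWorldConfig) -> ToyWorld:
    """Build a deterministic toy genome, gene truth and candidate annotation.

    ``fraction_fragmented`` of genes have their exons split across an
    ordered chromosome and/or unplaced contigs; for
    ``fraction_missing_from_genome`` of genes a terminal run of exons (or
    the whole gene) is absent from the genome and present only in the
    transcripts.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_ordered_chromosomes)]
    contigs = [f"contig_{i + 1:04d}" for i in range(config.n_unplaced_contigs)]
    chrom_class = {c: "ordered" for c in chroms}
    chrom_class.update({c: "unplaced" for c in contigs})
    parts: dict[str, list[str]] = {c: [_random_seq(rng, 200)] for c in chroms + contigs}
    cursors: dict[str, int] = {c: 200 for c in chroms + contigs}

    n_frag = round(config.fraction_fragmented * config.n_genes)
    n_hidden = round(config.fraction_missing_from_genome * config.n_genes)
    frag_ids = set(rng.choice(config.n_genes, size=n_frag, replace=False).tolist())
    non_frag = [i for i in range(config.n_genes) if i not in frag_ids]
    hidden_ids = set(
        rng.choice(non_frag, size=min(n_hidden, len(non_frag)), replace=False).tolist()
    )

    genes: dict[str, GeneTruth] = {}
    candidate_models: list[TranscriptModel] = []
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:04d}"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [
            int(rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1))
            for _ in range(n_exons)
        ]
        biotype = _BIOTYPE_CYCLE[g % len(_BIOTYPE_CYCLE)]
        total = sum(exon_lens)
        if biotype in ("protein_coding_named", "putative_protein",
                       "uncharacterized_protein", "miscellaneous"):
            mrna = _coding_mrna(rng, total)
        else:
            mrna = _noncoding_seq(rng, total)
        exon_seqs, pos = [], 0
        for L in exon_lens:
            exon_seqs.append(mrna[pos : pos + L])
            pos += L
        name = None
        if biotype == "protein_coding_named":
            name = f"TOYG{g + 1}"
        elif biotype == "miscellaneous":
            name = f"RN{g + 1}-rRNA"

        # decide where each exon lives
        placement_runs = _placement_runs(
            rng, n_exons, exon_lens, g in frag_ids, g in hidden_ids, chroms, contigs
        )
        exon_locs: list[tuple[str, int] | None] = [None] * n_exons
        for seqid, exon_idx in placement_runs:
            if seqid is None:
                continue
            cursors[seqid] += _append(parts, seqid, _random_seq(rng, 300))
            if rng.random() < 0.3:
                cursors[seqid] += _append(parts, seqid, "N" * 100)
            for j, ei in enumerate(exon_idx):
                if j > 0:
                    intron = _random_seq(
                        rng,
                        int(rng.integers(config.intron_length_range[0],
                                         config.intron_length_range[1] + 1)),
                    )
                    cursors[seqid] += _append(parts, seqid, intron)
                exon_locs[ei] = (seqid, cursors[seqid])
                cursors[seqid] += _append(parts, seqid, exon_seqs[ei])

        truth = GeneTruth(gene_id, name, biotype, exon_seqs, exon_locs)
        genes[gene_id] = truth

        # genome-guided candidate annotation: one transcript per visible run
        for p, (seqid, exon_idx) in enumerate(placement_runs):
            if seqid is None:
                continue
            exons = [
                GenomicInterval(seqid, exon_locs[ei][1],
                                exon_locs[ei][1] + len(exon_seqs[ei]), "+")
                for ei in exon_idx
            ]
            candidate_models.append(
                TranscriptModel(f"{gene_id}.p{p + 1}", gene_id, exons, source="guided")
            )

    for c in chroms + contigs:
        parts[c].append(_random_seq(rng, 200))
    genome = {c: "".join(parts[c]) for c in chroms + contigs}

    world = ToyWorld(config, genome, chrom_class, candidate_models, genes)
    for gene_id, truth in genes.items():
        k = int(rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1))
        make_isoforms(truth, k, int(rng.integers(0, 2**31 - 1)))
    return world


def _append(parts: dict[str, list[str]], seqid: str, chunk: str) -> int:
    parts[seqid].append(chunk)
    return len(chunk)


def _placement_runs(
    rng: np.random.Generator,
    n_exons: int,
    exon_lens: list[int],
    fragmented: bool,
    hidden: bool,
    chroms: list[str],
    contigs: list[str],
) -> list[tuple[str | None, list[int]]]:
    """Split the exon chain into runs and give each run a home sequence
    (or None for a hidden run of at least ~400 bp)."""
    home = chroms[int(rng.integers(0, len(chroms)))]
    idx = list(range(n_exons))
    if hidden:
        # hide a terminal run totalling >= 400 bp, or the whole gene
        if rng.random() < 0.4:
            return [(None, idx)]
        cut = n_exons - 1
        while cut > 1 and sum(exon_lens[cut:]) < 400:
            cut -= 1
        return [(home, idx[:cut]), (None, idx[cut:])]
    if fragmented and n_exons >= 2:
        cut = int(rng.integers(1, n_exons))
        style = rng.random()
        if style < 0.5 or len(chroms) < 2:
            other = contigs[int(rng.integers(0, len(contigs)))]
        elif style < 0.75:
            other = [c for c in chroms if c != home][0]
        else:
            home = contigs[int(rng.integers(0, len(contigs)))]
            other = [c for c in contigs if c != home][int(rng.integers(0, len(contigs) - 1))]
        return [(home, idx[:cut]), (other, idx[cut:])]
    return [(home, idx)]


# ---------------------------------------------------------------------------
# isoforms

def make_isoforms(gene_truth: GeneTruth, k: int, seed: int) -> dict[str, str]:
    """Define k isoforms as exon-index subsets sharing the terminal exons.

    Internal exons are either common to all isoforms, skipped by exactly
    one isoform, or private to exactly one isoform (no two private exons
    adjacent), so the exon-block oracle superTranscript — every exon once,
    in transcriptional order — is recoverable by pairwise ungapped merging.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(gene_truth.exon_seqs)
    all_idx = list(range(n))
    gene_truth.isoforms = {}
    if k == 1 or n <= 2:
        for i in range(k):
            gene_truth.isoforms[f"{gene_truth.gene_id}_i{i + 1}"] = list(all_idx)
        return gene_truth.isoform_seqs
    internal = list(range(1, n - 1))
    private_owner: dict[int, int] = {}  # exon -> isoform index
    skips: dict[int, int] = {}          # exon -> isoform that skips it
    for i in range(1, k):
        free = [
            e for e in internal
            if e not in private_owner and e not in skips
            and e - 1 not in private_owner and e + 1 not in private_owner
        ]
        if not free:
            break
        e = int(rng.choice(free))
        if rng.random() < 0.5:
            private_owner[e] = i
        else:
            skips[e] = i
    for i in range(k):
        iso = []
        for e in all_idx:
            if e in private_owner:
                keep = private_owner[e] == i
            elif e in skips:
                keep = skips[e] != i
            else:
                keep = True
            if keep:
                iso.append(e)
        gene_truth.isoforms[f"{gene_truth.gene_id}_i{i + 1}"] = iso
    return gene_truth.isoform_seqs


# ---------------------------------------------------------------------------
# read simulation

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _qualities(rng: np.random.Generator, length: int, low: bool) -> list[int]:
    # two-component quality model: Phred 38 +- 2 (good) vs 24 +- 2 (bad)
    centre = 24 if low else 38
    q = rng.normal(centre, 2.0, size=length).round().astype(int)
    return np.clip(q, 2, 41).tolist()


def simulate_read_pairs(
    transcripts: dict[str, tuple[str, str]],
    n_pairs: int,
    config: ToyWorldConfig,
    seed: int,
) -> tuple[list[tuple[str, str, list[int]]], list[tuple[str, str, list[int]]],
           list[ReadPairTruth]]:
    """Simulate stranded paired-end reads from transcript sequences.

    ``transcripts`` maps transcript_id -> (gene_id, sequence).  Fragments
    of fixed length (2 x read + insert) are placed uniformly along
    transcripts long enough to hold one; fr-firststrand orientation means
    the first-in-pair read is the reverse complement of the fragment's 3'
    end.  A ``low_quality_fraction`` of mates is drawn from the low
    quality component so the QC gate has work to do.

    Returns (reads1, reads2, truth) with reads as (id, seq, qualities).
    """
    rng = np.random.default_rng(seed)
    frag_len = config.fragment_length
    eligible = [
        (tid, gid, seq) for tid, (gid, seq) in sorted(transcripts.items())
        if len(seq) >= frag_len
    ]
    if not eligible:
        raise ValueError(f"no transcript is at least {frag_len} bp long")
    reads1, reads2, truth = [], [], []
    for i in range(n_pairs):
        tid, gid, seq = eligible[int(rng.integers(0, len(eligible)))]
        start = int(rng.integers(0, len(seq) - frag_len + 1))
        frag = seq[start : start + frag_len]
        r2 = frag[: config.read_length]                      # sense, second in pair
        r1 = _revcomp(frag[-config.read_length :])           # antisense, first in pair
        low1 = rng.random() < config.low_quality_fraction
        low2 = rng.random() < config.low_quality_fraction
        pair_id = f"pair{i + 1:06d}"
        reads1.append((pair_id, r1, _qualities(rng, config.read_length, low1)))
        reads2.append((pair_id, r2, _qualities(rng, config.read_length, low2)))
        truth.append(
            ReadPairTruth(pair_id, tid, gid, start, start + frag_len,
                          (1 if low1 else 0) + (2 if low2 else 0))
        )
    return reads1, reads2, truth


# ---------------------------------------------------------------------------
# alignment-free conversion of simulated pairs to SAM records

def _transcript_layout(
    truth: GeneTruth, exon_idx: list[int]
) -> list[tuple[int, int, str | None, int]]:
    """Per exon of one isoform: (transcript offset, length, seqid, genomic
    start); seqid None for hidden exons."""
    layout = []
    offset = 0
    for ei in exon_idx:
        L = len(truth.exon_seqs[ei])
        loc = truth.exon_locs[ei]
        layout.append((offset, L, loc[0] if loc else None, loc[1] if loc else -1))
        offset += L
    return layout


def _map_mate(
    layout: list[tuple[int, int, str | None, int]], t_start: int, t_end: int
) -> tuple[str, int, str] | None:
    """Map a transcript interval to (seqid, 1-based pos, CIGAR) through the
    exon layout; spliced across exons on one sequence, None if any base
    falls on a hidden exon or the exons straddle two sequences."""
    pieces: list[tuple[str, int, int]] = []  # (seqid, genomic start, len)
    for off, L, seqid, gstart in layout:
        lo, hi = max(t_start, off), min(t_end, off + L)
        if lo >= hi:
            continue
        if seqid is None:
            return None
        pieces.append((seqid, gstart + (lo - off), hi - lo))
    if not pieces or len({s for s, _, _ in pieces}) != 1:
        return None
    cigar = ""
    for j, (seqid, gstart, L) in enumerate(pieces):
        if j > 0:
            gap = gstart - (pieces[j - 1][1] + pieces[j - 1][2])
            if gap < 0:
                return None
            if gap > 0:
                cigar += f"{gap}N"
        cigar += f"{L}M"
    return pieces[0][0], pieces[0][1] + 1, cigar


def pairs_to_sam(
    world: ToyWorld,
    pair_truth: list[ReadPairTruth],
    extra_refs: dict[str, str] | None = None,
    duplicate_pairs: set[str] | None = None,
    seed: int = 0,
) -> list[str]:
    """Emulate a spliced aligner on the simulated pairs.

    Each mate is placed on the genome through the truth exon layout
    (spliced CIGARs across introns); mates whose sequence is absent from
    the genome are searched for exactly in ``extra_refs`` (the artificial
    chromosome).  Pairs with any unmappable mate are emitted as unmapped.
    Returns SAM lines including an @SQ header.
    """
    extra_refs = extra_refs or {}
    duplicate_pairs = duplicate_pairs or set()
    refs = dict(world.genome)
    refs.update(extra_refs)
    layouts = {}
    for gene in world.genes.values():
        for iso_id, exon_idx in gene.isoforms.items():
            layouts[iso_id] = _transcript_layout(gene, exon_idx)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in refs:
        lines.append(f"@SQ\tSN:{name}\tLN:{len(refs[name])}")
    rl = world.config.read_length
    for pt in pair_truth:
        layout = layouts[pt.transcript_id]
        m2 = _map_mate(layout, pt.frag_start, pt.frag_start + rl)
        m1 = _map_mate(layout, pt.frag_end - rl, pt.frag_end)
        gene = world.genes[pt.gene_id]
        iso_seq = gene.isoform_seqs[pt.transcript_id]
        if m2 is None:
            m2 = _search_extra(iso_seq[pt.frag_start : pt.frag_start + rl], extra_refs)
        if m1 is None:
            m1 = _search_extra(iso_seq[pt.frag_end - rl : pt.frag_end], extra_refs)
        dup = 0x400 if pt.pair_id in duplicate_pairs else 0
        seq2 = iso_seq[pt.frag_start : pt.frag_start + rl]
        seq1 = _revcomp(iso_seq[pt.frag_end - rl : pt.frag_end])
        if m1 is None or m2 is None:
            flag1 = 0x1 | 0x4 | 0x8 | 0x40
            flag2 = 0x1 | 0x4 | 0x8 | 0x80
            lines.append(_sam_line(pt.pair_id, flag1, "*", 0, 0, "*", seq1))
            lines.append(_sam_line(pt.pair_id, flag2, "*", 0, 0, "*", seq2))
            continue
        ref1, pos1, cig1 = m1
        ref2, pos2, cig2 = m2
        # fr-firststrand, transcript on plus strand: mate1 reverse, mate2 forward
        flag1 = 0x1 | 0x10 | 0x40 | dup
        flag2 = 0x1 | 0x20 | 0x80 | dup
        lines.append(_sam_line(pt.pair_id, flag1, ref1, pos1, 60, cig1, seq1))
        lines.append(_sam_line(pt.pair_id, flag2, ref2, pos2, 60, cig2, seq2))
    return lines


def _search_extra(mate_seq: str, extra_refs: dict[str, str]) -> tuple[str, int, str] | None:
    for name, seq in extra_refs.items():
        hit = seq.find(mate_seq)
        if hit >= 0:
            return name, hit + 1, f"{len(mate_seq)}M"
    return None


def _sam_line(qname: str, flag: int, rname: str, pos: int, mapq: int,
              cigar: str, seq: str) -> str:
    return "\t".join(
        (qname, str(flag), rname, str(pos), str(mapq), cigar,
         "*", "0", "0", seq, "I" * len(seq))
    )


def write_sam(lines: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# toy aligner (fixture oracle standing in for the external search tool)

def toy_align(
    queries: dict[str, str],
    subjects: dict[str, str],
    min_identity: float = 90.0,
    ungapped: bool = True,
    min_len: int = 20,
) -> list[AlignmentHit]:
    """Exhaustive exact ungapped plus-strand local matches as alignment hits.

    Seed-and-extend with exact k-mer seeds; every maximal exact match of at
    least ``min_len`` bp is reported once, at 100% identity, with a toy
    bitscore of twice its length.  Intended for sequences of a few kb.
    """
    hits: list[AlignmentHit] = []
    k = min(min_len, 16)
    for sid, sseq in sorted(subjects.items()):
        index: dict[str, list[int]] = {}
        for i in range(len(sseq) - k + 1):
            index.setdefault(sseq[i : i + k], []).append(i)
        for qid, qseq in sorted(queries.items()):
            seen: set[tuple[int, int]] = set()  # (diagonal, start) of maximal matches
            for j in range(len(qseq) - k + 1):
                for i in index.get(qseq[j : j + k], ()):  # subject position
                    d = i - j
                    qs, ss = j, i
                    while qs > 0 and ss > 0 and qseq[qs - 1] == sseq[ss - 1]:
                        qs -= 1
                        ss -= 1
                    if (d, qs) in seen:
                        continue
                    seen.add((d, qs))
                    qe, se = j + k, i + k
                    while qe < len(qseq) and se < len(sseq) and qseq[qe] == sseq[se]:
                        qe += 1
                        se += 1
                    if qe - qs >= min_len:
                        hits.append(
                            AlignmentHit.from_coords(
                                qid, sid, 100.0, qe - qs, 0, 0,
                                qs + 1, qe, ss + 1, se,
                                1e-180, 2.0 * (qe - qs),
                            )
                        )
    return hits
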