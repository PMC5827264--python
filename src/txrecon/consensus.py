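"""Non-redundant consensus gene (superTranscript) construction.

Isoforms of one gene candidate are folded into a single consensus
sequence: ungapped plus-strand shared blocks between the running
consensus and each isoform are identified, identical sequence is kept
once, and sequence unique to an isoform is inserted at the corresponding
position.  An isoform sharing nothing with the consensus is appended
rather than discarded, so transcript-specific sequence is never lost.
Retained sequences are finally concatenated into an artificial
chromosome, separated by N spacers sized to the sequenced fragment
length, so that reads from genome-absent regions can be mapped and
counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomicInterval, TranscriptModel

DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_MIN_BLOCK = 20    # folding-level floor against spurious micro-matches
DEFAULT_SPACER = 250      # read pair footprint: 50 + 150 insert + 50

__all__ = [
    "SharedBlock",
    "ConsensusGene",
    "ArtificialChromosome",
    "shared_blocks",
    "merge_isoform",
    "build_consensus",
    "build_artificial_chromosome",
]


@dataclass(frozen=True)
class SharedBlock:
    """An ungapped identical (or near-identical) segment shared between the
    current consensus and one isoform; equal-length on both sequences."""

    consensus_interval: GenomicInterval
    isoform_interval: GenomicInterval
    pct_identity: float

    def __post_init__(self) -> None:
        if len(self.consensus_interval) != len(self.isoform_interval):
            raise ValueError("ungapped block must have equal lengths")

    @property
    def length(self) -> int:
        return len(self.consensus_interval)


@dataclass
class _Segment:
    """One atomic stretch of consensus sequence with its provenance."""

    isoform_id: str
    i_start: int
    i_end: int
    text: str


@dataclass
class ConsensusGene:
    candidate_id: str
    segments: list[_Segment] = field(default_factory=list)
    isoform_maps: dict[str, list[tuple[tuple[int, int], tuple[int, int]]]] = field(
        default_factory=dict
    )

    @property
    def sequence(self) -> str:
        return "".join(s.text for s in self.segments)

    @property
    def provenance(self) -> list[tuple[GenomicInterval, str, GenomicInterval]]:
        """Ordered tiling of the consensus: (consensus interval, contributing
        isoform, interval on that isoform)."""
        out = []
        pos = 0
        for s in self.segments:
            out.append(
                (
                    GenomicInterval("consensus", pos, pos + len(s.text)),
                    s.isoform_id,
                    GenomicInterval(s.isoform_id, s.i_start, s.i_end),
                )
            )
            pos += len(s.text)
        return out


# ---------------------------------------------------------------------------
# shared block detection (ungapped, plus strand only)

def shared_blocks(
    consensus_seq: str,
    isoform_seq: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_block: int = 1,
) -> list[SharedBlock]:
    """Maximal ungapped plus-strand local matches, mutually non-overlapping.

    Candidate segments are found per diagonal: maximal exact-match runs,
    plus X-drop extensions of those runs across mismatches (match +1,
    mismatch -3, drop-off 12) kept when their identity stays >=
    min_identity.  Selection is greedy by descending length (ties:
    leftmost on the consensus), rejecting any candidate overlapping an
    accepted block on either sequence.  Only the plus strand is searched.
    """
    if not consensus_seq or not isoform_seq:
        raise ValueError("both sequences must be non-empty")
    a = np.frombuffer(consensus_seq.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(isoform_seq.upper().encode(), dtype=np.uint8)
    n, m = len(a), len(b)
    candidates: list[tuple[int, int, int, float]] = []  # (c_start, i_start, L, id)
    for d in range(-(m - 1), n):
        c0 = max(d, 0)
        i0 = c0 - d
        length = min(n - c0, m - i0)
        if length < min_block:
            continue
        matches = a[c0 : c0 + length] == b[i0 : i0 + length]
        for start, end, ident in _diagonal_segments(matches, min_identity / 100.0,
                                                    min_block):
            candidates.append((c0 + start, i0 + start, end - start, ident * 100))
    candidates.sort(key=lambda c: (-c[2], c[0], c[1]))
    accepted: list[tuple[int, int, int, float]] = []
    for c_start, i_start, length, _ in candidates:
        trimmed = _trim_against(c_start, i_start, length, accepted)
        if trimmed is None:
            continue
        cs, is_, L = trimmed
        if L < min_block:
            continue
        ident = 100.0 * float(
            np.count_nonzero(a[cs : cs + L] == b[is_ : is_ + L])
        ) / L
        if ident >= min_identity:
            accepted.append((cs, is_, L, ident))
    accepted.sort(key=lambda c: c[0])
    return [
        SharedBlock(
            GenomicInterval("consensus", cs, cs + L, "+"),
            GenomicInterval("isoform", is_, is_ + L, "+"),
            round(ident, 2),
        )
        for cs, is_, L, ident in accepted
    ]


def _trim_against(
    c_start: int, i_start: int, length: int,
    accepted: list[tuple[int, int, int, float]],
) -> tuple[int, int, int] | None:
    """Trim a candidate block's ends until it overlaps no accepted block on
    either sequence (the diagonal is preserved, so both coordinates move
    together).  Returns (c_start, i_start, length) or None when an accepted
    block sits strictly inside the candidate."""
    changed = True
    while changed:
        if length <= 0:
            return None
        changed = False
        for ac, ai, al, _ in accepted:
            for off, astart in ((c_start, ac), (i_start, ai)):
                lo = max(off, astart)
                hi = min(off + length, astart + al)
                if lo >= hi:
                    continue
                if lo == off:             # overlap at the candidate's start
                    shift = hi - off
                    c_start += shift
                    i_start += shift
                    length -= shift
                elif hi == off + length:  # overlap at the candidate's end
                    length = lo - off
                else:                     # accepted block splits the candidate
                    return None
                changed = True
                break
            if changed:
                break
    return c_start, i_start, length


_ANCHOR = 5          # a run this long is needed to justify crossing a gap
_GAP_PENALTY = 3     # each crossed mismatch must be paid for threefold


def _exact_runs(matches: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(matches)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def _diagonal_segments(
    matches: np.ndarray, min_identity: float, min_block: int
) -> list[tuple[int, int, float]]:
    """Candidate blocks on one diagonal: maximal exact runs, plus anchored
    extensions merging neighbouring runs across mismatch gaps.  A gap of g
    mismatches is crossed only when the run beyond it is a real anchor
    (>= _ANCHOR matches, and longer than _GAP_PENALTY * g), so chance
    micro-matches in unrelated sequence never get glued onto a block."""
    runs = _exact_runs(matches)
    segments: set[tuple[int, int]] = set()

    def _anchored(a: tuple[int, int], b: tuple[int, int]) -> bool:
        # both runs flanking the gap must justify crossing it, so a chance
        # micro-match can never borrow a long genuine run as its anchor
        gap = b[0] - a[1]
        shorter = min(a[1] - a[0], b[1] - b[0])
        return shorter >= _ANCHOR and shorter > _GAP_PENALTY * gap

    for i, (s, e) in enumerate(runs):
        if e - s >= min_block:
            segments.add((s, e))
        if e - s < _ANCHOR:
            continue
        right = i
        while right + 1 < len(runs) and _anchored(runs[right], runs[right + 1]):
            right += 1
        left = i
        while left - 1 >= 0 and _anchored(runs[left - 1], runs[left]):
            left -= 1
        if (left, right) != (i, i) and runs[right][1] - runs[left][0] >= min_block:
            segments.add((runs[left][0], runs[right][1]))
    out = []
    for s, e in segments:
        ident = float(np.count_nonzero(matches[s:e])) / (e - s)
        if ident >= min_identity:
            out.append((s, e, ident))
    return out


# ---------------------------------------------------------------------------
# folding isoforms into the consensus

def _colinear_chain(blocks: list[SharedBlock]) -> list[SharedBlock]:
    """Largest-total-length chain increasing on both sequences (weighted
    longest increasing subsequence over isoform coordinates)."""
    blocks = sorted(
        blocks, key=lambda b: (b.consensus_interval.start, b.isoform_interval.start)
    )
    best: list[int] = [0] * len(blocks)
    prev: list[int] = [-1] * len(blocks)
    for i, bi in enumerate(blocks):
        best[i] = bi.length
        for j in range(i):
            bj = blocks[j]
            if (
                bj.consensus_interval.end <= bi.consensus_interval.start
                and bj.isoform_interval.end <= bi.isoform_interval.start
                and best[j] + bi.length > best[i]
            ):
                best[i] = best[j] + bi.length
                prev[i] = j
    if not blocks:
        return []
    end = max(range(len(blocks)), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(blocks[end])
        end = prev[end]
    return chain[::-1]


def merge_isoform(
    consensus: ConsensusGene,
    isoform_id: str,
    isoform_seq: str,
    blocks: list[SharedBlock],
) -> ConsensusGene:
    """Fold one isoform into the consensus.

    Shared segments appear once; isoform segments outside the shared
    blocks are inserted: a leading segment is prepended, a segment between
    two blocks is inserted immediately before the next block's consensus
    position, and a trailing segment is appended.  An isoform with no
    shared blocks is appended whole — transcript-specific sequence is
    retained, never dropped.
    """
    if not blocks:
        if isoform_seq:
            consensus.segments.append(
                _Segment(isoform_id, 0, len(isoform_seq), isoform_seq)
            )
        return consensus
    chain = _colinear_chain(blocks)
    if len(chain) < len(blocks):
        warnings.warn(
            f"{isoform_id}: {len(blocks) - len(chain)} non-colinear shared "
            "block(s) dropped (rearrangement cannot be represented ungapped)",
            stacklevel=2,
        )
    # (consensus insertion position, isoform segment) for isoform-unique runs
    insertions: list[tuple[int, int, int]] = []  # (c_pos, i_start, i_end)
    first = chain[0]
    if first.isoform_interval.start > 0:
        insertions.append((0, 0, first.isoform_interval.start))
    for left, right in zip(chain, chain[1:]):
        i_gap = (left.isoform_interval.end, right.isoform_interval.start)
        if i_gap[1] > i_gap[0]:
            insertions.append((right.consensus_interval.start, *i_gap))
    last = chain[-1]
    total_len = sum(len(s.text) for s in consensus.segments)
    if last.isoform_interval.end < len(isoform_seq):
        insertions.append((total_len, last.isoform_interval.end, len(isoform_seq)))

    new_segments: list[_Segment] = []
    pos = 0
    pending = sorted(insertions)
    k = 0
    for seg in consensus.segments:
        while k < len(pending) and pending[k][0] <= pos:
            _, i_s, i_e = pending[k]
            new_segments.append(_Segment(isoform_id, i_s, i_e, isoform_seq[i_s:i_e]))
            k += 1
        seg_end = pos + len(seg.text)
        # split the segment at interior insertion points
        cut = pos
        local = seg
        while k < len(pending) and pending[k][0] < seg_end:
            c_pos, i_s, i_e = pending[k]
            offset = c_pos - cut
            head, tail = local.text[:offset], local.text[offset:]
            if head:
                new_segments.append(
                    _Segment(local.isoform_id, local.i_start, local.i_start + offset, head)
                )
            new_segments.append(_Segment(isoform_id, i_s, i_e, isoform_seq[i_s:i_e]))
            local = _Segment(
                local.isoform_id, local.i_start + offset, local.i_end, tail
            )
            cut = c_pos
            k += 1
        if local.text:
            new_segments.append(local)
        pos = seg_end
    while k < len(pending):
        _, i_s, i_e = pending[k]
        new_segments.append(_Segment(isoform_id, i_s, i_e, isoform_seq[i_s:i_e]))
        k += 1
    consensus.segments = new_segments
    return consensus


def build_consensus(
    candidate_id: str,
    isoforms: dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_block: int = DEFAULT_MIN_BLOCK,
) -> ConsensusGene:
    """Fold all isoforms of one gene candidate into a consensus gene.

    The longest isoform seeds the consensus (ties: lexicographic id);
    the rest are folded in descending length order.  After folding, each
    input isoform is re-aligned to the final consensus to record its
    block map (``isoform_maps``), so every isoform's placement on the
    consensus is recoverable.
    """
    if not isoforms:
        raise ValueError("at least one isoform required")
    order = sorted(isoforms, key=lambda i: (-len(isoforms[i]), i))
    seed = order[0]
    cons = ConsensusGene(
        candidate_id,
        [_Segment(seed, 0, len(isoforms[seed]), isoforms[seed])],
    )
    for iso_id in order[1:]:
        blocks = shared_blocks(
            cons.sequence, isoforms[iso_id], min_identity, min_block
        )
        cons = merge_isoform(cons, iso_id, isoforms[iso_id], blocks)
    final_seq = cons.sequence
    for iso_id in order:
        blocks = shared_blocks(final_seq, isoforms[iso_id], min_identity, min_block)
        cons.isoform_maps[iso_id] = [
            (
                (b.consensus_interval.start, b.consensus_interval.end),
                (b.isoform_interval.start, b.isoform_interval.end),
            )
            for b in _colinear_chain(blocks)
        ]
    return cons


# ---------------------------------------------------------------------------
# artificial chromosome

@dataclass
class ArtificialChromosome:
    name: str
    sequence: str
    features: list[tuple[str, GenomicInterval]]
    spacer_length: int


def build_artificial_chromosome(
    sequences: list[tuple[str, str]],
    spacer: int = DEFAULT_SPACER,
    name: str = "chrA_denovo",
) -> tuple[ArtificialChromosome, list[TranscriptModel]]:
    """Concatenate retained sequences with N spacers into one chromosome.

    The spacer defaults to the total footprint of one read pair
    (2 x 50 bp reads + 150 bp insert) so that no pair can bridge two
    neighbouring genes.  Returns the chromosome plus one single-exon
    transcript model per input sequence for GTF emission.
    """
    if not sequences:
        raise ValueError("at least one sequence required")
    parts: list[str] = []
    features: list[tuple[str, GenomicInterval]] = []
    pos = 0
    for i, (candidate_id, seq) in enumerate(sequences):
        if not seq:
            raise ValueError(f"empty sequence for {candidate_id}")
        if i > 0:
            parts.append("N" * spacer)
            pos += spacer
        parts.append(seq)
        features.append(
            (candidate_id, GenomicInterval(name, pos, pos + len(seq), "+"))
        )
        pos += len(seq)
    chrom = ArtificialChromosome(name, "".join(parts), features, spacer)
    models = [
        TranscriptModel(f"{cid}.t1", cid, [iv], source="txrecon")
        for cid, iv in features
    ]
    return chrom, models
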