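"""Read-quality gate applied before de novo assembly.

A read pair is kept only when *both* mates have a median Phred quality of
at least ``min_median`` (default 28; a median of exactly 28 passes).
Filtering is pair-level because the downstream assembler consumes complete
read pairs.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .io_formats import read_fastq, write_fastq

PHRED_OFFSET = 33
DEFAULT_MIN_MEDIAN = 28.0

__all__ = [
    "FastqRead",
    "median_quality",
    "filter_pairs",
    "filter_fastq_files",
    "DEFAULT_MIN_MEDIAN",
]


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.qualities and not all(0 <= q <= 60 for q in self.qualities):
            raise ValueError(f"{self.read_id}: Phred score outside [0, 60]")


def median_quality(read: FastqRead) -> float:
    """Statistical median of the read's Phred scores.

    For an even number of scores this is the mean of the two central
    values, so the result may be half-integral.
    """
    if not read.qualities:
        raise ValueError(f"{read.read_id}: empty quality string")
    return float(statistics.median(read.qualities))


def filter_pairs(
    pairs: list[tuple[FastqRead, FastqRead]],
    min_median: float = DEFAULT_MIN_MEDIAN,
) -> tuple[list[tuple[FastqRead, FastqRead]], list[dict]]:
    """Keep pairs where both mates reach the median-quality threshold.

    Returns ``(kept, discard_log)``; each discard-log entry records the
    pair id and which mate(s) failed, with their medians.
    """
    kept: list[tuple[FastqRead, FastqRead]] = []
    discard_log: list[dict] = []
    for r1, r2 in pairs:
        m1, m2 = median_quality(r1), median_quality(r2)
        failing = [
            mate
            for mate, m in (("1", m1), ("2", m2))
            if m < min_median
        ]
        if failing:
            discard_log.append(
                {
                    "pair_id": _pair_id(r1.read_id),
                    "failing_mates": failing,
                    "median1": m1,
                    "median2": m2,
                }
            )
        else:
            kept.append((r1, r2))
    return kept, discard_log


def _pair_id(read_id: str) -> str:
    # strip /1 /2 mate suffixes if present
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def filter_fastq_files(
    in1: str,
    in2: str,
    out_prefix: str,
    min_median: float = DEFAULT_MIN_MEDIAN,
) -> dict:
    """Apply the pair-level quality gate to two mate FASTQ files.

    Writes ``<out_prefix>_1.fastq`` / ``<out_prefix>_2.fastq`` and returns
    a summary with input/kept/discarded pair counts and the discard log.
    """
    reads1 = [FastqRead(i, s, tuple(q)) for i, s, q in read_fastq(in1)]
    reads2 = [FastqRead(i, s, tuple(q)) for i, s, q in read_fastq(in2)]
    if len(reads1) != len(reads2):
        raise ValueError(
            f"mate files differ in read count: {len(reads1)} vs {len(reads2)}"
        )
    kept, discard_log = filter_pairs(list(zip(reads1, reads2)), min_median)
    write_fastq(
        [(r.read_id, r.sequence, list(r.qualities)) for r, _ in kept],
        f"{out_prefix}_1.fastq",
    )
    write_fastq(
        [(r.read_id, r.sequence, list(r.qualities)) for _, r in kept],
        f"{out_prefix}_2.fastq",
    )
    return {
        "input_pairs": len(reads1),
        "kept_pairs": len(kept),
        "discarded_pairs": len(discard_log),
        "discard_log": discard_log,
    }
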