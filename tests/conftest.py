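import pytest

from txrecon.io_formats import AlignmentHit, GenomicInterval, TranscriptModel


@pytest.fixture
def hit():
    """Builder for alignment hits with sensible defaults."""

    def _make(
        query="contig1",
        subject="gene1",
        identity=95.0,
        q=(1, 100),
        s=(1, 100),
        bitscore=180.0,
        evalue=1e-50,
    ):
        return AlignmentHit.from_coords(
            query, subject, identity, max(q[1] - q[0] + 1, 1), 0, 0,
            q[0], q[1], s[0], s[1], evalue, bitscore,
        )

    return _make


@pytest.fixture
def transcript():
    """Builder for exon-structured transcripts from (start, end) pairs."""

    def _make(tid, gene, exons, seqid="chr1", strand="+", source="test"):
        return TranscriptModel(
            tid, gene,
            [GenomicInterval(seqid, s, e, strand) for s, e in exons],
            source=source,
        )

    return _make
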