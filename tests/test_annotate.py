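"""Naming cascade, ORF prediction and reference comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from txrecon.annotate import (
    AnnotationEvidence,
    assign_name_nt,
    assign_name_prot,
    bidirectional_coverage,
    classify_biotype,
    coverage_vs_reference,
    find_orfs,
    name_concordance,
)

STOPS = ("TAA", "TAG", "TGA")


class TestBidirectionalCoverage:
    def test_union_on_both_axes(self, hit):
        hits = [hit(q=(1, 400), s=(1, 300)), hit(q=(301, 600), s=(251, 550))]
        q_pct, s_pct = bidirectional_coverage(1000, 1000, hits)
        assert q_pct == 60.0
        assert s_pct == 55.0

    def test_no_hits(self):
        assert bidirectional_coverage(1000, 800, []) == (0.0, 0.0)

    def test_full_length_perfect_hit(self, hit):
        assert bidirectional_coverage(100, 100, [hit(q=(1, 100), s=(1, 100))]) == (
            100.0,
            100.0,
        )


class TestAssignNameNt:
    def _subjects(self):
        return {"refA": 1000, "refB": 1000}, {"refA": "COL26A1", "refB": "WNT11"}

    def test_chicken_hit_assigned(self, hit):
        lengths, names = self._subjects()
        h = hit(subject="refA", identity=95, q=(1, 800), s=(1, 800))
        named, discordant = assign_name_nt("c1", 1000, [(h, "chicken")], lengths, names)
        assert named == ("COL26A1", "nt") and not discordant

    def test_chicken_identity_exactly_90_not_qualifying(self, hit):
        lengths, names = self._subjects()
        h = hit(subject="refA", identity=90.0, q=(1, 800), s=(1, 800))
        named, _ = assign_name_nt("c1", 1000, [(h, "chicken")], lengths, names)
        assert named is None

    def test_bird_identity_exactly_75_qualifies(self, hit):
        lengths, names = self._subjects()
        h = hit(subject="refA", identity=75.0, q=(1, 800), s=(1, 800))
        named, _ = assign_name_nt("c1", 1000, [(h, "other_bird")], lengths, names)
        assert named == ("COL26A1", "nt")

    def test_insufficient_bidirectional_coverage_rejected(self, hit):
        lengths, names = self._subjects()
        h = hit(subject="refA", identity=99, q=(1, 499), s=(1, 499))  # 49.9%
        named, _ = assign_name_nt("c1", 1000, [(h, "chicken")], lengths, names)
        assert named is None

    def test_two_qualifying_names_set_discordance(self, hit):
        lengths, names = self._subjects()
        hits = [
            (hit(subject="refA", identity=95, q=(1, 800), s=(1, 800), bitscore=500),
             "chicken"),
            (hit(subject="refB", identity=96, q=(1, 800), s=(1, 800), bitscore=400),
             "chicken"),
        ]
        named, discordant = assign_name_nt("c1", 1000, hits, lengths, names)
        assert named == ("COL26A1", "nt")  # best total bitscore
        assert discordant


class TestAssignNameProt:
    ACC = {"NP_001": "Wnt11"}

    def test_qualifying_hit_mapped(self, hit):
        h = hit(subject="NP_001", bitscore=200)
        named, warnings = assign_name_prot(
            "c1", [h], {0: 45.0}, {0: 70.0}, self.ACC
        )
        assert named == ("Wnt11", "prot") and warnings == []

    def test_homology_just_below_30_rejected(self, hit):
        named, _ = assign_name_prot(
            "c1", [hit(subject="NP_001")], {0: 29.9}, {0: 70.0}, self.ACC
        )
        assert named is None

    def test_homology_exactly_30_eligible(self, hit):
        named, _ = assign_name_prot(
            "c1", [hit(subject="NP_001")], {0: 30.0}, {0: 50.0}, self.ACC
        )
        assert named == ("Wnt11", "prot")

    def test_low_coverage_rejected(self, hit):
        named, _ = assign_name_prot(
            "c1", [hit(subject="NP_001")], {0: 45.0}, {0: 40.0}, self.ACC
        )
        assert named is None

    def test_unmapped_accession_warns(self, hit):
        named, warnings = assign_name_prot(
            "c1", [hit(subject="XP_999")], {0: 45.0}, {0: 70.0}, self.ACC
        )
        assert named is None
        assert "XP_999" in warnings[0]


def brute_force_orfs(seq):
    """Independent 3-frame scan: per stop-free codon segment, the maximal
    readable stretch — from the 5' edge when no stop precedes the segment,
    else from its first ATG; a segment with neither an ATG nor a
    terminating stop is not an ORF.  Returns (frame, nt_start, nt_end, aa)."""
    out = []
    for frame in range(3):
        codons = [
            (i, seq[i : i + 3])
            for i in range(frame, len(seq) - 2, 3)
        ]
        seg = []
        edge = True
        for pos, codon in codons + [(None, "END")]:
            if codon in STOPS or codon == "END":
                stop_pos = pos
                has_atg = any(c == "ATG" for _, c in seg)
                if edge and seg and (has_atg or stop_pos is not None):
                    start = seg[0][0]
                elif not edge and has_atg:
                    start = next(p for p, c in seg if c == "ATG")
                else:
                    start = None
                if start is not None:
                    end = stop_pos if stop_pos is not None else seg[-1][0] + 3
                    aa = (end - start) // 3
                    if aa >= 1:
                        out.append((frame, start, end, aa))
                seg = []
                edge = False
            else:
                seg.append((pos, codon))
    return sorted(out)


def _rand_seq(rng, n):
    return "".join("ACGT"[k] for k in rng.integers(0, 4, n))


class TestFindOrfs:
    def test_embedded_complete_orf_of_100_aa(self):
        rng = np.random.default_rng(2)
        sense = [c for c in ("".join(_rand_seq(rng, 3) for _ in range(200)),)][0]
        codons = []
        rng2 = np.random.default_rng(3)
        while len(codons) < 99:
            c = _rand_seq(rng2, 3)
            if c not in STOPS and c != "ATG":
                codons.append(c)
        utr5 = "CCTCCTCCTAA"  # no ATG, ends on a stop in frame 0... keep simple
        seq = "CCACCTAA" + "ATG" + "".join(codons) + "TAA" + "CCCACCCAC"
        orfs = find_orfs(seq)
        complete = [o for o in orfs if o.completeness == "complete"]
        assert complete and complete[0].length_aa == 100

    def test_only_stop_codons_yield_nothing(self):
        assert find_orfs("TAATAATAGTGA") == []

    def test_strand_specific_misses_reverse_orf(self):
        rng = np.random.default_rng(19)
        codons = []
        while len(codons) < 120:
            c = _rand_seq(rng, 3)
            if c not in STOPS:
                codons.append(c)
        # mid-sequence codons whose reverse complement spells TAA in all
        # three antisense frames, so the antisense strand cannot stay open
        codons[58:62] = ["TTT", "ATT", "TAT", "TTA"]
        sense = "TAA" + "ATG" + "".join(codons) + "TAA"
        rc = sense.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd_long = [o for o in find_orfs(sense) if o.length_aa >= 100]
        rc_long = [o for o in find_orfs(rc) if o.length_aa >= 100]
        assert fwd_long and not rc_long

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = _rand_seq(rng, int(rng.integers(30, 600)))
        got = sorted(
            (o.frame, o.interval.start, o.interval.end, o.length_aa)
            for o in find_orfs(seq)
        )
        assert got == brute_force_orfs(seq)


class TestClassifyBiotype:
    def _evidence(self, orf_aa=0, domain=False):
        orfs = []
        if orf_aa:
            from txrecon.annotate import OpenReadingFrame
            from txrecon.io_formats import GenomicInterval

            orfs = [OpenReadingFrame("c1", 0, GenomicInterval("c1", 0, 3 * orf_aa, "+"),
                                     orf_aa, "complete")]
        return AnnotationEvidence("c1", orfs=orfs, has_domain=domain)

    def test_unnamed_long_orf_with_domain_is_putative(self):
        call = classify_biotype(self._evidence(150, domain=True), None)
        assert call.biotype == "putative_protein"

    def test_unnamed_long_orf_without_domain_is_uncharacterized(self):
        call = classify_biotype(self._evidence(150), None)
        assert call.biotype == "uncharacterized_protein"

    def test_orf_99_aa_is_ncrna(self):
        assert classify_biotype(self._evidence(99, domain=True), None).biotype == "ncRNA"

    def test_orf_exactly_100_aa_reaches_protein_tier(self):
        assert (
            classify_biotype(self._evidence(100), None).biotype
            == "uncharacterized_protein"
        )

    def test_named_rrna_is_miscellaneous(self):
        call = classify_biotype(self._evidence(150), "RN18S-like rRNA")
        assert call.biotype == "miscellaneous" and call.name == "RN18S-like rRNA"

    def test_named_gene_is_protein_coding(self):
        call = classify_biotype(self._evidence(), "FLNA")
        assert call.biotype == "protein_coding_named" and call.name == "FLNA"

    def test_every_candidate_gets_exactly_one_biotype(self):
        cases = [
            (None, 0, False), (None, 99, True), (None, 100, False),
            (None, 150, True), ("FLNA", 0, False), ("RNX-rRNA", 0, False),
        ]
        biotypes = {
            classify_biotype(self._evidence(aa, domain=dom), name).biotype
            for name, aa, dom in cases
        }
        assert biotypes == {
            "ncRNA", "uncharacterized_protein", "putative_protein",
            "protein_coding_named", "miscellaneous",
        }


class TestCoverageVsReference:
    def test_sixty_percent_binned_at_least_50(self, hit):
        pct, bin_ = coverage_vs_reference(1000, [hit(q=(1, 600))])
        assert pct == 60.0 and bin_ == "at_least_50"

    def test_no_hits_is_zero_bin(self):
        assert coverage_vs_reference(1000, []) == (0.0, "zero")

    def test_499_of_1000_below_50(self, hit):
        pct, bin_ = coverage_vs_reference(1000, [hit(q=(1, 499))])
        assert pct == 49.9 and bin_ == "below_50"


class TestNameConcordance:
    def test_concordant(self, hit):
        res = name_concordance("FLNA", [(hit(), "FLNA", 80.0)])
        assert res == "concordant"

    def test_case_insensitive_with_synonyms(self, hit):
        res = name_concordance(
            "Flna", [(hit(), "FLN-A", 80.0)], synonyms={"FLN-A": "FLNA"}
        )
        assert res == "concordant"

    def test_no_qualifying_hit(self, hit):
        assert name_concordance("FLNA", [(hit(), "FLNA", 49.0)]) == "no_match"

    def test_best_hit_unnamed_is_matched_undefined(self, hit):
        res = name_concordance(
            "FLNA",
            [(hit(bitscore=100), "FLNA", 80.0), (hit(bitscore=300), None, 90.0)],
        )
        assert res == "matched_undefined"

    def test_different_name_is_discordant(self, hit):
        assert name_concordance("FLNA", [(hit(), "WNT11", 80.0)]) == "discordant"
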