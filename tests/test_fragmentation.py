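"""Contig assignment, coverage algebra and fragmentation classes."""

import pytest
from hypothesis import given, settings, strategies as st

from txrecon.fragmentation import (
    CoverageMap,
    GeneCandidate,
    assign_contig,
    classify_genomic_placement,
    coverage_union,
    fragmentation_class,
    gather_parts,
    uncovered_regions,
)
from txrecon.io_formats import GenomicInterval


def brute_force_covered(intervals, length):
    """Per-base oracle: mark every covered base."""
    mask = [False] * length
    for s, e in intervals:
        for i in range(s, min(e, length)):
            mask[i] = True
    return mask


intervals_strategy = st.lists(
    st.tuples(st.integers(0, 199), st.integers(1, 60)).map(
        lambda t: (t[0], min(t[0] + t[1], 200))
    ),
    max_size=15,
)


class TestCoverageUnion:
    def test_overlapping_hits_merge(self, hit):
        hits = [hit(q=(1, 100)), hit(q=(50, 120))]
        cov = coverage_union(hits)
        assert cov.covered == [(0, 120)]

    def test_no_hits_empty(self):
        assert coverage_union([]).covered == []

    def test_disjoint_hits_stay_disjoint(self, hit):
        hits = [hit(q=(1, 10)), hit(q=(21, 30))]
        assert coverage_union(hits).covered == [(0, 10), (20, 30)]

    def test_mixed_query_ids_rejected(self, hit):
        with pytest.raises(ValueError):
            coverage_union([hit(query="c1"), hit(query="c2")])

    @given(intervals_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_union_matches_per_base_oracle(self, intervals):
        cov = CoverageMap("t", 200, list(intervals))
        mask = brute_force_covered(intervals, 200)
        assert cov.covered_bp == sum(mask)
        for s, e in cov.covered:
            assert all(mask[s:e])


class TestAssignContig:
    def test_second_hit_with_too_little_novelty_rejected(self, hit):
        h1 = hit(q=(1, 100), s=(1, 100), bitscore=200)
        h2 = hit(q=(51, 120), s=(201, 270), subject="gene2", bitscore=100)
        assignments, _ = assign_contig("contig1", [h1, h2])
        assert [a.gene_candidate_id for a in assignments] == ["gene1"]
        assert assignments[0].novel_bp == 100

    def test_identity_exactly_90_rejected(self, hit):
        assignments, _ = assign_contig("contig1", [hit(identity=90.0)])
        assert assignments == []

    def test_novelty_exactly_40_accepted(self, hit):
        assignments, _ = assign_contig("contig1", [hit(q=(1, 40), s=(1, 40))])
        assert len(assignments) == 1

    def test_order_determinism(self, hit):
        hits = [
            hit(q=(1, 100), subject="gA", bitscore=200),
            hit(q=(30, 130), subject="gB", bitscore=150),
            hit(q=(90, 190), subject="gC", bitscore=100),
        ]
        baseline = assign_contig("contig1", hits)[0]
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            permuted = assign_contig("contig1", [hits[i] for i in perm])[0]
            assert [(a.gene_candidate_id, a.novel_bp) for a in permuted] == [
                (a.gene_candidate_id, a.novel_bp) for a in baseline
            ]

    @given(st.integers(1, 120), st.floats(85, 99))
    @settings(max_examples=50, derandomize=True)
    def test_tightening_thresholds_never_grows_accepted_set(self, min_novel, min_id):
        # with non-overlapping hits acceptance is per-hit, so tightening
        # either threshold is monotone (overlapping hits interact through
        # the running coverage and can swap, not shrink, the accepted set)
        from txrecon.io_formats import AlignmentHit

        def hit(q, subject, identity, bitscore):
            return AlignmentHit.from_coords(
                "c", subject, identity, q[1] - q[0] + 1, 0, 0,
                q[0], q[1], 1, q[1] - q[0] + 1, 1e-50, bitscore,
            )

        hits = [
            hit(q=(1, 100), subject="gA", identity=95, bitscore=200),
            hit(q=(101, 200), subject="gB", identity=92, bitscore=150),
        ]
        loose, _ = assign_contig("c", hits, min_identity=min_id, min_novel_bp=min_novel)
        tight, _ = assign_contig(
            "c", hits, min_identity=min_id + 1, min_novel_bp=min_novel + 10
        )
        loose_hits = {(h.q_start, h.q_end) for a in loose for h in a.supporting_hits}
        tight_hits = {(h.q_start, h.q_end) for a in tight for h in a.supporting_hits}
        assert tight_hits <= loose_hits


class TestUncoveredRegions:
    def test_run_of_exactly_400_extracted(self):
        cov = CoverageMap("t", 2000, [(0, 500), (900, 2000)])
        (region,) = uncovered_regions(2000, cov)
        assert (region.start, region.end) == (500, 900)

    def test_run_of_399_dropped(self):
        cov = CoverageMap("t", 2000, [(0, 500), (899, 2000)])
        assert uncovered_regions(2000, cov) == []

    def test_fully_covered_target(self):
        cov = CoverageMap("t", 1000, [(0, 1000)])
        assert uncovered_regions(1000, cov) == []

    def test_terminal_runs_qualify(self):
        cov = CoverageMap("t", 1000, [(450, 550)])
        regions = uncovered_regions(1000, cov)
        assert [(r.start, r.end) for r in regions] == [(0, 450), (550, 1000)]

    def test_ambiguous_bases_do_not_count(self):
        # 500-bp gap but 150 of it is N: effective 350 < 400
        seq = "A" * 500 + "N" * 150 + "C" * 350 + "A" * 1000
        cov = CoverageMap("t", 2000, [(0, 500), (1000, 2000)])
        assert uncovered_regions(2000, cov, sequence=seq) == []
        assert len(uncovered_regions(2000, cov)) == 1

    @given(intervals_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_complement_tiles_target_exactly(self, intervals):
        cov = CoverageMap("t", 200, list(intervals))
        gaps = [(r.start, r.end) for r in uncovered_regions(200, cov, min_len=1)]
        mask = brute_force_covered(intervals, 200)
        uncovered_bases = {i for s, e in gaps for i in range(s, e)}
        assert uncovered_bases == {i for i in range(200) if not mask[i]}


class TestGenomicPlacement:
    FEATURES = [
        GenomicInterval("chr1", 1000, 1500, "+"),
        GenomicInterval("chr1", 3000, 3500, "+"),
        GenomicInterval("chr1", 6000, 6500, "+"),
    ]

    def test_between_two_features_is_internal_exon(self, hit):
        hits = [hit(subject="chr1", s=(4001, 4300))]
        assert classify_genomic_placement(hits, self.FEATURES) == "internal_exon"

    def test_downstream_within_vicinity_is_three_prime(self, hit):
        hits = [hit(subject="chr1", s=(8501, 8800))]  # 2 kb past the last exon
        assert (
            classify_genomic_placement(hits, self.FEATURES, vicinity_bp=10_000)
            == "three_prime_extension"
        )

    def test_upstream_is_five_prime_and_strand_aware(self, hit):
        hits = [hit(subject="chr1", s=(401, 700))]
        assert (
            classify_genomic_placement(hits, self.FEATURES) == "five_prime_extension"
        )
        minus_features = [
            GenomicInterval("chr1", iv.start, iv.end, "-") for iv in self.FEATURES
        ]
        assert (
            classify_genomic_placement(hits, minus_features) == "three_prime_extension"
        )

    def test_other_chromosome_is_unplaced(self, hit):
        hits = [hit(subject="chr9", s=(4001, 4300))]
        assert classify_genomic_placement(hits, self.FEATURES) == "unplaced"

    def test_beyond_vicinity_is_unplaced(self, hit):
        hits = [hit(subject="chr1", s=(20_001, 20_300))]
        assert (
            classify_genomic_placement(hits, self.FEATURES, vicinity_bp=10_000)
            == "unplaced"
        )


def _candidate(parts, classes):
    return GeneCandidate(
        "c1",
        [(s, GenomicInterval(s, a, b)) for s, a, b in parts],
        dict(classes),
    )


class TestFragmentationClass:
    @pytest.mark.parametrize(
        "parts,classes,expected",
        [
            ([("chr19", 0, 100)], {"chr19": "ordered"}, "single_location"),
            ([("chr1", 0, 100), ("chr2", 0, 100)],
             {"chr1": "ordered", "chr2": "ordered"}, "multi_ordered"),
            ([("contig_1", 0, 100), ("contig_2", 0, 100)],
             {"contig_1": "unplaced", "contig_2": "unplaced"}, "multi_unplaced"),
            ([("chr1", 0, 100), ("contig_0412", 0, 100)],
             {"chr1": "ordered", "contig_0412": "unplaced"}, "mixed"),
            ([("contig_1", 0, 100), ("contig_1", 500, 600)],
             {"contig_1": "unplaced"}, "single_location"),
        ],
    )
    def test_classes(self, parts, classes, expected):
        assert fragmentation_class(_candidate(parts, classes)) == expected

    def test_classes_partition_candidate_set(self):
        candidates = [
            _candidate([("chr1", 0, 100)], {"chr1": "ordered"}),
            _candidate([("chr1", 0, 100), ("chr2", 0, 100)],
                       {"chr1": "ordered", "chr2": "ordered"}),
            _candidate([("chr1", 0, 100), ("contig_9", 0, 100)],
                       {"chr1": "ordered", "contig_9": "unplaced"}),
        ]
        counts = {}
        for c in candidates:
            counts[fragmentation_class(c)] = counts.get(fragmentation_class(c), 0) + 1
        assert sum(counts.values()) == len(candidates)


class TestGatherParts:
    def test_contig_location_appended(self, hit):
        from txrecon.fragmentation import ContigAssignment

        cand = _candidate([("chrX", 0, 1000)], {"chrX": "ordered"})
        assignment = ContigAssignment("c7", "c1", [hit()], 100)
        locs = {"c7": [("contig_42", GenomicInterval("contig_42", 0, 500))]}
        updated, conflicts = gather_parts(
            [assignment], {"c1": cand}, locs, {"contig_42": "unplaced"}
        )
        assert conflicts == []
        assert len(updated["c1"].parts) == 2
        assert fragmentation_class(updated["c1"]) == "mixed"

    def test_no_assignments_no_change(self):
        cand = _candidate([("chr1", 0, 100)], {"chr1": "ordered"})
        updated, conflicts = gather_parts([], {"c1": cand}, {})
        assert updated["c1"].parts == cand.parts and conflicts == []

    def test_conflicting_assignment_reported_and_parts_deduplicated(self, hit):
        from txrecon.fragmentation import ContigAssignment

        c1 = _candidate([("chr1", 0, 100)], {"chr1": "ordered"})
        c2 = GeneCandidate("c2", [("chr2", GenomicInterval("chr2", 0, 100))],
                           {"chr2": "ordered"})
        assignments = [
            ContigAssignment("c7", "c1", [hit()], 50),
            ContigAssignment("c7", "c2", [hit()], 50),
            ContigAssignment("c7", "c1", [hit()], 50),  # duplicate location
        ]
        locs = {"c7": [("contig_1", GenomicInterval("contig_1", 0, 400))]}
        updated, conflicts = gather_parts(
            assignments, {"c1": c1, "c2": c2}, locs
        )
        assert conflicts == [{"contig_id": "c7", "candidates": ["c1", "c2"]}]
        assert len(updated["c1"].parts) == 2  # deduplicated
        assert len(updated["c2"].parts) == 2
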