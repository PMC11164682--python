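"""Site calling, duplicate collapse, near-position merging and filters.

merge_nearby is checked against an exhaustive brute-force single-linkage
oracle on all small site configurations, plus idempotence and order
invariance on random inputs.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbscreen.insertion_sites import (
    AlignmentRecord,
    IntegrationSite,
    SiteFilterConfig,
    apply_site_filters,
    collapse_duplicates,
    merge_nearby,
    read_alignments_bed,
    read_alignments_sam,
    read_sites_tsv,
    sites_from_alignments,
    write_sites_tsv,
)


def brute_force_merge(positions, window):
    """Single-linkage clusters via union-find over all pairs (oracle)."""
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(positions)), 2):
        if abs(positions[i] - positions[j]) <= window:
            parent[find(i)] = find(j)
    clusters = {}
    for i in range(len(positions)):
        clusters.setdefault(find(i), []).append(positions[i])
    return sorted(tuple(sorted(c)) for c in clusters.values())


class TestSitesFromAlignments:
    def test_junction_coordinate_convention(self):
        """+ strand uses the leftmost base, - strand the rightmost."""
        alns = [
            AlignmentRecord("r1", "L1", "chr1", 1000, 1050, "+", 60),
            AlignmentRecord("r2", "L1", "chr1", 1000, 1050, "-", 60),
        ]
        calls, rejected = sites_from_alignments(alns)
        assert [(c.pos, c.orientation) for c in calls] == [(1000, "+"), (1050, "-")]
        assert not rejected

    def test_low_mapq_dropped_not_fatal(self):
        alns = [AlignmentRecord("r1", "L1", "chr1", 100, 150, "+", 5)]
        calls, rejected = sites_from_alignments(alns, SiteFilterConfig(mapq_min=10))
        assert calls == [] and rejected[0][1] == "low_mapq"


class TestCollapseDuplicates:
    def test_grouping_and_conservation(self):
        calls = [IntegrationSite("L1", "chr1", 500, "+", 1)] * 12 + [
            IntegrationSite("L1", "chr1", 500, "-", 1)
        ]
        sites = collapse_duplicates(calls)
        assert len(sites) == 2  # opposite orientations stay separate
        assert sum(s.read_count for s in sites) == 13
        assert {s.read_count for s in sites} == {12, 1}


class TestMergeNearby:
    def test_stated_rule(self):
        """Close sites merge to the best-supported coordinate, counts summed."""
        sites = [
            IntegrationSite("L1", "chr1", 1000, "+", 12),
            IntegrationSite("L1", "chr1", 1003, "+", 3),
        ]
        (m,) = merge_nearby(sites, 5)
        assert (m.pos, m.read_count) == (1000, 15)

    def test_window_boundary_is_inclusive(self):
        sites = [
            IntegrationSite("L1", "chr1", 1000, "+", 1),
            IntegrationSite("L1", "chr1", 1006, "+", 1),
        ]
        assert len(merge_nearby(sites, 5)) == 2  # distance 6 > 5
        assert len(merge_nearby(sites, 6)) == 1

    def test_transitive_chain(self):
        sites = [IntegrationSite("L1", "chr1", p, "+", 1) for p in (1000, 1004, 1008)]
        (m,) = merge_nearby(sites, 5)
        assert m.read_count == 3

    def test_lesions_and_chromosomes_never_merge(self):
        sites = [
            IntegrationSite("L1", "chr1", 100, "+", 1),
            IntegrationSite("L2", "chr1", 101, "+", 1),
            IntegrationSite("L1", "chr2", 102, "+", 1),
        ]
        assert len(merge_nearby(sites, 5)) == 3

    def test_exhaustive_against_single_linkage_oracle(self):
        """Every site set of size <= 4 on positions 1..10 matches the oracle."""
        for k in range(1, 5):
            for positions in itertools.combinations(range(1, 11), k):
                sites = [
                    IntegrationSite("L1", "chr1", p, "+", 1 + (p % 3)) for p in positions
                ]
                merged = merge_nearby(sites, 5)
                expected = brute_force_merge(list(positions), 5)
                assert len(merged) == len(expected)
                got_counts = sorted(m.read_count for m in merged)
                exp_counts = sorted(sum(1 + (p % 3) for p in c) for c in expected)
                assert got_counts == exp_counts

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(
        positions=st.lists(st.integers(1, 2000), min_size=1, max_size=20),
        counts=st.data(),
        window=st.integers(0, 10),
    )
    def test_idempotent_order_invariant_conserving(self, positions, counts, window):
        reads = [counts.draw(st.integers(1, 50)) for _ in positions]
        sites = [
            IntegrationSite("L1", "chr1", p, "+", r) for p, r in zip(positions, reads)
        ]
        merged = merge_nearby(sites, window)
        # conservation of read support
        assert sum(m.read_count for m in merged) == sum(reads)
        # idempotence
        assert merge_nearby(merged, window) == merged
        # order invariance
        assert merge_nearby(list(reversed(sites)), window) == merged
        # pairwise separation of output
        pos = sorted(m.pos for m in merged)
        assert all(b - a > window for a, b in zip(pos, pos[1:]))


class TestFilters:
    def test_chromosome_then_read_depth(self):
        cfg = SiteFilterConfig(
            min_reads=10, exclude_chromosomes={"chr10"}, apply_read_filter=True
        )
        sites = [
            IntegrationSite("L1", "chr10", 100, "+", 50),  # donor: removed first
            IntegrationSite("L1", "chr1", 200, "+", 10),   # exactly 10: removed (> rule)
            IntegrationSite("L1", "chr1", 300, "+", 11),   # kept
        ]
        kept, removed = apply_site_filters(sites, cfg)
        assert [s.pos for s in kept] == [300]
        assert removed == {"excluded_chromosome": 1, "low_read_count": 1}

    def test_read_filter_off_by_default(self):
        sites = [IntegrationSite("L1", "chr1", 200, "+", 1)]
        kept, _ = apply_site_filters(sites, SiteFilterConfig(exclude_chromosomes={"chr10"}))
        assert kept == sites


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        sites = [
            IntegrationSite("L1", "chr1", 1000, "+", 12),
            IntegrationSite("L2", "chr2", 99, "-", 1),
        ]
        path = tmp_path / "sites.tsv"
        write_sites_tsv(sites, path)
        assert read_sites_tsv(path) == sites

    def test_bed_alignments_are_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t999\t1050\tL1/r1\t60\t+\n")
        (rec,) = read_alignments_bed(bed)
        assert (rec.start, rec.end, rec.lesion_id) == (1000, 1050, "L1")

    def test_sam_reader_uses_read_group_sample(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:100000\n"
            "@RG\tID:rg1\tSM:L007\n"
            "r1\t0\tchr1\t1000\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\tRG:Z:rg1\n"
            "r2\t16\tchr1\t1000\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\tRG:Z:rg1\n"
        )
        recs = read_alignments_sam(sam)
        assert [r.lesion_id for r in recs] == ["L007", "L007"]
        calls, _ = sites_from_alignments(recs)
        assert [(c.pos, c.orientation) for c in calls] == [(1000, "+"), (1049, "-")]
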