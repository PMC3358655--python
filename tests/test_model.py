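"""Reference partitioning, adjacency filtering, and graph construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prego import (Adjacency, Cluster, CoordinateError, DepthProfile,
                   InputError, Interval, SIGMA, build_graph,
                   detect_telomere_loss, filter_adjacencies,
                   partition_reference)
from prego.model import KIND_REFERENCE, KIND_VARIANT

from conftest import make_intervals


def cluster(c1, p1, s1, c2, p2, s2, support=10):
    return Cluster(c1, p1, s1, c2, p2, s2, support)


class TestPartition:
    def test_two_breakpoints_cut_three_intervals(self):
        res = partition_reference({"chr1": 100},
                                  [cluster("chr1", 40, "end", "chr1", 70, "start")],
                                  min_interval_len=1)
        assert [(iv.start, iv.end) for iv in res.intervals] == \
            [(0, 40), (40, 70), (70, 100)]
        assert res.adjacencies == [Adjacency((1, "end"), (3, "start"),
                                             support=10)]

    def test_no_adjacencies_gives_one_interval_per_chromosome(self):
        res = partition_reference({"chr1": 100, "chr2": 50}, [],
                                  min_interval_len=1)
        assert [(iv.chrom, iv.start, iv.end) for iv in res.intervals] == \
            [("chr1", 0, 100), ("chr2", 0, 50)]

    def test_min_interval_rule_rejects_close_breakpoints(self):
        # both cuts sit closer than 8 kb to the chromosome start, so the
        # adjacency is dropped wholesale and the chromosome stays uncut
        res = partition_reference({"chr1": 100},
                                  [cluster("chr1", 40, "end", "chr1", 44, "start")],
                                  min_interval_len=8000)
        assert len(res.intervals) == 1
        assert res.adjacencies == []
        assert len(res.dropped) == 1 and "min interval" in res.dropped[0][1]

    def test_rejecting_one_breakpoint_drops_the_whole_adjacency(self):
        # second breakpoint is fine on its own but belongs to a dropped cluster
        res = partition_reference({"chr1": 100_000},
                                  [cluster("chr1", 100, "end", "chr1", 50_000,
                                           "start")],
                                  min_interval_len=8000)
        assert len(res.intervals) == 1

    def test_breakpoint_outside_chromosome_raises(self):
        with pytest.raises(CoordinateError):
            partition_reference({"chr1": 100},
                                [cluster("chr1", 40, "end", "chr1", 170, "start")])

    def test_unknown_chromosome_raises(self):
        with pytest.raises(InputError):
            partition_reference({"chr1": 100},
                                [cluster("chrX", 40, "end", "chr1", 70, "start")])

    def test_identical_adjacencies_collapse_with_summed_support(self):
        cls = [cluster("chr1", 40, "end", "chr1", 70, "start", support=5),
               cluster("chr1", 40, "end", "chr1", 70, "start", support=7)]
        res = partition_reference({"chr1": 100}, cls, min_interval_len=1)
        assert len(res.adjacencies) == 1
        assert res.adjacencies[0].support == 12

    @given(st.lists(st.integers(1, 99), max_size=6), st.integers(1, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_intervals_always_tile_the_chromosome(self, cuts, min_len):
        cls = [cluster("chr1", c, "end", "chr1", c, "start") for c in cuts]
        res = partition_reference({"chr1": 100}, cls, min_interval_len=min_len)
        ivs = res.intervals
        assert ivs[0].start == 0 and ivs[-1].end == 100
        for a, b in zip(ivs[:-1], ivs[1:]):
            assert a.end == b.start
        assert sum(iv.length for iv in ivs) == 100
        assert all(iv.length >= min_len or len(ivs) == 1 for iv in ivs)


class TestFilter:
    def test_low_support_dropped(self):
        cl = cluster("chr1", 10, "end", "chr1", 90, "start", support=4)
        assert filter_adjacencies([cl], min_support=5) == []

    def test_no_centromere_file_is_noop(self):
        cl = cluster("chr1", 10, "end", "chr1", 90, "start", support=9)
        assert filter_adjacencies([cl], min_support=5, centromeres=None) == [cl]

    def test_three_predicates_leave_one_survivor(self):
        near = cluster("chr1", 2_500_000, "end", "chr1", 9_000_000, "start",
                       support=10)
        far = cluster("chr1", 20_000_000, "end", "chr1", 30_000_000, "start",
                      support=5)
        weak = cluster("chr1", 40_000_000, "end", "chr1", 50_000_000, "start",
                       support=2)
        kept = filter_adjacencies([near, far, weak], min_support=5,
                                  centromeres=[("chr1", 3_000_000, 3_100_000)],
                                  centromere_margin=1_000_000)
        assert kept == [far]

    def test_matched_normal_overlap_dropped(self):
        tumor = cluster("chr1", 10_000, "end", "chr1", 90_000, "start",
                        support=9)
        normal = cluster("chr1", 10_300, "end", "chr1", 89_800, "start",
                         support=3)
        assert filter_adjacencies([tumor], min_support=5,
                                  matched_normal_clusters=[normal]) == []
        shifted = cluster("chr2", 10_300, "end", "chr2", 89_800, "start",
                          support=3)
        assert filter_adjacencies([tumor], min_support=5,
                                  matched_normal_clusters=[shifted]) == [tumor]


class TestBuildGraph:
    def test_single_interval_no_adjacencies(self):
        g = build_graph(make_intervals(1), [])
        assert [e.kind for e in g.edges] == ["I"]
        assert g.telomeres == {("s", 1), ("t", 1)}

    def test_edge_counts_and_incidence(self, toy_graph):
        assert len(toy_graph.edges_of_kind("I")) == 4
        assert len(toy_graph.edges_of_kind(KIND_REFERENCE)) == 3
        assert len(toy_graph.edges_of_kind(KIND_VARIANT)) == 3
        for v in toy_graph.vertices:
            assert sum(e.kind == "I" for e in toy_graph.edges_at(v)) == 1

    def test_two_chromosomes_translocation(self):
        ivs = make_intervals(2) + make_intervals(2, chrom="chr2",
                                                 start_index=3)
        g = build_graph(ivs, [Adjacency((1, "end"), (4, "start"))])
        assert len(g.telomeres) == 4
        crossing = [e for e in g.edges_of_kind(KIND_VARIANT)
                    if g.interval(e.u[1]).chrom != g.interval(e.v[1]).chrom]
        assert len(crossing) == 1
        # reference edges never join chromosomes
        for e in g.edges_of_kind(KIND_REFERENCE):
            assert g.interval(e.u[1]).chrom == g.interval(e.v[1]).chrom

    def test_adjacency_to_missing_interval_raises(self):
        with pytest.raises(InputError):
            build_graph(make_intervals(2), [Adjacency((1, "end"), (5, "start"))])

    def test_self_junction_is_loop(self):
        g = build_graph(make_intervals(2), [Adjacency((1, "end"), (1, "end"))])
        loops = [e for e in g.edges_of_kind(KIND_VARIANT) if e.is_loop]
        assert len(loops) == 1 and loops[0].u == ("t", 1)


class TestTelomereLoss:
    def test_uniform_depth_unchanged(self):
        g = build_graph(make_intervals(2), [])
        depth = DepthProfile.from_intervals(g.intervals, [100, 100])
        g2 = detect_telomere_loss(g, depth, 0.5)
        assert g2 is g and not g2.has_sigma

    def test_terminal_drop_adds_sigma_edge(self):
        g = build_graph(make_intervals(2), [])
        depth = DepthProfile.from_intervals(g.intervals, [10_000, 100])
        g2 = detect_telomere_loss(g, depth, 0.5)
        assert g2.has_sigma and SIGMA in g2.telomeres
        sigma_edges = [e for e in g2.edges if SIGMA in (e.u, e.v)]
        assert len(sigma_edges) == 1
        # attaches to the boundary vertex of the retained (deeper) interval
        assert sigma_edges[0].other(SIGMA) == ("t", 1)

    def test_drop_explained_by_variant_edge_adds_nothing(self):
        ivs = make_intervals(3)
        g = build_graph(ivs, [Adjacency((2, "end"), (3, "start"))])
        depth = DepthProfile.from_intervals(ivs, [10_000, 10_000, 100])
        g2 = detect_telomere_loss(g, depth, 0.5)
        assert not g2.has_sigma

    def test_internal_dip_is_not_telomere_loss(self):
        # a low-coverage interval flanked by full coverage on both sides is
        # a missed internal deletion; the depression does not persist to a
        # chromosome end, so no sigma edge may be added
        ivs = make_intervals(3)
        g = build_graph(ivs, [])
        depth = DepthProfile.from_intervals(ivs, [10_000, 100, 10_000])
        g2 = detect_telomere_loss(g, depth, 0.5)
        assert not g2.has_sigma

    def test_sustained_terminal_loss_over_two_intervals(self):
        ivs = make_intervals(3)
        g = build_graph(ivs, [])
        depth = DepthProfile.from_intervals(ivs, [10_000, 120, 80])
        g2 = detect_telomere_loss(g, depth, 0.5)
        sigma_edges = [e for e in g2.edges if SIGMA in (e.u, e.v)]
        assert [e.other(SIGMA) for e in sigma_edges] == [("t", 1)]


def test_depth_profile_validation():
    with pytest.raises(InputError):
        DepthProfile(np.array([-1.0]), np.array([100.0]))
    with pytest.raises(InputError):
        DepthProfile(np.array([1.0, 2.0]), np.array([100.0]))
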