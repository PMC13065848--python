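"""Jaccard arithmetic, prefilters, thresholds, graph clustering."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from telofuse.cluster import (
    build_cluster_graph,
    build_interval_index,
    edge_threshold,
    find_candidates,
    jaccard,
    pick_representative,
    prefilter_pair,
    reciprocal_overlap,
    select_clusterable,
)
from telofuse.core_io import AlignmentSegment, PipelineConfig
from telofuse.fusion_annotate import InsertionInterval, build_event


def iv(chrom, start, end, strand="+"):
    return InsertionInterval(chrom, start, end, strand)


def make_event(rid, insertion_coords, flank_len=1000, score=2.0):
    """Event with the given interior insertions; query axis laid out
    contiguously so query_span is deterministic."""
    segs = []
    q = 0
    segs.append(AlignmentSegment(rid, q, q + flank_len, "subtel_1", 0, flank_len,
                                 "+", score * flank_len, flank_len))
    q += flank_len
    for chrom, start, end in insertion_coords:
        L = end - start
        segs.append(AlignmentSegment(rid, q, q + L, chrom, start, end, "+",
                                     score * L, L))
        q += L
    segs.append(AlignmentSegment(rid, q, q + flank_len, "subtel_2", 0, flank_len,
                                 "+", score * flank_len, flank_len))
    return build_event(segs)


class TestSelectClusterable:
    def test_two_alignment_events_excluded(self):
        evs = [make_event("a", []), make_event("b", [("chr1", 0, 500)])]
        kept = select_clusterable(evs)
        assert [e.read_id for e in kept] == ["b"]
        assert kept[0].n_insertions == 1

    def test_flank_removal_arithmetic(self):
        ev = make_event("r", [("chr1", i * 1000, i * 1000 + 500) for i in range(15)])
        assert ev.n_alignments == 17
        assert len(select_clusterable([ev])[0].insertions) == 15


class TestOverlapAndCandidates:
    @pytest.mark.parametrize("b_start,b_end,expected", [
        (0, 1000, True),       # identical: reciprocal overlap 1.0
        (500, 1500, False),    # reciprocal overlap 0.5
        (100, 1000, True),     # 0.9 both sides
    ])
    def test_reciprocal_overlap_rule(self, b_start, b_end, expected):
        a, b = iv("chr1", 0, 1000), iv("chr1", b_start, b_end)
        assert reciprocal_overlap(a, b, 0.80) is expected

    def test_find_candidates_requires_shared_insertion(self, config):
        evs = [
            make_event("a", [("chr1", 0, 1000)]),
            make_event("b", [("chr1", 100, 1000)]),
            make_event("c", [("chr1", 500, 1500)]),
            make_event("d", [("chr2", 0, 1000)]),
        ]
        index = build_interval_index(evs)
        assert find_candidates(evs[0], 0, index, evs, config) == [1]


class TestPrefilter:
    def test_count_diff_within_25_percent_compared(self, config):
        a = make_event("a", [("chr1", i * 1000, i * 1000 + 100) for i in range(4)])
        b = make_event("b", [("chr1", i * 1000, i * 1000 + 100) for i in range(5)])
        # query lengths differ by 100/2500 = 4% exactly -> not skipped
        assert abs(a.query_span - b.query_span) / max(a.query_span, b.query_span) <= 0.04
        assert prefilter_pair(a, b, config) is True

    def test_count_diff_over_25_percent_skipped(self, config):
        a = make_event("a", [("chr1", i * 1000, i * 1000 + 100) for i in range(4)])
        b = make_event("b", [("chr1", i * 1000, i * 1000 + 100) for i in range(6)])
        assert prefilter_pair(a, b, config) is False

    def test_query_length_diff_over_4_percent_skipped(self, config):
        a = make_event("a", [("chr1", 0, 8000)])
        b = make_event("b", [("chr1", 0, 8500)])
        # counts equal; lengths 10000 vs 10500 differ by 4.8%
        assert prefilter_pair(a, b, config) is False


class TestJaccard:
    def test_identical_sets_score_one(self, config):
        ins = [iv("chr1", 0, 500), iv("chr2", 0, 700), iv("chr3", 10, 400)]
        assert jaccard(ins, list(ins), config) == 1.0

    def test_disjoint_sets_score_zero(self, config):
        a = [iv("chr1", 0, 500), iv("chr2", 0, 500)]
        b = [iv("chr3", 0, 500), iv("chr4", 0, 500)]
        assert jaccard(a, b, config) == 0.0

    def test_partial_overlap_set_enumeration(self, config):
        shared = [iv("chr1", 0, 500), iv("chr2", 0, 700)]
        a = shared + [iv("chr3", 0, 400)]
        b = shared + [iv("chr4", 0, 400)]
        # |A n B| = 2, |A u B| = 4
        assert jaccard(a, b, config) == 0.5

    def test_both_empty_defined_zero(self, config):
        assert jaccard([], [], config) == 0.0

    @given(st.integers(0, 5), st.integers(0, 5), st.integers(0, 4))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_range(self, na, nb, shared):
        config = PipelineConfig()
        a = [iv("chr9", i * 10_000, i * 10_000 + 500) for i in range(shared)] + \
            [iv("chr1", i * 10_000, i * 10_000 + 500) for i in range(na)]
        b = [iv("chr9", i * 10_000, i * 10_000 + 500) for i in range(shared)] + \
            [iv("chr2", i * 10_000, i * 10_000 + 500) for i in range(nb)]
        ab, ba = jaccard(a, b, config), jaccard(b, a, config)
        assert ab == ba
        assert 0.0 <= ab <= 1.0
        if a:
            assert jaccard(a, a, config) == 1.0


class TestEdgeThreshold:
    @pytest.mark.parametrize("size,expected", [
        (1, 1), (2, 1), (3, 0.66), (4, 0.66), (5, 0.66), (6, 0.5), (9, 0.5),
    ])
    def test_threshold_table(self, size, expected, config):
        assert edge_threshold(size, config) == expected

    def test_size_below_one_errors(self, config):
        with pytest.raises(ValueError):
            edge_threshold(0, config)


class TestClusterGraph:
    def test_identical_events_one_cluster(self, config):
        evs = [make_event(f"r{i}", [("chr1", 0, 500), ("chr2", 100, 900)])
               for i in range(5)]
        clusters, g = build_cluster_graph(evs, config)
        assert len(clusters) == 1
        assert clusters[0].member_read_ids == {f"r{i}" for i in range(5)}

    def test_disjoint_groups_two_clusters(self, config):
        evs = [make_event(f"a{i}", [("chr1", 0, 500)]) for i in range(3)] + \
              [make_event(f"b{i}", [("chr5", 0, 500)]) for i in range(3)]
        clusters, _g = build_cluster_graph(evs, config)
        memberships = sorted(tuple(sorted(c.member_read_ids)) for c in clusters)
        assert memberships == [("a0", "a1", "a2"), ("b0", "b1", "b2")]

    def test_edge_cap_keeps_large_group_connected(self, config):
        """30 identical events stay one cluster despite the 10-edge cap
        (connectivity survives via transitivity)."""
        evs = [make_event(f"r{i:02d}", [("chr1", 0, 500), ("chr3", 0, 800)])
               for i in range(30)]
        clusters, g = build_cluster_graph(evs, config)
        assert len(clusters) == 1
        assert len(clusters[0].member_read_ids) == 30

    def test_capped_components_match_uncapped_for_small_groups(self, config):
        """Groups of <= 11 members: each node's own top-10 covers every
        mate, so capping cannot change components."""
        rng = np.random.default_rng(5)
        evs = []
        for group in range(4):
            size = int(rng.integers(2, 12))
            for i in range(size):
                evs.append(make_event(
                    f"g{group}_m{i}",
                    [("chr2", group * 20_000, group * 20_000 + 600)]))
        uncapped_cfg = PipelineConfig(max_edges_per_node=10_000)
        got = build_cluster_graph(list(evs), config)[0]
        want = build_cluster_graph(list(evs), uncapped_cfg)[0]
        assert sorted(tuple(sorted(c.member_read_ids)) for c in got) == \
            sorted(tuple(sorted(c.member_read_ids)) for c in want)

    def test_every_edge_ranked_top10_by_an_endpoint(self, config):
        evs = [make_event(f"r{i:02d}", [("chr1", 0, 500)]) for i in range(25)]
        _clusters, g = build_cluster_graph(evs, config)

        def rank(node, other):
            incident = sorted(
                (-g.edges[node, v]["jaccard"], v) for v in g.neighbors(node))
            return incident.index((-g.edges[node, other]["jaccard"], other))

        cap = config.max_edges_per_node
        for u, v in g.edges:
            assert rank(u, v) < cap or rank(v, u) < cap

    def test_partition_covers_all_events(self, config):
        rng = np.random.default_rng(8)
        evs = []
        for i in range(20):
            chrom = f"chr{int(rng.integers(1, 5))}"
            start = int(rng.integers(0, 50_000))
            evs.append(make_event(f"r{i}", [(chrom, start, start + 400)]))
        clusters, _ = build_cluster_graph(evs, config)
        seen = [rid for c in clusters for rid in c.member_read_ids]
        assert sorted(seen) == sorted(e.read_id for e in evs)
        assert all(c.representative_read_id in c.member_read_ids for c in clusters)

    def test_singletons_get_unique_ids(self, config):
        evs = [make_event("x", [("chr1", 0, 500)]),
               make_event("y", [("chr7", 30_000, 30_400)])]
        clusters, _ = build_cluster_graph(evs, config)
        ids = [c.cluster_id for c in clusters]
        assert len(ids) == len(set(ids)) == 2


class TestRepresentative:
    def test_singleton(self):
        ev = make_event("only", [("chr1", 0, 500)])
        assert pick_representative([ev]) == "only"

    def test_highest_per_base_score_wins(self):
        hi = make_event("hi", [("chr1", 0, 500)], score=1.8)
        lo = make_event("lo", [("chr1", 0, 500)], score=1.6)
        assert pick_representative([lo, hi]) == "hi"

    def test_tie_breaks_lexicographically(self):
        a = make_event("aaa", [("chr1", 0, 500)])
        b = make_event("bbb", [("chr1", 0, 500)])
        assert pick_representative([b, a]) == "aaa"
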