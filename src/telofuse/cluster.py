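"""Group complex-fusion reads into unique events.

Amplicon sequencing reads each fusion molecule many times, so reads
must be deduplicated into events. Simple head-to-head fusions (two
alignments) carry no distinguishing interior structure and are left
out; complex reads (>= 3 alignments) are compared on their insertion
sets — flanks are the PCR-targeted sub-telomeres shared by everything
and are ignored. An interval index retrieves candidate mates, cheap
prefilters discard obvious non-mates, and a Jaccard similarity over
position-matched insertions decides edges in a sparse graph whose
connected components are the clusters.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
from intervaltree import IntervalTree

from .core_io import FusionEvent, PipelineConfig
from .fusion_annotate import InsertionInterval


@dataclass
class FusionCluster:
    cluster_id: int
    member_read_ids: set[str]
    representative_read_id: str
    consensus_insertions: list[InsertionInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representative_read_id not in self.member_read_ids:
            raise ValueError("representative must be a cluster member")


def select_clusterable(events: list[FusionEvent]) -> list[FusionEvent]:
    """Complex fusions only: reads with >= 3 alignments."""
    return [ev for ev in events if ev.n_alignments >= 3]


def reciprocal_overlap(a, b, fraction: float = 0.80) -> bool:
    """True iff both intervals are covered >= fraction by their overlap
    (and share a chromosome)."""
    if a.chrom != b.chrom:
        return False
    ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    if ov <= 0:
        return False
    return (ov / (a.ref_end - a.ref_start) >= fraction
            and ov / (b.ref_end - b.ref_start) >= fraction)


def build_interval_index(events: list[FusionEvent]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over all clusterable insertions,
    mapping to event indices."""
    index: dict[str, IntervalTree] = {}
    for idx, ev in enumerate(events):
        for ins in ev.insertions:
            index.setdefault(ins.chrom, IntervalTree()).addi(
                ins.ref_start, ins.ref_end, idx)
    return index


def find_candidates(
    event: FusionEvent,
    event_index: int,
    index: dict[str, IntervalTree],
    events: list[FusionEvent],
    config: Optional[PipelineConfig] = None,
) -> list[int]:
    """Indices of events sharing >= 1 sufficiently-overlapping insertion
    (reciprocal overlap >= overlap_fraction) with the query event."""
    config = config or PipelineConfig()
    hits: set[int] = set()
    for ins in event.insertions:
        tree = index.get(ins.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(ins.ref_start, ins.ref_end):
            other_idx = iv.data
            if other_idx == event_index or other_idx in hits:
                continue
            probe = InsertionInterval(ins.chrom, iv.begin, iv.end, "+")
            if reciprocal_overlap(ins, probe, config.overlap_fraction):
                hits.add(other_idx)
    return sorted(hits)


def prefilter_pair(
    a: FusionEvent, b: FusionEvent, config: Optional[PipelineConfig] = None
) -> bool:
    """Cheap mate screen; False means the pair is not assessed further.

    Pairs are skipped when insertion counts differ by more than 25% or
    query lengths differ by more than 4% (relative to the larger).
    """
    config = config or PipelineConfig()
    na, nb = ev_n(a), ev_n(b)
    if na == 0 and nb == 0:
        return False
    if abs(na - nb) / max(na, nb) > config.insertion_count_rel_diff:
        return False
    la, lb = a.query_span, b.query_span
    if abs(la - lb) / max(la, lb) > config.query_len_rel_diff:
        return False
    return True


def ev_n(event: FusionEvent) -> int:
    return event.n_insertions


def jaccard(
    insertions_a: list,
    insertions_b: list,
    config: Optional[PipelineConfig] = None,
) -> float:
    """Jaccard similarity |A n B| / |A u B| over two insertion sets.

    Insertion identity across reads is positional: two insertions are
    equivalent when their reference intervals reciprocally overlap by
    >= overlap_fraction on the same chromosome. The intersection is a
    greedy one-to-one pairing by descending overlap (deterministic
    tie-break), so no insertion is matched twice. Symmetric; two empty
    sets score 0.
    """
    config = config or PipelineConfig()
    if not insertions_a and not insertions_b:
        return 0.0
    pairs = []
    for i, a in enumerate(insertions_a):
        for j, b in enumerate(insertions_b):
            if reciprocal_overlap(a, b, config.overlap_fraction):
                ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
                pairs.append((-ov, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for _negov, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched += 1
    union = len(insertions_a) + len(insertions_b) - matched
    return matched / union if union else 0.0


def edge_threshold(set_size: int, config: Optional[PipelineConfig] = None) -> float:
    """Set-size-dependent Jaccard threshold: sizes 1..6 use the
    configured six-entry table, larger sets the large-set threshold.
    Small sets must match perfectly; large sets tolerate misses."""
    config = config or PipelineConfig()
    if set_size < 1:
        raise ValueError("set size must be >= 1")
    if set_size <= 6:
        return config.jaccard_thresholds[set_size - 1]
    return config.jaccard_threshold_large


def build_cluster_graph(
    events: list[FusionEvent], config: Optional[PipelineConfig] = None
) -> tuple[list[FusionCluster], nx.Graph]:
    """Cluster clusterable events into connected components.

    An edge joins two events when the prefilter passes and their
    insertion-set Jaccard reaches the threshold indexed by the smaller
    set size. For sparsity each node retains only its 10 best edges
    (by Jaccard, deterministic tie-break); the retained edge set is the
    union over nodes, so transitive connectivity across large groups
    survives the cap. Every event — including edgeless singletons —
    receives exactly one cluster id.
    """
    config = config or PipelineConfig()
    index = build_interval_index(events)
    g = nx.Graph()
    g.add_nodes_from(range(len(events)))
    scored: dict[tuple[int, int], float] = {}
    for i, ev in enumerate(events):
        for j in find_candidates(ev, i, index, events, config):
            if j < i:
                continue  # evaluated once per unordered pair
            other = events[j]
            if not prefilter_pair(ev, other, config):
                continue
            size = min(ev.n_insertions, other.n_insertions)
            if size < 1:
                continue
            sim = jaccard(ev.insertions, other.insertions, config)
            if sim >= edge_threshold(size, config):
                scored[(i, j)] = sim
    # per-node cap: each node ranks its max_edges_per_node best edges;
    # an edge survives if either endpoint ranks it
    ranked: dict[int, list[tuple[float, int, int]]] = {}
    for (i, j), sim in scored.items():
        ranked.setdefault(i, []).append((sim, i, j))
        ranked.setdefault(j, []).append((sim, j, i))
    kept: set[tuple[int, int]] = set()
    for node, edges in ranked.items():
        edges.sort(key=lambda t: (-t[0], t[2]))
        for sim, a, b in edges[: config.max_edges_per_node]:
            kept.add((min(a, b), max(a, b)))
    for (i, j) in kept:
        g.add_edge(i, j, jaccard=scored[(i, j)])

    clusters = []
    components = sorted(nx.connected_components(g), key=min)
    for cid, comp in enumerate(components):
        members = {events[i].read_id for i in comp}
        rep = pick_representative([events[i] for i in comp])
        consensus = [
            InsertionInterval(s.chrom, s.ref_start, s.ref_end, s.strand)
            for i in sorted(comp) if events[i].read_id == rep
            for s in events[i].insertions
        ]
        clusters.append(FusionCluster(cid, members, rep, consensus))
        for i in comp:
            events[i].cluster_id = cid
    return clusters, g


def pick_representative(members: list[FusionEvent]) -> str:
    """Member with the highest average alignment score per aligned base;
    ties break toward the lexicographically smaller read id."""
    if not members:
        raise ValueError("empty cluster")

    def keyfn(ev: FusionEvent):
        total = sum(s.aligned_bases for s in ev.segments)
        rate = sum(s.score for s in ev.segments) / total if total else 0.0
        return (-rate, ev.read_id)

    return min(members, key=keyfn).read_id
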