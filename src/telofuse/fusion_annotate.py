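"""Annotate chained segments into fusion events.

A fusion molecule's first and last alignments are the PCR-targeted
sub-telomere flanks; interior alignments are templated insertions.
Consecutive segments are typed on the query axis: overlapping query
intervals indicate junction microhomology, abutting intervals a blunt
join, and a coverage gap an unmapped insertion or error tract. Per-event
analytics (insertion origin, 10-kb hotspots, foldbacks) and corpus
summaries follow.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core_io import (
    AlignmentSegment,
    ComplexityClass,
    FusionEvent,
    Junction,
    JunctionKind,
    OriginClass,
)


@dataclass(frozen=True)
class InsertionInterval:
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    origin_class: Optional[OriginClass] = None

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start <= 0:
            raise ValueError("insertion size must be > 0")

    @property
    def size(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class Hotspot:
    """A <=10-kb genomic window contributing >=2 insertions to one event."""

    chrom: str
    members: tuple[InsertionInterval, ...]
    overlapping_flag: bool

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a hotspot needs >= 2 member insertions")


def classify_junction(
    left: AlignmentSegment, right: AlignmentSegment, left_index: int = 0
) -> Junction:
    """Type the junction between two consecutive segments of one read.

    k = left.query_end - right.query_start: k > 0 is k bases of
    microhomology (shared by both alignments), k = 0 a blunt join,
    k < 0 a |k|-base unmapped gap.
    """
    k = left.query_end - right.query_start
    if k > 0:
        return Junction(left_index, JunctionKind.MICROHOMOLOGY, k)
    if k == 0:
        return Junction(left_index, JunctionKind.BLUNT, 0)
    return Junction(left_index, JunctionKind.INSERTION_GAP, -k)


def build_event(segments: list[AlignmentSegment]) -> FusionEvent:
    """Assemble an annotated fusion event from >= 2 chained segments."""
    if len(segments) < 2:
        raise ValueError("a fusion event needs >= 2 segments; fewer alignments "
                         "indicate an unfused or unmappable read")
    segments = sorted(segments, key=lambda s: (s.query_start, s.query_end))
    junctions = [
        classify_junction(segments[i], segments[i + 1], i)
        for i in range(len(segments) - 1)
    ]
    return FusionEvent(segments[0].read_id, segments, junctions)


def classify_origin(
    insertion: AlignmentSegment | InsertionInterval,
    catalogue: dict[str, OriginClass],
) -> OriginClass:
    """Origin of an insertion = catalogue tag of its reference contig."""
    try:
        return catalogue[insertion.chrom]
    except KeyError:
        raise KeyError(
            f"reference {insertion.chrom!r} is not tagged in the catalogue"
        ) from None


def _as_interval(seg) -> InsertionInterval:
    if isinstance(seg, InsertionInterval):
        return seg
    return InsertionInterval(seg.chrom, seg.ref_start, seg.ref_end, seg.strand)


def detect_hotspots(
    insertions: Iterable[AlignmentSegment | InsertionInterval],
    window: int = 10_000,
) -> list[Hotspot]:
    """Group one event's insertions into 10-kb hotspots.

    Single linkage per chromosome: two insertions join one hotspot iff
    the gap between their reference intervals is <= window. Only groups
    with >= 2 members are hotspots; overlapping_flag is set when any
    member pair overlaps by >= 1 bp. Order-independent.
    """
    per_chrom: dict[str, list[InsertionInterval]] = {}
    for ins in insertions:
        iv = _as_interval(ins)
        per_chrom.setdefault(iv.chrom, []).append(iv)
    hotspots = []
    for chrom in sorted(per_chrom):
        ivs = sorted(per_chrom[chrom], key=lambda i: (i.ref_start, i.ref_end))
        group: list[InsertionInterval] = []
        max_end = None
        for iv in ivs + [None]:
            if iv is not None and (max_end is None or iv.ref_start - max_end <= window):
                group.append(iv)
                max_end = iv.ref_end if max_end is None else max(max_end, iv.ref_end)
                continue
            if len(group) >= 2:
                overlapping = any(
                    a.ref_start < b.ref_end and b.ref_start < a.ref_end
                    for x, a in enumerate(group) for b in group[x + 1:]
                )
                hotspots.append(Hotspot(chrom, tuple(group), overlapping))
            if iv is not None:
                group, max_end = [iv], iv.ref_end
            else:
                group, max_end = [], None
    return hotspots


def detect_foldback(
    event: FusionEvent, reciprocal_overlap: float = 0.8
) -> list[tuple[AlignmentSegment, AlignmentSegment]]:
    """Flag segment pairs of one event mapping to (nearly) the same
    reference locus in opposite orientations — the signature of
    fold-back-primed synthesis."""
    pairs = []
    segs = event.segments
    for i, a in enumerate(segs):
        for b in segs[i + 1:]:
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
            if ov <= 0:
                continue
            if (ov / a.ref_length >= reciprocal_overlap
                    and ov / b.ref_length >= reciprocal_overlap):
                pairs.append((a, b))
    return pairs


def summarise(
    events: list[FusionEvent],
    catalogue: Optional[dict[str, OriginClass]] = None,
) -> dict[str, pd.DataFrame]:
    """Corpus-level analytics tables.

    Returns: alignment_counts (distribution of alignments per read),
    complexity (class proportions), junctions (kind proportions and the
    microhomology-size median), sizes (flank/insertion size medians),
    origins (per-contig counts for flanks and insertions, plus the
    external-DNA fraction when a catalogue is given).
    """
    if not events:
        raise ValueError("no events to summarise")
    n_aln = pd.Series([ev.n_alignments for ev in events], name="n_alignments")
    alignment_counts = (
        n_aln.value_counts().sort_index().rename("n_reads").reset_index()
    )

    cls = pd.Series([ev.complexity_class.value for ev in events])
    complexity = (
        cls.value_counts(normalize=True).rename("proportion")
        .reindex([c.value for c in ComplexityClass], fill_value=0.0)
        .rename_axis("complexity_class").reset_index()
    )

    kinds = [j.kind.value for ev in events for j in ev.junctions]
    micro = [j.size for ev in events for j in ev.junctions
             if j.kind is JunctionKind.MICROHOMOLOGY]
    junctions = (
        pd.Series(kinds).value_counts(normalize=True).rename("proportion")
        .reindex([k.value for k in JunctionKind], fill_value=0.0)
        .rename_axis("kind").reset_index()
    )
    junctions["median_size"] = np.nan
    if micro:
        junctions.loc[junctions["kind"] == JunctionKind.MICROHOMOLOGY.value,
                      "median_size"] = float(np.median(micro))

    flank_sizes = [s.ref_length for ev in events
                   for s in (ev.flank_left, ev.flank_right)]
    ins_sizes = [s.ref_length for ev in events for s in ev.insertions]
    sizes = pd.DataFrame({
        "role": ["flank", "insertion"],
        "n": [len(flank_sizes), len(ins_sizes)],
        "median_size": [float(np.median(flank_sizes)) if flank_sizes else np.nan,
                        float(np.median(ins_sizes)) if ins_sizes else np.nan],
    })

    rows = []
    for ev in events:
        last = len(ev.segments) - 1
        for i, s in enumerate(ev.segments):
            role = "flank" if i in (0, last) else "insertion"
            rows.append((role, s.chrom))
    origins = (
        pd.DataFrame(rows, columns=["role", "chrom"])
        .groupby(["role", "chrom"]).size().rename("n").reset_index()
    )
    out = {
        "alignment_counts": alignment_counts,
        "complexity": complexity,
        "junctions": junctions,
        "sizes": sizes,
        "origins": origins,
    }
    if catalogue is not None:
        ins_origins = [classify_origin(s, catalogue).value
                       for ev in events for s in ev.insertions]
        if ins_origins:
            ser = pd.Series(ins_origins).value_counts(normalize=True)
            external = float(ser.reindex(
                [OriginClass.EXTERNAL_PLASMID.value,
                 OriginClass.EXTERNAL_ECOLI.value], fill_value=0.0).sum())
        else:
            external = float("nan")
        out["external_fraction"] = pd.DataFrame(
            {"metric": ["external_insertion_fraction"], "value": [external]}
        )
    return out


def summarise_insertion_table(table: pd.DataFrame, window: int = 10_000) -> dict:
    """Per-molecule insertion-table analytics: insertion count, median
    insertion size, and the number of multi-member 10-kb hotspots.

    `table` needs columns chrom, ref_start, ref_end, strand (one row per
    insertion of one molecule).
    """
    ivs = [InsertionInterval(r.chrom, int(r.ref_start), int(r.ref_end), r.strand)
           for r in table.itertuples()]
    hotspots = detect_hotspots(ivs, window=window)
    return {
        "n_insertions": len(ivs),
        "median_insertion_size": float(np.median([iv.size for iv in ivs]))
        if ivs else float("nan"),
        "n_hotspots": len(hotspots),
        "n_hotspot_insertions": sum(len(h.members) for h in hotspots),
        "n_overlapping_hotspots": sum(h.overlapping_flag for h in hotspots),
    }
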