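"""Choose an optimal set of spanning alignments from mapper candidates.

The external mapper runs in report-all-candidates mode, so each read
arrives with many overlapping candidate alignments per locus. The
pipeline must pick the chain of candidates that best explains the read
end to end. Overlap between adjacent chosen segments is allowed — that
overlap IS the junction microhomology signal — but is penalised at the
per-base match rate so that redundant candidates never pay.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .core_io import AlignmentSegment, PipelineConfig

#: Recommended external mapper invocation (report-all-candidates mode).
MAPPER_FLAGS = "-c 1000 -A2 -B3 -O5 -E2 -T0 -L0 -D 0.25 -r 1.25 -d 200 -k 11 -a"


@dataclass
class CandidateSet:
    """All candidate alignments of one read."""

    read_id: str
    read_length: int
    candidates: list[AlignmentSegment]

    def __post_init__(self) -> None:
        for c in self.candidates:
            if c.query_start < 0 or c.query_end > self.read_length:
                raise ValueError(
                    f"candidate query interval [{c.query_start}, {c.query_end}) "
                    f"outside read of length {self.read_length}"
                )


def segment_sort_key(seg: AlignmentSegment) -> tuple:
    """Deterministic total order: by query_start, then query_end, then
    higher score first, then chrom / ref_start / strand."""
    return (seg.query_start, seg.query_end, -seg.score, seg.chrom,
            seg.ref_start, seg.strand)


def chain_value(
    chain: list[AlignmentSegment], config: Optional[PipelineConfig] = None
) -> Optional[float]:
    """Objective value of an ordered chain, or None if infeasible.

    The chain must be in segment_sort_key order. Each consecutive pair
    may overlap on the query by at most half the shorter segment
    (larger overlaps mean the candidates are alternative placements of
    the same sequence, not a split alignment); the value is
    sum(score) - match_score * (overlapped bases), so sharing a base
    between two segments can never beat aligning it once. Coverage gaps
    are unpenalised — they surface later as insertion-gap junctions.
    """
    config = config or PipelineConfig()
    total = 0.0
    for i, seg in enumerate(chain):
        total += seg.score
        if i:
            prev = chain[i - 1]
            ov = min(prev.query_end, seg.query_end) - max(prev.query_start, seg.query_start)
            if ov > 0:
                if ov > 0.5 * min(prev.query_length, seg.query_length):
                    return None
                total -= config.match_score * ov
    return total


def choose_spanning_set(
    candidate_set: CandidateSet, config: Optional[PipelineConfig] = None
) -> list[AlignmentSegment]:
    """Select the optimal spanning chain of candidate alignments.

    Exact dynamic programme over candidates in segment_sort_key order:
    because the objective couples only consecutive chain members, the
    best chain ending at each candidate is computable from the best
    feasible predecessor. Ties break deterministically toward the
    earlier candidate in sort order. The result equals exhaustive
    enumeration of all feasible chains.
    """
    config = config or PipelineConfig()
    if not candidate_set.candidates:
        raise ValueError(f"read {candidate_set.read_id!r}: no candidate alignments")
    cands = sorted(candidate_set.candidates, key=segment_sort_key)
    n = len(cands)
    best = [c.score for c in cands]  # best chain value ending at i
    prev = [-1] * n
    for i in range(1, n):
        ci = cands[i]
        for j in range(i):
            cj = cands[j]
            ov = min(cj.query_end, ci.query_end) - max(cj.query_start, ci.query_start)
            if ov > 0 and ov > 0.5 * min(cj.query_length, ci.query_length):
                continue
            penalty = config.match_score * ov if ov > 0 else 0.0
            val = best[j] + ci.score - penalty
            if val > best[i]:
                best[i] = val
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -i))
    chain = []
    while end != -1:
        chain.append(cands[end])
        end = prev[end]
    chain.reverse()
    return chain


def merge_colinear(
    chain: list[AlignmentSegment],
    max_gap: int = 300,
    max_diag_drift: int = 150,
) -> list[AlignmentSegment]:
    """Fuse consecutive chain segments that continue the same alignment.

    Error tracts can split one genuine alignment into two chained
    pieces. Two consecutive segments are merged when they lie on the
    same chromosome and strand, their query and reference gaps are both
    small (<= max_gap), and the gaps agree (diagonal drift <=
    max_diag_drift), i.e. the second segment resumes where the first
    left off rather than jumping to a new locus.
    """
    if not chain:
        return chain
    merged = [chain[0]]
    for seg in chain[1:]:
        prev = merged[-1]
        qgap = seg.query_start - prev.query_end
        if seg.chrom == prev.chrom and seg.strand == prev.strand:
            if seg.strand == "+":
                rgap = seg.ref_start - prev.ref_end
                ref_ok = prev.ref_start <= seg.ref_start
            else:
                rgap = prev.ref_start - seg.ref_end
                ref_ok = seg.ref_end <= prev.ref_end
            if (ref_ok and -max_diag_drift <= qgap <= max_gap
                    and -max_diag_drift <= rgap <= max_gap
                    and abs(qgap - rgap) <= max_diag_drift):
                merged[-1] = replace(
                    prev,
                    query_end=max(prev.query_end, seg.query_end),
                    ref_start=min(prev.ref_start, seg.ref_start),
                    ref_end=max(prev.ref_end, seg.ref_end),
                    score=prev.score + seg.score,
                    aligned_bases=prev.aligned_bases + seg.aligned_bases,
                )
                continue
        merged.append(seg)
    return merged


def mapper_contract() -> str:
    """The recommended external mapper invocation.

    The pipeline consumes any SAM that reports all candidate alignments
    per read with soft clips retained; the command below is the tested
    configuration (low thresholds and short seeds for sensitivity on
    chimeric amplicons, -a to emit every candidate).
    """
    return f"bwa mem {MAPPER_FLAGS} <reference.fa> <reads.fastq>"
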