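"""Score pipeline output against simulation ground truth.

Insertion-level scoring matches called insertions to truth insertions
one-to-one with a 50-bp tolerance on both breakpoints; cluster-level
scoring pairs each true cluster (reads sharing an event id) with the
called cluster of maximal intersection. Precision, recall and F1 are
pooled (micro-averaged) across reads; per-cluster macro averages are
reported alongside.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core_io import FusionEvent
from .simfusion import TruthInsertion, decode_truth_id

#: Breakpoint tolerance (bp) for a called insertion to count as correct.
DEFAULT_TOLERANCE = 50


@dataclass
class BenchmarkCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "BenchmarkCounts") -> "BenchmarkCounts":
        return BenchmarkCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else math.nan


def prf(counts: BenchmarkCounts) -> tuple[float, float, float]:
    """(precision, recall, f1); NaN marks an undefined ratio."""
    return counts.precision, counts.recall, counts.f1


def match_insertions(
    truth: Sequence[TruthInsertion],
    called: Sequence,
    tolerance: int = DEFAULT_TOLERANCE,
    require_strand: bool = False,
) -> BenchmarkCounts:
    """One-to-one matching of called vs truth insertions.

    A call matches a truth insertion when chromosomes agree and both
    |start - start_true| and |end - end_true| are <= tolerance (strand
    optionally required). Greedy by ascending total breakpoint offset,
    deterministic, order-invariant; unmatched calls are FP, unmatched
    truths FN.
    """
    pairs = []
    for ti, t in enumerate(truth):
        for ci, c in enumerate(called):
            if c.chrom != t.chrom:
                continue
            if require_strand and getattr(c, "strand", t.strand) != t.strand:
                continue
            ds = abs(c.ref_start - t.start) if hasattr(c, "ref_start") else abs(c.start - t.start)
            de = abs(c.ref_end - t.end) if hasattr(c, "ref_end") else abs(c.end - t.end)
            if ds <= tolerance and de <= tolerance:
                pairs.append((ds + de, ti, ci))
    pairs.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    tp = 0
    for _cost, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        tp += 1
    return BenchmarkCounts(tp=tp, fp=len(called) - tp, fn=len(truth) - tp)


def benchmark_insertions(
    events: Iterable[FusionEvent],
    tolerance: int = DEFAULT_TOLERANCE,
) -> tuple[BenchmarkCounts, pd.DataFrame]:
    """Pool insertion-level TP/FP/FN over reads with truth-encoding ids.

    Also returns the expected-vs-observed table of per-read insertion
    counts with its exact-agreement rate.
    """
    total = BenchmarkCounts()
    rows = []
    for ev in events:
        _event_id, truth = decode_truth_id(ev.read_id)
        counts = match_insertions(truth, ev.insertions, tolerance=tolerance)
        total = total + counts
        rows.append((ev.read_id, len(truth), ev.n_insertions))
    table = pd.DataFrame(rows, columns=["read_id", "n_true_insertions",
                                        "n_called_insertions"])
    if len(table):
        table.attrs["agreement_rate"] = float(
            (table.n_true_insertions == table.n_called_insertions).mean())
    return total, table


def expected_vs_observed_alignments(
    events: Iterable[FusionEvent],
) -> pd.DataFrame:
    """Per-read table of true vs called insertion counts."""
    _counts, table = benchmark_insertions(events)
    return table


def benchmark_clusters(
    true_clusters: dict[str, set[str]],
    called_clusters: dict[int, set[str]],
) -> tuple[BenchmarkCounts, pd.DataFrame]:
    """Score called clusters against truth clusters.

    Each true cluster is paired with the called cluster of maximal
    intersection (greedy by descending intersection, each called
    cluster used at most once); tp = |intersection|, fn = members of
    the true cluster missing from it, fp = extra members of the called
    cluster. Pooled counts plus a per-cluster size table are returned.
    """
    cands = []
    for t_id, t_members in true_clusters.items():
        for c_id, c_members in called_clusters.items():
            inter = len(t_members & c_members)
            if inter:
                cands.append((-inter, str(t_id), str(c_id), t_id, c_id))
    cands.sort()
    paired: dict = {}
    used_called: set = set()
    for _ni, _ts, _cs, t_id, c_id in cands:
        if t_id in paired or c_id in used_called:
            continue
        paired[t_id] = c_id
        used_called.add(c_id)

    total = BenchmarkCounts()
    rows = []
    for t_id, t_members in sorted(true_clusters.items(), key=lambda kv: str(kv[0])):
        c_id = paired.get(t_id)
        c_members = called_clusters.get(c_id, set()) if c_id is not None else set()
        inter = t_members & c_members
        counts = BenchmarkCounts(
            tp=len(inter),
            fn=len(t_members - c_members),
            fp=len(c_members - t_members),
        )
        total = total + counts
        rows.append((t_id, c_id, len(t_members), len(c_members), len(inter)))
    table = pd.DataFrame(rows, columns=["true_cluster", "called_cluster",
                                        "expected_size", "observed_size",
                                        "intersection"])
    return total, table


def true_clusters_from_reads(read_ids: Iterable[str]) -> dict[str, set[str]]:
    """Truth clusters: reads sharing an event id in their truth-encoded id."""
    clusters: dict[str, set[str]] = {}
    for rid in read_ids:
        event_id, _ = decode_truth_id(rid)
        clusters.setdefault(event_id, set()).add(rid)
    return clusters
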