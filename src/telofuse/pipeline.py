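"""End-to-end orchestration of the pipeline stages.

Stages run in protocol order — read filtering, primer identification,
mapping/selection, annotation, clustering — each writing its artifact
so stages can also be run individually with identical results. Mapping
is an external interface: the orchestrator consumes a candidate SAM/BAM
from any report-all-candidates mapper, or falls back on the built-in
toy mapper over a small reference.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from . import __version__
from .align_select import choose_spanning_set, merge_colinear
from .cluster import FusionCluster, build_cluster_graph, select_clusterable
from .core_io import (
    FusionEvent,
    PipelineConfig,
    PrimerSpec,
    QCStatus,
    SequencingRead,
    read_fastq,
    write_event_bed,
    write_fastq,
)
from .fusion_annotate import build_event
from .readqc import detect_concatemer, filter_artifacts, label_primers
from .toymap import ToyMapper

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance record written alongside every run's outputs."""

    version: str = ""
    seed: int = 0
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_passed: int,
               discarded: dict[str, int]) -> None:
        if n_in != n_passed + sum(discarded.values()):
            raise ValueError(
                f"{stage}: counts not conserved "
                f"({n_in} != {n_passed} + {sum(discarded.values())})")
        self.stage_counts[stage] = {
            "input": n_in, "passed": n_passed, "discarded": discarded}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def load_reference_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def filter_stage(
    reads: Iterable[SequencingRead],
    primers: list[PrimerSpec],
    config: PipelineConfig,
) -> tuple[list[SequencingRead], list[tuple[str, str]]]:
    """QC + primer labelling: returns (labelled pass reads, discards)."""
    passed, discards = [], []
    for read in reads:
        if filter_artifacts(read, config) is not QCStatus.PASS:
            discards.append((read.read_id, read.qc_status.value))
            continue
        if detect_concatemer(read, primers, config):
            discards.append((read.read_id, read.qc_status.value))
            continue
        label_primers(read, primers, config)
        passed.append(read)
    return passed, discards


def select_stage(
    reads: list[SequencingRead],
    reference: dict[str, str],
    config: PipelineConfig,
    mapper: Optional[ToyMapper] = None,
) -> tuple[list[FusionEvent], list[str]]:
    """Map (toy mapper), chain candidates, and build fusion events.

    Reads whose chosen chain has fewer than two segments are not fusions
    and are reported separately by read id.
    """
    mapper = mapper or ToyMapper(reference, config=config)
    events, unfused = [], []
    for read in reads:
        cands = mapper.map_read(read.read_id, read.sequence)
        if not cands.candidates:
            unfused.append(read.read_id)
            continue
        chain = merge_colinear(choose_spanning_set(cands, config))
        if len(chain) < 2:
            unfused.append(read.read_id)
            continue
        events.append(build_event(chain))
    return events, unfused


def select_stage_from_sam(
    candidates_by_read: dict[str, list],
    config: PipelineConfig,
) -> tuple[list[FusionEvent], list[str]]:
    """Chain externally-mapped candidates into fusion events."""
    from .align_select import CandidateSet

    events, unfused = [], []
    for read_id in sorted(candidates_by_read):
        cands = candidates_by_read[read_id]
        read_len = max(c.query_end for c in cands)
        chain = merge_colinear(
            choose_spanning_set(CandidateSet(read_id, read_len, cands), config))
        if len(chain) < 2:
            unfused.append(read_id)
            continue
        events.append(build_event(chain))
    return events, unfused


def cluster_stage(
    events: list[FusionEvent], config: PipelineConfig
) -> tuple[list[FusionCluster], list[FusionEvent]]:
    """Cluster complex events; returns (clusters, clusterable events)."""
    clusterable = select_clusterable(events)
    clusters, _graph = build_cluster_graph(clusterable, config)
    return clusters, clusterable


def run_pipeline(
    fastq: str,
    reference_fasta: str,
    primers: list[PrimerSpec],
    out_dir: str,
    config: Optional[PipelineConfig] = None,
    candidate_sam: Optional[str] = None,
) -> RunManifest:
    """Run filter -> map/select -> annotate -> cluster, writing artifacts.

    With `candidate_sam` the external-mapper route is used; otherwise the
    built-in toy mapper maps the filtered reads against the reference.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=config.rng_seed,
                           config=asdict(config),
                           inputs={"fastq": str(fastq),
                                   "reference": str(reference_fasta)})

    reads = list(read_fastq(fastq))
    passed, discards = filter_stage(reads, primers, config)
    by_reason: dict[str, int] = {}
    for _rid, reason in discards:
        by_reason[reason] = by_reason.get(reason, 0) + 1
    manifest.record("filter", len(reads), len(passed), by_reason)
    write_fastq(passed, str(out / "pass.fastq"))
    with open(out / "discards.tsv", "w") as fh:
        fh.write("#read_id\tverdict\n")
        for rid, reason in discards:
            fh.write(f"{rid}\t{reason}\n")

    reference = load_reference_fasta(reference_fasta)
    if candidate_sam is not None:
        from .core_io import read_candidate_alignments

        cands = read_candidate_alignments(candidate_sam)
        events, unfused = select_stage_from_sam(cands, config)
    else:
        events, unfused = select_stage(passed, reference, config)
    manifest.record("select", len(passed), len(events),
                    {"unfused_or_unmapped": len(unfused)})
    write_event_bed(events, str(out / "events.bed"))
    with open(out / "unfused.txt", "w") as fh:
        fh.writelines(rid + "\n" for rid in unfused)

    clusters, clusterable = cluster_stage(events, config)
    manifest.record("cluster", len(events), len(clusterable),
                    {"simple_or_no_insertion": len(events) - len(clusterable)})
    write_event_bed(clusterable, str(out / "clusters.bed"))
    singleton_ids = {c.representative_read_id for c in clusters
                     if len(c.member_read_ids) == 1}
    write_event_bed([ev for ev in clusterable if ev.read_id in singleton_ids],
                    str(out / "singletons.bed"))
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("#cluster_id\trepresentative\tn_members\tmembers\n")
        for c in clusters:
            fh.write(f"{c.cluster_id}\t{c.representative_read_id}\t"
                     f"{len(c.member_read_ids)}\t"
                     f"{','.join(sorted(c.member_read_ids))}\n")

    manifest.outputs = {name: str(out / name) for name in (
        "pass.fastq", "discards.tsv", "events.bed", "unfused.txt",
        "clusters.bed", "singletons.bed", "clusters.tsv")}
    manifest.write(out / "manifest.json")
    return manifest
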