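"""Domain types and file I/O shared by every pipeline stage.

All coordinates are 0-based half-open, on the query axis of the original
read orientation and on the reference axis of the forward strand. SAM's
1-based positions are converted on read; BED output needs no conversion.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence, TextIO

import pysam
import yaml

logger = logging.getLogger(__name__)

#: Marker used for a read end with no identified primer.
NO_PRIMER = "False"

#: Required length of a primer alignment target (primer + reference flank).
PRIMER_TARGET_LEN = 68


class QCStatus(str, Enum):
    PASS = "pass"
    ARTIFACT_LOW_COMPLEXITY = "artifact_low_complexity"
    ARTIFACT_CONCATEMER = "artifact_concatemer"


class JunctionKind(str, Enum):
    MICROHOMOLOGY = "microhomology"
    BLUNT = "blunt"
    INSERTION_GAP = "insertion_gap"


class ComplexityClass(str, Enum):
    NO_INSERTION = "no_insertion"   # two alignments, head-to-head fusion
    SIMPLE = "simple"               # 1-2 insertions
    COMPLEX = "complex"             # >=3 insertions


class OriginClass(str, Enum):
    CHROMOSOMAL = "chromosomal"
    EXTERNAL_PLASMID = "external_plasmid"
    EXTERNAL_ECOLI = "external_ecoli"
    MITOCHONDRIAL = "mitochondrial"


@dataclass
class SequencingRead:
    """A raw or trimmed long read with primer labels and a QC verdict."""

    read_id: str
    sequence: str
    qualities: Optional[Sequence[int]] = None
    primer_label_start: str = NO_PRIMER
    primer_label_end: str = NO_PRIMER
    qc_status: QCStatus = QCStatus.PASS
    trimmed_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSpec:
    """A PCR primer and its 68-bp alignment target (primer + genomic flank).

    Matching the bare 18-26 nt primer against noisy nanopore read ends is
    unreliable, so the expected downstream reference sequence is appended
    and the combined target is aligned instead.
    """

    name: str
    primer_seq: str
    alignment_target: str
    score_fraction_threshold: float = 0.4

    def __post_init__(self) -> None:
        if len(self.alignment_target) != PRIMER_TARGET_LEN:
            raise ValueError(
                f"primer {self.name!r}: alignment_target must be "
                f"{PRIMER_TARGET_LEN} nt, got {len(self.alignment_target)}"
            )
        if not self.alignment_target.upper().startswith(self.primer_seq.upper()):
            raise ValueError(
                f"primer {self.name!r}: primer_seq must be a prefix of alignment_target"
            )
        if not 0 < self.score_fraction_threshold <= 1:
            raise ValueError("score_fraction_threshold must be in (0, 1]")


@dataclass(frozen=True, order=True)
class AlignmentSegment:
    """One mapped piece of a read: query interval <-> reference interval."""

    read_id: str
    query_start: int
    query_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    score: float
    aligned_bases: int

    def __post_init__(self) -> None:
        if self.query_start >= self.query_end:
            raise ValueError("query_start must be < query_end")
        if self.ref_start >= self.ref_end:
            raise ValueError("ref_start must be < ref_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class Junction:
    """Relation between two consecutive segments on the query axis."""

    left_segment_index: int
    kind: JunctionKind
    size: int

    def __post_init__(self) -> None:
        if (self.kind is JunctionKind.BLUNT) != (self.size == 0):
            raise ValueError("blunt junctions have size 0 and vice versa")
        if self.size < 0:
            raise ValueError("junction size must be >= 0")


@dataclass
class FusionEvent:
    """An ordered chain of segments: two sub-telomere flanks enclosing
    zero or more templated insertions, with typed junctions between
    consecutive segments."""

    read_id: str
    segments: list[AlignmentSegment]
    junctions: list[Junction]
    cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.segments) < 2:
            raise ValueError("a fusion event needs >= 2 segments")
        starts = [s.query_start for s in self.segments]
        if starts != sorted(starts):
            raise ValueError("segments must be sorted by query_start")
        if len(self.junctions) != len(self.segments) - 1:
            raise ValueError("need exactly n_alignments - 1 junctions")

    @property
    def n_alignments(self) -> int:
        return len(self.segments)

    @property
    def flank_left(self) -> AlignmentSegment:
        return self.segments[0]

    @property
    def flank_right(self) -> AlignmentSegment:
        return self.segments[-1]

    @property
    def insertions(self) -> list[AlignmentSegment]:
        return self.segments[1:-1]

    @property
    def n_insertions(self) -> int:
        return len(self.segments) - 2

    @property
    def complexity_class(self) -> ComplexityClass:
        return complexity_class(self.n_insertions)

    @property
    def query_span(self) -> int:
        return self.segments[-1].query_end - self.segments[0].query_start


def complexity_class(n_insertions: int) -> ComplexityClass:
    """0 insertions -> no_insertion; 1-2 -> simple; >=3 -> complex."""
    if n_insertions < 0:
        raise ValueError("insertion count must be >= 0")
    if n_insertions == 0:
        return ComplexityClass.NO_INSERTION
    if n_insertions <= 2:
        return ComplexityClass.SIMPLE
    return ComplexityClass.COMPLEX


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, in one flat document.

    Defaults are the published operating point of the protocol this
    package implements; see docs/methods.md for units and rationale.
    """

    # read QC
    min_block_len: int = 150
    telomere_kmer_fraction: float = 0.30
    repetitiveness_cutoff: float = 0.3
    repetitiveness_k: int = 8
    telomere_motifs: tuple[str, ...] = ("TTAGGG", "CCCTAA")
    # primer search
    primer_score_fraction: float = 0.4
    end_window: int = 150
    interior_exclusion: int = 150
    # alignment scoring (mirrors the recommended mapper settings)
    match_score: int = 2
    mismatch_penalty: int = 3
    gap_open_penalty: int = 5
    gap_extend_penalty: int = 2
    # clustering
    overlap_fraction: float = 0.80
    insertion_count_rel_diff: float = 0.25
    query_len_rel_diff: float = 0.04
    jaccard_thresholds: tuple[float, ...] = (1, 1, 0.66, 0.66, 0.66, 0.5)
    jaccard_threshold_large: float = 0.5
    max_edges_per_node: int = 10
    # annotation
    hotspot_window: int = 10_000
    foldback_reciprocal_overlap: float = 0.8
    # misc
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("telomere_kmer_fraction", "repetitiveness_cutoff",
                     "primer_score_fraction", "overlap_fraction",
                     "insertion_count_rel_diff", "query_len_rel_diff",
                     "jaccard_threshold_large", "foldback_reciprocal_overlap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.jaccard_thresholds) != 6:
            raise ValueError("jaccard_thresholds must list 6 entries for set sizes 1..6")

    def to_yaml(self, path: str) -> None:
        doc = {f.name: getattr(self, f.name) for f in fields(self)}
        doc = {k: list(v) if isinstance(v, tuple) else v for k, v in doc.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k in ("telomere_motifs", "jaccard_thresholds"):
            if k in doc:
                doc[k] = tuple(doc[k])
        return cls(**doc)


# ---------------------------------------------------------------------------
# FASTQ

def _open_text(path: str, mode: str = "rt") -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str) -> Iterator[SequencingRead]:
    """Stream a (possibly gzip-compressed) FASTQ file as SequencingReads.

    Malformed records raise ValueError naming the record index; an empty
    file yields an empty stream with a warning.
    """
    n = 0
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"{path}: malformed FASTQ record at index {n}")
            if len(qual) != len(seq):
                raise ValueError(
                    f"{path}: record {n}: sequence/quality length mismatch"
                )
            read_id = header[1:].split()[0]
            yield SequencingRead(
                read_id=read_id,
                sequence=seq,
                qualities=[ord(c) - 33 for c in qual],
            )
            n += 1
    if n == 0:
        logger.warning("%s: empty FASTQ", path)


def write_fastq(reads: Iterable[SequencingRead], path: str) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = (
                "".join(chr(q + 33) for q in r.qualities)
                if r.qualities is not None
                else "I" * len(r.sequence)
            )
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM/BAM candidate alignments

def _query_interval_from_cigar(
    cigartuples: Sequence[tuple[int, int]], is_reverse: bool
) -> tuple[int, int, int, int]:
    """Return (query_start, query_end, full_read_length, aligned_bases)
    with query coordinates on the ORIGINAL read orientation.

    Soft (4) and hard (5) clips count toward the full read length; the
    aligned span is the sum of M/I/=/X on the query. Reverse-strand
    records store the reverse complement, so the interval is mirrored.
    """
    lead = trail = aligned_q = 0
    aligned_ref_match = 0
    seen_aln = False
    for op, length in cigartuples:
        if op in (4, 5):  # S, H
            if seen_aln:
                trail += length
            else:
                lead += length
        elif op in (0, 7, 8):  # M, =, X
            aligned_q += length
            aligned_ref_match += length
            seen_aln = True
        elif op == 1:  # I
            aligned_q += length
            seen_aln = True
        elif op in (2, 3):  # D, N consume reference only
            seen_aln = True
    full = lead + aligned_q + trail
    if is_reverse:
        qstart, qend = trail, trail + aligned_q
    else:
        qstart, qend = lead, lead + aligned_q
    return qstart, qend, full, aligned_ref_match


def read_candidate_alignments(path: str) -> dict[str, list[AlignmentSegment]]:
    """Load all candidate alignments per read from SAM/BAM.

    Secondary and supplementary records are kept (the mapper is expected
    to run in report-all-candidates mode); unmapped records are dropped.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    out: dict[str, list[AlignmentSegment]] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"{path}: record {rec.query_name!r} lacks a CIGAR")
            if rec.reference_name is None:
                raise ValueError(f"{path}: record {rec.query_name!r} has no reference name")
            qstart, qend, _full, aligned = _query_interval_from_cigar(
                rec.cigartuples, rec.is_reverse
            )
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else float(aligned)
            seg = AlignmentSegment(
                read_id=rec.query_name,
                query_start=qstart,
                query_end=qend,
                chrom=rec.reference_name,
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                score=max(score, 0.0),
                aligned_bases=aligned,
            )
            out.setdefault(rec.query_name, []).append(seg)
    return out


# ---------------------------------------------------------------------------
# BED

BED_COLUMNS = [
    "chrom", "ref_start", "ref_end", "read_id", "score", "strand",
    "query_start", "query_end", "role", "junction_kind", "junction_size",
    "cluster_id",
]


def write_event_bed(events: Iterable[FusionEvent], path: str) -> None:
    """One BED line per segment; junction columns describe the junction to
    the next segment of the same read ('.' on the last segment)."""
    rows = []
    for ev in events:
        for i, seg in enumerate(ev.segments):
            if i == 0 or i == len(ev.segments) - 1:
                role = "flank"
            else:
                role = "insertion"
            if i < len(ev.junctions):
                jk, js = ev.junctions[i].kind.value, str(ev.junctions[i].size)
            else:
                jk, js = ".", "."
            cid = "." if ev.cluster_id is None else str(ev.cluster_id)
            rows.append((
                seg.chrom, seg.ref_start, seg.ref_end, seg.read_id,
                f"{seg.score:g}", seg.strand, seg.query_start, seg.query_end,
                role, jk, js, cid, seg.aligned_bases,
            ))
    rows.sort(key=lambda r: (r[3], r[6]))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BED_COLUMNS + ["aligned_bases"]) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# role-specific aliases: alignment BEDs and cluster BEDs share one schema,
# clusters additionally carrying the cluster_id column
write_alignment_bed = write_event_bed
write_cluster_bed = write_event_bed


def read_event_bed(path: str) -> list[FusionEvent]:
    """Inverse of write_event_bed (lossless for all columns it carries)."""
    per_read: dict[str, list[tuple]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            per_read.setdefault(f[3], []).append(f)
    events = []
    for read_id in sorted(per_read):
        recs = sorted(per_read[read_id], key=lambda f: int(f[6]))
        segs, juncs = [], []
        cluster_id: Optional[int] = None
        for i, f in enumerate(recs):
            segs.append(AlignmentSegment(
                read_id=read_id, query_start=int(f[6]), query_end=int(f[7]),
                chrom=f[0], ref_start=int(f[1]), ref_end=int(f[2]),
                strand=f[5], score=float(f[4]), aligned_bases=int(f[12]),
            ))
            if f[9] != ".":
                juncs.append(Junction(i, JunctionKind(f[9]), int(f[10])))
            if f[11] != ".":
                cluster_id = int(f[11])
        events.append(FusionEvent(read_id, segs, juncs, cluster_id=cluster_id))
    return events


# ---------------------------------------------------------------------------
# primers and reference catalogue

def read_primers(path: str) -> list[PrimerSpec]:
    """Tab-separated primer file: name, primer_seq, alignment_target."""
    primers = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln + 1}: expected 3 tab-separated columns")
            primers.append(PrimerSpec(parts[0], parts[1], parts[2]))
    return primers


def write_primers(primers: Iterable[PrimerSpec], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tprimer_seq\talignment_target\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.primer_seq}\t{p.alignment_target}\n")


def read_catalogue(path: str) -> dict[str, OriginClass]:
    """Tab-separated reference catalogue: contig name, origin tag."""
    cat = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, tag = line.rstrip("\n").split("\t")[:2]
            cat[name] = OriginClass(tag)
    return cat


def write_catalogue(cat: dict[str, OriginClass], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\torigin\n")
        for name, tag in cat.items():
            fh.write(f"{name}\t{tag.value}\n")
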