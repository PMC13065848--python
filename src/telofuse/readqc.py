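"""Read filtering and primer labelling.

Nanopore amplicon libraries carry two spurious read classes that must be
removed before mapping: low-complexity sequencing artefacts (long tandem
repeat tracts that are not telomeric) and concatemers (two amplicons
read as one molecule). Surviving reads are then labelled at each end
with the PCR primer that generated them and trimmed to the primer match.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .core_io import (
    NO_PRIMER,
    PipelineConfig,
    PrimerSpec,
    QCStatus,
    SequencingRead,
)

@dataclass(frozen=True)
class MaskedBlock:
    """A maximal low-complexity run on a read, with the two scores the
    artefact filter consults."""

    start: int
    end: int
    repetitiveness: float
    telomere_fraction: float

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("block must span >= 1 base")
        if not 0 <= self.repetitiveness <= 1:
            raise ValueError("repetitiveness must be in [0, 1]")
        if not 0 <= self.telomere_fraction <= 1:
            raise ValueError("telomere_fraction must be in [0, 1]")

    def __len__(self) -> int:
        return self.end - self.start


def repetitiveness_score(sequence: str, k: int = 8) -> float:
    """Score sequence repetitiveness in [0, 1].

    Defined as 1 - (distinct k-mers / total k-mers): ~0 for maximally
    diverse composition, approaching 1 for a single repeated unit, and
    monotone under increasing duplication of a fixed unit. Sequences
    shorter than k score 0.
    """
    seq = sequence.upper()
    total = len(seq) - k + 1
    if total <= 0:
        return 0.0
    distinct = len({seq[i:i + k] for i in range(total)})
    return min(max(1.0 - distinct / total, 0.0), 1.0)


def telomere_kmer_fraction(
    sequence: str, motifs: Iterable[str] = ("TTAGGG", "CCCTAA")
) -> float:
    """Fraction of overlapping 6-mers that are rotations of a telomere
    repeat motif (TTAGGG / CCCTAA by default)."""
    motif_set = set()
    for m in motifs:
        m = m.upper()
        for i in range(len(m)):
            motif_set.add(m[i:] + m[:i])
    k = len(next(iter(motif_set)))
    seq = sequence.upper()
    total = len(seq) - k + 1
    if total <= 0:
        return 0.0
    hits = sum(seq[i:i + k] in motif_set for i in range(total))
    return hits / total


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)


def mask_low_complexity(
    sequence: str,
    config: Optional[PipelineConfig] = None,
    window: int = 32,
    step: int = 16,
    max_period: int = 24,
    max_mismatch_fraction: float = 0.2,
) -> list[MaskedBlock]:
    """Detect tandem-repeat / low-complexity blocks.

    A sliding window is flagged when some period p in [1, max_period]
    makes the window agree with itself shifted by p at >=80% of
    positions; flagged windows are merged into maximal blocks. Random
    sequence essentially never satisfies this (per-position agreement
    probability 0.25), while homopolymers and short tandem repeats
    always do. An external masker's lowercase-masked output can be
    supplied instead via :func:`blocks_from_lowercase`.
    """
    config = config or PipelineConfig()
    seq = _encode(sequence)
    n = len(seq)
    if n < window:
        # short sequences: test the whole sequence as one window
        if n < 9:
            return []
        window = n
        step = n
    starts = np.arange(0, n - window + 1, step)
    if len(starts) and starts[-1] + window < n:
        starts = np.append(starts, n - window)
    win_flag = np.zeros(len(starts), dtype=bool)
    for p in range(1, min(max_period, window - 8) + 1):
        mism = np.concatenate(([0], np.cumsum(seq[p:] != seq[:-p])))
        frac = (mism[starts + window - p] - mism[starts]) / (window - p)
        win_flag |= frac < max_mismatch_fraction
        if win_flag.all():
            break
    flagged = np.zeros(n, dtype=bool)
    for s in starts[win_flag]:
        flagged[s:s + window] = True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], flagged.view(np.int8), [0]))))
    blocks = []
    for i, j in zip(edges[::2], edges[1::2]):
        sub = sequence[i:j]
        blocks.append(MaskedBlock(
            start=int(i),
            end=int(j),
            repetitiveness=repetitiveness_score(sub, k=config.repetitiveness_k),
            telomere_fraction=telomere_kmer_fraction(sub, config.telomere_motifs),
        ))
    return blocks


def blocks_from_lowercase(
    masked_sequence: str, config: Optional[PipelineConfig] = None
) -> list[MaskedBlock]:
    """Build MaskedBlocks from an external masker's lowercase-masked output."""
    config = config or PipelineConfig()
    blocks = []
    i, n = 0, len(masked_sequence)
    while i < n:
        if masked_sequence[i].islower():
            j = i
            while j < n and masked_sequence[j].islower():
                j += 1
            sub = masked_sequence[i:j]
            blocks.append(MaskedBlock(
                start=i,
                end=j,
                repetitiveness=repetitiveness_score(sub, k=config.repetitiveness_k),
                telomere_fraction=telomere_kmer_fraction(sub, config.telomere_motifs),
            ))
            i = j
        else:
            i += 1
    return blocks


def filter_artifacts(
    read: SequencingRead,
    config: Optional[PipelineConfig] = None,
    blocks: Optional[list[MaskedBlock]] = None,
) -> QCStatus:
    """Flag probable sequencing artefacts.

    A read is discarded iff it carries a masked block longer than
    min_block_len whose telomere k-mer fraction is at most the telomere
    cutoff (telomeric tracts are exempt, whatever their repetitiveness)
    and whose repetitiveness exceeds the cutoff. The verdict is recorded
    on the read's qc_status.
    """
    config = config or PipelineConfig()
    if blocks is None:
        blocks = mask_low_complexity(read.sequence, config)
    verdict = QCStatus.PASS
    for b in blocks:
        if (
            len(b) > config.min_block_len
            and b.telomere_fraction <= config.telomere_kmer_fraction
            and b.repetitiveness > config.repetitiveness_cutoff
        ):
            verdict = QCStatus.ARTIFACT_LOW_COMPLEXITY
            break
    read.qc_status = verdict
    return verdict


# ---------------------------------------------------------------------------
# primer alignment

def _aligner(config: PipelineConfig) -> PairwiseAligner:
    # Affine gaps in mapper convention: a gap of length g costs open + g*extend.
    aln = PairwiseAligner()
    aln.mode = "local"
    aln.match_score = config.match_score
    aln.mismatch_score = -config.mismatch_penalty
    aln.open_gap_score = -(config.gap_open_penalty + config.gap_extend_penalty)
    aln.extend_gap_score = -config.gap_extend_penalty
    return aln


def max_alignment_score(primer: PrimerSpec, config: Optional[PipelineConfig] = None) -> float:
    config = config or PipelineConfig()
    return config.match_score * len(primer.alignment_target)


def _best_local(aligner: PairwiseAligner, target: str, window: str):
    """Best local alignment of target inside window: (score, start, end)
    in window coordinates, or None if no positive-score alignment."""
    if not window:
        return None
    alns = aligner.align(target, window)
    if len(alns) == 0 or alns.score <= 0:
        return None
    best = alns[0]
    wstart = int(best.aligned[1][0][0])
    wend = int(best.aligned[1][-1][1])
    return float(best.score), wstart, wend


def detect_concatemer(
    read: SequencingRead,
    primers: list[PrimerSpec],
    config: Optional[PipelineConfig] = None,
) -> bool:
    """True iff a primer target matches the interior of the read.

    The interior excludes one end window at each side (a genuine
    amplicon's primers live at the ends). Matching uses a fast edit-
    distance prescreen followed by score confirmation with the same
    scoring scheme as primer labelling. A True verdict sets
    qc_status=artifact_concatemer.
    """
    config = config or PipelineConfig()
    interior = read.sequence.upper()[config.interior_exclusion:len(read) - config.interior_exclusion]
    if not interior:
        return False
    aligner = _aligner(config)
    for primer in primers:
        threshold = primer.score_fraction_threshold * max_alignment_score(primer, config)
        for target in (primer.alignment_target.upper(),
                       reverse_complement(primer.alignment_target.upper())):
            # prescreen: best infix edit distance; a score >= 0.4*max needs
            # far fewer than len(target)/2 edits under the scoring scheme
            hit = edlib.align(target, interior, mode="HW", task="locations",
                              k=len(target) // 2)
            if hit["editDistance"] < 0:
                continue
            loc = hit["locations"][0]
            lo = max(0, loc[0] - 20)
            hi = min(len(interior), loc[1] + 21)
            res = _best_local(aligner, target, interior[lo:hi])
            if res is not None and res[0] >= threshold:
                read.qc_status = QCStatus.ARTIFACT_CONCATEMER
                return True
    return False


def label_primers(
    read: SequencingRead,
    primers: list[PrimerSpec],
    config: Optional[PipelineConfig] = None,
) -> SequencingRead:
    """Label each read end with its best-matching primer and trim.

    Each end window is searched against every primer's alignment target
    (the reverse complement is additionally tried at the 3' end, where
    the amplicon's second primer reads back toward the start). A best
    match scoring >= score_fraction * maximum score labels the end and
    trims the read to the start of the alignment; otherwise the end is
    labelled with the absent-marker. Windows are truncated at the read
    midpoint for very short reads. Idempotent on already-trimmed reads.
    """
    config = config or PipelineConfig()
    seq = read.sequence
    n = len(seq)
    mid = n // 2
    w = config.end_window
    start_win = seq[: min(w, mid)].upper()
    end_lo = max(n - w, mid)
    end_win = seq[end_lo:].upper()
    aligner = _aligner(config)

    best_start = None  # (score, trim_pos, name)
    best_end = None    # (score, trim_pos, name)
    for primer in primers:
        threshold = primer.score_fraction_threshold * max_alignment_score(primer, config)
        target = primer.alignment_target.upper()
        res = _best_local(aligner, target, start_win)
        if res is not None and res[0] >= threshold:
            if best_start is None or res[0] > best_start[0]:
                best_start = (res[0], res[1], primer.name)
        for t in (target, reverse_complement(target)):
            res = _best_local(aligner, t, end_win)
            if res is not None and res[0] >= threshold:
                trim = end_lo + res[2]  # retain up to the alignment's outer edge
                if best_end is None or res[0] > best_end[0]:
                    best_end = (res[0], trim, primer.name)

    lo, hi = 0, n
    if best_start is not None:
        read.primer_label_start = best_start[2]
        lo = best_start[1]
    else:
        read.primer_label_start = NO_PRIMER
    if best_end is not None:
        read.primer_label_end = best_end[2]
        hi = best_end[1]
    else:
        read.primer_label_end = NO_PRIMER
    if hi <= lo:  # pathological double-trim on a tiny read; keep everything
        lo, hi = 0, n
    base = read.trimmed_interval[0] if read.trimmed_interval else 0
    read.trimmed_interval = (base + lo, base + hi)
    read.sequence = seq[lo:hi]
    if read.qualities is not None:
        read.qualities = list(read.qualities[lo:hi])
    return read
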