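"""A miniature seed-and-extend mapper for tests and self-contained runs.

Mapping is an external interface of the pipeline (see
align_select.mapper_contract); this built-in exists so the whole
pipeline can run end to end on the miniature synthetic reference
without any external binary. It indexes exact k-mers (k=11, matching
the recommended external settings) on both strands, groups seed hits by
diagonal, and trims segment ends with an ungapped X-drop extension.
It is adequate for small references only.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from Bio.Seq import reverse_complement

from .align_select import CandidateSet
from .core_io import AlignmentSegment, PipelineConfig

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Integer code of every k-mer (or -1 where the window holds a
    non-ACGT base)."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes < 0
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = windows @ powers
    if bad.any():
        badwin = np.lib.stride_tricks.sliding_window_view(bad, k).any(axis=1)
        out[badwin] = -1
    return out


class ToyMapper:
    """Exact-seed mapper over a small reference (dict name -> sequence)."""

    def __init__(self, reference: dict[str, str], k: int = 11,
                 max_kmer_occ: int = 24,
                 config: Optional[PipelineConfig] = None) -> None:
        self.k = k
        self.config = config or PipelineConfig()
        self.reference = {name: seq.upper() for name, seq in reference.items()}
        # Index both strands: for '-', index the reverse complement of the
        # contig; hit coordinates are mapped back to forward-strand
        # intervals. The index is a code-sorted hit table queried with
        # searchsorted, so build and lookup both vectorise.
        self._strand_seq: dict[tuple[str, str], str] = {}
        self._loci: list[tuple[str, str]] = []
        code_parts, locus_parts, pos_parts = [], [], []
        for name, seq in self.reference.items():
            rc = reverse_complement(seq)
            self._strand_seq[(name, "+")] = seq
            self._strand_seq[(name, "-")] = rc
            for strand, s in (("+", seq), ("-", rc)):
                codes = _kmer_codes(s, k)
                self._loci.append((name, strand))
                code_parts.append(codes)
                locus_parts.append(np.full(len(codes), len(self._loci) - 1,
                                           dtype=np.int32))
                pos_parts.append(np.arange(len(codes), dtype=np.int64))
        codes_all = np.concatenate(code_parts) if code_parts else np.empty(0, np.int64)
        loci_all = np.concatenate(locus_parts) if locus_parts else np.empty(0, np.int32)
        pos_all = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(codes_all, kind="stable")
        codes_all, loci_all, pos_all = codes_all[order], loci_all[order], pos_all[order]
        valid = codes_all >= 0
        codes_all, loci_all, pos_all = codes_all[valid], loci_all[valid], pos_all[valid]
        # drop promiscuous k-mers (telomere repeats, microsatellites): a
        # k-mer seen at too many loci carries no placement information
        _uniq, inverse, counts = np.unique(codes_all, return_inverse=True,
                                           return_counts=True)
        keep = counts[inverse] <= max_kmer_occ
        self._codes = codes_all[keep]
        self._hit_locus = loci_all[keep].tolist()
        self._hit_pos = pos_all[keep].tolist()

    # -- internals ---------------------------------------------------------

    def _extend(self, read: str, sseq: str, qs: int, qe: int, ps: int, pe: int,
                xdrop: int = 8):
        """Ungapped X-drop extension of [qs,qe)<->[ps,pe) at both ends."""
        # left
        score, best, bi = 0, 0, 0
        i = 1
        while qs - i >= 0 and ps - i >= 0:
            score += 1 if read[qs - i] == sseq[ps - i] else -2
            if score > best:
                best, bi = score, i
            if best - score > xdrop:
                break
            i += 1
        qs, ps = qs - bi, ps - bi
        # right
        score, best, bi = 0, 0, 0
        i = 0
        while qe + i < len(read) and pe + i < len(sseq):
            score += 1 if read[qe + i] == sseq[pe + i] else -2
            if score > best:
                best, bi = score, i + 1
            if best - score > xdrop:
                break
            i += 1
        return qs, qe + bi, ps, pe + bi

    # -- public ------------------------------------------------------------

    def map_read(self, read_id: str, sequence: str,
                 diag_tolerance: int = 50, max_query_gap: int = 200,
                 min_seed_bases: int = 23, min_exact_run: int = 18,
                 seed_stride: int = 2) -> CandidateSet:
        """Return all candidate alignment segments of one read.

        Read k-mers are sampled every seed_stride bases; hits are grouped
        per (chrom, strand) by single-linkage clustering on the alignment
        diagonal (absorbing indel drift), chained along the read
        (splitting at query gaps > max_query_gap or reference
        back-jumps), extended, and scored at the match rate on
        seed-covered bases.

        A chain is kept only with >= min_seed_bases seed-covered bases
        or a contiguous exact match of >= min_exact_run bases: two
        isolated k-mer hits on one diagonal cover at most 2k bases and
        arise by chance anywhere on a read, whereas an exact 18-mer is
        effectively unique against a sub-megabase reference.
        """
        read = sequence.upper()
        k = self.k
        cfg = self.config
        codes = _kmer_codes(read, k)[::seed_stride]
        qpos = np.arange(len(codes)) * seed_stride
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        hit_locus, hit_pos, loci = self._hit_locus, self._hit_pos, self._loci
        per_locus: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
        for w in np.flatnonzero(hi > lo):
            i = int(qpos[w])
            for j in range(lo[w], hi[w]):
                p = hit_pos[j]
                per_locus.setdefault(loci[hit_locus[j]], []).append((p - i, i, p))

        candidates: dict[tuple, AlignmentSegment] = {}
        for (chrom, strand), hits in per_locus.items():
            hits.sort()
            sseq = self._strand_seq[(chrom, strand)]
            L = len(sseq)
            # split into diagonal groups, then chain each group by read order
            gstart = 0
            for h in range(1, len(hits) + 1):
                if h < len(hits) and hits[h][0] - hits[h - 1][0] <= diag_tolerance:
                    continue
                group = sorted(hits[gstart:h], key=lambda t: t[1])
                gstart = h
                chain_start = 0
                for c in range(1, len(group) + 1):
                    if c < len(group) \
                            and group[c][1] - group[c - 1][1] <= max_query_gap \
                            and group[c][2] >= group[c - 1][2] - k:
                        continue
                    chain = group[chain_start:c]
                    chain_start = c
                    qs, ps = chain[0][1], chain[0][2]
                    qe, pe = chain[-1][1] + k, chain[-1][2] + k
                    covered_q = covered_r = k
                    prev = chain[0]
                    run = best_run = k
                    for hit in chain[1:]:
                        step_q = hit[1] - prev[1]
                        step_r = hit[2] - prev[2]
                        covered_q += min(k, step_q)
                        covered_r += min(k, max(step_r, 0))
                        if step_q == step_r and step_q <= seed_stride:
                            run += step_q
                            best_run = max(best_run, run)
                        else:
                            run = k
                        prev = hit
                    # demand seed support on both axes: repetitive read
                    # tracts re-hitting one reference k-mer rack up query
                    # coverage while covering almost no reference
                    covered = min(covered_q, covered_r)
                    if covered < min_seed_bases and best_run < min_exact_run:
                        continue
                    qs, qe, ps, pe = self._extend(read, sseq, qs, qe, ps, pe)
                    if qe - qs < k or pe - ps <= 0:
                        continue
                    if strand == "+":
                        ref_start, ref_end = ps, pe
                    else:
                        ref_start, ref_end = L - pe, L - ps
                    key = (chrom, strand, ref_start // 25, qs // 25)
                    seg = AlignmentSegment(
                        read_id=read_id, query_start=qs, query_end=qe,
                        chrom=chrom, ref_start=ref_start, ref_end=ref_end,
                        strand=strand,
                        score=float(cfg.match_score * covered),
                        aligned_bases=qe - qs,
                    )
                    old = candidates.get(key)
                    if old is None or seg.score > old.score:
                        candidates[key] = seg
        return CandidateSet(read_id, len(read), sorted(
            candidates.values(), key=lambda s: (s.query_start, s.query_end,
                                                -s.score, s.chrom, s.ref_start)))
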