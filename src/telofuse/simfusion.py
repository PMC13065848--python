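"""Synthetic telomere-fusion events, amplification, and read simulation.

Generates ground-truth fusion molecules with the statistical structure
of the real amplicon libraries — gamma-distributed insertion lengths
(mean 900 bp, sd 1600 bp), Poisson insertion counts (mean 5), and
gamma-distributed per-event amplification (mean 15 reads, sd 35) — plus
a deterministic miniature reference so everything runs without external
data. Read ids encode the full event structure, so truth is recoverable
from any downstream output. An external read simulator producing FASTQ
with the same id convention is accepted as a drop-in.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from Bio.Seq import reverse_complement

from .core_io import OriginClass, PrimerSpec, SequencingRead, PRIMER_TARGET_LEN

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulatorConfig:
    """Default values are the study conditions the simulation models."""

    n_events: int = 3000
    insertion_len_mean: float = 900.0    # bp
    insertion_len_sd: float = 1600.0     # bp
    insertion_count_mean: float = 5.0    # Poisson
    amplification_mean: float = 15.0     # reads per event
    amplification_sd: float = 35.0       # reads per event
    error_rate: float = 0.05             # total per-base error
    sub_fraction: float = 0.4            # nanopore-like 40/30/30 split
    ins_fraction: float = 0.3
    del_fraction: float = 0.3
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("insertion_len_mean", "insertion_len_sd",
                     "insertion_count_mean", "amplification_mean",
                     "amplification_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if not np.isclose(self.sub_fraction + self.ins_fraction + self.del_fraction, 1.0):
            raise ValueError("error-type fractions must sum to 1")


@dataclass(frozen=True)
class TruthInsertion:
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class GroundTruthEvent:
    event_id: str
    left_subtelomere: str
    right_subtelomere: str
    insertions: list[TruthInsertion]
    amplification: int = 1
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.amplification < 1:
            raise ValueError("amplification must be >= 1")


@dataclass
class Reference:
    """Miniature reference: sequences plus the origin catalogue,
    sub-telomere contig names and matching primer definitions."""

    sequences: dict[str, str]
    catalogue: dict[str, OriginClass]
    subtelomeres: list[str]
    primers: list[PrimerSpec] = field(default_factory=list)

    @property
    def insertion_sources(self) -> list[str]:
        return [n for n in self.sequences if n not in self.subtelomeres]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def make_test_reference(
    rng: np.random.Generator,
    n_chroms: int = 8,
    chrom_len: int = 100_000,
    n_subtelomeres: int = 3,
    subtel_len: int = 1_500,
    telomere_repeats: int = 25,
) -> Reference:
    """Deterministic miniature reference for a given generator state.

    Pseudo-chromosomes of i.i.d. random sequence, sub-telomere contigs
    ending in a telomere repeat array, and tagged plasmid / E. coli /
    mitochondrial decoy contigs, plus primer definitions whose 68-bp
    alignment target is the start of each sub-telomere.
    """
    sequences: dict[str, str] = {}
    catalogue: dict[str, OriginClass] = {}
    for c in range(1, n_chroms + 1):
        name = f"chr{c}"
        sequences[name] = _random_seq(rng, chrom_len)
        catalogue[name] = OriginClass.CHROMOSOMAL
    for name in ("TALEN_L1", "TALEN_R1"):
        sequences[name] = _random_seq(rng, 6_000)
        catalogue[name] = OriginClass.EXTERNAL_PLASMID
    sequences["ecoli_1"] = _random_seq(rng, 20_000)
    catalogue["ecoli_1"] = OriginClass.EXTERNAL_ECOLI
    sequences["chrM"] = _random_seq(rng, 16_000)
    catalogue["chrM"] = OriginClass.MITOCHONDRIAL

    subtel_names = []
    primers = []
    for s in range(1, n_subtelomeres + 1):
        name = f"subtel_{s}"
        body = _random_seq(rng, subtel_len)
        sequences[name] = body + "TTAGGG" * telomere_repeats
        catalogue[name] = OriginClass.CHROMOSOMAL
        subtel_names.append(name)
        target = body[:PRIMER_TARGET_LEN]
        primers.append(PrimerSpec(name=f"primer_{s}", primer_seq=target[:22],
                                  alignment_target=target))
    return Reference(sequences, catalogue, subtel_names, primers)


def _gamma_moment_matched(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Gamma draws parameterised by moments: shape=(mean/sd)^2,
    scale=sd^2/mean; rounded to nearest integer with minimum 1."""
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    draws = rng.gamma(shape, scale, size=size)
    return np.maximum(np.rint(draws).astype(np.int64), 1)


def sample_insertion_length(rng: np.random.Generator, config: SimulatorConfig) -> int:
    return int(_gamma_moment_matched(
        rng, config.insertion_len_mean, config.insertion_len_sd, 1)[0])


def make_fusion_event(
    rng: np.random.Generator,
    reference: Reference,
    config: SimulatorConfig,
    event_index: int = 0,
) -> GroundTruthEvent:
    """One synthetic fusion: left sub-telomere + Poisson-many random
    insertions (uniform position and strand) + reverse-complemented
    right sub-telomere. Zero insertions yields a simple head-to-head
    fusion. Draws not fitting their chromosome are resampled."""
    left, right = rng.choice(reference.subtelomeres, size=2, replace=True)
    count = int(rng.poisson(config.insertion_count_mean))
    sources = reference.insertion_sources
    lengths = np.array([len(reference.sequences[s]) for s in sources], dtype=float)
    weights = lengths / lengths.sum()
    insertions = []
    parts = [reference.sequences[left]]
    for _ in range(count):
        while True:
            length = sample_insertion_length(rng, config)
            chrom = sources[int(rng.choice(len(sources), p=weights))]
            cl = len(reference.sequences[chrom])
            if length >= cl:
                continue
            start = int(rng.integers(0, cl - length + 1))
            break
        strand = "+" if rng.random() < 0.5 else "-"
        sub = reference.sequences[chrom][start:start + length]
        parts.append(sub if strand == "+" else reverse_complement(sub))
        insertions.append(TruthInsertion(chrom, start, start + length, strand))
    parts.append(reverse_complement(reference.sequences[right]))
    return GroundTruthEvent(
        event_id=f"event{event_index}",
        left_subtelomere=left,
        right_subtelomere=right,
        insertions=insertions,
        sequence="".join(parts),
    )


def amplify(
    events: list[GroundTruthEvent], rng: np.random.Generator, config: SimulatorConfig
) -> list[GroundTruthEvent]:
    """Assign each event a gamma-distributed read count (min 1).

    With shape (15/35)^2 ~ 0.18 most mass is near zero, so the min-1
    floor inflates the realised mean by a small positive bias (< +0.5)."""
    counts = _gamma_moment_matched(
        rng, config.amplification_mean, config.amplification_sd, len(events))
    for ev, c in zip(events, counts):
        ev.amplification = int(c)
    return events


def simulate_events(
    reference: Reference, config: SimulatorConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[GroundTruthEvent]:
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    events = [
        make_fusion_event(rng, reference, config, event_index=i)
        for i in range(config.n_events)
    ]
    return amplify(events, rng, config)


# ---------------------------------------------------------------------------
# truth-encoding read ids

def encode_truth_id(event: GroundTruthEvent, read_index: int) -> str:
    """`event{k};n={count};{chrom}:{start}-{end}:{strand};...|read{i}`"""
    locs = ";".join(f"{t.chrom}:{t.start}-{t.end}:{t.strand}"
                    for t in event.insertions)
    core = f"{event.event_id};n={len(event.insertions)}"
    if locs:
        core += ";" + locs
    return f"{core}|read{read_index}"


_LOC_RE = re.compile(r"^([^:]+):(\d+)-(\d+):([+-])$")


def decode_truth_id(read_id: str) -> tuple[str, list[TruthInsertion]]:
    """Inverse of encode_truth_id -> (event_id, insertions)."""
    core = read_id.split("|")[0]
    fields = core.split(";")
    event_id = fields[0]
    n = int(fields[1].removeprefix("n="))
    insertions = []
    for tok in fields[2:]:
        m = _LOC_RE.match(tok)
        if not m:
            raise ValueError(f"unparseable truth id token {tok!r} in {read_id!r}")
        insertions.append(TruthInsertion(
            m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)))
    if len(insertions) != n:
        raise ValueError(f"truth id {read_id!r}: n={n} but {len(insertions)} loci")
    return event_id, insertions


# ---------------------------------------------------------------------------
# read simulation

def add_read_errors(
    sequence: str, rng: np.random.Generator, config: SimulatorConfig
) -> str:
    """Apply a uniform substitution/insertion/deletion error process."""
    if config.error_rate <= 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    r = rng.random(n)
    p = config.error_rate
    p_sub = p * config.sub_fraction
    p_ins = p * config.ins_fraction
    p_del = p * config.del_fraction
    out = []
    sub_at = r < p_sub
    ins_at = (r >= p_sub) & (r < p_sub + p_ins)
    del_at = (r >= p_sub + p_ins) & (r < p_sub + p_ins + p_del)
    random_bases = rng.choice(_BASES, size=n)
    offsets = rng.integers(1, 4, size=n)
    for i in range(n):
        if del_at[i]:
            continue
        if ins_at[i]:
            out.append(random_bases[i])
        if sub_at[i]:
            # substitute with a guaranteed different base
            out.append(_BASES[(np.searchsorted(_BASES, arr[i]) + offsets[i]) % 4]
                       if arr[i] in _BASES else random_bases[i])
        else:
            out.append(arr[i])
    return np.array(out, dtype=np.uint8).tobytes().decode("ascii")


def simulate_reads(
    events: list[GroundTruthEvent],
    config: SimulatorConfig,
    rng: Optional[np.random.Generator] = None,
) -> Iterator[SequencingRead]:
    """Emit `amplification` error-bearing reads per event, with
    truth-encoding read ids. Roughly half the reads are emitted
    reverse-complemented, as on a real flow cell."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    for ev in events:
        for i in range(ev.amplification):
            seq = add_read_errors(ev.sequence, rng, config)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            yield SequencingRead(
                read_id=encode_truth_id(ev, i),
                sequence=seq,
                qualities=[20] * len(seq),
            )


def write_truth_table(events: list[GroundTruthEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#event_id\tleft\tright\tamplification\tn_insertions\tinsertions\n")
        for ev in events:
            locs = ";".join(f"{t.chrom}:{t.start}-{t.end}:{t.strand}"
                            for t in ev.insertions)
            fh.write(f"{ev.event_id}\t{ev.left_subtelomere}\t{ev.right_subtelomere}"
                     f"\t{ev.amplification}\t{len(ev.insertions)}\t{locs or '.'}\n")


def write_reference_fasta(reference: Reference, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
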