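# Methods

This note documents the models and procedures implemented in
`telofuse`, the parameters that matter, the numerical choices, and the
known limits of what the simulation-based tests demonstrate.

## The analysis problem

A telomere-fusion amplicon is a single DNA molecule of the form

    sub-telomere A | insertion 1 | ... | insertion n | sub-telomere B (rc)

where the flanking sub-telomeres are the loci targeted by the fusion
PCR primers and the interior insertions are sequences copied from
elsewhere (chromosomal loci, transfected plasmid, carried-over E. coli
or mitochondrial DNA). Nanopore reads of these molecules are split
alignments: each read decomposes into an ordered chain of segments,
and the relation between consecutive segments on the read (query) axis
carries the repair-mechanism signal — overlapping query intervals are
junction microhomology, abutting intervals a blunt join, a coverage
gap an unmapped insertion or error tract.

## Read QC

Two artefact classes are removed before mapping.

**Low-complexity artefacts.** Tandem-repeat blocks are masked by a
sliding-window period test: a 32-bp window is flagged when some period
p ∈ [1, 24] matches the window against itself shifted by p at > 80% of
positions; flagged windows merge into maximal blocks. For random
sequence the per-position agreement probability is 0.25, so false
blocks ≥ 150 bp essentially never arise (property-tested over 1000
seeded 240-mers). An external masker's lowercase-masked output is
accepted as a drop-in (`blocks_from_lowercase`). Each block is scored
for repetitiveness as 1 − (distinct 8-mers / total 8-mers) — 0 for
diverse sequence, → 1 for a repeated unit, monotone under duplication
— and for its telomere fraction, the share of overlapping 6-mers that
are rotations of TTAGGG/CCCTAA. A read is discarded iff some block is
longer than 150 bp, has telomere fraction ≤ 0.30 (telomere arrays are
exempt however repetitive), and repetitiveness > 0.3. The
repetitiveness statistic is this package's own definition with the
published range and cutoff semantics; the cutoff 0.3 keeps the filter
stringent.

**Concatemers.** Two amplicons read as one molecule betray themselves
by a primer match in the read interior. The interior (read minus a
150-bp window at each end) is screened with a fast infix edit-distance
search (edlib) for each 68-bp primer target in both orientations, and
hits are confirmed with the same local-alignment score used for primer
labelling; a confirmed interior match ≥ 0.4 × maximum discards the
read.

**Primer labelling.** Bare 18–26-nt primers align unreliably against
noisy read ends, so each primer is extended with its expected
downstream reference sequence to a 68-bp alignment target. Each end
window (150 bp, truncated at the read midpoint for short reads) is
aligned locally against every target — the 3′ end also against reverse
complements — with match +2, mismatch −3, gap open −7, gap extend −2
(the mapper's scoring scheme in affine-gap convention, the least
arbitrary choice since no separate primer scheme is published). A best
score ≥ 0.4 × (2 × 68) labels the end and trims the read to the outer
edge of the alignment; otherwise the end is labelled `False`. The
150-bp windows cover the 68-bp target plus nanopore end noise.
Labelling is idempotent on trimmed reads.

## Spanning-alignment selection

The external mapper (contract: `bwa mem -c 1000 -A2 -B3 -O5 -E2 -T0
-L0 -D 0.25 -r 1.25 -d 200 -k 11 -a`) reports *all* candidate
alignments. Selection is formalised as an ordered-chain optimisation:
candidates are totally ordered by (query_start, query_end, −score,
chrom, ref_start, strand); a chain is feasible when each consecutive
pair overlaps on the query by at most half the shorter segment (larger
overlap means alternative placements of the same sequence, not a split
alignment); its value is Σscore − 2 × (overlapped bases). Overlap is
thus allowed — junction microhomology requires it — but a shared base
can never earn more than aligning it once, and coverage gaps are free
(they surface as insertion-gap junctions). Because the penalty couples
only consecutive chain members, an O(n²) dynamic programme over the
sorted candidates is exact; the test suite proves equality against
exhaustive subset enumeration on 500 random instances of up to 12
candidates, plus order-invariance and immunity to dominated
candidates. Ties break deterministically toward the earlier candidate
in sort order.

After selection, consecutive segments on the same chromosome and
strand whose query and reference gaps are both ≤ 300 bp and agree
within 150 bp (diagonal drift) are fused: error tracts can split one
genuine alignment, and the resumption diagonal distinguishes a
continuation from a jump to a new locus.

**Built-in toy mapper.** Mapping itself is an external interface; for
self-contained runs and tests a miniature seed-and-extend mapper ships
in `telofuse.toymap`: exact 11-mers (matching the contract's `-k 11`)
indexed on both strands with promiscuous k-mers (> 24 loci, i.e.
telomere repeats and microsatellites) dropped, hits grouped by
chromosome/strand and single-linkage clustered on the alignment
diagonal (tolerance 50 bp, absorbing indel drift), chained along the
read, and trimmed by ungapped X-drop extension (match +1, mismatch −2,
X-drop 8). A chain is kept only with ≥ 23 seed-covered bases on *both*
axes or a contiguous exact run ≥ 18 bp: two isolated 11-mer hits on
one diagonal cover ≤ 22 bases and occur by chance ~10³ times per read
against a megabase two-strand index, whereas an exact 18-mer is
expected < 0.2 times per read. Read k-mers are sampled at stride 2.
The mapper is adequate for the sub-megabase test reference only.

## Annotation

Junction typing is pure query-axis arithmetic on consecutive segments:
k = left.query_end − right.query_start gives microhomology of k bases
(k > 0), a blunt join (k = 0) or an unmapped gap of |k| bases (k < 0);
reference-side homology confirmation is out of scope. Complexity
classes partition on insertion count: 0 / 1–2 / ≥ 3. Insertion origin
is a catalogue lookup on the reference contig. Hotspots group one
event's insertions per chromosome by single linkage with inter-interval
gap ≤ 10 kb (the window is configurable; a span-based rule is the
plausible alternative and differs only for chains of near-window gaps);
groups need ≥ 2 members, and any ≥ 1 bp member overlap sets the
overlapping flag, the signature of repeated replication of one locus.
Foldbacks are same-chromosome opposite-strand segment pairs with
reciprocal overlap ≥ 0.8 (reusing the clustering overlap constant for
a single overlap semantics).

## Clustering

Amplification makes every fusion molecule appear in many reads.
Deduplication operates on complex reads (≥ 3 alignments): simple
head-to-head fusions carry no interior structure to match on, and the
two flanks are shared by construction, so only the insertion sets are
compared. Candidate mates must share one insertion at reciprocal
overlap ≥ 0.80 (one-sided overlap would make tiny insertions
promiscuous); pairs differing > 25% in insertion count or > 4% in
query length are skipped. Insertion-set Jaccard uses positional
equivalence (same chromosome, reciprocal overlap ≥ 0.80) with greedy
highest-overlap one-to-one pairing, since set-element identity across
reads is otherwise undefined. The edge threshold is indexed by the
*smaller* set size (the conservative choice): 1, 1, 0.66, 0.66, 0.66,
0.5 for sizes 1–6, then 0.5 — small sets must match perfectly, large
sets tolerate misses. For sparsity each node retains its 10
highest-Jaccard edges (deterministic tie-break); the retained set is
the union over nodes, so a node's incident degree can exceed 10
through edges its neighbours kept, and transitive connectivity of
large duplicate groups survives the cap (a mutual-top-10 rule provably
disconnects 30 identical reads). Components on the capped graph equal
those on the uncapped graph whenever every true group has ≤ 11
members. Clusters are connected components; singletons get unique ids;
the representative maximises Σscore / Σaligned_bases with a
lexicographic tie-break.

## Simulator

The generator emulates the amplicon library's statistical structure:
per event, an insertion count ~ Poisson(mean 5, zero allowed — a
simple fusion), insertion lengths ~ gamma moment-matched to mean
900 bp / sd 1600 bp (shape (900/1600)² ≈ 0.316, scale 2844), positions
uniform over contigs weighted by length, strands uniform, and
per-event amplification ~ gamma mean 15 / sd 35 reads. Draws are
rounded to the nearest integer with a floor of 1; for the
amplification shape (≈ 0.18) the floor inflates the realised mean by a
small positive bias, bounded below +0.5 reads. Insertions longer than
their chromosome are resampled. The assembled molecule is
left sub-telomere + oriented insertions + reverse-complemented right
sub-telomere.

The miniature reference is deterministic for a given generator state:
8 pseudo-chromosomes × 100 kb of i.i.d. sequence, sub-telomere contigs
(1.5 kb unique sequence + 25 TTAGGG repeats) whose first 68 bp are the
primer alignment targets, and tagged plasmid / E. coli / mitochondrial
decoy contigs so origin classification is exercised.

Reads apply a uniform per-base error process (default 5% total,
40/30/30 substitution/insertion/deletion — a nanopore-like split);
half the reads are emitted reverse-complemented. Read ids encode the
full truth (`event{k};n={c};{chrom}:{s}-{e}:{strand};...|read{i}`), so
ground truth is recoverable from any downstream artifact; an external
simulator producing FASTQ with the same id convention is a drop-in.

What the simulator does *not* model: pore-level signal and homopolymer
error structure, chimeric/barcode-hopping artefacts, PCR recombination
between molecules, real sub-telomere paralogy, and repeat-rich genome
context. Passing tests therefore demonstrate the pipeline's arithmetic
and its behaviour under idealised noise, not calling performance on a
real genome.

## Benchmarking

Insertion-level: greedy one-to-one matching, a call is correct when
chromosomes agree and both breakpoints are within 50 bp of truth
(strand agreement optional, off by default); unmatched calls are FP,
unmatched truths FN; precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2TP/(2TP+FP+FN), pooled across reads (micro-averaged; per-cluster
tables allow macro views). Undefined ratios are NaN, never 0.
Cluster-level: truth clusters are reads sharing an event id; each
truth cluster pairs with the called cluster of maximal intersection
(greedy, each called cluster used once); tp = |intersection|,
fn = missing members, fp = extra members.

## The resolvable-insertion-length limit

The gamma length model (shape ≈ 0.316) places ≈ 19% of insertion mass
below 11 bp and ≈ 31% below 50 bp. An insertion shorter than the
11-bp seed length is unmappable by any seed-based aligner — it cannot
even be seeded under the mapper contract's own `-k 11` — and appears
as an insertion-gap junction instead, exactly the "insertions or gaps
(sequence that could not be mapped accurately)" class that dominates
real junction spectra alongside microhomology. Consequences, measured
on a 200-event simulation with the built-in mapper: at error 0,
insertion precision 0.9996 and recall 0.774 overall but 0.9996
restricted to insertions ≥ 23 bp; clustering precision 1.0, recall
0.992 (the rare event whose insertions are all sub-seed yields
two-alignment reads that are correctly excluded from clustering); at
5% error, F1 ≈ 0.85 with > 79% of misses shorter than 11 bp. These
ceilings are properties of the length distribution, not of the
implementation, and the corresponding acceptance tests assert the
idealised thresholds and are expected to fail at exactly this margin.

## Defaults that matter

| parameter | default | units | why |
|---|---|---|---|
| min_block_len | 150 | bp | artefact blocks shorter than this are ignored |
| telomere_kmer_fraction | 0.30 | fraction | exemption cutoff for telomeric blocks |
| repetitiveness_cutoff | 0.3 | score | stringent artefact filter |
| primer_score_fraction | 0.4 | fraction of max | primer match threshold |
| end_window / interior_exclusion | 150 | bp | primer search / concatemer interior bounds |
| match/mismatch/gap open/extend | 2/3/5/2 | score | mirrors the mapper contract |
| overlap_fraction | 0.80 | fraction | reciprocal-overlap equivalence everywhere |
| insertion_count_rel_diff | 0.25 | fraction | clustering prefilter |
| query_len_rel_diff | 0.04 | fraction | clustering prefilter |
| jaccard_thresholds | 1,1,0.66,0.66,0.66,0.5 | — | set sizes 1–6; 0.5 above |
| max_edges_per_node | 10 | edges | sparse-graph cap |
| hotspot_window | 10000 | bp | single-linkage gap |
| benchmark tolerance | 50 | bp | breakpoint match window |

All of these live in `PipelineConfig` (YAML-serialisable); every stage
reads only from it.

## Problem sizes

The test suite exercises the full default simulation (3000 events) for
distribution moments, a 200-event simulation (~3000 reads) for the
end-to-end and clustering benchmarks at error rates 0 and 5%, and a
4 × 20 kb reference for unit-level mapping tests; these sizes give
stable statistics (3-SE Monte-Carlo bands) at interactive runtimes.
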