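"""Low-complexity masking, artefact filtering, concatemer detection and
primer labelling."""
import numpy as np
import pytest

from telofuse.core_io import NO_PRIMER, PipelineConfig, PrimerSpec, QCStatus, SequencingRead
from telofuse.readqc import (
    blocks_from_lowercase,
    detect_concatemer,
    filter_artifacts,
    label_primers,
    mask_low_complexity,
    repetitiveness_score,
    telomere_kmer_fraction,
)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestRepetitiveness:
    def test_homopolymer_scores_high(self):
        assert repetitiveness_score("A" * 200) >= 0.9

    def test_random_sequence_scores_low(self):
        rng = np.random.default_rng(0)
        scores = [repetitiveness_score(random_seq(rng, 200)) for _ in range(1000)]
        assert max(scores) < 0.3

    def test_monotone_between_extremes(self):
        rng = np.random.default_rng(1)
        rand = random_seq(rng, 100)
        mixed = rand + "A" * 100
        low = repetitiveness_score(rand + random_seq(rng, 100))
        high = repetitiveness_score("A" * 200)
        mid = repetitiveness_score(mixed)
        assert low < mid < high

    def test_shorter_than_k_is_zero(self):
        assert repetitiveness_score("ACGT", k=8) == 0.0


class TestTelomereKmerFraction:
    def test_pure_telomere_repeat_is_one(self):
        assert telomere_kmer_fraction("TTAGGG" * 10) == 1.0
        assert telomere_kmer_fraction("CCCTAA" * 10) == 1.0

    def test_rotations_count(self):
        # starting mid-motif still yields all-rotation 6-mers
        assert telomere_kmer_fraction("AGGGTT" * 10) == 1.0

    def test_homopolymer_is_zero(self):
        assert telomere_kmer_fraction("A" * 60) == 0.0

    def test_half_and_half(self):
        seq = "TTAGGG" * 20 + "A" * 120
        frac = telomere_kmer_fraction(seq)
        # sliding-window oracle: count matching 6-mers directly
        rotations = {("TTAGGG" * 2)[i:i + 6] for i in range(6)} \
            | {("CCCTAA" * 2)[i:i + 6] for i in range(6)}
        expected = sum(seq[i:i + 6] in rotations for i in range(len(seq) - 5)) \
            / (len(seq) - 5)
        assert frac == pytest.approx(expected)
        assert frac == pytest.approx(0.5, abs=0.05)


class TestMasking:
    def test_period4_tandem_masked(self):
        seq = "ACGT" * 60
        blocks = mask_low_complexity(seq)
        assert len(blocks) == 1
        assert len(blocks[0]) >= 0.9 * len(seq)

    def test_random_sequence_unmasked(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            blocks = mask_low_complexity(random_seq(rng, 240))
            assert not any(len(b) >= 150 for b in blocks)

    def test_telomere_repeat_block_flagged_telomeric(self):
        blocks = mask_low_complexity("TTAGGG" * 40)
        assert len(blocks) == 1
        assert blocks[0].telomere_fraction > 0.9

    def test_lowercase_override(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 100) + "acgt" * 50 + random_seq(rng, 100)
        blocks = blocks_from_lowercase(seq)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (100, 300)


class TestArtifactFilter:
    def test_long_homopolymer_block_discards(self):
        rng = np.random.default_rng(4)
        read = SequencingRead("r", random_seq(rng, 200) + "A" * 300 + random_seq(rng, 200))
        assert filter_artifacts(read) is QCStatus.ARTIFACT_LOW_COMPLEXITY
        assert read.qc_status is QCStatus.ARTIFACT_LOW_COMPLEXITY

    def test_telomere_array_exempt(self):
        rng = np.random.default_rng(5)
        read = SequencingRead("r", random_seq(rng, 200) + "TTAGGG" * 60 + random_seq(rng, 200))
        assert filter_artifacts(read) is QCStatus.PASS

    def test_short_block_below_length_threshold_passes(self):
        rng = np.random.default_rng(6)
        read = SequencingRead("r", random_seq(rng, 200) + "A" * 140 + random_seq(rng, 200))
        assert filter_artifacts(read) is QCStatus.PASS

    def test_telomere_exemption_holds_for_any_repetitiveness(self):
        """A read whose only long blocks are telomeric is never discarded."""
        for n in (30, 60, 120):
            read = SequencingRead("r", "TTAGGG" * n)
            assert filter_artifacts(read) is QCStatus.PASS

    def test_spiked_artifact_fraction_recovered(self):
        """Recovered artefact fraction matches a known spike-in within
        binomial error."""
        from scipy.stats import binom

        rng = np.random.default_rng(7)
        spike = 0.05
        n = 400
        verdicts = []
        for _ in range(n):
            if rng.random() < spike:
                s = random_seq(rng, 150) + "AC" * 250 + random_seq(rng, 150)
            else:
                s = random_seq(rng, 800)
            verdicts.append(filter_artifacts(SequencingRead("r", s)))
        found = sum(v is QCStatus.ARTIFACT_LOW_COMPLEXITY for v in verdicts)
        lo, hi = binom.ppf([0.0005, 0.9995], n, spike)
        assert lo <= found <= hi


def make_primer(rng):
    target = random_seq(rng, 68)
    return PrimerSpec("p1", target[:20], target)


class TestConcatemer:
    def test_concatenated_amplicons_detected(self):
        rng = np.random.default_rng(8)
        primer = make_primer(rng)
        amplicon = primer.alignment_target + random_seq(rng, 700)
        read = SequencingRead("r", amplicon + amplicon)
        assert detect_concatemer(read, [primer]) is True
        assert read.qc_status is QCStatus.ARTIFACT_CONCATEMER

    def test_clean_amplicon_negative(self):
        rng = np.random.default_rng(9)
        primer = make_primer(rng)
        read = SequencingRead("r", primer.alignment_target + random_seq(rng, 700))
        assert detect_concatemer(read, [primer]) is False

    def test_mismatched_interior_primer_still_detected(self):
        """A few scattered mismatches keep the score above 0.4 x max."""
        rng = np.random.default_rng(10)
        primer = make_primer(rng)
        t = list(primer.alignment_target)
        for pos in (10, 30, 50):
            t[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[t[pos]]
        read = SequencingRead(
            "r", random_seq(rng, 400) + "".join(t) + random_seq(rng, 400))
        # score >= (68-3)*2 - 3*3 = 121 >= 0.4*136
        assert detect_concatemer(read, [primer]) is True

    def test_short_read_empty_interior(self):
        rng = np.random.default_rng(11)
        primer = make_primer(rng)
        read = SequencingRead("r", random_seq(rng, 200))
        assert detect_concatemer(read, [primer]) is False


class TestLabelPrimers:
    def test_exact_target_at_start(self):
        rng = np.random.default_rng(12)
        primer = make_primer(rng)
        read = SequencingRead("r", primer.alignment_target + random_seq(rng, 500))
        label_primers(read, [primer])
        assert read.primer_label_start == "p1"
        assert read.trimmed_interval[0] == 0

    def test_no_resemblance_labels_absent(self):
        rng = np.random.default_rng(13)
        primer = make_primer(rng)
        read = SequencingRead("r", random_seq(rng, 600))
        label_primers(read, [primer])
        assert read.primer_label_start == NO_PRIMER
        assert read.primer_label_end == NO_PRIMER
        assert read.primer_label_start == "False"

    def test_leading_garbage_trimmed(self):
        rng = np.random.default_rng(14)
        primer = make_primer(rng)
        seq = random_seq(rng, 10) + primer.alignment_target + random_seq(rng, 500)
        read = SequencingRead("r", seq)
        label_primers(read, [primer])
        assert read.primer_label_start == "p1"
        assert read.trimmed_interval[0] == 10
        assert read.sequence.startswith(primer.alignment_target)

    def test_reverse_complement_found_at_three_prime_end(self):
        from Bio.Seq import reverse_complement

        rng = np.random.default_rng(15)
        primer = make_primer(rng)
        seq = random_seq(rng, 500) + reverse_complement(primer.alignment_target) \
            + random_seq(rng, 8)
        read = SequencingRead("r", seq)
        label_primers(read, [primer])
        assert read.primer_label_end == "p1"
        assert read.trimmed_interval[1] == 568

    def test_idempotent_on_trimmed_reads(self):
        from Bio.Seq import reverse_complement

        rng = np.random.default_rng(16)
        primer = make_primer(rng)
        seq = (random_seq(rng, 12) + primer.alignment_target + random_seq(rng, 500)
               + reverse_complement(primer.alignment_target) + random_seq(rng, 9))
        read = SequencingRead("r", seq)
        label_primers(read, [primer])
        first = (read.sequence, read.trimmed_interval,
                 read.primer_label_start, read.primer_label_end)
        label_primers(read, [primer])
        assert (read.sequence, read.trimmed_interval,
                read.primer_label_start, read.primer_label_end) == first


def test_qc_verdicts_mutually_exclusive():
    """One read receives exactly one verdict from the QC vocabulary."""
    rng = np.random.default_rng(17)
    primer = make_primer(rng)
    config = PipelineConfig()
    reads = [
        SequencingRead("clean", primer.alignment_target + random_seq(rng, 500)),
        SequencingRead("lowc", random_seq(rng, 100) + "AG" * 200 + random_seq(rng, 100)),
        SequencingRead("concat", (primer.alignment_target + random_seq(rng, 400)) * 2),
    ]
    verdicts = []
    for read in reads:
        v = filter_artifacts(read, config)
        if v is QCStatus.PASS:
            detect_concatemer(read, [primer], config)
        verdicts.append(read.qc_status)
    assert verdicts == [QCStatus.PASS, QCStatus.ARTIFACT_LOW_COMPLEXITY,
                        QCStatus.ARTIFACT_CONCATEMER]
    assert all(v in QCStatus for v in verdicts)
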