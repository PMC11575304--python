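"""Quality trimming, primer removal, pair logic and artifact classification."""

import pytest

from metacrispr.io_core import CRISPR1, CRISPR3, Read, ReadPair, revcomp
from metacrispr.simulate import SimConfig, make_array, simulate_sample
from metacrispr.spacer_extract import (
    ArtifactLabel,
    ExtractParams,
    classify_artifact,
    extract_read_pair,
    extract_sample,
    find_and_trim_primer,
    length_filter,
    quality_trim,
    reconcile_pair,
)

from conftest import random_read


def mott_oracle(qual, error_limit=0.01):
    """Exhaustive O(n^2) search over all contiguous windows.

    Maximizes the cumulative Mott score; ties prefer the smaller start, then
    the larger end. The empty window (0, 0) scores 0.
    """
    scores = [error_limit - 10.0 ** (-q / 10.0) for q in qual]
    best = (0, 0)
    best_sum = 0.0
    for i in range(len(qual)):
        total = 0.0
        for j in range(i + 1, len(qual) + 1):
            total += scores[j - 1]
            if total > best_sum or (
                total == best_sum and (i < best[0] or (i == best[0] and j > best[1]))
            ):
                best_sum = total
                best = (i, j)
    return best


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        read = Read(id="r", seq="ACGTACGT", qual=(30,) * 8)
        assert quality_trim(read) == read

    def test_low_quality_read_empties(self):
        read = Read(id="r", seq="ACGTACGT", qual=(10,) * 8)
        assert len(quality_trim(read)) == 0

    def test_matches_exhaustive_window_oracle(self, rng):
        for i in range(1000):
            read = random_read(rng, int(rng.integers(1, 61)), qmin=2, qmax=41, read_id=f"r{i}")
            start, end = mott_oracle(read.qual)
            trimmed = quality_trim(read)
            assert trimmed.seq == read.seq[start:end], read.qual

    def test_mixed_read_keeps_best_window(self):
        # 4 good bases, 3 terrible, 3 good: the contiguous optimum is one of
        # the flanks, found by the same rule as the oracle.
        qual = (30,) * 4 + (2,) * 3 + (30,) * 3
        read = Read(id="r", seq="ACGTACGTAC", qual=qual)
        start, end = mott_oracle(qual)
        assert quality_trim(read).seq == read.seq[start:end]
        assert (start, end) == (0, 4)


class TestPrimerTrim:
    def test_exact_prefix_removed(self, crispr3):
        seq = crispr3.fwd_locus + "ACGTACGT"
        assert find_and_trim_primer(seq, crispr3.fwd_locus) == "ACGTACGT"

    def test_one_substitution_tolerated(self, crispr3):
        primer = crispr3.fwd_locus
        mutated = "A" + primer[1:] if primer[0] != "A" else "C" + primer[1:]
        assert find_and_trim_primer(mutated + "ACGTACGT", primer) == "ACGTACGT"

    def test_three_mismatches_not_found(self, crispr3):
        primer = crispr3.fwd_locus
        bad = _mutate(primer, (0, 5, 10)) + "ACGTACGT"
        assert find_and_trim_primer(bad, primer) is None

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            find_and_trim_primer("ACGTACGTACGT", "ACGTACG")


def _mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = "A" if out[p] != "A" else "C"
    return "".join(out)


class TestReconcile:
    def test_identical_inserts_pass(self):
        seq = "ACGTACGTACGTACGTACGTAC"
        assert reconcile_pair(seq, seq) == seq

    def test_single_mismatch_resolved_by_quality(self):
        a = "ACGTACGTACGTACGTACGTAC"
        b = a[:5] + "T" + a[6:]
        qa = [38] * len(a)
        qb = [12] * len(a)
        assert reconcile_pair(a, b, (qa, qb)) == a
        assert reconcile_pair(a, b, (qb, qa)) == b

    def test_two_mismatches_conflict(self):
        a = "ACGTACGTACGTACGTACGTAC"
        b = _mutate(a, (2, 9))
        assert reconcile_pair(a, b) is None

    def test_length_mismatch_conflict(self):
        assert reconcile_pair("ACGT", "ACG") is None


@pytest.mark.parametrize(
    "length,expected", [(19, False), (20, True), (40, True), (41, False)]
)
def test_length_filter_bounds_inclusive(length, expected):
    assert length_filter("A" * length) is expected


class TestArtifactClassifier:
    def test_reverse_tail_dimer_insert(self, crispr3):
        # Insert whose reverse complement is the 5' end of the Illumina tag
        # on the reverse primer: the classic reverse-primer dimer artifact.
        assert (
            classify_artifact("ACATCTCCGAGCCCACGAGAC", crispr3)
            is ArtifactLabel.PRIMER_DIMER_REV_TAIL
        )

    def test_forward_primer_fragment(self, crispr1):
        assert (
            classify_artifact("ACTCTCAAGATTTAAGTAACT", crispr1)
            is ArtifactLabel.PRIMER_DIMER_FWD
        )

    def test_unrelated_sequence_is_ok(self, crispr3, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=25))
            assert classify_artifact(seq, crispr3) is ArtifactLabel.OK


def _noiseless_pair(primers, spacer, pair_id="p"):
    amplicon = primers.fwd_locus + spacer + revcomp(primers.rev_locus)
    q = (35,) * len(amplicon)
    return ReadPair(Read(pair_id, amplicon, q), Read(pair_id, revcomp(amplicon), q))


class TestExtractPipeline:
    @pytest.mark.parametrize("length", range(20, 41))
    def test_exact_recovery_for_all_spacer_lengths(self, crispr3, rng, length):
        array = make_array(crispr3, 1, spacer_len_range=(length, length), seed=length)
        spacer = array.spacers[0]
        label, recovered = extract_read_pair(_noiseless_pair(crispr3, spacer), crispr3)
        assert label is ArtifactLabel.OK
        assert recovered == spacer

    def test_idempotent_on_reembedded_spacers(self, crispr3):
        array = make_array(crispr3, 6, seed=7)
        pairs = [_noiseless_pair(crispr3, s, f"p{i}") for i, s in enumerate(array.spacers)]
        obs, _ = extract_sample((p.r1 for p in pairs), (p.r2 for p in pairs), crispr3)
        first = {o.seq for o in obs}
        assert first == set(array.spacers)
        pairs2 = [_noiseless_pair(crispr3, s, f"q{i}") for i, s in enumerate(sorted(first))]
        obs2, _ = extract_sample((p.r1 for p in pairs2), (p.r2 for p in pairs2), crispr3)
        assert {o.seq for o in obs2} == first

    def test_labels_conserve_reads(self, crispr3, crispr1):
        array = make_array(crispr3, 4, seed=3)
        config = SimConfig(read_depth=2000, dimer_reads_expected=500.0)
        pairs = simulate_sample(array, config, 100.0, seed=5, sample_id="s")
        _, report = extract_sample((p.r1 for p in pairs), (p.r2 for p in pairs), crispr3, sample_id="s")
        assert sum(report.values()) == len(pairs)
        assert report[ArtifactLabel.PRIMER_DIMER_REV_TAIL] > 0

    def test_ntc_yields_no_spacers(self, crispr3):
        array = make_array(crispr3, 4, seed=3)
        config = SimConfig(read_depth=2000, dimer_reads_expected=500.0, contaminant_rate=0.0)
        pairs = simulate_sample(array, config, 0.0, seed=11, sample_id="ntc")
        obs, report = extract_sample((p.r1 for p in pairs), (p.r2 for p in pairs), crispr3, sample_id="ntc")
        dimer = report[ArtifactLabel.PRIMER_DIMER_REV_TAIL] + report[ArtifactLabel.PRIMER_DIMER_FWD]
        assert dimer / max(1, len(pairs)) > 0.95
        assert sum(o.count for o in obs) <= 0.05 * len(pairs)

    def test_empty_input(self, crispr3):
        obs, report = extract_sample(iter([]), iter([]), crispr3)
        assert obs == [] and sum(report.values()) == 0

    def test_unmated_inputs_rejected(self, crispr3):
        r = Read("a", "ACGT", (30,) * 4)
        with pytest.raises(ValueError, match="unmated"):
            extract_sample(iter([r]), iter([]), crispr3)
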