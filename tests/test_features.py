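"""Nine-feature mismatch characterization and cause classification."""

import itertools

import pytest

from protqc.error_detect import SequenceError
from protqc.features import (
    ALL_FEATURES,
    EVIDENCE_CLASS,
    FALSE_POSITIVE_FEATURES,
    FeatureFlag,
    MISPREDICTION_FEATURES,
    classify_mismatch,
    flag_alt_isoform,
    flag_conserved_4plus,
    flag_n_chars,
    flag_noncanonical_splice_ref,
    flag_repeat_region,
    flag_short_intron,
    tandem_repeat_coverage,
)
from protqc.io_formats import ExonInterval, GeneModel, ProteinGenomeMap, SequenceRecord


def mismatch(sid="t", cols=(100, 140), seq=(100, 140), ref=(100, 140)):
    return SequenceError(sid, "MISMATCH", cols, seq, ref, 10.0)


class TestClassification:
    def test_exhaustive_partition(self):
        """Every combination of the nine features maps to exactly one of
        the four classes, following the evidence-class logic."""
        counts = {c: 0 for c in
                  ("GENE_PREDICTION_ERROR", "FALSE_POSITIVE", "UNCONFIRMED",
                   "UNEXPLAINED")}
        for r in range(len(ALL_FEATURES) + 1):
            for combo in itertools.combinations(ALL_FEATURES, r):
                names = set(combo)
                got = classify_mismatch(names)
                counts[got] += 1
                mis = bool(names & set(MISPREDICTION_FEATURES))
                fp = bool(names & set(FALSE_POSITIVE_FEATURES))
                if mis and not fp:
                    assert got == "GENE_PREDICTION_ERROR"
                elif fp and not mis:
                    assert got == "FALSE_POSITIVE"
                elif mis and fp:
                    assert got == "UNCONFIRMED"
                elif names:
                    assert got == "UNCONFIRMED"  # recurrence feature only
                else:
                    assert got == "UNEXPLAINED"
        assert sum(counts.values()) == 2 ** 9
        assert counts["UNEXPLAINED"] == 1

    def test_evidence_classes_fixed_per_feature(self):
        for f in MISPREDICTION_FEATURES:
            assert FeatureFlag(f).evidence_class == "MISPREDICTION"
        for f in FALSE_POSITIVE_FEATURES:
            assert FeatureFlag(f).evidence_class == "FALSE_POSITIVE"
        assert FeatureFlag("CONSERVED_4PLUS").evidence_class == "UNDETERMINED"

    def test_examples(self):
        assert classify_mismatch({"SHORT_INTRON"}) == "GENE_PREDICTION_ERROR"
        assert classify_mismatch({"ALT_ISOFORM_MATCH"}) == "FALSE_POSITIVE"
        assert classify_mismatch({"SHORT_INTRON", "MSA_ERROR"}) == "UNCONFIRMED"
        assert classify_mismatch(set()) == "UNEXPLAINED"

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            classify_mismatch({"BOGUS"})


class TestNChars:
    def _model(self):
        return GeneModel("g", "t", "c", "+",
                         [ExonInterval(10, 40), ExonInterval(80, 110)])

    def test_n_in_intron_flags(self):
        contig = SequenceRecord(
            "c", "A" * 50 + "NNNN" + "A" * 60, "nucleotide")
        flag = flag_n_chars(self._model(), contig)
        assert flag and flag.feature == "N_CHARS"

    def test_n_outside_span_ignored(self):
        contig = SequenceRecord("c", "NNNN" + "A" * 106 + "NNNN", "nucleotide")
        assert flag_n_chars(self._model(), contig) is None


class TestShortIntron:
    def _model(self, intron_len):
        return GeneModel("g", "t", "c", "+",
                         [ExonInterval(0, 30), ExonInterval(30 + intron_len,
                                                            60 + intron_len)])

    def test_29_nt_flags(self):
        assert flag_short_intron(self._model(29)) is not None

    def test_30_nt_does_not(self):
        assert flag_short_intron(self._model(30)) is None

    def test_single_exon_no_flag(self):
        m = GeneModel("g", "t", "c", "+", [ExonInterval(0, 30)])
        assert flag_short_intron(m) is None


class TestNoncanonicalSplice:
    def _setup(self, intron, strand="+"):
        # exon1 (0,30) intron (30, 30+len) exon2 ...
        L = len(intron)
        seq = "ATG" + "GCT" * 9 + intron + "GCT" * 10
        if strand == "-":
            from Bio.Seq import reverse_complement

            n = len(seq)
            contig = SequenceRecord("c", reverse_complement(seq), "nucleotide")
            exons = [ExonInterval(n - 30, n), ExonInterval(0, n - 30 - L)]
        else:
            contig = SequenceRecord("c", seq, "nucleotide")
            exons = [ExonInterval(0, 30), ExonInterval(30 + L, 60 + L)]
        model = GeneModel("g", "t", "c", strand, exons)
        return model, contig

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_canonical_not_flagged(self, strand):
        model, contig = self._setup("GT" + "A" * 28 + "AG", strand)
        err = mismatch(seq=(2, 18), ref=(2, 18))
        pm = ProteinGenomeMap(model)
        assert flag_noncanonical_splice_ref(err, model, contig, pm) is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_gc_donor_flagged(self, strand):
        model, contig = self._setup("GC" + "A" * 28 + "AG", strand)
        err = mismatch(seq=(2, 18), ref=(2, 18))
        pm = ProteinGenomeMap(model)
        flag = flag_noncanonical_splice_ref(err, model, contig, pm)
        assert flag and flag.feature == "NONCANONICAL_SPLICE_REF"


class TestRepeatRegion:
    def test_period2_repeat_flags(self):
        assert flag_repeat_region("QA" * 10) is not None

    def test_high_complexity_no_flag(self):
        seg = "ACDEFGHIKLMNPQRSTVWY" * 2  # period 20 > max scanned period
        assert flag_repeat_region(seg) is None

    def test_coverage_oracle(self):
        # direct autocorrelation check on a half-repeat segment
        seg = "QA" * 10 + "CDEFGHIKLMNPQRSTVWYM"
        cov = tandem_repeat_coverage(seg)
        assert (flag_repeat_region(seg) is not None) == (cov >= 0.5)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            flag_repeat_region("QAQA")


class TestAltIsoform:
    def test_verbatim_match_flags(self):
        seg = "WDEKFHILMQRSTVAYCPGN"
        iso = SequenceRecord("iso", "MMM" + seg + "KKK", "protein")
        flag = flag_alt_isoform(seg, [iso])
        assert flag and flag.feature == "ALT_ISOFORM_MATCH"

    def test_empty_isoform_set_never_flags(self):
        assert flag_alt_isoform("WDEKFHILMQRSTVAYCPGN", []) is None

    def test_unrelated_isoform_no_flag(self):
        iso = SequenceRecord("iso", "G" * 60, "protein")
        assert flag_alt_isoform("WDEKFHILMQRSTVAYCPWN", [iso]) is None


class TestConserved4Plus:
    def _mismatches(self, n_rows, cols=(100, 140)):
        return [mismatch(sid=f"s{i}", cols=cols) for i in range(n_rows)]

    def test_four_rows_flag(self):
        ms = self._mismatches(4)
        assert flag_conserved_4plus(ms[0], ms) is not None

    def test_three_rows_no_flag(self):
        ms = self._mismatches(3)
        assert flag_conserved_4plus(ms[0], ms) is None

    def test_low_overlap_not_counted(self):
        ms = self._mismatches(3) + [mismatch(sid="far", cols=(200, 240))]
        assert flag_conserved_4plus(ms[0], ms) is None

    def test_fragmented_row_pooled(self):
        ms = self._mismatches(3) + [
            mismatch(sid="frag", cols=(100, 120)),
            mismatch(sid="frag", cols=(120, 140)),
        ]
        assert flag_conserved_4plus(ms[0], ms) is not None
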