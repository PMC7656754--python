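"""Translated genomic search, transcript surgery, and quality scoring."""

import random

import numpy as np
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from protqc.correction import (
    quality_from_rows,
    rebuild_protein,
    score_alignment,
    splice_in_exon,
    translated_search,
    verify_transcript,
)
from protqc.io_formats import (
    STANDARD_TABLE,
    ExonInterval,
    GeneModel,
    SequenceRecord,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def back_translate(pep, seed=0):
    r = random.Random(seed)
    return "".join(r.choice(STANDARD_TABLE.codons_for[a]) for a in pep)


def rand_nt(n, seed):
    r = random.Random(seed)
    return "".join(r.choice("ACGT") for _ in range(n))


class TestTranslatedSearch:
    def test_exact_embedded_query_found_in_frame(self):
        pep = "WDEKFHILMQRSTVAYCPGNMKWW"
        coding = back_translate(pep, 1)
        region = "A" + coding + rand_nt(40, 2)  # frame +2 (offset 1)
        hits = translated_search(pep, region)
        top = hits[0]
        assert top.frame == 2
        assert top.identity_pct == 100.0
        assert (top.genomic_span.start, top.genomic_span.end) == (1, 1 + len(coding))
        # brute-force check: translating the hit span reproduces the subject
        span = region[top.genomic_span.start : top.genomic_span.end]
        trans = "".join(
            STANDARD_TABLE.translate_codon(span[i : i + 3])
            for i in range(0, len(span), 3)
        )
        assert trans == top.subject_aa == pep

    def test_reverse_strand_hit(self):
        pep = "WDEKFHILMQRSTVAYCPGNMKWW"
        coding = back_translate(pep, 3)
        region = rand_nt(30, 4) + reverse_complement(coding) + rand_nt(31, 5)
        hits = translated_search(pep, region)
        top = hits[0]
        assert top.frame < 0
        assert top.identity_pct == 100.0
        span = region[top.genomic_span.start : top.genomic_span.end]
        rc = reverse_complement(span)
        trans = "".join(
            STANDARD_TABLE.translate_codon(rc[i : i + 3])
            for i in range(0, len(rc), 3)
        )
        assert trans == pep

    def test_random_region_no_hits_at_thresholds(self):
        r = random.Random(9)
        hits_total = 0
        for seed in range(100):
            pep = "".join(r.choice(AA) for _ in range(30))
            region = rand_nt(60, 1000 + seed)
            hits_total += len(translated_search(pep, region))
        assert hits_total == 0

    def test_region_too_short_rejected(self):
        with pytest.raises(ValueError):
            translated_search("MK", "AC")


class TestVerifyTranscript:
    def test_clean_gene_ok(self, clean_study):
        models = {m.protein_id: m for m in clean_study.models}
        contigs = {c.id: c for c in clean_study.contigs}
        m = clean_study.models[0]
        assert verify_transcript(m, contigs[m.contig_id]) == "ok"

    def test_overlapping_exons(self):
        m = GeneModel.__new__(GeneModel)
        m.gene_id = m.transcript_id = m.contig_id = "x"
        m.strand = "+"
        m.exons = [ExonInterval(100, 200), ExonInterval(150, 250)]
        m.protein_id = "x"
        contig = SequenceRecord("x", "A" * 300, "nucleotide")
        assert verify_transcript(m, contig) == "overlapping_exons"

    def test_frameshift_length(self):
        m = GeneModel("g", "t", "c", "+", [ExonInterval(0, 301)])
        contig = SequenceRecord("c", "ATG" + "AAA" * 100, "nucleotide")
        assert verify_transcript(m, contig) == "frameshift"

    def test_internal_stop(self):
        m = GeneModel("g", "t", "c", "+", [ExonInterval(0, 9)])
        contig = SequenceRecord("c", "ATGTAAAAA", "nucleotide")
        assert verify_transcript(m, contig) == "internal_stop"


class TestRebuildProtein:
    def test_normal_start(self):
        m = GeneModel("g", "t", "c", "+", [ExonInterval(0, 9)])
        contig = SequenceRecord("c", "ATGAAATGA", "nucleotide")
        protein, fallback = rebuild_protein(m, contig)
        assert (protein.seq, fallback) == ("MK", False)

    def test_alternative_start_scan(self):
        m = GeneModel("g", "t", "c", "+", [ExonInterval(0, 12)])
        contig = SequenceRecord("c", "AAAATGGAATGA", "nucleotide")
        protein, fallback = rebuild_protein(m, contig)
        assert (protein.seq, fallback) == ("ME", True)

    def test_no_start_codon_anywhere(self):
        m = GeneModel("g", "t", "c", "+", [ExonInterval(0, 9)])
        contig = SequenceRecord("c", "AAAGAAGAA", "nucleotide")
        protein, fallback = rebuild_protein(m, contig)
        assert protein is None and fallback is True


class TestQualityScores:
    def test_identical_proteins(self):
        p = SequenceRecord("p", "M" + "KVLHEAARG" * 11, "protein")
        q = score_alignment(p, p)
        assert (q.identity_I, q.coverage_C) == (100.0, 100.0)

    def test_hand_computed_formula(self):
        # alignment of 100 columns, 80 aligned pairs, 72 identities
        row_a = "A" * 72 + "C" * 8 + "-" * 20
        row_b = "A" * 72 + "W" * 8 + "Y" * 20
        q = quality_from_rows(row_a, row_b)
        assert (q.identity_I, q.coverage_C) == (90.0, 80.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_swap_invariance(self, seed):
        r = random.Random(seed)
        a = "".join(r.choice(AA) for _ in range(r.randint(30, 80)))
        b = "".join(r.choice(AA) for _ in range(r.randint(30, 80)))
        ra, rb = SequenceRecord("a", a, "protein"), SequenceRecord("b", b, "protein")
        q1, q2 = score_alignment(ra, rb), score_alignment(rb, ra)
        assert q1.identity_I == pytest.approx(q2.identity_I)
        assert q1.coverage_C == pytest.approx(q2.coverage_C)


class TestSpliceInExon:
    def test_opposite_strand_hit_inverted(self):
        from protqc.correction import TranslatedHit

        m = GeneModel("g", "t", "c", "+",
                      [ExonInterval(0, 30), ExonInterval(60, 90)])
        hit = TranslatedHit(
            frame=-1, genomic_span=ExonInterval(60, 90), query_span=(0, 10),
            identity_pct=100.0, evalue=0.0, raw_score=50.0, query_len=10,
        )
        refined, exon, status = splice_in_exon(m, [m.exons[1]], hit, 200)
        assert refined is None and status == "inverted_exons"

    def test_one_for_one_replacement(self):
        from protqc.correction import TranslatedHit

        m = GeneModel("g", "t", "c", "+",
                      [ExonInterval(0, 30), ExonInterval(60, 90),
                       ExonInterval(120, 150)])
        hit = TranslatedHit(
            frame=1, genomic_span=ExonInterval(60, 90), query_span=(0, 10),
            identity_pct=100.0, evalue=0.0, raw_score=50.0, query_len=10,
        )
        refined, exon, status = splice_in_exon(m, [m.exons[1]], hit, 200)
        assert status == "ok"
        assert len(refined.exons) == 3
        assert exon == ExonInterval(60, 90)
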