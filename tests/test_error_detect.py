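"""Reference-anchored MSA construction and seven-category error detection."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protqc.error_detect import (
    DetectionConfig,
    _mismatch_windows,
    build_msa,
    detect_errors,
    error_census,
    length_ratio_filter,
)
from protqc.io_formats import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def prot(name, seq):
    return SequenceRecord(name, seq, "protein")


def rand_prot(n, seed):
    r = random.Random(seed)
    return "".join(r.choice(AA) for _ in range(n))


def scrambled(seq, rng=None):
    """A same-length block with (near-)zero identity to ``seq``."""
    r = rng or random.Random(5)
    return "".join(r.choice([a for a in AA if a != c]) for c in seq)


class TestLengthRatioFilter:
    @pytest.mark.parametrize(
        "ref_len,orth_len,keep",
        [(100, 100, True), (100, 301, False), (100, 300, True),
         (100, 33, False), (100, 34, True)],
    )
    def test_boundaries(self, ref_len, orth_len, keep):
        ref = prot("r", "A" * ref_len)
        orth = prot("o", "A" * orth_len)
        assert length_ratio_filter(ref, orth) is keep


class TestBuildMsa:
    def test_identical_rows_no_gaps(self):
        seq = "MKVLHEAARGW" * 4
        msa = build_msa(prot("r", seq), [prot("a", seq), prot("b", seq)])
        assert msa.column_count == len(seq)
        assert all("-" not in row for row in msa.rows.values())

    def test_insertion_creates_reference_gap_columns(self):
        base = "MKVLHEAARGWDDEFIKL" * 3
        ins = base[:20] + "WWWWW" + base[20:]
        msa = build_msa(prot("r", base), [prot("a", ins)])
        ref_row = msa.rows["r"]
        assert ref_row.count("-") == 5
        assert msa.rows["a"].count("-") == 0

    def test_ungap_reproduces_inputs(self, clean_study):
        ref = clean_study.reference_proteins[0]
        orths = [clean_study.target_proteins[sp][0] for sp in clean_study.species]
        msa = build_msa(ref, orths)
        for rec in [ref] + orths:
            assert msa.ungapped(rec.id) == rec.seq

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            build_msa(prot("r", "MKV"), [])


class TestDetectErrors:
    def test_identical_ortholog_no_errors(self):
        seq = "MKVLHEAARGWDDEFIKL" * 5
        msa = build_msa(prot("r", seq), [prot("a", seq)])
        assert detect_errors(msa) == []

    def test_scrambled_block_single_mismatch(self):
        base = rand_prot(120, 1)
        block = scrambled(base[50:75])
        alt = base[:50] + block + base[75:]
        msa = build_msa(prot("r", base), [prot("a", alt)])
        errs = detect_errors(msa)
        mism = [e for e in errs if e.category == "MISMATCH"]
        assert len(mism) == 1
        lo, hi = mism[0].seq_positions
        assert lo <= 50 and hi >= 75
        assert mism[0].segment_identity_pct < 50.0

    def test_cterminal_truncation(self):
        base = rand_prot(150, 2)
        msa = build_msa(prot("r", base), [prot("a", base[:-30])])
        errs = detect_errors(msa)
        assert [e.category for e in errs] == ["CTER_DELETION"]

    def test_nterminal_extension(self):
        base = rand_prot(150, 3)
        msa = build_msa(prot("r", base), [prot("a", "WWWWWWWW" + base)])
        errs = detect_errors(msa)
        assert [e.category for e in errs] == ["NTER_EXTENSION"]

    def test_internal_deletion(self):
        base = rand_prot(150, 4)
        msa = build_msa(prot("r", base), [prot("a", base[:60] + base[75:])])
        errs = detect_errors(msa)
        assert [e.category for e in errs] == ["INTERNAL_DELETION"]

    def test_coordinate_consistency_and_disjointness(self, mixed_bundle):
        from protqc.pipeline import (
            PipelineConfig, StudyInputs, stage_detect, stage_orthologs,
        )

        inputs = StudyInputs.load(mixed_bundle)
        cfg = PipelineConfig()
        st = stage_orthologs(inputs, cfg)
        stage_detect(inputs, st, cfg)
        assert any(e.category == "MISMATCH" for e in st.errors)
        by_row = {}
        for e in st.errors:
            ref_id = f"ref_{e.sequence_id.split('_', 1)[1]}"
            msa = st.msas[ref_id]
            row = msa.rows[e.sequence_id]
            lo, hi = e.msa_columns
            seg_cols = row[lo:hi].replace("-", "")
            a, b = e.seq_positions
            seg_seq = msa.ungapped(e.sequence_id)[a:b]
            assert seg_cols == seg_seq
            if e.category == "MISMATCH":
                assert b - a >= 20 and e.segment_identity_pct < 50.0
                by_row.setdefault(e.sequence_id, []).append((lo, hi))
        for spans in by_row.values():
            spans.sort()
            assert all(x[1] <= y[0] for x, y in zip(spans, spans[1:]))

    def test_row_order_invariance(self, clean_study):
        ref = clean_study.reference_proteins[1]
        orths = [clean_study.target_proteins[sp][1] for sp in clean_study.species]
        a = detect_errors(build_msa(ref, orths))
        b = detect_errors(build_msa(ref, orths[::-1]))
        key = lambda es: sorted(
            (e.sequence_id, e.category, e.seq_positions) for e in es
        )
        assert key(a) == key(b)

    def test_divergence_alone_triggers_nothing(self, clean_study):
        """False-positive control: clean orthologs at study divergence
        produce zero mismatch calls."""
        for i, ref in enumerate(clean_study.reference_proteins):
            orths = [clean_study.target_proteins[sp][i] for sp in clean_study.species]
            errs = detect_errors(build_msa(ref, orths))
            assert [e for e in errs if e.category == "MISMATCH"] == []


class TestMismatchWindows:
    def test_pure_block(self):
        match = [True] * 30 + [False] * 25 + [True] * 30
        (win,) = _mismatch_windows(match, 20, 0.5)
        assert win == (30, 55, 0.0)

    def test_block_below_min_length_ignored(self):
        match = [True] * 30 + [False] * 19 + [True] * 30
        assert list(_mismatch_windows(match, 20, 0.5)) == []

    def test_exactly_half_identity_not_called(self):
        match = ([False, True] * 10) + [True] * 30  # 20 cols at exactly 50%
        assert list(_mismatch_windows(match, 20, 0.5)) == []

    def test_gap_columns_bridged_only_inside(self):
        # low-identity flanks around a gap run merge into one segment
        match = [True] * 20 + [False] * 12 + [None] * 9 + [False] * 12 + [True] * 20
        (win,) = _mismatch_windows(match, 20, 0.5)
        assert win[0] == 20 and win[1] == 53
        # a gap run adjacent to conserved sequence is never included
        match2 = [True] * 20 + [None] * 9 + [False] * 25 + [True] * 20
        (w2,) = _mismatch_windows(match2, 20, 0.5)
        assert w2[0] == 29 and w2[1] == 54

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([True, False, None]), min_size=0, max_size=120),
           st.integers(min_value=5, max_value=25))
    def test_invariants(self, match, min_len):
        wins = list(_mismatch_windows(match, min_len, 0.5))
        prev_end = 0
        for lo, hi, ident in wins:
            assert prev_end <= lo < hi <= len(match)
            aligned = [m for m in match[lo:hi] if m is not None]
            assert len(aligned) >= min_len
            assert ident < 0.5
            assert ident == pytest.approx(sum(aligned) / len(aligned))
            # boundaries are non-identical aligned columns
            assert match[lo] is False and match[hi - 1] is False
            prev_end = hi


class TestCensus:
    def test_empty(self):
        df = error_census([], {}, {"sp1": 3})
        assert df.loc["sp1", "total_errors"] == 0
        assert df.loc["sp1", "errors_per_sequence"] == 0.0

    def test_counts_and_rate(self):
        from protqc.error_detect import SequenceError

        errs = [
            SequenceError("a1", "MISMATCH", (0, 20), (0, 20), (0, 20), 10.0)
            for _ in range(3)
        ] + [SequenceError("a1", "INTERNAL_DELETION", (30, 40), (30, 30), (30, 40))]
        df = error_census(errs, {"a1": "sp1"}, {"sp1": 10, "sp2": 4})
        assert df.loc["sp1", "MISMATCH"] == 3
        assert df.loc["sp1", "total_errors"] == 4
        assert df.loc["sp1", "errors_per_sequence"] == pytest.approx(0.4)
        assert df.loc["sp2", "total_errors"] == 0
        assert df["total_errors"].sum() == len(errs)
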