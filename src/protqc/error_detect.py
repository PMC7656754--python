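"""Reference-anchored multiple alignment and detection of the seven
protein-sequence error categories.

A set of orthologs is aligned to the reference by the star method: each
ortholog is globally aligned to the reference (affine gaps, BLOSUM62,
free end gaps) and the pairwise alignments are merged on reference
coordinates, insertions relative to the reference being left-justified
in shared gap columns.  Each non-reference row is then scanned for:

* N/C-terminal extensions (leading/trailing reference-gap columns),
* N/C-terminal deletions (leading/trailing row-gap columns),
* internal insertions/deletions (gap runs of at least ``indel_min_len``),
* mismatched segments: runs of mutually aligned columns at least
  ``mismatch_min_len`` long with identity below ``mismatch_max_identity``.

A mismatched segment is a hallmark of a wrong-reading-frame or
wrong-boundary exon prediction; segments are reported maximal and trimmed
so that their boundary columns are non-identical (while staying at or
above the minimum length), which localizes the segment on the offending
exon rather than letting it soak up well-aligned flanking sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io_formats import SequenceRecord
from .orthology import ScoringScheme, _make_aligner

#: Scheme for reference-anchored row alignment.  Stiffer gaps than the
#: local-search scheme: within an MSA, gaps should model genuine indels;
#: cheap gaps would shred non-homologous (e.g. wrong-frame) segments into
#: spurious short gap runs and hide them from the mismatch scan.
MSA_SCHEME = ScoringScheme(gap_open=20.0, gap_extend=2.0)

CATEGORIES = (
    "NTER_EXTENSION",
    "NTER_DELETION",
    "CTER_EXTENSION",
    "CTER_DELETION",
    "INTERNAL_INSERTION",
    "INTERNAL_DELETION",
    "MISMATCH",
)


@dataclass
class DetectionConfig:
    mismatch_min_len: int = 20          # aa; segments of at least this length
    mismatch_max_identity: float = 50.0  # %; strictly below calls a mismatch
    indel_min_len: int = 5              # aa; suppresses single-gap jitter
    length_ratio_max: float = 3.0       # ortholog/reference length filter

    def __post_init__(self):
        if min(self.mismatch_min_len, self.indel_min_len) <= 0:
            raise ValueError("lengths must be positive")
        if self.mismatch_max_identity <= 0 or self.length_ratio_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ReferenceAnchoredMSA:
    reference_id: str
    rows: dict[str, str]  # sequence id -> gapped row (reference included)
    column_count: int

    def __post_init__(self):
        for sid, row in self.rows.items():
            if len(row) != self.column_count:
                raise ValueError(f"row {sid!r} has wrong length")
        if self.reference_id not in self.rows:
            raise ValueError("reference row missing")

    def ungapped(self, sid: str) -> str:
        return self.rows[sid].replace("-", "")


@dataclass
class SequenceError:
    sequence_id: str
    category: str
    msa_columns: tuple[int, int]
    seq_positions: tuple[int, int]  # in the target; flanking point for deletions
    ref_positions: tuple[int, int]
    segment_identity_pct: float | None = None  # MISMATCH only


def length_ratio_filter(
    reference: SequenceRecord, ortholog: SequenceRecord,
    config: DetectionConfig = DetectionConfig(),
) -> bool:
    """True (keep) unless the ortholog is strictly more than
    ``length_ratio_max`` times longer or shorter than the reference."""
    r, o = len(reference.seq), len(ortholog.seq)
    if r <= 0 or o <= 0:
        raise ValueError("lengths must be positive")
    return not (o > config.length_ratio_max * r or o < r / config.length_ratio_max)


def build_msa(
    reference: SequenceRecord,
    orthologs: list[SequenceRecord],
    scheme: ScoringScheme = MSA_SCHEME,
) -> ReferenceAnchoredMSA:
    """Star alignment of orthologs around the reference."""
    if not orthologs:
        raise ValueError("at least one ortholog required")
    ref = reference.seq
    if not ref:
        raise ValueError("empty reference sequence")
    al = _make_aligner(scheme, "global", free_ends=True)
    R = len(ref)
    # per row: inserted text before each reference position (index 0..R),
    # and the aligned character ('-' or residue) at each reference position
    per_row: dict[str, tuple[list[str], list[str]]] = {}
    for orth in orthologs:
        if not orth.seq:
            raise ValueError(f"empty ortholog sequence {orth.id!r}")
        aln = al.align(ref.replace("*", "X"), orth.seq.replace("*", "X"))[0]
        ins = [""] * (R + 1)
        at = ["-"] * R
        rpos = qpos = 0
        for (rs, re_), (qs, qe) in zip(*(b.tolist() for b in aln.aligned)):
            if qs > qpos:
                ins[rs] += orth.seq[qpos:qs]
            for k in range(rs, re_):
                at[k] = orth.seq[qs + (k - rs)]
            rpos, qpos = re_, qe
        if qpos < len(orth.seq):
            ins[R] += orth.seq[qpos:]
        per_row[orth.id] = (ins, at)
    widths = [
        max(len(per_row[sid][0][r]) for sid in per_row) for r in range(R + 1)
    ]
    rows: dict[str, str] = {}
    ref_cols = []
    for r in range(R + 1):
        ref_cols.append("-" * widths[r])
        if r < R:
            ref_cols.append(ref[r])
    rows[reference.id] = "".join(ref_cols)
    for sid, (ins, at) in per_row.items():
        cols = []
        for r in range(R + 1):
            cols.append(ins[r].ljust(widths[r], "-"))
            if r < R:
                cols.append(at[r])
        rows[sid] = "".join(cols)
    return ReferenceAnchoredMSA(
        reference_id=reference.id, rows=rows, column_count=len(rows[reference.id])
    )


def detect_errors(
    msa: ReferenceAnchoredMSA,
    config: DetectionConfig = DetectionConfig(),
    row_ids: list[str] | None = None,
) -> list[SequenceError]:
    """Scan every non-reference row of the MSA for the seven error types."""
    out: list[SequenceError] = []
    ids = row_ids if row_ids is not None else [
        sid for sid in msa.rows if sid != msa.reference_id
    ]
    for sid in ids:
        if sid not in msa.rows:
            raise KeyError(f"row {sid!r} not in MSA")
        out.extend(_detect_row(msa, sid, config))
    return out


def _detect_row(msa, sid, config) -> list[SequenceError]:
    ref_row = msa.rows[msa.reference_id]
    row = msa.rows[sid]
    # project to columns where at least one of (reference, row) has a residue
    cols = [
        (c, rc, xc)
        for c, (rc, xc) in enumerate(zip(ref_row, row))
        if rc != "-" or xc != "-"
    ]
    events = []  # (column, kind, ref_char, row_char); kind in a/i/d
    for c, rc, xc in cols:
        kind = "a" if (rc != "-" and xc != "-") else ("i" if rc == "-" else "d")
        events.append((c, kind, rc, xc))
    aligned_idx = [k for k, e in enumerate(events) if e[1] == "a"]
    errors: list[SequenceError] = []
    seq_pos = _cum_positions(events, 3)  # row residue index before event k
    ref_pos = _cum_positions(events, 2)
    if not aligned_idx:
        return errors
    first_a, last_a = aligned_idx[0], aligned_idx[-1]

    def add(cat, k0, k1, identity=None):
        errors.append(
            SequenceError(
                sequence_id=sid,
                category=cat,
                msa_columns=(events[k0][0], events[k1 - 1][0] + 1),
                seq_positions=(seq_pos[k0], seq_pos[k1]),
                ref_positions=(ref_pos[k0], ref_pos[k1]),
                segment_identity_pct=identity,
            )
        )

    # terminal errors
    for lo, hi, nter in ((0, first_a, True), (last_a + 1, len(events), False)):
        n_i = sum(1 for k in range(lo, hi) if events[k][1] == "i")
        n_d = (hi - lo) - n_i
        if n_i >= config.indel_min_len:
            ks = [k for k in range(lo, hi) if events[k][1] == "i"]
            add("NTER_EXTENSION" if nter else "CTER_EXTENSION", ks[0], ks[-1] + 1)
        if n_d >= config.indel_min_len:
            ks = [k for k in range(lo, hi) if events[k][1] == "d"]
            add("NTER_DELETION" if nter else "CTER_DELETION", ks[0], ks[-1] + 1)

    # internal indel runs
    k = first_a
    while k <= last_a:
        kind = events[k][1]
        j = k
        while j <= last_a and events[j][1] == kind:
            j += 1
        if kind == "i" and j - k >= config.indel_min_len:
            add("INTERNAL_INSERTION", k, j)
        elif kind == "d" and j - k >= config.indel_min_len:
            add("INTERNAL_DELETION", k, j)
        k = j

    # mismatch scan over the whole internal region: gap columns score
    # zero, so a segment bridges indels exactly when low-identity aligned
    # material flanks them (gap placement inside a non-homologous region
    # is an alignment artifact and must not fragment the segment); the
    # length criterion counts aligned columns only
    match = [
        (events[t][2] == events[t][3]
         and events[t][2] != "X" and events[t][3] != "X")
        if events[t][1] == "a" else None
        for t in range(first_a, last_a + 1)
    ]
    for s0, s1, ident in _mismatch_windows(
        match, config.mismatch_min_len, config.mismatch_max_identity / 100.0
    ):
        add("MISMATCH", first_a + s0, first_a + s1, round(100.0 * ident, 2))
    errors.sort(key=lambda e: e.msa_columns)
    return errors


def _cum_positions(events, field: int) -> list[int]:
    """Residue index (in row if field==3, reference if field==2) attained
    before each event, plus one trailing entry."""
    out = [0]
    for _c, _k, rc, xc in events:
        ch = (rc, xc)[field - 2]
        out.append(out[-1] + (ch != "-"))
    return out


def _mismatch_windows(match: list, min_len: int, max_ident: float):
    """Low-identity segments over a region of alignment columns.

    ``match`` holds True/False for aligned columns (identical pair or
    not) and None for gap columns.  Aligned columns are scored ``+t``
    for a non-identical pair and ``-(1 - t)`` for an identical pair
    (``t`` = identity threshold), gap columns score zero; a segment's
    aligned-column identity is strictly below ``t`` exactly when its
    score is positive.  The region is decomposed into disjoint
    maximal-scoring segments (recursive best-segment splitting,
    deterministic), and those with at least ``min_len`` aligned columns
    are reported.  Segments start and end on non-identical aligned
    columns, staying tightly localized on the offending region instead
    of soaking up well-conserved flanks.  Yields
    (start, end, aligned-column identity), non-overlapping, left to
    right.
    """
    t = max_ident
    score = [0.0 if m is None else (t if not m else -(1.0 - t)) for m in match]
    pref_m = [0]  # identical aligned columns
    pref_a = [0]  # aligned columns
    for m in match:
        pref_m.append(pref_m[-1] + (m is True))
        pref_a.append(pref_a[-1] + (m is not None))
    out = []
    _best_segments(score, 0, len(score), out)
    for lo, hi in sorted(out):
        aligned = pref_a[hi] - pref_a[lo]
        if aligned >= min_len:
            yield lo, hi, (pref_m[hi] - pref_m[lo]) / aligned


def _best_segments(score, lo, hi, out, eps=1e-9):
    """Disjoint maximal positive-score segments of score[lo:hi]."""
    if hi - lo <= 0:
        return
    best, best_lo, best_hi = 0.0, -1, -1
    run, run_lo = 0.0, lo
    for i in range(lo, hi):
        if run < -eps:
            run, run_lo = 0.0, i
        run += score[i]
        # strict improvement moves the segment; an exact tie with the
        # same start extends it (leftmost-longest maximal segment), so a
        # region at exactly threshold identity around a scoring core is
        # still reported in full
        if run > best + eps or (run > best - eps and run_lo == best_lo):
            best, best_lo, best_hi = run, run_lo, i + 1
    if best_lo < 0 or best <= eps:
        return
    # trim leading non-positive prefix (start on a scoring column)
    while best_lo < best_hi and score[best_lo] <= 0:
        best_lo += 1
    out.append((best_lo, best_hi))
    _best_segments(score, lo, best_lo, out, eps)
    _best_segments(score, best_hi, hi, out, eps)


def error_census(
    errors: list[SequenceError],
    species_of: dict[str, str],
    orthologs_per_species: dict[str, int],
) -> pd.DataFrame:
    """Counts per species x category, with totals and per-sequence error
    rates (total errors divided by the number of orthologs)."""
    counts: Counter = Counter()
    for e in errors:
        counts[(species_of.get(e.sequence_id, "?"), e.category)] += 1
    species = sorted(orthologs_per_species)
    data = {
        cat: [counts[(sp, cat)] for sp in species] for cat in CATEGORIES
    }
    df = pd.DataFrame(data, index=species)
    df["total_errors"] = df[list(CATEGORIES)].sum(axis=1)
    df["n_orthologs"] = [orthologs_per_species[sp] for sp in species]
    df["errors_per_sequence"] = (
        df["total_errors"] / df["n_orthologs"].where(df["n_orthologs"] > 0)
    ).fillna(0.0)
    return df
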