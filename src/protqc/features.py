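"""Characterization of mismatched segments with nine genomic features and
classification of their probable cause.

Each detected mismatch is examined for nine features falling in three
evidence classes:

* gene-misprediction evidence: undetermined ('N') nucleotides in the
  gene's genomic span; introns shorter than 30 nt; one reference exon
  facing three or more target exons; non-canonical splice sites in the
  reference gene; a frameshifting indel in the target exon;
* false-positive evidence (the mismatch call itself is suspect): an
  alternative reference isoform matching the segment; the mismatch
  dissolving under pairwise realignment (an alignment artifact); the
  segment lying in a tandem-repeat region;
* undetermined: the same mismatch recurring in four or more species.

A mismatch with misprediction evidence only is classified
``GENE_PREDICTION_ERROR``; false-positive evidence only gives
``FALSE_POSITIVE``; both kinds (or only the recurrence feature) give
``UNCONFIRMED``; no feature at all gives ``UNEXPLAINED``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .error_detect import ReferenceAnchoredMSA, SequenceError
from .io_formats import (
    ExonInterval,
    GeneModel,
    ProteinGenomeMap,
    SequenceRecord,
    extract_cds,
)
from .orthology import ScoringScheme, _make_aligner, alignment_identity, local_align

MISPREDICTION_FEATURES = (
    "N_CHARS",
    "SHORT_INTRON",
    "EXON_SPLIT_1_TO_3",
    "NONCANONICAL_SPLICE_REF",
    "FRAMESHIFT_EXON",
)
FALSE_POSITIVE_FEATURES = ("ALT_ISOFORM_MATCH", "MSA_ERROR", "REPEAT_REGION")
UNDETERMINED_FEATURES = ("CONSERVED_4PLUS",)
ALL_FEATURES = MISPREDICTION_FEATURES + FALSE_POSITIVE_FEATURES + UNDETERMINED_FEATURES

EVIDENCE_CLASS = {
    **{f: "MISPREDICTION" for f in MISPREDICTION_FEATURES},
    **{f: "FALSE_POSITIVE" for f in FALSE_POSITIVE_FEATURES},
    **{f: "UNDETERMINED" for f in UNDETERMINED_FEATURES},
}

CLASSIFICATIONS = (
    "GENE_PREDICTION_ERROR",
    "FALSE_POSITIVE",
    "UNCONFIRMED",
    "UNEXPLAINED",
)


@dataclass(frozen=True)
class FeatureFlag:
    feature: str
    evidence_class: str = ""
    details: str = ""

    def __post_init__(self):
        if self.feature not in EVIDENCE_CLASS:
            raise ValueError(f"unknown feature {self.feature!r}")
        object.__setattr__(self, "evidence_class", EVIDENCE_CLASS[self.feature])


@dataclass
class MismatchReport:
    error: SequenceError
    gene_model: GeneModel | None
    flags: frozenset[FeatureFlag]
    classification: str
    skipped_features: tuple[str, ...] = ()  # unevaluable, not negative

    @property
    def flag_names(self) -> frozenset[str]:
        return frozenset(f.feature for f in self.flags)


def classify_mismatch(flags) -> str:
    """Map a set of feature flags (or names) to one of the four causes."""
    names = {f.feature if isinstance(f, FeatureFlag) else f for f in flags}
    unknown = names - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    mis = names & set(MISPREDICTION_FEATURES)
    fp = names & set(FALSE_POSITIVE_FEATURES)
    if mis and not fp:
        return "GENE_PREDICTION_ERROR"
    if fp and not mis:
        return "FALSE_POSITIVE"
    if mis and fp:
        return "UNCONFIRMED"
    if names:  # only the recurrence feature
        return "UNCONFIRMED"
    return "UNEXPLAINED"


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------

def flag_n_chars(model: GeneModel, contig: SequenceRecord) -> FeatureFlag | None:
    """Undetermined nucleotides anywhere in the transcript's genomic span
    (introns included): evidence of a sequencing gap or assembly problem,
    which need not sit inside the mismatched exon itself."""
    if contig is None:
        raise ValueError(f"contig {model.contig_id!r} missing")
    span = model.span
    region = contig.seq[span.start : span.end]
    pos = region.find("N")
    if pos < 0:
        return None
    end = pos
    while end < len(region) and region[end] == "N":
        end += 1
    return FeatureFlag(
        "N_CHARS", details=f"N run at {span.start + pos}-{span.start + end}"
    )


def flag_short_intron(model: GeneModel, min_len: int = 30) -> FeatureFlag | None:
    """Any intron shorter than the minimum length a spliceosome can
    process (30 nt in human)."""
    short = [len(i) for i in model.introns if len(i) < min_len]
    if not short:
        return None
    return FeatureFlag("SHORT_INTRON", details=f"intron lengths {short}")


def _overlapping_exons(
    model: GeneModel, intervals: list[ExonInterval], min_overlap: int = 1
) -> list[ExonInterval]:
    return [e for e in model.exons if _overlap_len(e, intervals) >= min_overlap]


def flag_exon_split(
    error: SequenceError,
    target_model: GeneModel,
    ref_model: GeneModel,
    target_map: ProteinGenomeMap,
    ref_map: ProteinGenomeMap,
    exon_split_min: int = 3,
) -> FeatureFlag | None:
    """A single reference exon facing ``exon_split_min`` or more target
    exons over the mismatched segment: typical of an exon fragmented by
    the predictor."""
    t_iv = target_map.protein_interval_to_genomic(*error.seq_positions)
    r_iv = ref_map.protein_interval_to_genomic(*error.ref_positions)
    # exons touched only by a junction-straddling codon (a few nt) do not
    # count as facing the segment
    n_t = len(_overlapping_exons(target_model, t_iv, min_overlap=6))
    r_ex = _overlapping_exons(ref_model, r_iv, min_overlap=6)
    if len(r_ex) == 1 and n_t >= exon_split_min:
        return FeatureFlag(
            "EXON_SPLIT_1_TO_3", details=f"ref exons 1, target exons {n_t}"
        )
    # The segment's span can be displaced by up to the aligned gap length
    # (gap placement inside a non-homologous segment is arbitrary),
    # dragging a neighboring reference exon into the span or restricting
    # the segment to one fragment of a split exon.  Fall back to the
    # dominant reference exon: if a single exon covers the majority of
    # the span, test whether its own coding region faces
    # >= exon_split_min target exons.
    if r_ex:
        total = sum(_overlap_len(e, r_iv) for e in r_ex)
        best = max(r_ex, key=lambda e: _overlap_len(e, r_iv))
        if _overlap_len(best, r_iv) > 0.5 * total:
            aa = _exon_codon_span(ref_model, ref_map, best)
            if aa is not None:
                offset = error.ref_positions[0] - error.seq_positions[0]
                t_lo = max(0, aa[0] - offset)
                t_hi = min(target_map.protein_length, aa[1] - offset)
                if t_hi - t_lo >= 2:
                    t_ivd = target_map.protein_interval_to_genomic(t_lo, t_hi)
                    n_td = len(
                        _overlapping_exons(target_model, t_ivd, min_overlap=6)
                    )
                    if n_td >= exon_split_min:
                        return FeatureFlag(
                            "EXON_SPLIT_1_TO_3",
                            details=f"ref exons 1 (dominant), target exons {n_td}",
                        )
    return None


def _overlap_len(exon: ExonInterval, intervals: list[ExonInterval]) -> int:
    return sum(
        max(0, min(exon.end, iv.end) - max(exon.start, iv.start)) for iv in intervals
    )


def flag_noncanonical_splice_ref(
    error: SequenceError,
    ref_model: GeneModel,
    ref_contig: SequenceRecord,
    ref_map: ProteinGenomeMap,
) -> FeatureFlag | None:
    """Non-GT/AG splice sites on reference introns adjacent to the exons
    coding the mismatch-corresponding reference segment."""
    if error.ref_positions[0] >= error.ref_positions[1]:
        return None
    r_iv = ref_map.protein_interval_to_genomic(*error.ref_positions)
    exons = _overlapping_exons(ref_model, r_iv)
    idx = [i for i, e in enumerate(ref_model.exons) if e in exons]
    introns = ref_model.introns
    bad = []
    for i in idx:
        for j in (i - 1, i):
            if 0 <= j < len(introns):
                seq = _oriented(ref_contig, introns[j], ref_model.strand)
                if not (seq.startswith("GT") and seq.endswith("AG")):
                    bad.append(f"{seq[:2]}..{seq[-2:]}")
    if bad:
        return FeatureFlag("NONCANONICAL_SPLICE_REF", details=";".join(bad))
    return None


def _oriented(contig: SequenceRecord, iv: ExonInterval, strand: str) -> str:
    from Bio.Seq import reverse_complement

    seq = contig.seq[iv.start : iv.end].upper()
    return reverse_complement(seq) if strand == "-" else seq


def flag_frameshift_exon(
    error: SequenceError,
    target_model: GeneModel,
    ref_model: GeneModel,
    target_map: ProteinGenomeMap,
    ref_map: ProteinGenomeMap,
) -> tuple[FeatureFlag | None, bool]:
    """A target exon whose length differs from its reference counterpart
    by a non-multiple of 3 - the net indel of a nucleotide-level global
    alignment equals that length difference, and shifts the frame.

    Returns (flag, evaluated); ``evaluated`` is False when no one-to-one
    exon correspondence could be resolved.
    """
    offset = error.ref_positions[0] - error.seq_positions[0]
    t_iv = target_map.protein_interval_to_genomic(*error.seq_positions)
    evaluated = False
    for e in _overlapping_exons(target_model, t_iv):
        aa = _exon_codon_span(target_model, target_map, e)
        if aa is None:
            continue
        r_lo = max(0, aa[0] + offset)
        r_hi = min(ref_map.protein_length, aa[1] + offset)
        if r_hi - r_lo < 2:
            continue
        r_iv = ref_map.protein_interval_to_genomic(r_lo, r_hi)
        ref_exons = _overlapping_exons(ref_model, r_iv)
        if not ref_exons:
            continue
        # dominant counterpart: junction-straddling codons routinely drag
        # in a neighboring exon with a few-nucleotide overlap
        best = max(ref_exons, key=lambda x: _overlap_len(x, r_iv))
        if _overlap_len(best, r_iv) < 6:
            continue
        evaluated = True
        diff = len(e) - len(best)
        if diff % 3 != 0:
            return (
                FeatureFlag(
                    "FRAMESHIFT_EXON",
                    details=f"exon {e.start}-{e.end} net indel {diff:+d} nt",
                ),
                True,
            )
    return None, evaluated


def _exon_codon_span(model, pmap, exon) -> tuple[int, int] | None:
    """Protein positions whose codons overlap this exon."""
    hits = [
        i
        for i in range(pmap.protein_length)
        if any(exon.start <= p < exon.end for p in pmap.codon_positions(i))
    ]
    if not hits:
        return None
    return hits[0], hits[-1] + 1


def flag_alt_isoform(
    segment: str,
    isoforms: list[SequenceRecord],
    identity_min: float = 50.0,
    coverage_min: float = 0.8,
    scheme: ScoringScheme = ScoringScheme(),
) -> FeatureFlag | None:
    """The segment matches an alternative reference isoform well enough
    that it would not have been called a mismatch against that isoform."""
    if not isoforms:
        return None
    for iso in isoforms:
        hit = local_align(segment, iso, scheme)
        cov = (hit.query_span[1] - hit.query_span[0]) / len(segment)
        if hit.identity_pct >= identity_min and cov >= coverage_min:
            return FeatureFlag(
                "ALT_ISOFORM_MATCH",
                details=f"{iso.id} identity {hit.identity_pct:.1f}%",
            )
    return None


def flag_msa_error(
    error: SequenceError,
    target: SequenceRecord,
    reference: SequenceRecord,
    identity_min: float = 50.0,
    scheme: ScoringScheme | None = None,
) -> FeatureFlag | None:
    """The mismatch dissolves when the two full-length proteins are
    realigned pairwise: the original call was an alignment artifact.

    The realignment uses the same stiff-gap scheme as MSA construction;
    a cheaper gap scheme would gap out genuinely misaligned residues and
    dissolve real mismatches.
    """
    from .error_detect import MSA_SCHEME

    al = _make_aligner(scheme or MSA_SCHEME, "global", free_ends=True)
    aln = al.align(reference.seq.replace("*", "X"), target.seq.replace("*", "X"))[0]
    gr, gt = str(aln[0]), str(aln[1])
    lo, hi = error.seq_positions
    tpos = -1
    pairs = []
    for a, b in zip(gr, gt):
        if b != "-":
            tpos += 1
            if lo <= tpos < hi and a != "-":
                pairs.append((a, b))
    if not pairs:
        return None
    ident = 100.0 * sum(1 for a, b in pairs if a == b and a != "X") / len(pairs)
    if ident >= identity_min:
        return FeatureFlag("MSA_ERROR", details=f"realigned identity {ident:.1f}%")
    return None


def tandem_repeat_coverage(segment: str, max_period: int = 6) -> float:
    """Fraction of positions covered by an exact tandem repeat of period
    at most ``max_period`` (at least two full copies), by autocorrelation
    scan."""
    n = len(segment)
    covered = [False] * n
    for p in range(1, max_period + 1):
        i = 0
        while i + p < n:
            if segment[i] == segment[i + p]:
                j = i
                while j + p < n and segment[j] == segment[j + p]:
                    j += 1
                run = j - i  # matched pairs; repeat spans i .. j+p
                if run >= p:
                    for k in range(i, j + p):
                        covered[k] = True
                i = j + 1
            else:
                i += 1
    return sum(covered) / n if n else 0.0


def flag_repeat_region(
    segment: str, max_period: int = 6, coverage_min: float = 0.5
) -> FeatureFlag | None:
    """At least half the segment lies in tandem repeats of short period:
    repeats both misalign easily and confuse predictors, so a mismatch
    here is unreliable."""
    if len(segment) < 20:
        raise ValueError("repeat scan requires a segment of >= 20 residues")
    cov = tandem_repeat_coverage(segment, max_period)
    if cov >= coverage_min:
        return FeatureFlag("REPEAT_REGION", details=f"repeat coverage {cov:.2f}")
    return None


def flag_conserved_4plus(
    error: SequenceError,
    all_mismatches: list[SequenceError],
    min_species: int = 4,
    overlap_min: float = 0.5,
) -> FeatureFlag | None:
    """The same mismatch (reciprocal column overlap of at least 50%)
    occurs in ``min_species`` or more rows of the alignment - either a
    propagated misprediction or a reference-specific region."""
    lo, hi = error.msa_columns
    by_row: dict[str, list[SequenceError]] = {}
    for m in all_mismatches:
        if m.category == "MISMATCH":
            by_row.setdefault(m.sequence_id, []).append(m)
    carriers = set()
    for sid, row_mismatches in by_row.items():
        # a row's mismatch may be fragmented; pool its overlapping pieces
        ov = other = 0
        for m in row_mismatches:
            a, b = m.msa_columns
            o = max(0, min(hi, b) - max(lo, a))
            if o > 0:
                ov += o
                other += b - a
        if other and ov / (hi - lo) >= overlap_min and ov / other >= overlap_min:
            carriers.add(sid)
    if len(carriers) >= min_species:
        return FeatureFlag(
            "CONSERVED_4PLUS", details=f"shared by {len(carriers)} sequences"
        )
    return None


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class CharacterizationData:
    """Everything the feature battery needs, keyed by protein id."""

    proteins: dict[str, SequenceRecord]
    models: dict[str, GeneModel]          # protein id -> gene model
    contigs: dict[str, SequenceRecord]    # contig id -> contig
    reference_of: dict[str, str]          # target protein id -> reference id
    alt_isoforms: list[SequenceRecord] = field(default_factory=list)

    def model(self, protein_id: str) -> GeneModel | None:
        return self.models.get(protein_id)

    def contig_for(self, model: GeneModel | None) -> SequenceRecord | None:
        return self.contigs.get(model.contig_id) if model else None


def characterize_mismatch(
    error: SequenceError,
    all_mismatches: list[SequenceError],
    data: CharacterizationData,
    intron_min_len: int = 30,
    exon_split_min: int = 3,
    conserved_min_species: int = 4,
    scheme: ScoringScheme = ScoringScheme(),
) -> MismatchReport:
    """Run the nine-feature battery on one mismatch and classify it.

    Features needing genomic data that is absent are recorded as skipped
    (unevaluated), not as negative.
    """
    if error.category != "MISMATCH":
        raise ValueError("characterization applies to MISMATCH errors only")
    tid = error.sequence_id
    target = data.proteins[tid]
    ref_id = data.reference_of[tid]
    reference = data.proteins[ref_id]
    t_model = data.model(tid)
    r_model = data.model(ref_id)
    t_contig = data.contig_for(t_model)
    r_contig = data.contig_for(r_model)
    flags: set[FeatureFlag] = set()
    skipped: list[str] = []

    if t_model is not None and t_contig is not None:
        f = flag_n_chars(t_model, t_contig)
        if f:
            flags.add(f)
        f = flag_short_intron(t_model, intron_min_len)
        if f:
            flags.add(f)
    else:
        skipped += ["N_CHARS", "SHORT_INTRON"]

    if t_model is not None and r_model is not None:
        t_map = ProteinGenomeMap(t_model)
        r_map = ProteinGenomeMap(r_model)
        if error.ref_positions[1] > error.ref_positions[0]:
            f = flag_exon_split(error, t_model, r_model, t_map, r_map, exon_split_min)
            if f:
                flags.add(f)
            fs, evaluated = flag_frameshift_exon(error, t_model, r_model, t_map, r_map)
            if fs:
                flags.add(fs)
            elif not evaluated:
                skipped.append("FRAMESHIFT_EXON")
        if r_contig is not None and error.ref_positions[1] > error.ref_positions[0]:
            f = flag_noncanonical_splice_ref(error, r_model, r_contig, r_map)
            if f:
                flags.add(f)
        elif r_contig is None:
            skipped.append("NONCANONICAL_SPLICE_REF")
    else:
        skipped += ["EXON_SPLIT_1_TO_3", "NONCANONICAL_SPLICE_REF", "FRAMESHIFT_EXON"]

    segment = target.seq[error.seq_positions[0] : error.seq_positions[1]]
    f = flag_alt_isoform(segment, data.alt_isoforms, scheme=scheme)
    if f:
        flags.add(f)
    f = flag_msa_error(error, target, reference)
    if f:
        flags.add(f)
    if len(segment) >= 20:
        f = flag_repeat_region(segment)
        if f:
            flags.add(f)
    f = flag_conserved_4plus(error, all_mismatches, conserved_min_species)
    if f:
        flags.add(f)

    return MismatchReport(
        error=error,
        gene_model=t_model,
        flags=frozenset(flags),
        classification=classify_mismatch(flags),
        skipped_features=tuple(skipped),
    )
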