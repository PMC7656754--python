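"""Correction of mispredicted segments by translated genomic search and
transcript surgery.

For a mismatch attributed to gene misprediction, the reference segment
corresponding to the mismatch is searched (six-frame, translated, exact
local alignment per ORF fragment) against the genomic region of the
target transcript.  A hit passing the thresholds (default E < 1e-3,
identity > 80%) replaces the exons coding the mismatch: the hit's span is
snapped to the transcript's codon phase, inserted as a single new exon,
the transcript is integrity-checked (overlapping/inverted exons,
frameshift, internal stop), and a new CDS and protein are built.  If the
original start codon is lost, the first in-frame start codon is used
instead and flagged.  Quality is scored before and after as percent
identity I = i/N x 100 and coverage C = N/N_tot x 100 on a global
alignment with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from .error_detect import (
    DetectionConfig,
    SequenceError,
    build_msa,
    detect_errors,
)
from .features import MismatchReport
from .io_formats import (
    STANDARD_TABLE,
    CodonTable,
    ExonInterval,
    GeneModel,
    ProteinGenomeMap,
    SequenceRecord,
    _protein_record,
    extract_cds,
    translate_cds,
)
from .orthology import ScoringScheme, _make_aligner, estimate_evalue, local_align

REFUSAL_STATUSES = (
    "not_gene_prediction_error",
    "no_hit",
    "integrity_failure",
    "no_start_codon",
)
INTEGRITY_STATUSES = (
    "ok", "overlapping_exons", "inverted_exons", "frameshift", "internal_stop",
)


@dataclass
class TranslatedHit:
    """A local alignment between a protein query and one translated frame
    of a genomic region."""

    frame: int                      # +1,+2,+3 forward; -1,-2,-3 reverse
    genomic_span: ExonInterval      # on the contig, codon-trimmed
    query_span: tuple[int, int]
    identity_pct: float
    evalue: float
    raw_score: float
    subject_aa: str = ""
    query_len: int = 0


@dataclass
class QualityScores:
    """I = i/N x 100 (identity over aligned residue pairs) and
    C = N/N_tot x 100 (aligned pairs over total alignment columns)."""

    identity_I: float
    coverage_C: float


@dataclass
class CorrectionResult:
    status: str                     # "corrected" or a refusal status
    original_protein: SequenceRecord
    refined_protein: SequenceRecord | None = None
    original_model: GeneModel | None = None
    refined_model: GeneModel | None = None
    inserted_exon: ExonInterval | None = None
    frame: int = 0
    integrity: str = "ok"
    scores_before: QualityScores | None = None
    scores_after: QualityScores | None = None
    errors_before: dict[str, int] = field(default_factory=dict)
    errors_after: dict[str, int] = field(default_factory=dict)
    start_codon_fallback_used: bool = False


def translated_search(
    query_segment: str | SequenceRecord,
    region: str,
    region_offset: int = 0,
    scheme: ScoringScheme = ScoringScheme(),
    evalue_max: float = 1e-3,
    identity_min: float = 80.0,
) -> list[TranslatedHit]:
    """Six-frame translated search of a protein segment in a genomic
    region.  Stop codons break each frame into ORF fragments; each
    fragment is aligned locally to the query.  Hits passing both
    thresholds are returned sorted by raw score (descending), with
    genomic coordinates mapped back strand-aware."""
    qseq = query_segment.seq if isinstance(query_segment, SequenceRecord) else query_segment
    region = region.upper()
    L = len(region)
    if L < 3 or not qseq:
        raise ValueError("region must be >= 3 nt and query non-empty")
    frames: list[tuple[int, str]] = []
    rc = reverse_complement(region)
    for f in range(3):
        frames.append((f + 1, _translate_frame(region, f)))
        frames.append((-(f + 1), _translate_frame(rc, f)))
    db_residues = sum(len(t) for _f, t in frames)
    hits: list[TranslatedHit] = []
    for frame, trans in frames:
        off = 0
        for frag in trans.split("*"):
            if len(frag) * 3 >= 9:  # ignore sub-codon noise fragments
                hit = _align_fragment(
                    qseq, frag, off, frame, L, region_offset, scheme, db_residues,
                )
                if hit and hit.evalue < evalue_max and hit.identity_pct > identity_min:
                    hits.append(hit)
            off += len(frag) + 1
    hits.sort(key=lambda h: (-h.raw_score, h.frame, h.genomic_span.start))
    return hits


def _translate_frame(seq: str, f: int) -> str:
    n = len(seq) - f
    n -= n % 3
    return "".join(
        STANDARD_TABLE.translate_codon(seq[i : i + 3]) for i in range(f, f + n, 3)
    )


def _align_fragment(qseq, frag, frag_off, frame, L, region_offset, scheme, db_residues):
    aln = local_align(qseq, frag, scheme)
    if aln.raw_score <= 0:
        return None
    a0, a1 = aln.subject_span  # residues within the fragment
    f = abs(frame) - 1
    g0 = f + 3 * (frag_off + a0)
    g1 = f + 3 * (frag_off + a1)
    if frame > 0:
        span = ExonInterval(region_offset + g0, region_offset + g1)
    else:
        span = ExonInterval(region_offset + L - g1, region_offset + L - g0)
    return TranslatedHit(
        frame=frame,
        genomic_span=span,
        query_span=aln.query_span,
        identity_pct=aln.identity_pct,
        evalue=estimate_evalue(aln.raw_score, len(qseq), db_residues, scheme),
        raw_score=aln.raw_score,
        subject_aa=aln.aligned_subject.replace("-", ""),
        query_len=len(qseq),
    )


def verify_transcript(model: GeneModel, contig: SequenceRecord,
                      table: CodonTable = STANDARD_TABLE) -> str:
    """First integrity failure among overlapping exons, inverted exon
    order, frameshift (CDS length not a codon multiple) and internal stop
    codons; 'ok' otherwise."""
    exons = model.exons
    srt = sorted(exons)
    for a, b in zip(srt, srt[1:]):
        if a.overlaps(b):
            return "overlapping_exons"
    genomic_sorted = srt if model.strand == "+" else srt[::-1]
    if list(exons) != genomic_sorted:
        return "inverted_exons"
    if model.cds_length % 3 != 0:
        return "frameshift"
    prot = translate_cds(extract_cds(model, contig), table).protein.seq
    if "*" in prot[:-1]:
        return "internal_stop"
    return "ok"


def rebuild_protein(
    model: GeneModel, contig: SequenceRecord, table: CodonTable = STANDARD_TABLE
) -> tuple[SequenceRecord | None, bool]:
    """New CDS and protein from a (refined) gene model.  If the CDS does
    not begin with a start codon, scan frame 0 for the first one and
    translate from there (fallback flagged).  Returns (protein, fallback);
    (None, True) when no in-frame start codon exists."""
    cds = extract_cds(model, contig).seq
    fallback = False
    start = 0
    if cds[:3] not in table.start_codons:
        fallback = True
        start = next(
            (i for i in range(3, len(cds) - 2, 3) if cds[i : i + 3] in table.start_codons),
            -1,
        )
        if start < 0:
            return None, True
    tr = translate_cds(
        SequenceRecord(id=model.protein_id or model.transcript_id,
                       seq=cds[start:], moltype="nucleotide"),
        table,
    )
    return _protein_record(model.protein_id or model.transcript_id,
                           tr.protein.seq.rstrip("*")), fallback


def score_alignment(
    reference: SequenceRecord, target: SequenceRecord,
    scheme: ScoringScheme = ScoringScheme(),
) -> QualityScores:
    """Global pairwise alignment quality: I and C as defined above.  Both
    statistics are symmetric by definition; the pair is aligned in a
    canonical order so that co-optimal traceback choices cannot make the
    result depend on argument order."""
    if not reference.seq or not target.seq:
        raise ValueError("sequences must be non-empty")
    a, b = sorted([reference.seq.replace("*", "X"), target.seq.replace("*", "X")])
    al = _make_aligner(scheme, "global", free_ends=True)
    aln = al.align(a, b)[0]
    return quality_from_rows(str(aln[0]), str(aln[1]))


def quality_from_rows(row_a: str, row_b: str) -> QualityScores:
    """I and C computed directly from two gapped alignment rows."""
    n_tot = len(row_a)
    pairs = [(a, b) for a, b in zip(row_a, row_b) if a != "-" and b != "-"]
    n = len(pairs)
    i = sum(1 for a, b in pairs if a == b and a != "X")
    return QualityScores(
        identity_I=100.0 * i / n if n else 0.0,
        coverage_C=100.0 * n / n_tot if n_tot else 0.0,
    )


def splice_in_exon(
    model: GeneModel,
    removed: list[ExonInterval],
    hit: TranslatedHit,
    contig_length: int,
) -> tuple[GeneModel | None, ExonInterval | None, str]:
    """Replace the removed exons with the hit's genomic span as one new
    exon, snapped to the transcript's codon phase.

    The 5' edge of the new exon is extended (at most 2 nt) so that the
    hit's codons land on the running reading frame, and the 3' edge is
    extended so that the new exon length is congruent mod 3 with the
    removed length, keeping downstream exons in their original frame.
    Returns (refined model or None, inserted exon, integrity status).
    """
    if (hit.frame > 0) != (model.strand == "+"):
        return None, None, "inverted_exons"
    kept = [e for e in model.exons if e not in removed]
    if not kept:
        return None, None, "overlapping_exons"
    first_removed = min(
        i for i, e in enumerate(model.exons) if e in removed
    )
    ins_at = sum(1 for i in range(first_removed) if model.exons[i] in kept)
    pre_len = sum(len(e) for e in kept[:ins_at])
    removed_len = sum(len(e) for e in removed)
    # extend the HSP to cover the whole query segment: the flanking query
    # residues continue colinearly in the genome, and local alignment may
    # have shaved a few diverged residues off the segment's edges
    q0, q1 = hit.query_span
    head, tail = 3 * q0, 3 * max(0, hit.query_len - q1)
    h = hit.genomic_span
    if model.strand == "+":
        h0, h1 = h.start - head, h.end + tail
        d5 = (-pre_len) % 3
        start = h0 - d5
        d3 = (removed_len - (h1 - start)) % 3
        end = h1 + d3
        if start < 0 or end > contig_length:
            return None, None, "overlapping_exons"
        new_exon = ExonInterval(start, end)
    else:
        h0, h1 = h.start - tail, h.end + head
        d5 = (-pre_len) % 3
        end = h1 + d5
        d3 = (removed_len - (end - h0)) % 3
        start = h0 - d3
        if start < 0 or end > contig_length:
            return None, None, "overlapping_exons"
        new_exon = ExonInterval(start, end)
    if any(new_exon.overlaps(e) for e in kept):
        return None, None, "overlapping_exons"
    exons = kept[:ins_at] + [new_exon] + kept[ins_at:]
    try:
        refined = GeneModel(
            gene_id=model.gene_id,
            transcript_id=model.transcript_id,
            contig_id=model.contig_id,
            strand=model.strand,
            exons=exons,
            protein_id=model.protein_id,
        )
    except ValueError:
        return None, None, "inverted_exons"
    return refined, new_exon, "ok"


def _adjust_exon(model: GeneModel, exon: ExonInterval, d5: int, d3: int,
                 contig_length: int):
    """In-frame (multiple-of-3) boundary variant of one exon of a model;
    None if the variant is geometrically invalid."""
    if model.strand == "+":
        start, end = exon.start + d5, exon.end + d3
    else:
        start, end = exon.start - d3, exon.end - d5
    if start < 0 or end > contig_length or end - start < 3:
        return None
    new = ExonInterval(start, end)
    if any(new.overlaps(e) for e in model.exons if e != exon):
        return None
    exons = [new if e == exon else e for e in model.exons]
    try:
        return (
            GeneModel(
                gene_id=model.gene_id,
                transcript_id=model.transcript_id,
                contig_id=model.contig_id,
                strand=model.strand,
                exons=exons,
                protein_id=model.protein_id,
            ),
            new,
        )
    except ValueError:
        return None


def count_errors_by_category(errors: list[SequenceError]) -> dict[str, int]:
    out: dict[str, int] = {}
    for e in errors:
        out[e.category] = out.get(e.category, 0) + 1
    return out


def correct_mismatch(
    report: MismatchReport,
    target_model: GeneModel,
    target_contig: SequenceRecord,
    reference: SequenceRecord,
    original_protein: SequenceRecord,
    scheme: ScoringScheme = ScoringScheme(),
    detection: DetectionConfig = DetectionConfig(),
    evalue_max: float = 1e-3,
    identity_min: float = 80.0,
    region_margin: int = 500,
    require_gene_prediction_error: bool = True,
) -> CorrectionResult:
    """Full correction pipeline for one mismatch report.

    ``require_gene_prediction_error`` enforces the production rule that
    only mismatches classified as gene-prediction errors are touched;
    controlled experiments on labeled data may disable it.
    """
    base = CorrectionResult(
        status="corrected",
        original_protein=original_protein,
        original_model=target_model,
    )
    if require_gene_prediction_error and report.classification != "GENE_PREDICTION_ERROR":
        base.status = "not_gene_prediction_error"
        return base
    error = report.error
    pmap = ProteinGenomeMap(target_model)
    lo, hi = error.seq_positions
    hi = min(hi, pmap.protein_length)
    if hi - lo < 1:
        base.status = "no_hit"
        return base
    coding = pmap.protein_interval_to_genomic(lo, hi)
    # an exon counts as coding the mismatch only with at least one full
    # codon of overlap; junction-straddling codons contribute 1-2 nt to a
    # neighboring exon that is otherwise sound
    def _ov(e):
        return sum(
            max(0, min(e.end, iv.end) - max(e.start, iv.start)) for iv in coding
        )

    removed = [e for e in target_model.exons if _ov(e) >= 3]
    if not removed:
        removed = [e for e in target_model.exons if _ov(e) > 0]
    rlo, rhi = error.ref_positions
    segment = reference.seq[rlo:rhi]
    if not removed or not segment:
        base.status = "no_hit"
        return base
    span = target_model.span
    r0 = max(0, span.start - region_margin)
    r1 = min(len(target_contig.seq), span.end + region_margin)
    hits = translated_search(
        segment, target_contig.seq[r0:r1], region_offset=r0,
        scheme=scheme, evalue_max=evalue_max, identity_min=identity_min,
    )
    if not hits:
        base.status = "no_hit"
        return base
    hit = hits[0]
    base.frame = hit.frame
    refined, new_exon, integrity = splice_in_exon(
        target_model, removed, hit, len(target_contig.seq)
    )
    if refined is None:
        base.status = "integrity_failure"
        base.integrity = integrity
        return base
    # Boundary refinement: the exact exon ends are ambiguous by about one
    # codon on each side (junction-straddling codons are invisible to a
    # translated search), so in-frame boundary variants are tried and the
    # variant whose rebuilt protein best matches the reference is kept.
    best = None
    for d5 in (0, -3, 3, -6, 6):
        for d3 in (0, -3, 3, -6, 6):
            cand = _adjust_exon(refined, new_exon, d5, d3, len(target_contig.seq))
            if cand is None:
                continue
            cand_model, cand_exon = cand
            status = verify_transcript(cand_model, target_contig)
            if d5 == 0 and d3 == 0:
                base.integrity = status
            if status != "ok":
                continue
            protein, fallback = rebuild_protein(cand_model, target_contig)
            if protein is None:
                continue
            q = score_alignment(reference, protein, scheme)
            key = (q.identity_I, q.coverage_C, -(abs(d5) + abs(d3)))
            if best is None or key > best[0]:
                best = (key, cand_model, cand_exon, protein, fallback, q)
    if best is None:
        base.status = (
            "no_start_codon" if base.integrity == "ok" else "integrity_failure"
        )
        return base
    _key, refined, new_exon, protein, fallback, q_after = best
    base.inserted_exon = new_exon
    base.integrity = "ok"
    base.start_codon_fallback_used = fallback
    base.refined_model = refined
    base.refined_protein = protein
    base.scores_before = score_alignment(reference, original_protein, scheme)
    base.scores_after = score_alignment(reference, protein, scheme)
    base.errors_before = count_errors_by_category(
        detect_errors(build_msa(reference, [original_protein]), detection)
    )
    base.errors_after = count_errors_by_category(
        detect_errors(build_msa(reference, [protein]), detection)
    )
    return base
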