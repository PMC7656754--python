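"""Synthetic genome/proteome generator with injected gene-prediction errors.

The generator emulates the study design used to audit primate proteome
quality against a human reference: a set of multi-exon protein-coding
genes with canonical GT/AG introns is generated for a reference species,
orthologs are derived for several target species by codon-level
divergence (synonymous-biased, giving 80-99% protein identity), and a
configurable fraction of target genes receives one injected error
scenario.  Every emitted (gene model, contig, protein) triple is exactly
self-consistent: the protein is the literal translation of the spliced
CDS, including for corrupted predictions.

Scenarios and the genomic evidence they plant:

* ``WRONG_FRAME_EXON`` - one internal exon's boundaries shifted by 1-2 nt
  so the exon is translated in the wrong frame (the canonical mismatch
  generator); the true exon survives in the contig.
* ``N_RUN`` - a run of undetermined nucleotides in an intron of the gene,
  plus a wrong-frame exon to emulate the misprediction it causes.
* ``SHORT_INTRON`` - the wrong-frame exon is additionally split by a
  spurious intron shorter than 30 nt.
* ``EXON_SPLIT`` - the wrong-frame exon is split into three exons where
  the reference has one.
* ``NONCANONICAL_SPLICE_REF`` - the reference intron flanking the
  mismatched exon gets a non-GT donor.
* ``FRAMESHIFT_INDEL`` - the target contig gains a 1-2 nt insertion in an
  exon; exon boundaries absorb it so the frameshift is local.
* ``ALT_ISOFORM`` - the reference emits a second isoform with a swapped
  exon block and the target follows it (a false-positive mechanism).
* ``REPEAT_REGION`` - reference and target carry different tandem repeats
  at the same position (a false-positive mechanism).
* ``PROPAGATED_4PLUS`` - the same wrong-frame corruption applied
  identically to four or more species.

Internal stop codons that a corruption would create are removed by
resampling synonymous codons (or, rarely, the underlying residue) before
the gene is emitted, mirroring the fact that real gene predictors only
emit open reading frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.Seq import reverse_complement

from .io_formats import (
    STANDARD_TABLE,
    ExonInterval,
    GeneModel,
    SequenceRecord,
    _protein_record,
    extract_cds,
    translate_cds,
    write_fasta,
    write_gff3_models,
    write_tsv,
)

SCENARIOS = (
    "NONE",
    "N_RUN",
    "SHORT_INTRON",
    "EXON_SPLIT",
    "NONCANONICAL_SPLICE_REF",
    "FRAMESHIFT_INDEL",
    "ALT_ISOFORM",
    "REPEAT_REGION",
    "PROPAGATED_4PLUS",
    "WRONG_FRAME_EXON",
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ResampleRequest(Exception):
    """A scenario could not be injected into this gene; draw a new one."""


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_target_species: int = 5
    exon_count_range: tuple[int, int] = (10, 14)
    exon_length_range: tuple[int, int] = (120, 240)
    anchor_exon_length_range: tuple[int, int] = (150, 210)
    intron_length_range: tuple[int, int] = (35, 120)
    protein_divergence: tuple[float, float] = (0.01, 0.08)
    scenario_mix: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.protein_divergence, (int, float)):
            self.protein_divergence = (
                float(self.protein_divergence),
                float(self.protein_divergence),
            )
        if self.intron_length_range[0] < 30:
            raise ValueError("intron length minimum must be >= 30")
        bad = set(self.scenario_mix) - set(SCENARIOS)
        if bad:
            raise ValueError(f"unknown scenarios {sorted(bad)}")
        if sum(self.scenario_mix.values()) > 1.0 + 1e-9:
            raise ValueError("scenario proportions must sum to <= 1")
        if not (0 <= self.protein_divergence[0] <= self.protein_divergence[1] <= 0.2):
            raise ValueError("divergence must lie in [0, 0.2]")


@dataclass
class GroundTruthLabel:
    gene_id: str
    species: str
    scenario: str
    affected_protein_span: tuple[int, int]
    true_protein: SequenceRecord
    protein_id: str = ""


# ---------------------------------------------------------------------------
# gene layout: plus-orientation scaffold a gene is built and corrupted in
# ---------------------------------------------------------------------------

@dataclass
class GeneLayout:
    """A gene in plus-orientation construction space: codons of the true
    CDS, exon lengths, intron sequences, and flanks.  The strand flip, if
    any, happens only when the layout is rendered to a contig + model."""

    species: str
    gene_name: str
    codons: list[str]            # includes start (ATG...) and final stop codon
    exon_lengths: list[int]
    introns: list[str]
    flank5: str
    flank3: str
    strand: str
    anchor_idx: int              # index of the long internal exon

    @property
    def cds(self) -> str:
        return "".join(self.codons)

    def exon_bounds(self) -> list[tuple[int, int]]:
        """(start, end) of each exon in plus-contig coordinates."""
        out, pos = [], len(self.flank5)
        for i, ln in enumerate(self.exon_lengths):
            out.append((pos, pos + ln))
            pos += ln
            if i < len(self.introns):
                pos += len(self.introns[i])
        return out

    def plus_contig(self) -> str:
        parts, cds, off = [self.flank5], self.cds, 0
        for i, ln in enumerate(self.exon_lengths):
            parts.append(cds[off : off + ln])
            off += ln
            if i < len(self.introns):
                parts.append(self.introns[i])
        parts.append(self.flank3)
        return "".join(parts)

    def cds_offset_of_exon(self, idx: int) -> int:
        return sum(self.exon_lengths[:idx])

    def source_of(self, pos: int) -> tuple[str, int, int]:
        """Classify a plus-contig position: ('exon', exon_idx, offset),
        ('intron', intron_idx, offset) or ('flank', -1, pos)."""
        bounds = self.exon_bounds()
        for i, (s, e) in enumerate(bounds):
            if s <= pos < e:
                return ("exon", i, pos - s)
            if i < len(self.introns) and e <= pos < e + len(self.introns[i]):
                return ("intron", i, pos - e)
        return ("flank", -1, pos)

    def ids(self) -> dict[str, str]:
        tag = f"{self.species}_{self.gene_name}"
        return {
            "gene_id": f"{self.gene_name}_{self.species}",
            "transcript_id": f"t_{tag}",
            "contig_id": f"ctg_{tag}",
            "protein_id": tag,
        }


def _rand_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _rand_protein(rng, n: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, n)])


def _back_translate(rng, protein: str) -> list[str]:
    out = []
    for aa in protein:
        choices = STANDARD_TABLE.codons_for[aa]
        out.append(choices[rng.integers(0, len(choices))])
    return out


def simulate_clean_gene(
    rng: np.random.Generator,
    config: SimulationConfig,
    gene_name: str = "g0001",
    species: str = "ref",
) -> GeneLayout:
    """One error-free multi-exon gene: ATG start, single terminal stop,
    GT/AG introns of at least 30 nt."""
    lo, hi = config.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    lengths = [
        int(rng.integers(config.exon_length_range[0], config.exon_length_range[1] + 1))
        for _ in range(n_exons)
    ]
    anchor_idx = n_exons // 2 if n_exons >= 3 else 0
    if n_exons >= 3:
        a_lo, a_hi = config.anchor_exon_length_range
        lengths[anchor_idx] = int(rng.integers(a_lo, a_hi + 1))
    total = sum(lengths)
    lengths[-1] += (3 - total % 3) % 3
    total = sum(lengths)
    n_codons = total // 3
    protein = "M" + _rand_protein(rng, n_codons - 2)
    codons = _back_translate(rng, protein)
    codons[0] = "ATG"
    codons.append(("TAA", "TAG", "TGA")[rng.integers(0, 3)])
    introns = []
    for _ in range(n_exons - 1):
        ln = int(
            rng.integers(config.intron_length_range[0], config.intron_length_range[1] + 1)
        )
        introns.append("GT" + _rand_seq(rng, ln - 4) + "AG")
    return GeneLayout(
        species=species,
        gene_name=gene_name,
        codons=codons,
        exon_lengths=lengths,
        introns=introns,
        flank5=_rand_seq(rng, int(rng.integers(100, 301))),
        flank3=_rand_seq(rng, int(rng.integers(100, 301))),
        strand="+" if rng.integers(0, 2) == 0 else "-",
        anchor_idx=anchor_idx,
    )


def diverge_ortholog(
    rng: np.random.Generator, reference: GeneLayout, divergence: float,
    species: str = "sp01",
) -> GeneLayout:
    """Derive an ortholog by codon substitutions with a synonymous bias:
    each internal codon mutates non-synonymously with probability
    ``divergence`` and synonymously with probability ``3 * divergence``,
    preserving splice sites and exon structure."""
    if not 0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    codons = list(reference.codons)
    for i in range(1, len(codons) - 1):
        aa = STANDARD_TABLE.translate_codon(codons[i])
        if rng.random() < divergence:
            other = [a for a in AMINO_ACIDS if a != aa]
            new_aa = other[rng.integers(0, len(other))]
            choices = STANDARD_TABLE.codons_for[new_aa]
            codons[i] = choices[rng.integers(0, len(choices))]
        elif rng.random() < min(1.0, 3.0 * divergence):
            syn = [c for c in STANDARD_TABLE.codons_for[aa] if c != codons[i]]
            if syn:
                codons[i] = syn[rng.integers(0, len(syn))]
    return replace(
        reference,
        species=species,
        codons=codons,
        introns=list(reference.introns),
        strand="+" if rng.integers(0, 2) == 0 else "-",
    )


# ---------------------------------------------------------------------------
# rendering a layout (optionally corrupted) to model + contig + protein
# ---------------------------------------------------------------------------

def render_gene(
    layout: GeneLayout,
    intervals: list[tuple[int, int]] | None = None,
    contig_seq: str | None = None,
) -> tuple[GeneModel, SequenceRecord, SequenceRecord]:
    """Materialize (GeneModel, contig, protein).  ``intervals`` override
    the clean exon bounds (plus-orientation, transcript order) and
    ``contig_seq`` overrides the plus-orientation contig."""
    ivals = intervals if intervals is not None else layout.exon_bounds()
    plus = contig_seq if contig_seq is not None else layout.plus_contig()
    ids = layout.ids()
    if layout.strand == "+":
        exons = [ExonInterval(s, e) for s, e in ivals]
        seq = plus
    else:
        L = len(plus)
        exons = [ExonInterval(L - e, L - s) for s, e in ivals]
        seq = reverse_complement(plus)
    model = GeneModel(
        gene_id=ids["gene_id"],
        transcript_id=ids["transcript_id"],
        contig_id=ids["contig_id"],
        strand=layout.strand,
        exons=exons,
        protein_id=ids["protein_id"],
    )
    contig = SequenceRecord(id=ids["contig_id"], seq=seq, moltype="nucleotide")
    tr = translate_cds(extract_cds(model, contig))
    protein = _protein_record(ids["protein_id"], tr.protein.seq.rstrip("*"))
    return model, contig, protein


def true_protein(layout: GeneLayout) -> SequenceRecord:
    aas = "".join(STANDARD_TABLE.translate_codon(c) for c in layout.codons[:-1])
    return _protein_record(layout.ids()["protein_id"], aas)


# ---------------------------------------------------------------------------
# corruption machinery
# ---------------------------------------------------------------------------

@dataclass
class _Corruption:
    """A model/contig corruption in layout space.  ``src_of(pos)`` maps a
    corrupted-contig position back to the layout contig, or to an index in
    ``inserted`` for novel bases."""

    intervals: list[tuple[int, int]]
    inserted: list[str]
    insert_at: int = -1  # layout position where `inserted` bases go

    def src_of(self, pos: int) -> tuple[str, int]:
        if self.insert_at < 0 or pos < self.insert_at:
            return ("layout", pos)
        k = len("".join(self.inserted))
        if pos < self.insert_at + k:
            return ("ins", pos - self.insert_at)
        return ("layout", pos - k)

    def contig(self, layout: GeneLayout) -> str:
        plus = layout.plus_contig()
        if self.insert_at < 0:
            return plus
        ins = "".join(self.inserted)
        return plus[: self.insert_at] + ins + plus[self.insert_at :]


def _corrupted_translation(layout: GeneLayout, corr: _Corruption) -> str:
    contig = corr.contig(layout)
    cds = "".join(contig[s:e] for s, e in corr.intervals)
    n = len(cds) - len(cds) % 3
    return "".join(
        STANDARD_TABLE.translate_codon(cds[i : i + 3]) for i in range(0, n, 3)
    )


def _sanitize_stops(rng, layout: GeneLayout, corr: _Corruption, max_iter: int = 300):
    """Remove internal stop codons from the corrupted reading by mutating
    the underlying gene (synonymous first), mimicking predictors that only
    emit ORFs.  Mutates ``layout``/``corr`` in place."""
    for _ in range(max_iter):
        prot = _corrupted_translation(layout, corr)
        hit = prot.find("*")
        if hit < 0 or hit == len(prot) - 1:
            return
        # corrupted-contig positions of the offending codon
        track = []
        for s, e in corr.intervals:
            track.extend(range(s, e))
        positions = track[3 * hit : 3 * hit + 3]
        order = list(rng.permutation(3))
        if not any(_mutate_at(rng, layout, corr, positions[i]) for i in order):
            raise ResampleRequest("unremovable internal stop")
    raise ResampleRequest("stop sanitation did not converge")


def _mutate_at(rng, layout: GeneLayout, corr: _Corruption, pos: int) -> bool:
    where, p = corr.src_of(pos)
    if where == "ins":
        cur = "".join(corr.inserted)[p]
        corr.inserted = [
            "".join(
                b if i != p else [x for x in "ACGT" if x != cur][rng.integers(0, 3)]
                for i, b in enumerate("".join(corr.inserted))
            )
        ]
        return True
    kind, idx, off = layout.source_of(p)
    if kind == "intron":
        if off < 2 or off >= len(layout.introns[idx]) - 2:
            return False  # splice sites are sacrosanct
        cur = layout.introns[idx][off]
        new = [x for x in "ACGT" if x != cur][rng.integers(0, 3)]
        layout.introns[idx] = (
            layout.introns[idx][:off] + new + layout.introns[idx][off + 1 :]
        )
        return True
    if kind == "flank":
        return False
    cds_idx = layout.cds_offset_of_exon(idx) + off
    c = cds_idx // 3
    if c == 0 or c == len(layout.codons) - 1:
        return False  # keep start and stop codons intact
    aa = STANDARD_TABLE.translate_codon(layout.codons[c])
    syn = [x for x in STANDARD_TABLE.codons_for[aa] if x != layout.codons[c]]
    if syn and rng.random() < 0.8:
        layout.codons[c] = syn[rng.integers(0, len(syn))]
    else:
        other = [a for a in AMINO_ACIDS if a != aa]
        new_aa = other[rng.integers(0, len(other))]
        choices = STANDARD_TABLE.codons_for[new_aa]
        layout.codons[c] = choices[rng.integers(0, len(choices))]
    return True


def _shift_intervals(layout: GeneLayout, d: int) -> list[tuple[int, int]]:
    bounds = layout.exon_bounds()
    s, e = bounds[layout.anchor_idx]
    bounds[layout.anchor_idx] = (s + d, e + d)
    return bounds


def _span_of_region(corr: _Corruption, lo: int, hi: int) -> tuple[int, int]:
    """Protein-coordinate span of corrupted-contig region [lo, hi) under
    the corruption's reading (full codons only)."""
    track = []
    for s, e in corr.intervals:
        track.extend(range(s, e))
    idx = [i for i, p in enumerate(track) if lo <= p < hi]
    if not idx:
        return (0, 0)
    return ((idx[0] + 2) // 3, idx[-1] // 3 + 1)


def inject_scenario(
    rng: np.random.Generator,
    layout: GeneLayout,
    scenario: str,
    ref_layout: GeneLayout | None = None,
    config: SimulationConfig | None = None,
    shift: int | None = None,
) -> tuple[GeneModel, SequenceRecord, SequenceRecord, GroundTruthLabel]:
    """Corrupt one target gene according to ``scenario``.

    Returns the corrupted (model, contig, mispredicted protein) triple -
    mutually consistent by construction - plus a ground-truth label whose
    ``true_protein`` is what an error-free prediction would have given.
    Raises :class:`ResampleRequest` if the gene cannot host the scenario.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "NONE":
        model, contig, prot = render_gene(layout)
        label = _label(layout, scenario, (0, 0), prot)
        return model, contig, prot, label
    if len(layout.exon_lengths) < 3:
        raise ResampleRequest("scenario needs an internal exon")
    handler = {
        "WRONG_FRAME_EXON": _inject_wrong_frame,
        "PROPAGATED_4PLUS": _inject_wrong_frame,
        "NONCANONICAL_SPLICE_REF": _inject_wrong_frame,
        "N_RUN": _inject_n_run,
        "SHORT_INTRON": _inject_short_intron,
        "EXON_SPLIT": _inject_exon_split,
        "FRAMESHIFT_INDEL": _inject_frameshift,
        "ALT_ISOFORM": _inject_block_swap,
        "REPEAT_REGION": _inject_block_swap,
    }[scenario]
    return handler(rng, layout, scenario, shift=shift)


def _label(layout, scenario, span, truth) -> GroundTruthLabel:
    return GroundTruthLabel(
        gene_id=layout.gene_name,
        species=layout.species,
        scenario=scenario,
        affected_protein_span=span,
        true_protein=truth,
        protein_id=layout.ids()["protein_id"],
    )


def _wrong_frame_corruption(rng, layout, shift=None) -> tuple[_Corruption, int]:
    d = int(rng.integers(1, 3)) if shift is None else int(shift)
    corr = _Corruption(intervals=_shift_intervals(layout, d), inserted=[])
    _sanitize_stops(rng, layout, corr)
    return corr, d


def _finish(rng, layout, corr, scenario, span_region) -> tuple:
    truth = true_protein(layout)
    model, contig, prot = render_gene(
        layout, intervals=corr.intervals, contig_seq=corr.contig(layout)
    )
    span = _span_of_region(corr, *span_region)
    _assert_detectable(prot, truth, span, scenario)
    return model, contig, prot, _label(layout, scenario, span, truth)


def _assert_detectable(mispredicted, truth, span, scenario):
    if scenario in ("ALT_ISOFORM", "REPEAT_REGION"):
        return  # detectability vs the reference is asserted at block build
    a, b = span
    if b - a < 20:
        raise ResampleRequest("corrupted span too short")
    if len(mispredicted.seq) == len(truth.seq):
        seg_m, seg_t = mispredicted.seq[a:b], truth.seq[a:b]
        ident = sum(x == y for x, y in zip(seg_m, seg_t)) / (b - a)
        if ident >= 0.4:
            raise ResampleRequest("corruption insufficiently divergent")


def _inject_wrong_frame(rng, layout, scenario, shift=None):
    corr, _d = _wrong_frame_corruption(rng, layout, shift)
    s, e = layout.exon_bounds()[layout.anchor_idx]
    return _finish(rng, layout, corr, scenario, (s + 3, e - 3))


def _inject_n_run(rng, layout, scenario, shift=None):
    corr, _d = _wrong_frame_corruption(rng, layout, shift)
    # plant the undetermined run in an intron of the gene span
    j = layout.anchor_idx - 1 if layout.anchor_idx >= 1 else 0
    intron = layout.introns[j]
    run = int(rng.integers(10, 51))
    if len(intron) < run + 8:
        run = len(intron) - 8
    if run < 10:
        raise ResampleRequest("intron too short for an N run")
    off = int(rng.integers(4, len(intron) - run - 3))
    layout.introns[j] = intron[:off] + "N" * run + intron[off + run :]
    s, e = layout.exon_bounds()[layout.anchor_idx]
    return _finish(rng, layout, corr, scenario, (s + 3, e - 3))


def _inject_short_intron(rng, layout, scenario, shift=None):
    d = int(rng.integers(1, 3))
    bounds = layout.exon_bounds()
    s, e = bounds[layout.anchor_idx]
    L = int(rng.choice([15, 18, 21, 24, 27]))
    if e - s - L < 72:
        raise ResampleRequest("anchor exon too short for a spurious intron")
    q = int(rng.integers(s + d + 33, e + d - L - 33))
    pieces = [(s + d, q), (q + L, e + d)]
    ivals = bounds[: layout.anchor_idx] + pieces + bounds[layout.anchor_idx + 1 :]
    corr = _Corruption(intervals=ivals, inserted=[])
    _sanitize_stops(rng, layout, corr)
    return _finish(rng, layout, corr, scenario, (s + 3, e - 3))


def _inject_exon_split(rng, layout, scenario, shift=None):
    d = int(rng.integers(1, 3)) if shift is None else int(shift)
    bounds = layout.exon_bounds()
    s, e = bounds[layout.anchor_idx]
    L1, L2 = 33, 36
    edge = 12
    if e - s < 195:
        raise ResampleRequest("anchor exon too short to split in three")
    # spurious introns sit near the anchor's edges so the wrong-frame
    # remnant stays one contiguous (detectable) block
    q1 = s + d + edge
    q2 = e + d - edge - L2
    pieces = [(s + d, q1), (q1 + L1, q2), (q2 + L2, e + d)]
    ivals = bounds[: layout.anchor_idx] + pieces + bounds[layout.anchor_idx + 1 :]
    corr = _Corruption(intervals=ivals, inserted=[])
    _sanitize_stops(rng, layout, corr)
    return _finish(rng, layout, corr, scenario, (s + 3, e - 3))


def _inject_frameshift(rng, layout, scenario, shift=None):
    bounds = layout.exon_bounds()
    s, e = bounds[layout.anchor_idx]
    k = int(rng.integers(1, 3))
    if e - s < 90:
        raise ResampleRequest("anchor exon too short for a frameshift")
    p = int(rng.integers(s + 3, e - 75))
    ins = _rand_seq(rng, k)
    ivals = []
    for i, (a, b) in enumerate(bounds):
        if i < layout.anchor_idx:
            ivals.append((a, b))
        elif i == layout.anchor_idx:
            ivals.append((a, b + k))
        elif i == layout.anchor_idx + 1:
            ivals.append((a + 2 * k, b + k))
        else:
            ivals.append((a + k, b + k))
    corr = _Corruption(intervals=ivals, inserted=[ins], insert_at=p)
    _sanitize_stops(rng, layout, corr)
    return _finish(rng, layout, corr, scenario, (p, e + k))


# block swap scenarios operate at generation time (see generate_study);
# this handler simply renders the already-modified gene as its own truth.
def _inject_block_swap(rng, layout, scenario, shift=None):
    model, contig, prot = render_gene(layout)
    span = getattr(layout, "_block_span", (0, 0))
    return model, contig, prot, _label(layout, scenario, span, prot)


def _anchor_codon_range(layout: GeneLayout) -> tuple[int, int]:
    """Protein positions whose codons lie entirely inside the anchor exon."""
    off = layout.cds_offset_of_exon(layout.anchor_idx)
    end = off + layout.exon_lengths[layout.anchor_idx]
    return (off + 2) // 3, end // 3


def _set_block(layout: GeneLayout, rng, start: int, block: str) -> None:
    new = _back_translate(rng, block)
    layout.codons[start : start + len(block)] = new


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    reference_proteins: list[SequenceRecord]
    target_proteins: dict[str, list[SequenceRecord]]
    contigs: list[SequenceRecord]
    models: list[GeneModel]
    alt_isoforms: list[SequenceRecord]
    labels: list[GroundTruthLabel]

    @property
    def species(self) -> list[str]:
        return list(self.target_proteins)


def _assign_scenarios(rng, config) -> list[str]:
    picks: list[str] = []
    for name, prop in sorted(config.scenario_mix.items()):
        if name != "NONE":
            picks.extend([name] * round(prop * config.n_genes))
    picks = picks[: config.n_genes]
    picks += ["NONE"] * (config.n_genes - len(picks))
    return [picks[i] for i in rng.permutation(len(picks))]


def generate_study(config: SimulationConfig) -> StudyData:
    """Generate the full synthetic study in memory."""
    rng = np.random.default_rng(config.seed)
    n_sp = config.n_target_species
    species = [f"sp{i + 1:02d}" for i in range(n_sp)]
    lo, hi = config.protein_divergence
    divergences = {
        sp: lo + (hi - lo) * (i / max(1, n_sp - 1)) for i, sp in enumerate(species)
    }
    scenarios = _assign_scenarios(rng, config)
    data = StudyData([], {sp: [] for sp in species}, [], [], [], [])
    for gi, scenario in enumerate(scenarios):
        for attempt in range(30):
            try:
                _make_gene_family(rng, config, gi, scenario, species, divergences, data)
                break
            except ResampleRequest:
                if attempt == 29:
                    raise
    return data


def _make_gene_family(rng, config, gi, scenario, species, divergences, data):
    gene_name = f"g{gi + 1:04d}"
    gene_config = config
    if scenario == "EXON_SPLIT":
        # splitting removes two >=30 nt introns' worth of coding sequence;
        # a larger anchor keeps every fragment of the mismatch detectable
        lo = max(195, config.anchor_exon_length_range[0])
        hi = max(240, config.anchor_exon_length_range[1])
        gene_config = replace(config, anchor_exon_length_range=(lo, hi))
    ref = simulate_clean_gene(rng, gene_config, gene_name=gene_name, species="ref")
    if scenario == "PROPAGATED_4PLUS" and len(species) < 4:
        raise ValueError("PROPAGATED_4PLUS requires at least 4 target species")
    shared_shift = None
    if scenario == "PROPAGATED_4PLUS":
        affected = sorted(
            species[i] for i in rng.permutation(len(species))[:4]
        )
        shared_shift = int(rng.integers(1, 3))  # applied identically
    else:
        affected = [species[rng.integers(0, len(species))]]

    alt_iso = None
    block = None
    if scenario in ("ALT_ISOFORM", "REPEAT_REGION"):
        c0, c1 = _anchor_codon_range(ref)
        if c1 - c0 < 34:
            raise ResampleRequest("anchor exon codon range too short for a block")
        if scenario == "REPEAT_REGION":
            period = int(rng.integers(2, 4))
            copies = max(10, 26 // period + 1)
            letters = [AMINO_ACIDS[i] for i in rng.permutation(20)]
            unit_a = "".join(letters[:period])
            unit_b = "".join(letters[period : 2 * period])
            block_a, block_b = unit_a * copies, unit_b * copies
        else:
            blen = int(rng.integers(25, 33))
            block_a = _rand_protein(rng, blen)
            block_b = "".join(
                [a for a in AMINO_ACIDS if a != x][rng.integers(0, 19)] for x in block_a
            )
        start = c0 + 2
        if start + len(block_a) > c1 - 1:
            raise ResampleRequest("block does not fit in anchor exon")
        _set_block(ref, rng, start, block_a)
        block = (start, block_a, block_b)
        if scenario == "ALT_ISOFORM":
            iso_seq = list(true_protein(ref).seq)
            iso_seq[start : start + len(block_b)] = block_b
            alt_iso = _protein_record(f"ref_{gene_name}_iso2", "".join(iso_seq))

    # render (possibly modified) reference
    if scenario == "NONCANONICAL_SPLICE_REF":
        # corrupt the donor of the intron downstream of the reference anchor
        j = ref.anchor_idx
        if j >= len(ref.introns):
            j = ref.anchor_idx - 1
        noncanonical_j = j
    orthologs = {
        sp: diverge_ortholog(rng, ref, divergences[sp], species=sp) for sp in species
    }
    if scenario == "NONCANONICAL_SPLICE_REF":
        ref.introns[noncanonical_j] = "GC" + ref.introns[noncanonical_j][2:]
    ref_model, ref_contig, ref_prot = render_gene(ref)
    assert translate_cds(extract_cds(ref_model, ref_contig)).protein.seq.rstrip("*") == ref_prot.seq

    new_models = [ref_model]
    new_contigs = [ref_contig]
    new_targets: dict[str, SequenceRecord] = {}
    new_labels = []
    for sp in species:
        lay = orthologs[sp]
        if sp in affected and scenario != "NONE":
            if block is not None:
                start, block_a, block_b = block
                _set_block(lay, rng, start, block_b)
                lay._block_span = (start, start + len(block_b))
            model, contig, prot, label = inject_scenario(
                rng, lay, scenario, ref_layout=ref, shift=shared_shift
            )
            new_labels.append(label)
        else:
            model, contig, prot = render_gene(lay)
            new_labels.append(_label(lay, "NONE", (0, 0), prot))
        assert translate_cds(extract_cds(model, contig)).protein.seq.rstrip("*") == prot.seq
        if "*" in prot.seq or "X" in prot.seq:
            raise ResampleRequest("emitted protein contains stop or X")
        new_models.append(model)
        new_contigs.append(contig)
        new_targets[sp] = prot

    # commit (only after every species succeeded)
    data.reference_proteins.append(ref_prot)
    data.models.extend(new_models)
    data.contigs.extend(new_contigs)
    for sp in species:
        data.target_proteins[sp].append(new_targets[sp])
    if alt_iso is not None:
        data.alt_isoforms.append(alt_iso)
    data.labels.extend(new_labels)


def simulate_study(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate a study and write the on-disk bundle: reference proteome,
    per-species proteomes, contigs, GFF3 gene models, alternative
    reference isoforms and the ground-truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate_study(config)
    paths = {
        "reference": out / "reference.faa",
        "contigs": out / "contigs.fna",
        "models": out / "models.gff3",
        "isoforms": out / "alt_isoforms.faa",
        "truth": out / "ground_truth.tsv",
    }
    write_fasta(data.reference_proteins, paths["reference"])
    for sp, prots in data.target_proteins.items():
        paths[f"proteome_{sp}"] = out / f"proteome_{sp}.faa"
        write_fasta(prots, paths[f"proteome_{sp}"])
    write_fasta(data.contigs, paths["contigs"])
    write_gff3_models(data.models, paths["models"])
    write_fasta(data.alt_isoforms, paths["isoforms"])
    write_tsv(
        [
            {
                "species": lb.species,
                "gene_id": lb.gene_id,
                "protein_id": lb.protein_id,
                "scenario": lb.scenario,
                "aa_start": lb.affected_protein_span[0],
                "aa_end": lb.affected_protein_span[1],
                "true_protein": lb.true_protein.seq,
            }
            for lb in data.labels
        ],
        paths["truth"],
        ["species", "gene_id", "protein_id", "scenario", "aa_start", "aa_end",
         "true_protein"],
    )
    return paths
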