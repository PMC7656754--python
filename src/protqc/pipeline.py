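"""End-to-end orchestration: simulate -> orthologs -> detect ->
characterize -> correct -> report, with one config object holding every
threshold and full determinism under a fixed seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import correction as corr_mod
from . import features as feat_mod
from .error_detect import (
    DetectionConfig,
    ReferenceAnchoredMSA,
    SequenceError,
    build_msa,
    detect_errors,
    error_census,
    length_ratio_filter,
)
from .io_formats import (
    GeneModel,
    SequenceRecord,
    read_fasta,
    read_gff3_models,
    write_fasta,
    write_tsv,
)
from .orthology import OrthologPair, ScoringScheme, find_orthologs
from .simulator import SimulationConfig, simulate_study


@dataclass
class PipelineConfig:
    """All decision thresholds of the quality-control protocol.  The
    defaults are the protocol's published operating points, so a
    config-free run applies the standard decision rules."""

    ortholog_evalue_max: float = 1e-50
    ortholog_identity_min: float = 80.0
    mismatch_min_len: int = 20
    mismatch_max_identity: float = 50.0
    length_ratio_max: float = 3.0
    intron_min_len: int = 30
    exon_split_min: int = 3
    conserved_min_species: int = 4
    correction_evalue_max: float = 1e-3
    correction_identity_min: float = 80.0
    correction_region_margin: int = 500
    indel_min_len: int = 5
    seed: int = 0

    def __post_init__(self):
        numeric = {
            k: v for k, v in dataclasses.asdict(self).items() if k != "seed"
        }
        if any(v <= 0 for v in numeric.values()):
            raise ValueError("all thresholds must be positive")

    def detection(self) -> DetectionConfig:
        return DetectionConfig(
            mismatch_min_len=self.mismatch_min_len,
            mismatch_max_identity=self.mismatch_max_identity,
            indel_min_len=self.indel_min_len,
            length_ratio_max=self.length_ratio_max,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else source)
        return cls(**data)


@dataclass
class StudyInputs:
    """Loaded study bundle (from disk or in-memory simulation)."""

    reference: list[SequenceRecord]
    proteomes: dict[str, list[SequenceRecord]]
    contigs: dict[str, SequenceRecord]
    models_by_protein: dict[str, GeneModel]
    alt_isoforms: list[SequenceRecord]

    @classmethod
    def load(cls, directory) -> "StudyInputs":
        d = Path(directory)
        reference = read_fasta(d / "reference.faa", "protein")
        proteomes = {}
        for p in sorted(d.glob("proteome_*.faa")):
            sp = p.stem.removeprefix("proteome_")
            proteomes[sp] = read_fasta(p, "protein")
        contigs = {
            c.id: c for c in read_fasta(d / "contigs.fna", "nucleotide")
        }
        models = read_gff3_models(d / "models.gff3")
        iso_path = d / "alt_isoforms.faa"
        isoforms = read_fasta(iso_path, "protein") if iso_path.exists() else []
        return cls(
            reference=reference,
            proteomes=proteomes,
            contigs=contigs,
            models_by_protein={m.protein_id: m for m in models},
            alt_isoforms=isoforms,
        )

    @property
    def species(self) -> list[str]:
        return sorted(self.proteomes)

    def all_proteins(self) -> dict[str, SequenceRecord]:
        out = {r.id: r for r in self.reference}
        for prots in self.proteomes.values():
            out.update({r.id: r for r in prots})
        return out


@dataclass
class StageOutputs:
    pairs: dict[str, list[OrthologPair]] = field(default_factory=dict)
    msas: dict[str, ReferenceAnchoredMSA] = field(default_factory=dict)
    errors: list[SequenceError] = field(default_factory=list)
    reports: list[feat_mod.MismatchReport] = field(default_factory=list)
    corrections: list[corr_mod.CorrectionResult] = field(default_factory=list)
    species_of: dict[str, str] = field(default_factory=dict)
    reference_of: dict[str, str] = field(default_factory=dict)


def stage_orthologs(inputs: StudyInputs, cfg: PipelineConfig,
                    scheme: ScoringScheme = ScoringScheme()) -> StageOutputs:
    out = StageOutputs()
    for sp in inputs.species:
        out.pairs[sp] = find_orthologs(
            inputs.reference, inputs.proteomes[sp], sp, scheme,
            evalue_max=cfg.ortholog_evalue_max,
            identity_min=cfg.ortholog_identity_min,
        )
        for pair in out.pairs[sp]:
            out.species_of[pair.target_id] = sp
            out.reference_of[pair.target_id] = pair.reference_id
    return out


def stage_detect(inputs: StudyInputs, out: StageOutputs, cfg: PipelineConfig,
                 scheme: ScoringScheme = ScoringScheme()) -> None:
    """Reference-anchored MSA per reference protein (over its orthologs
    passing the length-ratio filter) and error detection on every row."""
    det = cfg.detection()
    proteins = inputs.all_proteins()
    by_ref: dict[str, list[str]] = {}
    for sp in inputs.species:
        for pair in out.pairs[sp]:
            by_ref.setdefault(pair.reference_id, []).append(pair.target_id)
    for ref_id in sorted(by_ref):
        ref = proteins[ref_id]
        rows = [
            proteins[t] for t in by_ref[ref_id]
            if length_ratio_filter(ref, proteins[t], det)
        ]
        if not rows:
            continue
        msa = build_msa(ref, rows)
        out.msas[ref_id] = msa
        out.errors.extend(detect_errors(msa, det))


def stage_characterize(inputs: StudyInputs, out: StageOutputs,
                       cfg: PipelineConfig,
                       scheme: ScoringScheme = ScoringScheme()) -> None:
    models = inputs.models_by_protein
    data = feat_mod.CharacterizationData(
        proteins=inputs.all_proteins(),
        models=models,
        contigs=inputs.contigs,
        reference_of=out.reference_of,
        alt_isoforms=inputs.alt_isoforms,
    )
    by_ref: dict[str, list[SequenceError]] = {}
    for e in out.errors:
        if e.category == "MISMATCH":
            by_ref.setdefault(out.reference_of[e.sequence_id], []).append(e)
    for ref_id in sorted(by_ref):
        gene_mismatches = by_ref[ref_id]
        for e in gene_mismatches:
            out.reports.append(
                feat_mod.characterize_mismatch(
                    e, gene_mismatches, data,
                    intron_min_len=cfg.intron_min_len,
                    exon_split_min=cfg.exon_split_min,
                    conserved_min_species=cfg.conserved_min_species,
                    scheme=scheme,
                )
            )


def stage_correct(inputs: StudyInputs, out: StageOutputs, cfg: PipelineConfig,
                  scheme: ScoringScheme = ScoringScheme(),
                  require_gene_prediction_error: bool = True) -> None:
    proteins = inputs.all_proteins()
    for report in out.reports:
        tid = report.error.sequence_id
        model = inputs.models_by_protein.get(tid)
        if model is None:
            continue
        contig = inputs.contigs[model.contig_id]
        out.corrections.append(
            corr_mod.correct_mismatch(
                report, model, contig,
                proteins[out.reference_of[tid]], proteins[tid],
                scheme=scheme, detection=cfg.detection(),
                evalue_max=cfg.correction_evalue_max,
                identity_min=cfg.correction_identity_min,
                region_margin=cfg.correction_region_margin,
                require_gene_prediction_error=require_gene_prediction_error,
            )
        )


def summarize(inputs: StudyInputs, out: StageOutputs) -> dict:
    """Study summary: ortholog counts and rates, error census per species
    and category, mismatch feature/classification census, and correction
    before/after statistics."""
    n_ref = len(inputs.reference)
    ortholog_counts = {sp: len(out.pairs.get(sp, [])) for sp in inputs.species}
    census = error_census(out.errors, out.species_of, ortholog_counts)
    feature_counts = {f: 0 for f in feat_mod.ALL_FEATURES}
    class_counts = {c: 0 for c in feat_mod.CLASSIFICATIONS}
    for r in out.reports:
        class_counts[r.classification] += 1
        for name in r.flag_names:
            feature_counts[name] += 1
    mism_by_species: dict[str, set[str]] = {sp: set() for sp in inputs.species}
    for e in out.errors:
        if e.category == "MISMATCH":
            mism_by_species[out.species_of[e.sequence_id]].add(e.sequence_id)
    corrected = [c for c in out.corrections if c.status == "corrected"]
    corr_stats = {
        "attempted": len(out.corrections),
        "corrected": len(corrected),
        "refusals": {
            s: sum(1 for c in out.corrections if c.status == s)
            for s in corr_mod.REFUSAL_STATUSES
        },
        "errors_before_total": sum(sum(c.errors_before.values()) for c in corrected),
        "errors_after_total": sum(sum(c.errors_after.values()) for c in corrected),
        "mismatches_before": sum(c.errors_before.get("MISMATCH", 0) for c in corrected),
        "mismatches_after": sum(c.errors_after.get("MISMATCH", 0) for c in corrected),
        "mean_identity_before": _mean([c.scores_before.identity_I for c in corrected]),
        "mean_identity_after": _mean([c.scores_after.identity_I for c in corrected]),
        "mean_coverage_before": _mean([c.scores_before.coverage_C for c in corrected]),
        "mean_coverage_after": _mean([c.scores_after.coverage_C for c in corrected]),
    }
    return {
        "n_reference_proteins": n_ref,
        "orthologs": {
            sp: {
                "count": ortholog_counts[sp],
                "pct_reference_with_ortholog": round(
                    100.0 * ortholog_counts[sp] / n_ref, 2
                ) if n_ref else 0.0,
            }
            for sp in inputs.species
        },
        "error_census": json.loads(census.to_json(orient="index")),
        "pct_sequences_with_mismatch": {
            sp: round(
                100.0 * len(mism_by_species[sp]) / ortholog_counts[sp], 2
            ) if ortholog_counts[sp] else 0.0
            for sp in inputs.species
        },
        "mismatch_features": feature_counts,
        "mismatch_classes": class_counts,
        "correction": corr_stats,
    }


def _mean(xs):
    return round(sum(xs) / len(xs), 4) if xs else 0.0


def run_pipeline(
    cfg: PipelineConfig,
    input_dir=None,
    out_dir=None,
    sim_config: SimulationConfig | None = None,
    require_gene_prediction_error: bool = True,
) -> tuple[dict, StageOutputs, StudyInputs]:
    """Run every stage; if ``sim_config`` is given the study is simulated
    first.  Writes summary.json and per-table TSVs under ``out_dir``."""
    if sim_config is not None:
        if input_dir is None:
            if out_dir is None:
                raise ValueError("need input_dir or out_dir to place simulation")
            input_dir = Path(out_dir) / "bundle"
        simulate_study(sim_config, input_dir)
    if input_dir is None:
        raise ValueError("input_dir required when not simulating")
    inputs = StudyInputs.load(input_dir)
    scheme = ScoringScheme()
    out = stage_orthologs(inputs, cfg, scheme)
    stage_detect(inputs, out, cfg, scheme)
    stage_characterize(inputs, out, cfg, scheme)
    stage_correct(inputs, out, cfg, scheme, require_gene_prediction_error)
    summary = summarize(inputs, out)
    summary["config_sha256"] = hashlib.sha256(
        cfg.to_json().encode()
    ).hexdigest()[:16]
    if out_dir is not None:
        _write_outputs(Path(out_dir), cfg, out, summary)
    return summary, out, inputs


def _write_outputs(out_dir: Path, cfg, out: StageOutputs, summary: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_json(out_dir / "config.json")
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    write_tsv(
        [
            {
                "species": p.species, "reference_id": p.reference_id,
                "target_id": p.target_id, "score": p.hit.raw_score,
                "evalue": f"{p.hit.evalue:.3e}",
                "identity_pct": round(p.hit.identity_pct, 2),
            }
            for sp in sorted(out.pairs) for p in out.pairs[sp]
        ],
        out_dir / "orthologs.tsv",
        ["species", "reference_id", "target_id", "score", "evalue", "identity_pct"],
    )
    write_tsv(
        [
            {
                "species": out.species_of.get(e.sequence_id, "?"),
                "sequence_id": e.sequence_id, "category": e.category,
                "msa_start": e.msa_columns[0], "msa_end": e.msa_columns[1],
                "seq_start": e.seq_positions[0], "seq_end": e.seq_positions[1],
                "ref_start": e.ref_positions[0], "ref_end": e.ref_positions[1],
                "segment_identity": (
                    "" if e.segment_identity_pct is None else e.segment_identity_pct
                ),
            }
            for e in out.errors
        ],
        out_dir / "errors.tsv",
        ["species", "sequence_id", "category", "msa_start", "msa_end",
         "seq_start", "seq_end", "ref_start", "ref_end", "segment_identity"],
    )
    feat_cols = list(feat_mod.ALL_FEATURES)
    write_tsv(
        [
            {
                "species": out.species_of.get(r.error.sequence_id, "?"),
                "sequence_id": r.error.sequence_id,
                "seq_start": r.error.seq_positions[0],
                "seq_end": r.error.seq_positions[1],
                **{
                    f: ("NA" if f in r.skipped_features
                        else int(f in r.flag_names))
                    for f in feat_cols
                },
                "classification": r.classification,
            }
            for r in out.reports
        ],
        out_dir / "mismatch_report.tsv",
        ["species", "sequence_id", "seq_start", "seq_end", *feat_cols,
         "classification"],
    )
    write_tsv(
        [
            {
                "sequence_id": c.original_protein.id,
                "status": c.status,
                "inserted_exon_start": c.inserted_exon.start if c.inserted_exon else "",
                "inserted_exon_end": c.inserted_exon.end if c.inserted_exon else "",
                "frame": c.frame or "",
                "I_before": c.scores_before.identity_I if c.scores_before else "",
                "I_after": c.scores_after.identity_I if c.scores_after else "",
                "C_before": c.scores_before.coverage_C if c.scores_before else "",
                "C_after": c.scores_after.coverage_C if c.scores_after else "",
                "errors_before_total": sum(c.errors_before.values()),
                "errors_after_total": sum(c.errors_after.values()),
                "start_codon_fallback": int(c.start_codon_fallback_used),
            }
            for c in out.corrections
        ],
        out_dir / "corrections.tsv",
        ["sequence_id", "status", "inserted_exon_start", "inserted_exon_end",
         "frame", "I_before", "I_after", "C_before", "C_after",
         "errors_before_total", "errors_after_total", "start_codon_fallback"],
    )
    refined = [
        c.refined_protein for c in out.corrections
        if c.status == "corrected" and c.refined_protein is not None
    ]
    if refined:
        write_fasta(refined, out_dir / "refined.faa")
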