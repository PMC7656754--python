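"""Synthetic genome generator: consistency, divergence control, scenario
injection, and reproducibility."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from protqc.io_formats import extract_cds, translate_cds
from protqc.simulator import (
    SCENARIOS,
    GroundTruthLabel,
    ResampleRequest,
    SimulationConfig,
    diverge_ortholog,
    generate_study,
    inject_scenario,
    render_gene,
    simulate_clean_gene,
    simulate_study,
    true_protein,
)


def _roundtrip_ok(model, contig, protein):
    tr = translate_cds(extract_cds(model, contig))
    return tr.protein.seq.rstrip("*") == protein.seq


class TestCleanGene:
    def test_structure_and_roundtrip(self, rng):
        cfg = SimulationConfig(seed=0)
        lay = simulate_clean_gene(rng, cfg)
        model, contig, prot = render_gene(lay)
        assert _roundtrip_ok(model, contig, prot)
        assert "*" not in prot.seq and "X" not in prot.seq
        cds = extract_cds(model, contig).seq
        assert cds.startswith("ATG") and cds[-3:] in ("TAA", "TAG", "TGA")
        # introns >= 30 nt with canonical GT/AG in transcript orientation
        from protqc.features import _oriented

        for iv in model.introns:
            assert len(iv) >= 30
            s = _oriented(contig, iv, model.strand)
            assert s.startswith("GT") and s.endswith("AG")

    def test_single_exon_config(self, rng):
        cfg = SimulationConfig(exon_count_range=(1, 1), seed=0)
        lay = simulate_clean_gene(rng, cfg)
        model, contig, prot = render_gene(lay)
        assert len(model.exons) == 1
        assert "*" not in prot.seq

    def test_determinism(self):
        cfg = SimulationConfig(seed=0)
        a = simulate_clean_gene(np.random.default_rng(99), cfg)
        b = simulate_clean_gene(np.random.default_rng(99), cfg)
        assert a == b


class TestDivergence:
    def test_zero_divergence_identity(self, rng):
        lay = simulate_clean_gene(rng, SimulationConfig(seed=0))
        orth = diverge_ortholog(np.random.default_rng(0), lay, 0.0, "sp01")
        assert true_protein(orth).seq == true_protein(lay).seq

    def test_divergence_controls_identity(self):
        """At 10% divergence, protein identity lands in [0.85, 0.95]."""
        cfg = SimulationConfig(seed=0)
        gen = np.random.default_rng(7)
        lay = simulate_clean_gene(gen, cfg)
        ref = true_protein(lay).seq
        idents = []
        for seed in range(100):
            orth = diverge_ortholog(np.random.default_rng(seed), lay, 0.1, "s")
            tp = true_protein(orth).seq
            idents.append(sum(a == b for a, b in zip(ref, tp)) / len(ref))
        assert all(0.85 <= x <= 0.95 for x in idents)

    def test_no_stops_ever_introduced(self):
        cfg = SimulationConfig(seed=0, exon_count_range=(4, 6))
        gen = np.random.default_rng(13)
        for _ in range(60):
            lay = simulate_clean_gene(gen, cfg)
            for div in (0.05, 0.15, 0.2):
                orth = diverge_ortholog(gen, lay, div, "s")
                assert "*" not in true_protein(orth).seq

    def test_structure_preserved(self, rng):
        lay = simulate_clean_gene(rng, SimulationConfig(seed=0))
        orth = diverge_ortholog(np.random.default_rng(3), lay, 0.1, "sp01")
        assert orth.exon_lengths == lay.exon_lengths
        assert orth.introns == lay.introns


class TestInjection:
    @pytest.mark.parametrize(
        "scenario",
        ["WRONG_FRAME_EXON", "SHORT_INTRON", "EXON_SPLIT", "FRAMESHIFT_INDEL",
         "N_RUN"],
    )
    def test_corrupted_triple_is_consistent(self, scenario):
        cfg = SimulationConfig(
            seed=0, anchor_exon_length_range=(195, 240)
        )
        gen = np.random.default_rng(5)
        for _ in range(20):  # retry loop mirrors the study generator
            lay = simulate_clean_gene(gen, cfg)
            try:
                model, contig, prot, label = inject_scenario(gen, lay, scenario)
                break
            except ResampleRequest:
                continue
        else:
            pytest.fail("could not inject scenario")
        assert _roundtrip_ok(model, contig, prot)
        assert "*" not in prot.seq
        a, b = label.affected_protein_span
        assert b - a >= 20
        assert label.scenario == scenario

    def test_wrong_frame_span_is_divergent(self):
        cfg = SimulationConfig(seed=0)
        gen = np.random.default_rng(6)
        lay = simulate_clean_gene(gen, cfg)
        model, contig, prot, label = inject_scenario(gen, lay, "WRONG_FRAME_EXON")
        a, b = label.affected_protein_span
        truth = label.true_protein.seq
        ident = sum(x == y for x, y in zip(prot.seq[a:b], truth[a:b])) / (b - a)
        assert ident < 0.4
        # the true exon sequence survives in the contig (model-only corruption)
        assert label.true_protein.seq != prot.seq

    def test_n_run_in_gene_span(self):
        cfg = SimulationConfig(seed=0)
        gen = np.random.default_rng(8)
        lay = simulate_clean_gene(gen, cfg)
        model, contig, prot, label = inject_scenario(gen, lay, "N_RUN")
        span = model.span
        region = contig.seq[span.start : span.end]
        assert "N" * 10 in region
        assert "X" not in prot.seq  # the run sits in an intron, not an exon
        run_start = contig.seq.find("N" * 10)
        assert not any(
            e.start <= run_start < e.end for e in model.exons
        )

    def test_incompatible_gene_resample_request(self):
        cfg = SimulationConfig(exon_count_range=(1, 1), seed=0)
        gen = np.random.default_rng(2)
        lay = simulate_clean_gene(gen, cfg)
        with pytest.raises(ResampleRequest):
            inject_scenario(gen, lay, "EXON_SPLIT")


class TestStudy:
    def test_every_triple_consistent_and_labeled(self, mixed_bundle, clean_study):
        data = clean_study
        models = {m.protein_id: m for m in data.models}
        contigs = {c.id: c for c in data.contigs}
        labeled = {(l.species, l.gene_id) for l in data.labels}
        for sp, prots in data.target_proteins.items():
            for p in prots:
                m = models[p.id]
                assert _roundtrip_ok(m, contigs[m.contig_id], p)
                gene = p.id.split("_", 1)[1]
                assert (sp, gene) in labeled

    def test_all_none_mix_yields_equal_proteins(self, clean_study):
        for label in clean_study.labels:
            assert label.scenario == "NONE"

    def test_scenario_mix_all_wrong_frame(self):
        cfg = SimulationConfig(
            n_genes=4, n_target_species=2, seed=3,
            scenario_mix={"WRONG_FRAME_EXON": 1.0},
        )
        data = generate_study(cfg)
        per_gene = {}
        for l in data.labels:
            if l.scenario != "NONE":
                per_gene[l.gene_id] = l.scenario
        assert len(per_gene) == 4
        assert set(per_gene.values()) == {"WRONG_FRAME_EXON"}

    def test_propagated_hits_four_species(self):
        cfg = SimulationConfig(
            n_genes=3, n_target_species=5, seed=3,
            scenario_mix={"PROPAGATED_4PLUS": 1.0},
        )
        data = generate_study(cfg)
        by_gene = {}
        for l in data.labels:
            if l.scenario == "PROPAGATED_4PLUS":
                by_gene.setdefault(l.gene_id, []).append(l.species)
        assert len(by_gene) == 3
        assert all(len(v) == 4 for v in by_gene.values())

    def test_bundle_byte_identical_under_seed(self, tmp_path):
        cfg = SimulationConfig(
            n_genes=4, n_target_species=2, seed=11,
            scenario_mix={"WRONG_FRAME_EXON": 0.5},
        )
        digests = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            paths = simulate_study(cfg, out)
            h = hashlib.sha256()
            for p in sorted(Path(out).iterdir()):
                h.update(p.name.encode() + p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]
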