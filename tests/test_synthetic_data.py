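"""Simulator: genome validity, determinism, composition and estimator recovery."""

import json
import math

import numpy as np
import pytest

import mitocomp as mc
from mitocomp.codon_stats import VERTEBRATE_MITO, split_codons
from mitocomp.synthetic_data import SimConfig, evolve_rna_alignment

from conftest import random_sense_cds


class TestSimConfig:
    def test_bad_composition_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(composition_bias={"A": 10, "C": 10, "G": 10, "T": 10})

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(omega_per_gene={"ND1": 0.0})

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(branch_length=-0.1)


class TestGenerateMitogenome:
    def test_template_structure_reproduced(self, sim_genome):
        assert len(sim_genome) == 16723
        assert mc.strand_census(sim_genome.table)[:2] == (28, 9)
        assert mc.validate_avian_order(sim_genome.table).is_ancestral_avian

    def test_all_pcgs_are_valid_orfs(self, sim_genome):
        for feat in sim_genome.table.by_category("PCG"):
            cds = mc.extract_gene_sequence(sim_genome, feat)
            codons, remnant = split_codons(cds)
            assert codons[0] in VERTEBRATE_MITO.start_codons
            internal = codons[1:] if remnant else codons[1:-1]
            assert not any(VERTEBRATE_MITO.is_stop(c) for c in internal), feat.name
            if remnant:
                assert remnant in ("T", "TA")
            else:
                assert VERTEBRATE_MITO.is_stop(codons[-1])

    def test_truncated_stops_on_configured_genes(self, sim_genome):
        for name, remnant in (("ND2", "TA"), ("COX3", "T"), ("ND4", "T")):
            cds = mc.extract_gene_sequence(sim_genome, sim_genome.table.get(name))
            rep = mc.detect_start_stop(cds)
            assert rep.stop_is_truncated and rep.stop_token == remnant

    def test_gtg_starts_follow_template(self, sim_genome):
        for name in ("COX1", "ND2"):
            cds = mc.extract_gene_sequence(sim_genome, sim_genome.table.get(name))
            assert mc.detect_start_stop(cds).start_codon == "GTG"

    def test_determinism_same_seed(self):
        g1 = mc.generate_mitogenome(SimConfig(seed=9))
        g2 = mc.generate_mitogenome(SimConfig(seed=9))
        assert g1.sequence == g2.sequence

    def test_different_seed_differs(self):
        g1 = mc.generate_mitogenome(SimConfig(seed=9))
        g2 = mc.generate_mitogenome(SimConfig(seed=10))
        assert g1.sequence != g2.sequence

    def test_composition_recovery_uniform_100kb(self):
        cfg = SimConfig(seed=2, genome_length_target=100_000,
                        composition_bias={"A": 25, "C": 25, "G": 25, "T": 25})
        comp = mc.base_composition(mc.generate_mitogenome(cfg).sequence)
        for b in "acgt":
            assert abs(comp.pct(b) - 25.0) < 1.0

    def test_biased_composition_recovery(self):
        cfg = SimConfig(seed=3, genome_length_target=100_000)
        comp = mc.base_composition(mc.generate_mitogenome(cfg).sequence)
        # D-loop dominates at this length, so bias is recovered within ~1%
        for b, target in (("a", 29.63), ("c", 32.88), ("g", 14.73), ("t", 22.75)):
            assert abs(comp.pct(b) - target) < 1.5

    def test_infeasible_length_rejected(self):
        with pytest.raises(ValueError):
            mc.generate_mitogenome(SimConfig(genome_length_target=15_000))


class TestEvolveAlignment:
    def test_zero_branch_length_identity(self):
        rng = np.random.default_rng(1)
        root = random_sense_cds(50, rng)
        cfg = SimConfig(seed=1, n_taxa=4, branch_length=0.0, omega_per_gene={"g": 0.1})
        aln = mc.evolve_alignment(root, cfg, "g")
        assert all(row == root for row in aln.rows)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        root = random_sense_cds(50, rng)
        cfg = SimConfig(seed=5, n_taxa=4, branch_length=0.1, omega_per_gene={"g": 0.2})
        a1 = mc.evolve_alignment(root, cfg, "g")
        a2 = mc.evolve_alignment(root, cfg, "g")
        assert a1.rows == a2.rows

    def test_tiny_omega_changes_no_amino_acid(self):
        rng = np.random.default_rng(3)
        root = random_sense_cds(300, rng)
        cfg = SimConfig(seed=3, n_taxa=6, branch_length=0.08,
                        omega_per_gene={"g": 1e-9})
        aln = mc.evolve_alignment(root, cfg, "g")
        # every observed difference is synonymous: translations are untouched
        proteins = {
            "".join(VERTEBRATE_MITO.codon_to_aa[row[i:i + 3]]
                    for i in range(0, len(row), 3))
            for row in aln.rows
        }
        assert len(proteins) == 1
        s = mc.gene_divergence_summary(aln)
        assert s.ks > 0
        # pathway averaging leaves a small residual Ka; the ratio stays tiny
        assert s.ka_ks < 0.05

    def test_no_stops_ever_appear(self):
        rng = np.random.default_rng(4)
        root = random_sense_cds(100, rng)
        cfg = SimConfig(seed=4, n_taxa=8, branch_length=0.3, omega_per_gene={"g": 0.5})
        aln = mc.evolve_alignment(root, cfg, "g")
        for row in aln.rows:
            codons, _ = split_codons(row)
            assert not any(VERTEBRATE_MITO.is_stop(c) for c in codons)

    def test_supplied_tree_topology(self):
        rng = np.random.default_rng(6)
        root = random_sense_cds(60, rng)
        cfg = SimConfig(seed=6, omega_per_gene={"g": 0.2},
                        tree_newick="((A:0.02,B:0.02):0.05,(C:0.02,D:0.02):0.05);")
        aln = mc.evolve_alignment(root, cfg, "g")
        assert sorted(aln.taxa) == ["A", "B", "C", "D"]
        d = {t: r for t, r in zip(aln.taxa, aln.rows)}
        diff = lambda x, y: sum(a != b for a, b in zip(d[x], d[y]))
        # sister pairs are closer than cross pairs
        assert diff("A", "B") < diff("A", "C")

    def test_missing_omega_is_error(self):
        with pytest.raises(KeyError):
            mc.evolve_alignment("ATGGCTGCT", SimConfig(omega_per_gene={}), "nope")


class TestPiCalibration:
    def test_star_tree_pairwise_distance_near_2b(self):
        rng = np.random.default_rng(8)
        cfg = SimConfig(seed=8, n_taxa=10, branch_length=0.01)
        root = "".join(rng.choice(list("ACGT"), size=5000, p=cfg.base_probs))
        aln = evolve_rna_alignment(root, cfg, "neutral")
        pi = mc.nucleotide_diversity(aln)
        # expected pairwise divergence 2b in the small-b regime; 3 SE band
        se = math.sqrt(0.02 * 0.98 / 5000) / math.sqrt(5)
        assert abs(pi - 0.02) < 3 * se + 0.0005


class TestStudyFixture:
    def test_bundle_contents(self, small_fixture):
        assert len(small_fixture.genomes) == 6
        assert len(small_fixture.alignments) == 15  # 13 PCGs + 2 rRNAs
        assert set(small_fixture.manifest["omega_per_gene"]) == {
            f.name for f in small_fixture.root.table.by_category("PCG")
        }

    def test_genomes_are_annotated_and_extractable(self, small_fixture):
        g = small_fixture.genomes[0]
        assert len(g) == small_fixture.root.table.genome_length
        for feat in g.table.by_category("PCG"):
            cds = mc.extract_gene_sequence(g, feat)
            codons, remnant = split_codons(cds)
            internal = codons[1:] if remnant else codons[1:-1]
            assert not any(VERTEBRATE_MITO.is_stop(c) for c in internal), feat.name

    def test_alignment_rows_match_genome_genes(self, small_fixture):
        aln = small_fixture.alignments["COX2"]
        for taxon, row in zip(aln.taxa, aln.rows):
            genome = next(g for g in small_fixture.genomes if g.id == taxon)
            cds = mc.extract_gene_sequence(genome, genome.table.get("COX2"))
            assert cds.startswith(row)  # row excludes the invariant terminator

    def test_two_taxon_mode(self):
        fx = mc.generate_study_fixture(SimConfig(seed=12, n_taxa=2))
        s = mc.gene_divergence_summary(fx.alignments["ND1"])
        assert s.n_taxa == 2

    def test_fixture_files_deterministic(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        mc.generate_study_fixture(SimConfig(seed=13, n_taxa=3), outdir=str(d1))
        mc.generate_study_fixture(SimConfig(seed=13, n_taxa=3), outdir=str(d2))
        f1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        f2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert f1 == f2
        for rel in f1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        truth = json.loads((d1 / "truth.json").read_text())
        assert truth["seed"] == 13
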