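"""Nucleotide diversity, variable sites, and Nei-Gojobori Ka/Ks against oracles."""

import math

import numpy as np
import pytest

import mitocomp as mc
from mitocomp.divergence import nei_gojobori
from mitocomp.synthetic_data import SimConfig

from conftest import oracle_ng, oracle_pi, random_sense_cds


def _aln(rows, gene="g", codon_aware=False):
    taxa = [f"t{i}" for i in range(len(rows))]
    return mc.GeneAlignment(gene=gene, taxa=taxa, rows=rows, codon_aware=codon_aware)


class TestAlignmentContainer:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            _aln(["ACGT", "ACG"])

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError):
            mc.GeneAlignment(gene="g", taxa=["a", "a"], rows=["ACGT", "ACGT"])

    def test_fasta_roundtrip(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text(">tax1\nACGTAC\n>tax2\nACCTAC\n")
        aln = mc.GeneAlignment.from_fasta(str(p), gene="g")
        assert aln.taxa == ["tax1", "tax2"]
        assert aln.codon_aware  # length multiple of 3


class TestNucleotideDiversity:
    def test_identical_rows(self):
        assert mc.nucleotide_diversity(_aln(["ACGTACGTAC"] * 2)) == 0.0

    def test_one_difference_in_ten(self):
        assert mc.nucleotide_diversity(_aln(["ACGTACGTAC", "ACGTACGTAA"])) == pytest.approx(0.1)

    def test_matches_brute_force_oracle_on_random_alignment(self):
        rng = np.random.default_rng(17)
        rows = ["".join(rng.choice(list("ACGT-"), size=30, p=[0.23] * 4 + [0.08]))
                for _ in range(4)]
        aln = _aln(rows)
        assert mc.nucleotide_diversity(aln) == pytest.approx(oracle_pi(rows))

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(5)]
        pi1 = mc.nucleotide_diversity(_aln(rows))
        pi2 = mc.nucleotide_diversity(_aln(rows[::-1]))
        assert pi1 == pytest.approx(pi2)

    def test_all_gapped_columns_give_nan(self):
        assert math.isnan(mc.nucleotide_diversity(_aln(["---", "AC-"])))

    def test_pairwise_deletion_mode(self):
        # column 0 unusable only for the pair involving row 2
        rows = ["ACGT", "ACGA", "-CGT"]
        pi_pair = mc.nucleotide_diversity(_aln(rows), deletion="pairwise")
        # pairs: (0,1): 1/4 diff; (0,2): 0/3; (1,2): 1/3
        assert pi_pair == pytest.approx((0.25 + 0.0 + 1 / 3) / 3)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            mc.nucleotide_diversity(_aln(["ACGT"]))


class TestVariableSites:
    def test_no_variation(self):
        assert mc.variable_sites(_aln(["ACGT", "ACGT"])) == (0, 0.0)

    def test_all_usable_columns_variable(self):
        count, pct = mc.variable_sites(_aln(["AAAA", "CCCC"]))
        assert (count, pct) == (4, 100.0)

    def test_matches_column_scan_oracle(self):
        rng = np.random.default_rng(23)
        rows = ["".join(rng.choice(list("ACGT-"), size=60, p=[0.23] * 4 + [0.08]))
                for _ in range(5)]
        count, pct = mc.variable_sites(_aln(rows))
        usable = [i for i in range(60) if all(r[i] in "ACGT" for r in rows)]
        expect = sum(1 for i in usable if len({r[i] for r in rows}) > 1)
        assert count == expect
        assert pct == pytest.approx(100 * expect / len(usable))


class TestNeiGojobori:
    def test_identical_sequences(self):
        cds = "ATGGCTGCTGCA"
        res = nei_gojobori(cds, cds)
        assert res.ka == 0.0 and res.ks == 0.0
        assert math.isnan(res.ka_ks)  # 0/0

    def test_single_synonymous_change_matches_oracle(self):
        a = "GCT" * 100
        b = "GCC" + "GCT" * 99
        res = nei_gojobori(a, b)
        exp = oracle_ng(a, b)
        assert res.ka == 0.0
        assert res.ks == pytest.approx(exp["ks"])
        assert res.s_sites == pytest.approx(exp["S"])
        assert res.n_sites == pytest.approx(exp["N"])

    def test_single_nonsynonymous_change_matches_oracle(self):
        a = "GCT" * 100
        b = "GTT" + "GCT" * 99
        res = nei_gojobori(a, b)
        exp = oracle_ng(a, b)
        assert res.ks == 0.0
        assert res.ka == pytest.approx(exp["ka"])

    def test_multi_difference_codons_match_pathway_oracle(self):
        rng = np.random.default_rng(11)
        a = random_sense_cds(60, rng)
        b_codons = [a[i:i + 3] for i in range(0, len(a), 3)]
        # mutate ~25% of codons at 1-3 positions, avoiding stops
        sense = [c for c in mc.codon_stats.ALL_CODONS
                 if mc.VERTEBRATE_MITO.codon_to_aa[c] != "*"]
        for k in rng.choice(len(b_codons), size=15, replace=False):
            b_codons[k] = str(rng.choice(sense))
        b = "".join(b_codons)
        res = nei_gojobori(a, b)
        exp = oracle_ng(a, b)
        assert res.sd == pytest.approx(exp["sd"])
        assert res.nd == pytest.approx(exp["nd"])
        assert res.s_sites == pytest.approx(exp["S"])
        assert res.ka == pytest.approx(exp["ka"])
        assert res.ks == pytest.approx(exp["ks"])

    def test_site_counts_partition_three_per_codon(self):
        rng = np.random.default_rng(5)
        a = random_sense_cds(50, rng)
        res = nei_gojobori(a, a)
        assert res.n_sites + res.s_sites == pytest.approx(3 * res.n_codons)

    def test_trailing_stop_trimmed(self):
        res = nei_gojobori("ATGGCTTAA", "ATGGCTTAA")
        assert res.n_codons == 2

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori("ATGTAAGCT", "ATGTAAGCT")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori("ATGG", "ATGG")

    def test_saturation_gives_nan_not_clamp(self):
        # maximally divergent third positions: force ps >= 3/4 artificially
        a = "GGT" * 30
        b = "GGC" * 10 + "GGA" * 10 + "GGG" * 10
        res = nei_gojobori(a, b)
        # 20 synonymous diffs over ~10 syn sites
        assert math.isnan(res.ks)
        assert math.isnan(res.ka_ks)


class TestGeneDivergenceSummary:
    def test_two_taxon_summary_equals_single_pairwise(self):
        rng = np.random.default_rng(9)
        a = random_sense_cds(80, rng)
        b_codons = [a[i:i + 3] for i in range(0, len(a), 3)]
        sense = [c for c in mc.codon_stats.ALL_CODONS
                 if mc.VERTEBRATE_MITO.codon_to_aa[c] != "*"]
        for k in rng.choice(len(b_codons), size=8, replace=False):
            b_codons[k] = str(rng.choice(sense))
        b = "".join(b_codons)
        s = mc.gene_divergence_summary(_aln([a, b], codon_aware=True))
        pair = nei_gojobori(a, b)
        assert s.ka == pytest.approx(pair.ka)
        assert s.ks == pytest.approx(pair.ks)

    def test_identical_rows_pi_zero_ratio_undefined(self):
        cds = "ATGGCTGCAGCC" * 5
        s = mc.gene_divergence_summary(_aln([cds, cds], codon_aware=True))
        assert s.pi == 0.0
        assert math.isnan(s.ka_ks)
        assert s.purifying is None

    def test_purifying_band_under_simulation(self):
        rng = np.random.default_rng(77)
        root = random_sense_cds(500, rng)
        cfg = SimConfig(seed=77, n_taxa=20, branch_length=0.05,
                        omega_per_gene={"g": 0.1})  # kappa 2: known mild downward bias
        aln = mc.evolve_alignment(root, cfg, "g", rng=rng)
        s = mc.gene_divergence_summary(aln)
        assert 0.05 <= s.ka_ks <= 0.2
        assert s.purifying

    def test_rrna_alignment_skips_kaks(self, small_fixture):
        s = mc.gene_divergence_summary(small_fixture.alignments["rrnS"])
        assert math.isnan(s.ka)
        assert not math.isnan(s.pi)

    def test_pi_invariant_to_taxon_relabeling(self, small_fixture):
        aln = small_fixture.alignments["ND2"]
        relabeled = mc.GeneAlignment(
            gene=aln.gene, taxa=[f"x{i}" for i in range(aln.n_taxa)],
            rows=list(aln.rows), codon_aware=True,
        )
        assert mc.nucleotide_diversity(relabeled) == pytest.approx(
            mc.nucleotide_diversity(aln)
        )
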