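"""Shared fixtures and independent oracles for the test suite.

The Nei-Gojobori oracle here deliberately re-derives synonymous/nonsynonymous
site and difference counts by brute-force enumeration, translating through
Biopython's ``Seq.translate`` rather than through the package's own genetic
code tables, so that agreement between the two is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

import mitocomp as mc
from mitocomp.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def indicus_table() -> mc.GeneTable:
    return mc.load_bundled_table("indicus")


@pytest.fixture(scope="session")
def cyanurus_table() -> mc.GeneTable:
    return mc.load_bundled_table("cyanurus")


@pytest.fixture(scope="session")
def sim_genome() -> mc.Mitogenome:
    return mc.generate_mitogenome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """A 6-taxon synthetic study: genomes + per-gene alignments + truth."""
    return mc.generate_study_fixture(SimConfig(seed=4, n_taxa=6))


@pytest.fixture
def toy_genome() -> mc.Mitogenome:
    table = mc.GeneTable(
        features=[
            mc.GeneFeature("geneA", 2, 4, "+", category="other"),
            mc.GeneFeature("geneB", 2, 4, "-", category="other"),
            mc.GeneFeature("wrap", 6, 2, "+", category="other"),
        ],
        genome_length=6,
    )
    return mc.Mitogenome(id="toy", sequence="AAACGT", table=table)


# ---------------------------------------------------------------------------
# Independent oracles


def translate2(codon: str) -> str:
    """Amino acid of a codon under the vertebrate mitochondrial code, via Biopython."""
    return str(Seq(codon).translate(table=2))


def oracle_ng_sites(codon: str) -> tuple[float, float]:
    """(syn, nonsyn) site counts of one codon by enumerating all 9 mutations.

    Mutations to stop codons are excluded from each position's denominator;
    each position contributes one site split between the two classes.
    """
    aa = translate2(codon)
    assert aa != "*"
    s = 0.0
    for pos in range(3):
        outcomes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            mut_aa = translate2(mut)
            if mut_aa == "*":
                continue
            outcomes.append(mut_aa == aa)
        if outcomes:
            s += sum(outcomes) / len(outcomes)
    return s, 3.0 - s


def oracle_ng_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaging stop-free pathways."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in itertools.permutations(diff):
        cur, s, n, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if translate2(nxt) == "*" and nxt != c2:
                ok = False
            if translate2(nxt) == translate2(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        (valid if ok else blocked).append((s, n))
    paths = valid or blocked
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_ng(cds1: str, cds2: str) -> dict:
    """Full brute-force Nei-Gojobori computation for two coding sequences."""
    codons1 = [cds1[i : i + 3] for i in range(0, len(cds1), 3)]
    codons2 = [cds2[i : i + 3] for i in range(0, len(cds2), 3)]
    S = N = sd = nd = 0.0
    for a, b in zip(codons1, codons2):
        s1, n1 = oracle_ng_sites(a)
        s2, n2 = oracle_ng_sites(b)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        ds, dn = oracle_ng_diffs(a, b)
        sd += ds
        nd += dn

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {
        "S": S, "N": N, "sd": sd, "nd": nd,
        "ks": jc(sd / S) if S else 0.0,
        "ka": jc(nd / N) if N else 0.0,
    }


def oracle_pi(rows: list[str]) -> float:
    """All-pairs, all-columns brute-force nucleotide diversity (complete deletion)."""
    usable = [
        i
        for i in range(len(rows[0]))
        if all(r[i] in "ACGT" for r in rows)
    ]
    pairs = list(itertools.combinations(range(len(rows)), 2))
    total = 0.0
    for i, j in pairs:
        diffs = sum(1 for k in usable if rows[i][k] != rows[j][k])
        total += diffs / len(usable)
    return total / len(pairs)


def random_sense_cds(n_codons: int, rng: np.random.Generator, start: str = "ATG") -> str:
    """A stop-free coding sequence of ``n_codons`` codons."""
    sense = [c for c in mc.codon_stats.ALL_CODONS if translate2(c) != "*"]
    return start + "".join(rng.choice(sense, size=n_codons - 1))
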