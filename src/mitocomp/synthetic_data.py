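"""Synthetic annotated mitogenomes and codon-model alignments with known truth.

The generator emulates the structure of a typical passerine mitogenome — a
~16-17 kb circular molecule carrying 13 protein-coding genes, 22 tRNAs, 2
rRNAs and one control region in the ancestral avian order, with a C/A-biased
base composition, GTG starts on COX1/ND2 and truncated stop codons on
ND2/COX3/ND4 — and evolves multi-taxon per-gene alignments under a codon
substitution model with a known nonsynonymous/synonymous rate ratio (omega)
per gene, so that every estimator downstream can be checked against ground
truth.

Substitution is simulated site-by-site with exponential waiting times
(Gillespie): at each codon site, a candidate single-nucleotide change is
accepted with relative rate kappa (transition) or 1 (transversion), times
omega when it changes the amino acid, and 0 when it would create a stop.
Branch lengths are calibrated to expected substitutions per nucleotide site
against the root sequence's mean rate.  Non-coding regions and rRNAs evolve
under an HKY nucleotide process with the genome's stationary composition.
No indels are simulated, so evolved homologous regions are alignments as-is.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import dendropy
import numpy as np

from .codon_stats import GeneticCode, VERTEBRATE_MITO, split_codons
from .divergence import GeneAlignment, _codon_index, _IDX_TO_CODON
from .genome_model import (
    GeneFeature,
    GeneTable,
    Mitogenome,
    extract_gene_sequence,
    gene_length,
    load_bundled_table,
    reverse_complement,
    write_feature_table,
)

__all__ = [
    "SimConfig",
    "StudyFixture",
    "generate_mitogenome",
    "evolve_alignment",
    "evolve_rna_alignment",
    "generate_study_fixture",
]

#: Default per-gene omega, a purifying-selection staircase with ATP8 fastest
#: and COX1 slowest, the ordering typical of passerine mitogenomes.
DEFAULT_OMEGA = {
    "COX1": 0.015, "COX2": 0.04, "COX3": 0.045, "Cytb": 0.06,
    "ND1": 0.07, "ND4L": 0.08, "ND3": 0.09, "ND4": 0.095, "ATP6": 0.10,
    "ND5": 0.105, "ND6": 0.11, "ND2": 0.12, "ATP8": 0.135,
}

#: Whole-genome base composition of a C/A-biased passerine mitogenome (%).
DEFAULT_COMPOSITION = {"A": 29.63, "C": 32.88, "G": 14.73, "T": 22.75}

_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"


@dataclass
class SimConfig:
    """Knobs of the simulator; defaults describe the study conditions.

    ``branch_length`` is the root-to-tip length of the default star tree in
    expected substitutions per nucleotide site (pairwise divergence is twice
    that); ``tree_newick``, when given, overrides the star tree and must carry
    edge lengths on the same scale.
    """

    seed: int = 0
    genome_length_target: int = 16723
    composition_bias: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    gene_template: Optional[GeneTable] = None  # default: bundled T. indicus layout
    n_taxa: int = 25
    branch_length: float = 0.04
    tree_newick: Optional[str] = None
    omega_per_gene: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    kappa: float = 2.0
    truncated_stop_genes: frozenset[str] = frozenset({"ND2", "COX3", "ND4"})
    #: rRNA/tRNA genes evolve at this fraction of the neutral nucleotide rate,
    #: reflecting secondary-structure constraint; it places rRNA diversity at
    #: the bottom of the per-gene range, where it sits in real mitogenome panels.
    rna_rate_scale: float = 0.3
    code: GeneticCode = VERTEBRATE_MITO

    def __post_init__(self) -> None:
        total = sum(self.composition_bias.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"composition percentages sum to {total}, expected 100")
        if any(w <= 0 for w in self.omega_per_gene.values()):
            raise ValueError("omega must be positive for every gene")
        if self.branch_length < 0:
            raise ValueError("branch lengths must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.rna_rate_scale <= 0:
            raise ValueError("rna_rate_scale must be positive")

    @property
    def base_probs(self) -> np.ndarray:
        """Stationary base probabilities in A,C,G,T order."""
        return np.array([self.composition_bias[b] for b in _BASES]) / sum(
            self.composition_bias.values()
        )

    def template(self) -> GeneTable:
        return self.gene_template or load_bundled_table("indicus")


# ---------------------------------------------------------------------------
# Genome generation


def _sense_codon_probs(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    """Sense codons and sampling probabilities under the composition bias."""
    p = dict(zip(_BASES, cfg.base_probs))
    codons, probs = [], []
    for codon in _IDX_TO_CODON:
        if cfg.code.codon_to_aa[codon] == "*":
            continue
        w = p[codon[0]] * p[codon[1]] * p[codon[2]]
        codons.append(codon)
        probs.append(w)
    total = float(np.sum(probs))
    if total <= 0:
        raise ValueError("composition bias leaves no sense codon with positive probability")
    return codons, np.asarray(probs) / total


def _random_bases(n: int, cfg: SimConfig, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=n, p=cfg.base_probs))


def _generate_cds(feat: GeneFeature, length: int, cfg: SimConfig,
                  rng: np.random.Generator) -> str:
    """A valid ORF of the requested length: start codon, sense interior, stop."""
    remnant_len = length % 3
    truncated = feat.name in cfg.truncated_stop_genes or remnant_len > 0
    start = feat.start_codon or "ATG"
    if start not in cfg.code.start_codons:
        raise ValueError(f"{feat.name}: {start!r} is not a start codon of code {cfg.code.id}")
    stop = feat.stop_codon if (feat.stop_codon and len(feat.stop_codon) == 3) else "TAA"
    if stop not in cfg.code.stop_codons:
        raise ValueError(f"{feat.name}: {stop!r} is not a stop codon of code {cfg.code.id}")
    n_codons = length // 3
    n_internal = n_codons - 1 - (0 if truncated and remnant_len else 1)
    if n_internal < 0:
        raise ValueError(f"{feat.name}: length {length} too short for an ORF")
    codons, probs = _sense_codon_probs(cfg)
    body = "".join(rng.choice(codons, size=n_internal, p=probs))
    if truncated and remnant_len:
        return start + body + "TA"[:remnant_len]
    return start + body + stop


def generate_mitogenome(cfg: SimConfig, rng: Optional[np.random.Generator] = None,
                        genome_id: str = "sim") -> Mitogenome:
    """Generate one annotated circular mitogenome from the template layout.

    Gene order, lengths, strands and start/stop codon choices follow the
    template table; intergenic spacing reuses the template's gaps (clamped at
    zero, so template overlaps become abutting genes), and the control region
    absorbs whatever length is needed to reach ``genome_length_target``.
    Light-strand genes are generated in coding orientation and stored
    reverse-complemented, so extraction returns valid ORFs.  Deterministic for
    a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    template = cfg.template()
    L_tpl = template.genome_length
    feats = list(template.features)
    if not feats:
        raise ValueError("gene template is empty")
    lengths = {f.name: gene_length(f, L_tpl) for f in feats}
    gaps: list[int] = [feats[0].start - 1]
    for prev, nxt in zip(feats, feats[1:]):
        gaps.append(max(nxt.start - prev.end - 1, 0))

    fixed = sum(lengths[f.name] for f in feats if f.category != "control-region")
    fixed += sum(gaps)
    n_cr = sum(1 for f in feats if f.category == "control-region")
    if n_cr != 1:
        raise ValueError("template must contain exactly one control region")
    cr_len = cfg.genome_length_target - fixed
    if cr_len < 50:
        raise ValueError(
            f"genome_length_target {cfg.genome_length_target} leaves only {cr_len} bp "
            "for the control region"
        )

    parts: list[str] = []
    new_feats: list[GeneFeature] = []
    pos = 1
    for feat, gap in zip(feats, gaps):
        if gap:
            parts.append(_random_bases(gap, cfg, rng))
            pos += gap
        L = cr_len if feat.category == "control-region" else lengths[feat.name]
        if feat.category == "PCG":
            seq = _generate_cds(feat, L, cfg, rng)
        else:
            seq = _random_bases(L, cfg, rng)
        if feat.strand == "-":
            seq = reverse_complement(seq)
        parts.append(seq)
        new_feats.append(
            replace(feat, start=pos, end=pos + L - 1)
        )
        pos += L
    sequence = "".join(parts)
    table = GeneTable(features=new_feats, genome_length=len(sequence))
    return Mitogenome(id=genome_id, sequence=sequence, table=table)


# ---------------------------------------------------------------------------
# Substitution simulation


@lru_cache(maxsize=None)
def _codon_model(code_id: int, kappa: float, omega: float):
    """Per-codon neighbor lists, rates, totals and cumulative choice probs."""
    code = GeneticCode.from_ncbi(code_id)
    neighbors = np.zeros((64, 9), dtype=np.int64)
    rates = np.zeros((64, 9))
    for codon in _IDX_TO_CODON:
        i = _codon_index(codon)
        if code.codon_to_aa[codon] == "*":
            continue
        k = 0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                rate = kappa if _TS_PARTNER[codon[pos]] == b else 1.0
                aa_from, aa_to = code.codon_to_aa[codon], code.codon_to_aa[mut]
                if aa_to == "*":
                    rate = 0.0
                elif aa_to != aa_from:
                    rate *= omega
                neighbors[i, k] = _codon_index(mut)
                rates[i, k] = rate
                k += 1
    totals = rates.sum(axis=1)
    cum = np.cumsum(rates, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = cum / totals[:, None]
    return neighbors, totals, cum


@lru_cache(maxsize=None)
def _hky_model(pi: tuple[float, float, float, float], kappa: float):
    """HKY rate structure over A,C,G,T, normalized to 1 substitution/site/unit."""
    neighbors = np.zeros((4, 3), dtype=np.int64)
    rates = np.zeros((4, 3))
    for i, bi in enumerate(_BASES):
        k = 0
        for j, bj in enumerate(_BASES):
            if i == j:
                continue
            rate = pi[j] * (kappa if _TS_PARTNER[bi] == bj else 1.0)
            neighbors[i, k] = j
            rates[i, k] = rate
            k += 1
    totals = rates.sum(axis=1)
    mu = float(np.dot(pi, totals))  # mean rate at stationarity
    totals = totals / mu
    cum = np.cumsum(rates, axis=1)
    cum = cum / cum[:, -1][:, None]
    return neighbors, totals, cum


def _evolve_sites(states: np.ndarray, duration: float, neighbors: np.ndarray,
                  totals: np.ndarray, cum: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Evolve independent sites for ``duration`` time units; returns new states."""
    out = states.copy()
    if duration <= 0 or len(out) == 0:
        return out
    waits = rng.exponential(size=len(out)) / totals[out]
    for i in np.nonzero(waits < duration)[0]:
        t = waits[i]
        s = out[i]
        while t < duration:
            s = neighbors[s, np.searchsorted(cum[s], rng.random())]
            t += rng.exponential() / totals[s]
        out[i] = s
    return out


def _tree_or_star(cfg: SimConfig):
    """Yield (taxon_label, list of branch lengths root->tip) traversal plan."""
    if cfg.tree_newick:
        tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick")
        return tree
    return None


def _evolve_over_tree(root_states: np.ndarray, cfg: SimConfig, model,
                      rng: np.random.Generator,
                      time_scale: float) -> tuple[list[str], list[np.ndarray]]:
    """Evolve a state vector down the configured tree (or star) to every leaf."""
    neighbors, totals, cum = model
    taxa: list[str] = []
    leaves: list[np.ndarray] = []
    tree = _tree_or_star(cfg)
    if tree is None:
        width = len(str(cfg.n_taxa))
        for k in range(cfg.n_taxa):
            taxa.append(f"taxon_{k + 1:0{width}d}")
            leaves.append(
                _evolve_sites(root_states, cfg.branch_length * time_scale,
                              neighbors, totals, cum, rng)
            )
        return taxa, leaves

    def walk(node, states):
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            child_states = _evolve_sites(states, b * time_scale,
                                         neighbors, totals, cum, rng)
            if child.is_leaf():
                label = child.taxon.label if child.taxon else f"leaf_{len(taxa) + 1}"
                taxa.append(label.replace(" ", "_"))
                leaves.append(child_states)
            else:
                walk(child, child_states)

    walk(tree.seed_node, root_states)
    return taxa, leaves


def evolve_alignment(root_cds: str, cfg: SimConfig, gene: str,
                     rng: Optional[np.random.Generator] = None) -> GeneAlignment:
    """Evolve a coding sequence into a multi-taxon alignment under the codon model.

    The root's trailing truncated remnant and terminal stop codon, if present,
    are trimmed before evolution (terminators are invariant under the model,
    which forbids stops).  Omega comes from ``cfg.omega_per_gene``; the output
    is gap-free and codon-aware, and deterministic per seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    omega = cfg.omega_per_gene.get(gene)
    if omega is None:
        raise KeyError(f"no omega configured for gene {gene!r}")
    if omega <= 0:
        raise ValueError("omega must be positive")
    codons, _ = split_codons(root_cds)
    while codons and cfg.code.is_stop(codons[-1]):
        codons = codons[:-1]
    if not codons:
        raise ValueError("root CDS has no sense codons")
    states = np.array([_codon_index(c) for c in codons])
    model = _codon_model(cfg.code.id, cfg.kappa, omega)
    _, totals, _ = model
    if (totals[states] <= 0).any():
        raise ValueError("root CDS contains a stop codon")
    # calibrate: branch length b = expected substitutions per nucleotide site,
    # i.e. 3b expected codon events, against the root's mean total rate
    mean_rate = float(totals[states].mean())
    time_scale = 3.0 / mean_rate
    taxa, leaves = _evolve_over_tree(states, cfg, model, rng, time_scale)
    rows = ["".join(_IDX_TO_CODON[s] for s in leaf) for leaf in leaves]
    return GeneAlignment(gene=gene, taxa=taxa, rows=rows, codon_aware=True)


def evolve_rna_alignment(root_seq: str, cfg: SimConfig, gene: str,
                         rng: Optional[np.random.Generator] = None,
                         rate_scale: float = 1.0) -> GeneAlignment:
    """Evolve a non-coding/rRNA sequence under an HKY nucleotide process.

    ``rate_scale`` multiplies the branch lengths; structural RNAs are evolved
    at ``cfg.rna_rate_scale`` by the fixture generator.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    seq = root_seq.upper()
    if set(seq) - set(_BASES):
        raise ValueError("root sequence must be unambiguous A/C/G/T")
    states = np.array([_BASES.index(b) for b in seq])
    model = _hky_model(tuple(cfg.base_probs), cfg.kappa)
    taxa, leaves = _evolve_over_tree(states, cfg, model, rng, time_scale=rate_scale)
    rows = ["".join(_BASES[s] for s in leaf) for leaf in leaves]
    return GeneAlignment(gene=gene, taxa=taxa, rows=rows, codon_aware=False)


# ---------------------------------------------------------------------------
# End-to-end fixture


@dataclass
class StudyFixture:
    """A complete synthetic study: genomes, per-gene alignments, and the truth."""

    root: Mitogenome
    genomes: list[Mitogenome]
    alignments: dict[str, GeneAlignment]  # 13 PCGs + 2 rRNAs
    manifest: dict


def generate_study_fixture(cfg: SimConfig, outdir: Optional[str] = None) -> StudyFixture:
    """Generate a root genome, evolve every region across taxa, assemble genomes.

    Mirrors a multi-genome family panel: one annotated genome per taxon plus
    per-gene alignments for the 13 protein-coding genes (codon model, known
    omega) and the 2 rRNAs (HKY), and a JSON-able manifest of the simulation
    truth.  With ``outdir`` set, writes per-genome gene-table TSV + FASTA,
    per-gene aligned FASTA, and ``truth.json``.
    """
    rng = np.random.default_rng(cfg.seed)
    root = generate_mitogenome(cfg, rng, genome_id="root")
    keep_terminator: dict[str, str] = {}
    region_rows: dict[str, list[str]] = {}
    taxa: list[str] = []
    alignments: dict[str, GeneAlignment] = {}

    for feat in root.table.features:
        seq = extract_gene_sequence(root, feat)
        if feat.category == "PCG":
            n_keep = len(seq) - len(seq) % 3
            codons = [seq[i : i + 3] for i in range(0, n_keep, 3)]
            tail = seq[n_keep:]
            if codons and cfg.code.is_stop(codons[-1]):
                tail = codons[-1] + tail
            core = seq[: len(seq) - len(tail)]
            keep_terminator[feat.name] = tail
            aln = evolve_alignment(core, cfg, feat.name, rng)
            alignments[feat.name] = aln
            region_rows[feat.name] = aln.rows
        else:
            scale = cfg.rna_rate_scale if feat.category in ("rRNA", "tRNA") else 1.0
            aln = evolve_rna_alignment(seq, cfg, feat.name, rng, rate_scale=scale)
            if feat.category == "rRNA":
                alignments[feat.name] = aln
            region_rows[feat.name] = aln.rows
        taxa = aln.taxa

    # spacer regions evolve too, so assembled genomes are fully divergent
    spacer_rows: dict[int, list[str]] = {}
    cursor = 1
    for k, feat in enumerate(root.table.features):
        if feat.start > cursor:
            spacer = root.sequence[cursor - 1 : feat.start - 1]
            spacer_rows[k] = evolve_rna_alignment(spacer, cfg, f"spacer_{k}", rng).rows
        cursor = feat.end + 1

    genomes: list[Mitogenome] = []
    for t_idx, taxon in enumerate(taxa):
        parts: list[str] = []
        cursor = 1
        feats: list[GeneFeature] = []
        for k, feat in enumerate(root.table.features):
            if k in spacer_rows:
                parts.append(spacer_rows[k][t_idx])
                cursor = feat.start
            seq = region_rows[feat.name][t_idx]
            if feat.category == "PCG":
                seq += keep_terminator[feat.name]
            if feat.strand == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            feats.append(replace(feat))
            cursor = feat.end + 1
        genomes.append(
            Mitogenome(
                id=taxon,
                sequence="".join(parts),
                table=GeneTable(features=feats, genome_length=root.table.genome_length),
            )
        )

    manifest = {
        "seed": cfg.seed,
        "n_taxa": cfg.n_taxa if cfg.tree_newick is None else len(taxa),
        "tree": cfg.tree_newick or f"star(branch_length={cfg.branch_length})",
        "kappa": cfg.kappa,
        "omega_per_gene": dict(cfg.omega_per_gene),
        "composition_bias": dict(cfg.composition_bias),
        "genome_length": root.table.genome_length,
        "genes": {
            f.name: {"start": f.start, "end": f.end, "strand": f.strand,
                     "category": f.category}
            for f in root.table.features
        },
    }

    fixture = StudyFixture(root=root, genomes=genomes, alignments=alignments,
                           manifest=manifest)
    if outdir is not None:
        _write_fixture(fixture, outdir)
    return fixture


def _write_fixture(fx: StudyFixture, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    aln_dir = os.path.join(outdir, "alignments")
    gen_dir = os.path.join(outdir, "genomes")
    os.makedirs(aln_dir, exist_ok=True)
    os.makedirs(gen_dir, exist_ok=True)
    for gene, aln in fx.alignments.items():
        with open(os.path.join(aln_dir, f"{gene}.fasta"), "w") as fh:
            for taxon, row in zip(aln.taxa, aln.rows):
                fh.write(f">{taxon}\n")
                for i in range(0, len(row), 70):
                    fh.write(row[i : i + 70] + "\n")
    for genome in [fx.root] + fx.genomes:
        with open(os.path.join(gen_dir, f"{genome.id}.fasta"), "w") as fh:
            fh.write(f">{genome.id}\n")
            for i in range(0, len(genome.sequence), 70):
                fh.write(genome.sequence[i : i + 70] + "\n")
        with open(os.path.join(gen_dir, f"{genome.id}.genes.tsv"), "w") as fh:
            fh.write(write_feature_table(genome.table))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(fx.manifest, fh, indent=2)
        fh.write("\n")
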