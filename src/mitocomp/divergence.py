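"""Alignment-based evolution statistics: nucleotide diversity, variable sites,
and Nei-Gojobori Ka/Ks.

Nucleotide diversity (Pi) is the mean, over all unordered sequence pairs in an
alignment, of the proportion of compared sites at which the pair differs.

Ka and Ks follow the counting method of Nei & Gojobori (1986):

* every codon position contributes a synonymous-site fraction equal to the
  proportion of its possible single-nucleotide changes that preserve the
  amino acid, with changes that would create a stop codon excluded from the
  denominator; the three positions of a codon always sum to 3 sites, split
  S + N;
* observed differences between two codons are classified by enumerating all
  minimal single-step substitution pathways between them, discarding pathways
  that pass through a stop codon, and averaging synonymous/nonsynonymous step
  counts over the remaining pathways with equal weight;
* the per-site proportions p_s = Sd/S and p_n = Nd/N are corrected for
  multiple hits with the Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p);
  saturation (p >= 3/4) yields NaN rather than a clamped value.

Ka/Ks < 1 indicates purifying selection, = 1 neutrality, > 1 positive
selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio import SeqIO

from .codon_stats import ALL_CODONS, GeneticCode, VERTEBRATE_MITO

__all__ = [
    "GeneAlignment",
    "DivergenceSummary",
    "NGResult",
    "nucleotide_diversity",
    "variable_sites",
    "nei_gojobori",
    "gene_divergence_summary",
]

_BASE_ORD = {"T": 0, "C": 1, "A": 2, "G": 3}


def _codon_index(codon: str) -> int:
    return 16 * _BASE_ORD[codon[0]] + 4 * _BASE_ORD[codon[1]] + _BASE_ORD[codon[2]]


_IDX_TO_CODON = sorted(ALL_CODONS, key=_codon_index)


@lru_cache(maxsize=None)
def _ng_tables(code_id: int):
    """Precomputed Nei-Gojobori tables for a genetic code.

    Returns ``(syn_sites[64], syn_diff[64,64], nonsyn_diff[64,64], is_stop[64])``.
    Entries involving stop codons are NaN.
    """
    code = GeneticCode.from_ncbi(code_id)
    aa = [code.codon_to_aa[c] for c in _IDX_TO_CODON]
    is_stop = np.array([a == "*" for a in aa])

    syn_sites = np.full(64, np.nan)
    for i, codon in enumerate(_IDX_TO_CODON):
        if is_stop[i]:
            continue
        s = 0.0
        for pos in range(3):
            syn = valid = 0
            for b in "TCAG":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if code.codon_to_aa[mut] == "*":
                    continue  # mutations to stop excluded from the denominator
                valid += 1
                if code.codon_to_aa[mut] == aa[i]:
                    syn += 1
            s += syn / valid if valid else 0.0
        syn_sites[i] = s

    syn_diff = np.full((64, 64), np.nan)
    nonsyn_diff = np.full((64, 64), np.nan)
    for i, c1 in enumerate(_IDX_TO_CODON):
        if is_stop[i]:
            continue
        for j, c2 in enumerate(_IDX_TO_CODON):
            if is_stop[j]:
                continue
            diff_pos = [p for p in range(3) if c1[p] != c2[p]]
            if not diff_pos:
                syn_diff[i, j] = nonsyn_diff[i, j] = 0.0
                continue
            path_syn: list[int] = []
            path_nonsyn: list[int] = []
            blocked_syn: list[int] = []
            blocked_nonsyn: list[int] = []
            for order in itertools.permutations(diff_pos):
                cur = c1
                s = n = 0
                through_stop = False
                for pos in order:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if code.codon_to_aa[nxt] == "*" and nxt != c2:
                        through_stop = True
                    if code.codon_to_aa[nxt] == code.codon_to_aa[cur]:
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                if through_stop:
                    blocked_syn.append(s)
                    blocked_nonsyn.append(n)
                else:
                    path_syn.append(s)
                    path_nonsyn.append(n)
            if not path_syn:  # every pathway crosses a stop; fall back to all
                path_syn, path_nonsyn = blocked_syn, blocked_nonsyn
            syn_diff[i, j] = float(np.mean(path_syn))
            nonsyn_diff[i, j] = float(np.mean(path_nonsyn))
    return syn_sites, syn_diff, nonsyn_diff, is_stop


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class GeneAlignment:
    """One gene's aligned sequences across taxa (gap character ``-``)."""

    gene: str
    taxa: list[str]
    rows: list[str]
    codon_aware: bool = False

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"duplicate taxon ids in alignment {self.gene!r}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows of alignment {self.gene!r} have unequal lengths")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path, gene: str = "", codon_aware: Optional[bool] = None) -> "GeneAlignment":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        taxa = [r.id for r in records]
        rows = [str(r.seq) for r in records]
        aln = cls(gene=gene or getattr(path, "stem", str(path)), taxa=taxa, rows=rows)
        aln.codon_aware = (aln.length % 3 == 0) if codon_aware is None else codon_aware
        return aln

    def _matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            self.n_taxa, self.length
        )


def _usable_mask(mat: np.ndarray) -> np.ndarray:
    """Columns free of gaps and ambiguity in every row (complete deletion)."""
    ok = np.zeros(mat.shape[1], dtype=bool)
    good = np.isin(mat, np.array([b"A", b"C", b"G", b"T"]))
    np.all(good, axis=0, out=ok)
    return ok


def nucleotide_diversity(aln: GeneAlignment, deletion: str = "complete") -> float:
    """Average pairwise proportion of differing sites (Pi).

    ``deletion="complete"`` (default, matching classic population-genetics
    site filtering) drops every column containing a gap or ambiguity before
    comparing; ``"pairwise"`` drops such columns per pair.  Returns NaN when
    no usable columns remain.
    """
    if aln.n_taxa < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    mat = aln._matrix()
    pairs = list(itertools.combinations(range(aln.n_taxa), 2))
    if deletion == "complete":
        mask = _usable_mask(mat)
        if not mask.any():
            return math.nan
        sub = mat[:, mask]
        total = 0.0
        for i, j in pairs:
            total += np.count_nonzero(sub[i] != sub[j]) / sub.shape[1]
        return total / len(pairs)
    good = np.isin(mat, np.array([b"A", b"C", b"G", b"T"]))
    props = []
    for i, j in pairs:
        both = good[i] & good[j]
        n = np.count_nonzero(both)
        if n:
            props.append(np.count_nonzero((mat[i] != mat[j]) & both) / n)
    return float(np.mean(props)) if props else math.nan


def variable_sites(aln: GeneAlignment) -> tuple[int, float]:
    """Count and percentage of variable columns among usable columns.

    A usable column (no gap or ambiguity in any row) is variable when at
    least two distinct bases occur in it.
    """
    if aln.n_taxa < 2:
        raise ValueError("variable sites need at least two sequences")
    mat = aln._matrix()
    mask = _usable_mask(mat)
    n_usable = int(mask.sum())
    if n_usable == 0:
        return 0, math.nan
    sub = mat[:, mask]
    var = int(np.count_nonzero(np.any(sub != sub[0], axis=0)))
    return var, 100.0 * var / n_usable


# ---------------------------------------------------------------------------
# Nei-Gojobori


@dataclass(frozen=True)
class NGResult:
    ka: float
    ks: float
    ka_ks: float  # NaN when Ks is 0 or either rate is saturated
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _encode_codons(cds: str, code: GeneticCode, label: str) -> np.ndarray:
    if len(cds) % 3:
        raise ValueError(f"{label}: length {len(cds)} is not a multiple of 3")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"{label}: gaps/ambiguity not allowed: {sorted(bad)}")
    idx = np.array([_codon_index(cds[i : i + 3]) for i in range(0, len(cds), 3)])
    return idx


def nei_gojobori(
    cds1: str, cds2: str, code: GeneticCode = VERTEBRATE_MITO
) -> NGResult:
    """Nei-Gojobori (1986) Ka and Ks for two aligned, gap-free coding sequences.

    Trailing stop codons (on either sequence) are trimmed; an internal stop is
    an error.  See the module docstring for the site-counting, pathway and
    Jukes-Cantor conventions.
    """
    cds1 = cds1.upper().replace("U", "T")
    cds2 = cds2.upper().replace("U", "T")
    if len(cds1) != len(cds2):
        raise ValueError("sequences differ in length")
    syn_sites, syn_diff, nonsyn_diff, is_stop = _ng_tables(code.id)
    idx1 = _encode_codons(cds1, code, "cds1")
    idx2 = _encode_codons(cds2, code, "cds2")
    # trim trailing stop codon(s)
    while len(idx1) and (is_stop[idx1[-1]] or is_stop[idx2[-1]]):
        idx1, idx2 = idx1[:-1], idx2[:-1]
    if len(idx1) == 0:
        raise ValueError("no codons left after stop trimming")
    if is_stop[idx1].any() or is_stop[idx2].any():
        raise ValueError("internal stop codon in coding sequence")

    s = 0.5 * (syn_sites[idx1].sum() + syn_sites[idx2].sum())
    n = 3.0 * len(idx1) - s
    sd = float(syn_diff[idx1, idx2].sum())
    nd = float(nonsyn_diff[idx1, idx2].sum())
    ps = sd / s if s else 0.0
    pn = nd / n if n else 0.0
    ks = _jc_correct(ps)
    ka = _jc_correct(pn)
    if math.isnan(ka) or math.isnan(ks) or ks == 0.0:
        ratio = math.nan
    else:
        ratio = ka / ks
    return NGResult(ka=ka, ks=ks, ka_ks=ratio, n_sites=n, s_sites=s,
                    nd=nd, sd=sd, n_codons=len(idx1))


# ---------------------------------------------------------------------------
# Per-gene summary


@dataclass
class DivergenceSummary:
    """Per-gene diversity and selection statistics across a taxon panel."""

    gene: str
    pi: float
    var_sites: int
    var_site_pct: float
    ka: float = math.nan
    ks: float = math.nan
    ka_ks: float = math.nan
    purifying: Optional[bool] = None  # ka_ks < 1; None when undefined
    n_taxa: int = 0
    n_sites_used: int = 0


def _codon_filtered_rows(aln: GeneAlignment, code: GeneticCode) -> list[str]:
    """Rows reduced to codon columns that are clean in every taxon.

    A codon column is dropped when any row holds a gap, an ambiguity code, or
    a stop codon there — stop codons cannot be traversed by the counting
    method, and terminators are not informative for selection.
    """
    _, _, _, is_stop = _ng_tables(code.id)
    L = aln.length - aln.length % 3
    mat = aln._matrix()[:, :L]
    n_codons = L // 3
    keep = np.ones(n_codons, dtype=bool)
    good = np.isin(mat, np.array([b"A", b"C", b"G", b"T"])).reshape(aln.n_taxa, n_codons, 3)
    keep &= good.all(axis=(0, 2))
    cods = mat.reshape(aln.n_taxa, n_codons, 3)
    for k in np.nonzero(keep)[0]:
        for r in range(aln.n_taxa):
            codon = cods[r, k].tobytes().decode()
            if is_stop[_codon_index(codon)]:
                keep[k] = False
                break
    out = []
    for r in range(aln.n_taxa):
        out.append(b"".join(cods[r, k].tobytes() for k in np.nonzero(keep)[0]).decode())
    return out


def gene_divergence_summary(
    aln: GeneAlignment,
    code: GeneticCode = VERTEBRATE_MITO,
    mean_of_ratios: bool = False,
) -> DivergenceSummary:
    """Pi, variable sites and (for codon-aware alignments) averaged Ka/Ks.

    The per-gene Ka/Ks is (mean pairwise Ka) / (mean pairwise Ks) by default —
    robust to individual pairs with Ks = 0 — with ``mean_of_ratios=True``
    switching to the mean of defined pairwise ratios.  Undefined pairwise
    values (saturated or zero-Ks pairs) are propagated as NaN and excluded
    from means rather than aborting the batch.
    """
    pi = nucleotide_diversity(aln)
    nvar, pct = variable_sites(aln)
    mat = aln._matrix()
    summary = DivergenceSummary(
        gene=aln.gene, pi=pi, var_sites=nvar, var_site_pct=pct,
        n_taxa=aln.n_taxa, n_sites_used=int(_usable_mask(mat).sum()),
    )
    if not aln.codon_aware or aln.n_taxa < 2:
        return summary
    rows = _codon_filtered_rows(aln, code)
    if not rows[0]:
        return summary
    kas, kss, ratios = [], [], []
    for i, j in itertools.combinations(range(aln.n_taxa), 2):
        res = nei_gojobori(rows[i], rows[j], code)
        if not math.isnan(res.ka):
            kas.append(res.ka)
        if not math.isnan(res.ks):
            kss.append(res.ks)
        if not math.isnan(res.ka_ks):
            ratios.append(res.ka_ks)
    summary.ka = float(np.mean(kas)) if kas else math.nan
    summary.ks = float(np.mean(kss)) if kss else math.nan
    if mean_of_ratios:
        summary.ka_ks = float(np.mean(ratios)) if ratios else math.nan
    else:
        summary.ka_ks = (
            summary.ka / summary.ks
            if summary.ks and not math.isnan(summary.ks) and not math.isnan(summary.ka)
            else math.nan
        )
    summary.purifying = summary.ka_ks < 1.0 if not math.isnan(summary.ka_ks) else None
    return summary
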