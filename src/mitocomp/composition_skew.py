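"""Base composition, GC/AT content, and strand-skew statistics.

Strand skews measure compositional asymmetry between the two strands of a
DNA molecule:

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

Both lie in [-1, 1] and are negated by taking the reverse complement.  In
avian mitogenomes AT-skew is typically positive and GC-skew negative on the
reference (heavy) strand: C and A are over-represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .genome_model import Mitogenome, extract_gene_sequence

__all__ = [
    "CompositionStats",
    "base_composition",
    "skew",
    "per_gene_composition",
    "content_skew_correlation",
]


@dataclass(frozen=True)
class CompositionStats:
    """Counts, percentages and skews of the four unambiguous bases."""

    a: int
    c: int
    g: int
    t: int

    @property
    def n_effective(self) -> int:
        """Bases counted; IUPAC ambiguity codes are excluded, never split fractionally."""
        return self.a + self.c + self.g + self.t

    def pct(self, base: str) -> float:
        return 100.0 * getattr(self, base.lower()) / self.n_effective

    @property
    def at_content(self) -> float:
        return 100.0 * (self.a + self.t) / self.n_effective

    @property
    def gc_content(self) -> float:
        return 100.0 * (self.g + self.c) / self.n_effective

    @property
    def at_skew(self) -> float:
        return skew(self.a, self.t)

    @property
    def gc_skew(self) -> float:
        return skew(self.g, self.c)

    def merged(self, other: "CompositionStats") -> "CompositionStats":
        """Composition of the concatenation of the two underlying sequences."""
        return CompositionStats(self.a + other.a, self.c + other.c,
                                self.g + other.g, self.t + other.t)


def base_composition(seq: str) -> CompositionStats:
    """Composition over the unambiguous A/C/G/T content of a sequence.

    Raises ``ValueError`` on an empty or all-ambiguous sequence.
    """
    s = seq.upper().replace("U", "T")
    stats_ = CompositionStats(s.count("A"), s.count("C"), s.count("G"), s.count("T"))
    if stats_.n_effective == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T content")
    return stats_


def skew(a_like: float, t_like: float) -> float:
    """(a - t) / (a + t); NaN (not 0) when the denominator vanishes.

    Works identically on raw counts and on percentages, since the common
    scale cancels.
    """
    if a_like < 0 or t_like < 0:
        raise ValueError("skew requires non-negative counts")
    denom = a_like + t_like
    if denom == 0:
        return math.nan
    return (a_like - t_like) / denom


def per_gene_composition(
    genome: Mitogenome, orientation: str = "reference"
) -> pd.DataFrame:
    """Composition and skews per annotated region, plus pooled summary rows.

    One row per gene (PCG, tRNA, rRNA, control region), then rows ``PCGs``
    (concatenated 13 coding genes), ``rRNAs`` (concatenated rRNAs) and
    ``genome`` (full reference sequence).

    ``orientation="reference"`` (default) measures every region on the
    reference heavy strand, so light-strand genes contribute their reference-
    strand subsequence; ``orientation="coding"`` measures light-strand genes
    on their extracted coding strand instead.  The convention used is recorded
    in the output.
    """
    if orientation not in ("reference", "coding"):
        raise ValueError(f"orientation must be 'reference' or 'coding', got {orientation!r}")
    if not genome.table.features:
        raise ValueError(f"genome {genome.id} has no annotation")

    def region_seq(feat) -> str:
        seq = extract_gene_sequence(genome, feat)
        if orientation == "reference" and feat.strand == "-":
            # undo the coding-strand flip that extract_gene_sequence applies
            from .genome_model import reverse_complement

            seq = reverse_complement(seq)
        return seq

    rows = []

    def add_row(region: str, category: str, strand: str, seq: str) -> None:
        comp = base_composition(seq)
        rows.append(
            {
                "genome": genome.id,
                "region": region,
                "category": category,
                "strand": strand,
                "orientation": orientation,
                "length": len(seq),
                "pct_a": comp.pct("a"),
                "pct_c": comp.pct("c"),
                "pct_g": comp.pct("g"),
                "pct_t": comp.pct("t"),
                "at_content": comp.at_content,
                "gc_content": comp.gc_content,
                "at_skew": comp.at_skew,
                "gc_skew": comp.gc_skew,
            }
        )

    pcg_parts: list[str] = []
    rrna_parts: list[str] = []
    for feat in genome.table.features:
        seq = region_seq(feat)
        add_row(feat.name, feat.category, feat.strand, seq)
        if feat.category == "PCG":
            pcg_parts.append(extract_gene_sequence(genome, feat))
        elif feat.category == "rRNA":
            rrna_parts.append(extract_gene_sequence(genome, feat))
    if pcg_parts:
        add_row("PCGs", "concatenated", "+", "".join(pcg_parts))
    if rrna_parts:
        add_row("rRNAs", "concatenated", "+", "".join(rrna_parts))
    add_row("genome", "whole", "+", genome.sequence)
    return pd.DataFrame(rows)


def content_skew_correlation(
    points: Sequence[tuple[float, float]] | Iterable[tuple[float, float]]
) -> tuple[float, int]:
    """Pearson correlation between nucleotide content and the matching skew.

    Input is (content %, skew) pairs, one per genome or region.  Returns
    ``(r, n)``; ``r`` is NaN when either coordinate has zero variance.
    No p-value is computed: with the handful of points a mitogenome panel
    offers, the correlation is descriptive.
    """
    pts = [(float(x), float(y)) for x, y in points]
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points for a correlation")
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return math.nan, n
    r = stats.pearsonr(xs, ys).statistic
    return float(r), n
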