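"""Codon usage statistics under the vertebrate mitochondrial genetic code.

Covers codon splitting with incomplete (truncated) stop handling, start/stop
codon classification, codon and amino-acid counting, and relative synonymous
codon usage (RSCU).

RSCU for codon ``c`` in a synonymous family of degeneracy ``k`` is

    RSCU(c) = k * n_c / sum(n_j for j in family)

i.e. the observed count divided by the count expected if all synonymous codons
were used equally.  Stop codons form no family.  Under NCBI translation
table 2 (vertebrate mitochondrial) the stops are TAA, TAG, AGA and AGG, so
Ser is a 6-codon family of TCN + AGT/AGC while Arg has only the CGN codons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "GeneticCode",
    "CodonUsage",
    "RSCUTable",
    "StartStopReport",
    "split_codons",
    "detect_start_stop",
    "count_codons",
    "amino_acid_usage",
    "compute_rscu",
    "codon_usage_frame",
]

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

AA_3LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter",
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table with start and stop codon sets (DNA alphabet)."""

    id: int
    codon_to_aa: Mapping[str, str]  # all 64 codons; stops map to "*"
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    @lru_cache(maxsize=None)
    def from_ncbi(cls, table_id: int = 2) -> "GeneticCode":
        """Build from an NCBI translation table (default 2, vertebrate mitochondrial)."""
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(tab.forward_table)
        for stop in tab.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(
            id=table_id,
            codon_to_aa=mapping,
            start_codons=frozenset(tab.start_codons),
            stop_codons=frozenset(tab.stop_codons),
        )

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon.upper().replace("U", "T")]

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("U", "T") in self.stop_codons

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families over sense codons: amino acid -> its codons."""
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            aa = self.codon_to_aa[codon]
            if aa == "*":
                continue
            fams.setdefault(aa, []).append(codon)
        return {aa: tuple(cods) for aa, cods in fams.items()}


VERTEBRATE_MITO = GeneticCode.from_ncbi(2)


def _check_nt(cds: str) -> str:
    cds = cds.upper().replace("U", "T")
    bad = set(cds) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in coding sequence: {sorted(bad)}")
    return cds


def split_codons(cds: str) -> tuple[list[str], str]:
    """Split a coding sequence into consecutive triplets plus a trailing remnant.

    The remnant (1-2 nt when the length is not a multiple of 3) is how
    mitochondrial genes with truncated stop codons ("T"/"TA", completed to TAA
    by polyadenylation) present themselves.
    """
    cds = _check_nt(cds)
    if not cds:
        raise ValueError("empty coding sequence")
    n_full = len(cds) // 3
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_full)]
    return codons, cds[3 * n_full :]


@dataclass(frozen=True)
class StartStopReport:
    start_codon: str
    stop_token: str  # full stop triplet, or the 1-2 nt truncated remnant
    start_is_canonical_atg: bool
    start_is_alternative: bool  # in the code's start set but not ATG (e.g. GTG)
    stop_is_truncated: bool
    stop_is_complete_stop: bool


def detect_start_stop(cds: str, code: GeneticCode = VERTEBRATE_MITO) -> StartStopReport:
    """Classify the start codon and the stop token of a coding sequence.

    The stop token is the trailing remnant when one exists (a truncated stop),
    otherwise the final complete triplet.
    """
    codons, remnant = split_codons(cds)
    if len(_check_nt(cds)) < 6:
        raise ValueError("coding sequence too short to classify (< 6 nt)")
    start = codons[0]
    if remnant:
        stop_token = remnant
        truncated = True
        complete = False
    else:
        stop_token = codons[-1]
        truncated = False
        complete = code.is_stop(stop_token)
    return StartStopReport(
        start_codon=start,
        stop_token=stop_token,
        start_is_canonical_atg=start == "ATG",
        start_is_alternative=start != "ATG" and start in code.start_codons,
        stop_is_truncated=truncated,
        stop_is_complete_stop=complete,
    )


@dataclass
class CodonUsage:
    """Codon counts pooled over a set of coding sequences."""

    counts: Counter = field(default_factory=Counter)
    code: GeneticCode = VERTEBRATE_MITO
    includes_stops: bool = True

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonUsage") -> "CodonUsage":
        if self.code.id != other.code.id or self.includes_stops != other.includes_stops:
            raise ValueError("cannot add usages with different codes or stop conventions")
        return CodonUsage(self.counts + other.counts, self.code, self.includes_stops)


def count_codons(
    cds_set: Iterable[str],
    code: GeneticCode = VERTEBRATE_MITO,
    include_stops: bool = True,
) -> CodonUsage:
    """Pool codon counts over coding sequences.

    Only complete triplets are counted — truncated-stop remnants never are —
    so with ``include_stops=True`` the total equals sum(floor(len/3)) over the
    inputs, the convention under which the 13 protein-coding genes of a
    typical passerine mitogenome sum to their printed codon total.  With
    ``include_stops=False`` complete stop triplets are dropped from both the
    counts and the total.  Codons containing ambiguity codes are skipped.
    """
    usage = CodonUsage(code=code, includes_stops=include_stops)
    for cds in cds_set:
        codons, _ = split_codons(cds)
        for codon in codons:
            if "N" in codon:
                continue
            if not include_stops and code.is_stop(codon):
                continue
            usage.counts[codon] += 1
    return usage


def amino_acid_usage(usage: CodonUsage) -> dict[str, int]:
    """Amino-acid counts from codon usage (3-letter names; stops pooled as 'Ter').

    Leu pools all six of its codons, and likewise for every other family of
    the active code.
    """
    out: Counter = Counter()
    for codon, n in usage.counts.items():
        out[AA_3LETTER[usage.code.codon_to_aa[codon]]] += n
    return dict(out)


@dataclass
class RSCUTable:
    """Relative synonymous codon usage, plus the family map that produced it."""

    rscu: dict[str, float]
    family: dict[str, str]  # codon -> amino acid (1-letter family id)
    zero_usage_families: set[str] = field(default_factory=set)

    def as_rna(self) -> dict[str, float]:
        """RSCU keyed by RNA-style codons (CUA rather than CTA), for display."""
        return {c.replace("T", "U"): v for c, v in self.rscu.items()}


def compute_rscu(usage: CodonUsage) -> RSCUTable:
    """RSCU over the sense codons of the usage's genetic code.

    Stop codons are excluded from every family.  Families with zero total
    usage get RSCU 0 for all their codons and are flagged in
    ``zero_usage_families``.
    """
    fams = usage.code.families
    rscu: dict[str, float] = {}
    family_of: dict[str, str] = {}
    zero: set[str] = set()
    for aa, codons in fams.items():
        k = len(codons)
        total = sum(usage.counts.get(c, 0) for c in codons)
        for c in codons:
            family_of[c] = aa
            rscu[c] = (usage.counts.get(c, 0) * k / total) if total else 0.0
        if total == 0:
            zero.add(aa)
    return RSCUTable(rscu=rscu, family=family_of, zero_usage_families=zero)


def codon_usage_frame(
    usage: CodonUsage,
    rscu: Optional[RSCUTable] = None,
    rna_style: bool = True,
) -> pd.DataFrame:
    """Tidy codon-usage table (codon, amino acid, count, RSCU), ready for TSV export."""
    if rscu is None:
        rscu = compute_rscu(usage)
    rows = []
    for codon in ALL_CODONS:
        aa = usage.code.codon_to_aa[codon]
        rows.append(
            {
                "codon": codon.replace("T", "U") if rna_style else codon,
                "amino_acid": AA_3LETTER[aa],
                "count": usage.counts.get(codon, 0),
                "rscu": round(rscu.rscu[codon], 4) if aa != "*" else float("nan"),
            }
        )
    return pd.DataFrame(rows)
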