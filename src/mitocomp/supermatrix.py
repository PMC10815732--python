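"""Concatenate per-gene alignments into a partitioned supermatrix.

The supermatrix plus a partition file (RAxML or NEXUS dialect) is the
standard input for partitioned phylogenetic inference; tree building itself
is left to IQ-TREE/MrBayes-class tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .divergence import GeneAlignment

__all__ = [
    "Supermatrix",
    "concatenate",
    "extract_partition",
    "write_partitions",
    "write_fasta",
    "write_phylip",
    "manifest",
]

MISSING_CHAR = "?"  # distinguishes absent-taxon fill from alignment gaps "-"


@dataclass
class Supermatrix:
    """Per-taxon concatenated matrix with 1-based inclusive gene partitions."""

    taxa: list[str]
    matrix: dict[str, str]  # taxon -> concatenated sequence
    partitions: list[tuple[str, int, int]]  # (gene, start, end), tiling 1..length

    @property
    def length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0


def concatenate(
    alignments: Sequence[GeneAlignment], taxa_policy: str = "intersection"
) -> Supermatrix:
    """Concatenate gene alignments in input order.

    ``taxa_policy="intersection"`` keeps taxa present in every gene;
    ``"union"`` keeps all taxa, filling a taxon's missing genes with ``?``.
    Taxon row order follows first appearance across the input.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    if taxa_policy not in ("intersection", "union"):
        raise ValueError(f"unknown taxa policy {taxa_policy!r}")
    for aln in alignments:
        if len(set(aln.taxa)) != len(aln.taxa):
            raise ValueError(f"duplicate taxon ids in alignment {aln.gene!r}")
    ordered: list[str] = []
    seen: set[str] = set()
    for aln in alignments:
        for t in aln.taxa:
            if t not in seen:
                seen.add(t)
                ordered.append(t)
    if taxa_policy == "intersection":
        keep = set(ordered)
        for aln in alignments:
            keep &= set(aln.taxa)
        taxa = [t for t in ordered if t in keep]
        if not taxa:
            raise ValueError("no taxa shared by all alignments")
    else:
        taxa = ordered

    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for aln in alignments:
        L = aln.length
        row_of = dict(zip(aln.taxa, aln.rows))
        for t in taxa:
            chunks[t].append(row_of.get(t, MISSING_CHAR * L))
        parts.append((aln.gene, pos, pos + L - 1))
        pos += L
    return Supermatrix(
        taxa=taxa, matrix={t: "".join(chunks[t]) for t in taxa}, partitions=parts
    )


def extract_partition(sm: Supermatrix, gene: str) -> GeneAlignment:
    """Recover one gene's alignment block from the supermatrix."""
    for name, start, end in sm.partitions:
        if name == gene:
            rows = [sm.matrix[t][start - 1 : end] for t in sm.taxa]
            return GeneAlignment(gene=name, taxa=list(sm.taxa), rows=rows)
    raise KeyError(gene)


def write_partitions(sm: Supermatrix, dialect: str = "raxml") -> str:
    """Partition definitions as text: ``raxml`` lines or a ``nexus`` sets block.

    Output is byte-stable for a fixed supermatrix.
    """
    if dialect == "raxml":
        return "".join(
            f"DNA, {name} = {start}-{end}\n" for name, start, end in sm.partitions
        )
    if dialect == "nexus":
        lines = ["#NEXUS", "begin sets;"]
        lines += [
            f"    charset {name} = {start}-{end};" for name, start, end in sm.partitions
        ]
        lines += ["end;", ""]
        return "\n".join(lines)
    raise ValueError(f"unknown partition dialect {dialect!r}")


def write_fasta(sm: Supermatrix, handle) -> None:
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for t in sm.taxa:
            fh.write(f">{t}\n")
            seq = sm.matrix[t]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    finally:
        if own:
            fh.close()


def write_phylip(sm: Supermatrix, handle) -> None:
    """Relaxed PHYLIP: full taxon names, two-space separator."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write(f" {len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.matrix[t]}\n")
    finally:
        if own:
            fh.close()


def manifest(sm: Supermatrix, alignments: Iterable[GeneAlignment] = ()) -> str:
    """JSON manifest of gene order, partition spans and taxa."""
    doc = {
        "n_taxa": len(sm.taxa),
        "matrix_length": sm.length,
        "taxa": sm.taxa,
        "partitions": [
            {"gene": name, "start": start, "end": end, "length": end - start + 1}
            for name, start, end in sm.partitions
        ],
    }
    return json.dumps(doc, indent=2) + "\n"
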