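"""Circular annotated mitogenomes: feature tables, sequence extraction, structure checks.

Coordinates are 1-based and fully inclusive throughout, following the GenBank
convention.  A feature whose ``end`` is smaller than its ``start`` wraps across
the origin of the circular molecule.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "GeneFeature",
    "GeneTable",
    "Mitogenome",
    "OrderReport",
    "CANONICAL_PCGS",
    "AVIAN_GENE_ORDER",
    "normalize_gene_name",
    "parse_feature_table",
    "write_feature_table",
    "gene_length",
    "extract_gene_sequence",
    "strand_census",
    "validate_avian_order",
    "read_genbank",
    "write_genes_fasta",
    "load_bundled_table",
]

#: The 13 canonical mitochondrial protein-coding genes.
CANONICAL_PCGS = frozenset(
    {
        "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
        "COX1", "COX2", "COX3", "ATP6", "ATP8", "Cytb",
    }
)

CANONICAL_TRNAS = frozenset(
    {
        "trnF", "trnV", "trnL1", "trnL2", "trnI", "trnQ", "trnM", "trnW",
        "trnA", "trnN", "trnC", "trnY", "trnS1", "trnS2", "trnD", "trnK",
        "trnG", "trnR", "trnH", "trnT", "trnP", "trnE",
    }
)

CANONICAL_RRNAS = frozenset({"rrnS", "rrnL"})

#: Ancestral avian mitochondrial gene arrangement (trnF .. trnE, then the
#: control region), as found in most Passeriformes.
AVIAN_GENE_ORDER = (
    "trnF", "rrnS", "trnV", "rrnL", "trnL2", "ND1", "trnI", "trnQ", "trnM",
    "ND2", "trnW", "trnA", "trnN", "trnC", "trnY", "COX1", "trnS2", "trnD",
    "COX2", "trnK", "ATP8", "ATP6", "COX3", "trnG", "ND3", "trnR", "ND4L",
    "ND4", "trnH", "trnS1", "trnL1", "ND5", "Cytb", "trnT", "trnP", "ND6",
    "trnE", "D-loop",
)

# Synonyms seen in GenBank records and annotation pipelines, mapped to the
# canonical short names used here.  Matching is case-insensitive.
_NAME_SYNONYMS = {
    "coi": "COX1", "coii": "COX2", "coiii": "COX3",
    "co1": "COX1", "co2": "COX2", "co3": "COX3",
    "cox1": "COX1", "cox2": "COX2", "cox3": "COX3",
    "cytb": "Cytb", "cob": "Cytb", "cyt b": "Cytb",
    "atp6": "ATP6", "atp8": "ATP8", "atpase6": "ATP6", "atpase8": "ATP8",
    "nad1": "ND1", "nad2": "ND2", "nad3": "ND3", "nad4": "ND4",
    "nad4l": "ND4L", "nad5": "ND5", "nad6": "ND6",
    "12s": "rrnS", "16s": "rrnL", "12s rrna": "rrnS", "16s rrna": "rrnL",
    "rrns": "rrnS", "rrnl": "rrnL", "s-rrna": "rrnS", "l-rrna": "rrnL",
    "d-loop": "D-loop", "dloop": "D-loop", "control region": "D-loop",
    "cr": "D-loop",
}

_AA3_TO_TRNA = {
    "phe": "F", "val": "V", "ile": "I", "gln": "Q", "met": "M", "trp": "W",
    "ala": "A", "asn": "N", "cys": "C", "tyr": "Y", "asp": "D", "lys": "K",
    "gly": "G", "arg": "R", "his": "H", "thr": "T", "pro": "P", "glu": "E",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_IUPAC = set("ACGTRYSWKMBDHVN")


def normalize_gene_name(raw: str) -> str:
    """Map a gene label to its canonical short name.

    Handles COI/COX1-style synonyms, 12S/16S rRNA labels, tRNA-Phe-style
    names (with (UUR)/(AGY)-type disambiguation for Leu and Ser), and
    control-region aliases.  Unknown names are returned stripped but
    otherwise untouched.
    """
    name = raw.strip()
    low = name.lower()
    if low in _NAME_SYNONYMS:
        return _NAME_SYNONYMS[low]
    m = re.match(r"^trna[-_ ]?([a-z]{3})\s*(\d)?\s*(\(([a-z]{3})\))?$", low)
    if m:
        aa3, num = m.group(1), m.group(2)
        if aa3 in ("leu", "ser"):
            letter = "L" if aa3 == "leu" else "S"
            if num in ("1", "2"):
                return f"trn{letter}{num}"
            codon = (m.group(4) or "").upper()
            if aa3 == "leu":
                return "trnL2" if codon in ("UUR", "UUA", "UUG", "TAA") else "trnL1"
            return "trnS1" if codon in ("AGY", "AGC", "AGT", "GCU", "GCT") else "trnS2"
        if aa3 in _AA3_TO_TRNA:
            return f"trn{_AA3_TO_TRNA[aa3]}"
    m = re.match(r"^trn([a-z])(\d)?$", low)
    if m:
        return f"trn{m.group(1).upper()}{m.group(2) or ''}"
    for canon in CANONICAL_PCGS:
        if low == canon.lower():
            return canon
    return name


def infer_category(name: str) -> str:
    """Gene category from a canonical name: PCG, tRNA, rRNA, control-region, other."""
    if name in CANONICAL_PCGS:
        return "PCG"
    if name in CANONICAL_TRNAS or name.startswith("trn"):
        return "tRNA"
    if name in CANONICAL_RRNAS:
        return "rRNA"
    if name == "D-loop":
        return "control-region"
    return "other"


@dataclass
class GeneFeature:
    """One annotated feature of a circular mitogenome (a row of a gene table)."""

    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; end < start means the feature wraps the origin
    strand: str  # "+" heavy, "-" light
    category: str = ""
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r} for {self.name}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates must be >= 1 for {self.name}")
        if not self.category:
            self.category = infer_category(self.name)


@dataclass
class GeneTable:
    """Ordered collection of features annotated on one mitogenome."""

    features: list[GeneFeature] = field(default_factory=list)
    genome_length: int = 0
    #: (gene, printed length, coordinate length) rows where a declared length
    #: column disagreed with coordinate arithmetic.
    discrepancies: list[tuple[str, int, int]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    @property
    def is_complete(self) -> bool:
        """True when the table holds the full 37-gene complement plus one control region."""
        return not self.missing_canonical_genes() and len(self.by_category("control-region")) == 1

    def missing_canonical_genes(self) -> list[str]:
        present = {f.name for f in self.features}
        expected = CANONICAL_PCGS | CANONICAL_TRNAS | CANONICAL_RRNAS
        return sorted(expected - present)


@dataclass
class Mitogenome:
    """A circular nucleotide sequence bound to its gene table."""

    id: str
    sequence: str
    table: GeneTable

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters in {self.id}: {sorted(bad)}")
        if self.table.genome_length and self.table.genome_length != len(self.sequence):
            raise ValueError(
                f"table genome_length {self.table.genome_length} != sequence length "
                f"{len(self.sequence)} for {self.id}"
            )
        self.table.genome_length = len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# Parsing and writing


def _clean_int(tok: str) -> int:
    """Parse a coordinate that may carry thousands separators."""
    tok = tok.strip().replace(",", "").replace(" ", "")
    if not re.fullmatch(r"\d+", tok):
        raise ValueError(f"malformed coordinate {tok!r}")
    return int(tok)


_DASHES = "‒–—―−"


def _parse_location(loc: str) -> tuple[int, int, Optional[str]]:
    """Parse a 'start-end: strand' location string; strand part optional."""
    s = loc.strip()
    for d in _DASHES:
        s = s.replace(d, "-")
    strand = None
    if ":" in s:
        s, strand_part = s.rsplit(":", 1)
        strand = strand_part.strip()
        if strand in ("−",):
            strand = "-"
    m = re.fullmatch(r"\s*([\d,]+)\s*-\s*([\d,]+)\s*", s)
    if not m:
        raise ValueError(f"malformed location {loc!r}")
    return _clean_int(m.group(1)), _clean_int(m.group(2)), strand


def parse_feature_table(text: str, genome_length: int = 0) -> GeneTable:
    """Parse a gene-table TSV into a :class:`GeneTable`.

    The dialect has a header row and either separate ``start``/``end``/``strand``
    columns or a combined ``location`` column holding ``start-end: strand``.
    Recognised optional columns: ``category``, ``length``, ``start_codon``,
    ``stop_codon``, ``anticodon``.  Lines starting with ``#`` are comments.
    Thousands separators and en/em dashes are tolerated in coordinates.

    A declared ``length`` column is cross-checked against coordinate
    arithmetic; disagreements are recorded in ``table.discrepancies`` rather
    than rejected.

    Raises ``ValueError`` naming the offending row for malformed coordinates,
    unknown strand symbols, or duplicate canonical gene names.
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    table = GeneTable(genome_length=genome_length)
    if not lines:
        return table
    header = [h.strip().lower() for h in lines[0].split("\t")]
    idx = {h: i for i, h in enumerate(header)}
    name_col = idx.get("gene", idx.get("name", 0))
    seen: set[str] = set()
    for ln in lines[1:]:
        cells = ln.split("\t")

        def cell(col: str) -> str:
            i = idx.get(col)
            return cells[i].strip() if i is not None and i < len(cells) else ""

        raw_name = cells[name_col].strip().strip("*")
        name = normalize_gene_name(raw_name)
        try:
            if "location" in idx and cell("location"):
                start, end, strand = _parse_location(cell("location"))
                strand = strand or cell("strand") or "+"
            else:
                start = _clean_int(cell("start"))
                end = _clean_int(cell("end"))
                strand = cell("strand").replace("−", "-") or "+"
        except ValueError as exc:
            raise ValueError(f"row {raw_name!r}: {exc}") from exc
        if strand not in ("+", "-"):
            raise ValueError(f"row {raw_name!r}: unknown strand symbol {strand!r}")
        canonical = name in CANONICAL_PCGS | CANONICAL_TRNAS | CANONICAL_RRNAS | {"D-loop"}
        if canonical and name in seen:
            raise ValueError(f"duplicate canonical gene name {name!r}")
        seen.add(name)
        feat = GeneFeature(
            name=name,
            start=start,
            end=end,
            strand=strand,
            category=cell("category") or infer_category(name),
            anticodon=cell("anticodon") or None,
            start_codon=cell("start_codon") or None,
            stop_codon=cell("stop_codon") or None,
        )
        table.features.append(feat)
        declared = cell("length")
        if declared:
            L = genome_length or max(end, start)
            actual = gene_length(feat, L)
            if _clean_int(declared) != actual:
                table.discrepancies.append((name, _clean_int(declared), actual))
    if not table.genome_length and table.features:
        table.genome_length = max(max(f.start, f.end) for f in table.features)
    return table


def write_feature_table(table: GeneTable) -> str:
    """Serialize a GeneTable back to the normalized TSV dialect."""
    out = io.StringIO()
    out.write("gene\tstart\tend\tstrand\tcategory\tlength\tstart_codon\tstop_codon\tanticodon\n")
    for f in table.features:
        out.write(
            "\t".join(
                [
                    f.name,
                    str(f.start),
                    str(f.end),
                    f.strand,
                    f.category,
                    str(gene_length(f, table.genome_length)),
                    f.start_codon or "",
                    f.stop_codon or "",
                    f.anticodon or "",
                ]
            )
            + "\n"
        )
    return out.getvalue()


# ---------------------------------------------------------------------------
# Coordinate arithmetic and extraction


def gene_length(feature: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circular genome of ``genome_length`` bp.

    ``end >= start`` is the ordinary case; ``end < start`` wraps the origin and
    the length is ``(genome_length - start + 1) + end``.
    """
    if genome_length < 1:
        raise ValueError("genome_length must be positive")
    if not (1 <= feature.start <= genome_length and 1 <= feature.end <= genome_length):
        raise ValueError(
            f"{feature.name}: coordinates {feature.start}-{feature.end} outside "
            f"[1, {genome_length}]"
        )
    if feature.end >= feature.start:
        return feature.end - feature.start + 1
    return (genome_length - feature.start + 1) + feature.end


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_gene_sequence(genome: Mitogenome, feature: GeneFeature) -> str:
    """Strand-correct sequence of a feature, honouring circular wrap-around.

    Heavy-strand features return the reference subsequence ``start..end``;
    light-strand features return its reverse complement, so protein-coding
    genes always come back in coding orientation.
    """
    L = len(genome.sequence)
    gene_length(feature, L)  # validates coordinates
    if feature.end >= feature.start:
        sub = genome.sequence[feature.start - 1 : feature.end]
    else:
        sub = genome.sequence[feature.start - 1 :] + genome.sequence[: feature.end]
    return reverse_complement(sub) if feature.strand == "-" else sub


def strand_census(table: GeneTable) -> tuple[int, int, set[str]]:
    """Count heavy/light-strand genes (control region and unknowns excluded).

    Returns ``(heavy_count, light_count, light_gene_names)`` over the tRNA,
    rRNA and protein-coding features — the 37 genes of a complete table.
    """
    heavy = light = 0
    light_names: set[str] = set()
    for f in table.features:
        if f.category not in ("PCG", "tRNA", "rRNA"):
            continue
        if f.strand == "+":
            heavy += 1
        else:
            light += 1
            light_names.add(f.name)
    return heavy, light, light_names


@dataclass
class OrderReport:
    """Outcome of comparing a table's cyclic gene order to the ancestral avian order."""

    is_ancestral_avian: bool
    n_matched: int
    mismatches: list[tuple[int, str, str]]  # (position, observed, expected)
    rotation_offset: int


def validate_avian_order(table: GeneTable) -> OrderReport:
    """Compare the table's cyclic gene order against the ancestral avian arrangement.

    The comparison is rotation-invariant: every rotation of the observed cycle
    is scored against :data:`AVIAN_GENE_ORDER` and the best alignment is
    reported.  Features of category ``other`` are ignored.

    Raises ``ValueError`` listing missing canonical genes when the table is
    incomplete.
    """
    missing = table.missing_canonical_genes()
    if missing or not table.by_category("control-region"):
        if not table.by_category("control-region"):
            missing = missing + ["D-loop"]
        raise ValueError(f"incomplete gene table; missing: {', '.join(missing)}")
    observed = [f.name for f in table.features if f.category != "other"]
    ref = list(AVIAN_GENE_ORDER)
    if len(observed) != len(ref):
        raise ValueError(
            f"expected {len(ref)} features in cyclic order, found {len(observed)}"
        )
    best = None
    for off in range(len(observed)):
        rotated = observed[off:] + observed[:off]
        mism = [
            (i + 1, got, want)
            for i, (got, want) in enumerate(zip(rotated, ref))
            if got != want
        ]
        if best is None or len(mism) < len(best[1]):
            best = (off, mism)
    off, mism = best
    return OrderReport(
        is_ancestral_avian=not mism,
        n_matched=len(ref) - len(mism),
        mismatches=mism,
        rotation_offset=off,
    )


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O

_GB_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "D-loop": "control-region", "D_loop": "control-region"}


def read_genbank(path) -> Mitogenome:
    """Read an annotated mitogenome from a GenBank flat file.

    CDS, tRNA, rRNA and D-loop (or control-region misc_feature) entries become
    gene-table rows; gene labels are normalized via :func:`normalize_gene_name`.
    """
    record = SeqIO.read(path, "genbank")
    table = GeneTable(genome_length=len(record.seq))
    for feat in record.features:
        cat = _GB_CATEGORY.get(feat.type)
        if feat.type == "misc_feature":
            note = " ".join(feat.qualifiers.get("note", [])).lower()
            if "control region" in note or "d-loop" in note:
                cat = "control-region"
        if cat is None:
            continue
        label = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("product", [None])[0]
            or ("D-loop" if cat == "control-region" else "")
        )
        if not label:
            continue
        name = normalize_gene_name(label)
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        table.features.append(
            GeneFeature(name=name, start=start, end=end, strand=strand,
                        category=cat if cat != "PCG" else infer_category(name) or "PCG")
        )
    return Mitogenome(id=record.id or record.name, sequence=str(record.seq), table=table)


def write_genes_fasta(genome: Mitogenome, handle, categories: Iterable[str] = ("PCG", "tRNA", "rRNA", "control-region")) -> None:
    """Write extracted, strand-correct gene sequences as FASTA (id ``<genome>|<gene>``)."""
    cats = set(categories)
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        for f in genome.table.features:
            if f.category not in cats:
                continue
            seq = extract_gene_sequence(genome, f)
            fh.write(f">{genome.id}|{f.name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    finally:
        if own:
            fh.close()


def load_bundled_table(which: str = "indicus") -> GeneTable:
    """Load one of the packaged Tarsiger gene tables.

    ``which`` is ``"indicus"`` (OR459825, 16,723 bp) or ``"cyanurus"``
    (KF997864, 16,803 bp).
    """
    files = {
        "indicus": ("tarsiger_indicus_OR459825.tsv", 16723),
        "cyanurus": ("tarsiger_cyanurus_KF997864.tsv", 16803),
    }
    try:
        fname, length = files[which]
    except KeyError:
        raise ValueError(f"unknown bundled table {which!r}; choose from {sorted(files)}")
    text = resources.files("mitocomp").joinpath("data", fname).read_text()
    return parse_feature_table(text, genome_length=length)
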