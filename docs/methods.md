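# Methods

This note documents the statistical and modelling choices behind mitocomp:
what each estimator computes, which conventions were open and how they were
fixed, what the simulator does and does not emulate, and the numerical
edge-case policies. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and circularity

All coordinates are 1-based and fully inclusive, the GenBank convention. A
feature with `end < start` wraps the replication origin of the circular
molecule; its length is `(L − start + 1) + end` and extraction concatenates
the two arcs. In the bundled passerine layout no gene wraps the origin (the
control region ends exactly at position L), but wrap support is implemented
and tested because circular genomes in general need it. Overlapping genes
(ATP8/ATP6 overlap by 10 bp, ND4L/ND4 by 7 bp in the bundled table) are
legal and never de-overlapped.

Gene labels are normalized through a fixed synonym map (COI→COX1, 12S→rrnS,
tRNA-Leu(UUR)→trnL2, ...). Unknown labels pass through with category
`other` and are excluded from the 37-gene census and the order check.

When a parsed table carries a printed length column, the parser cross-checks
it against coordinate arithmetic and records disagreements in
`GeneTable.discrepancies` instead of failing or silently "fixing" them —
published comparison tables occasionally contain such inconsistencies, and
surfacing them is more useful than resolving them.

The gene-order check is rotation-invariant: every rotation of the observed
cycle is scored against the ancestral avian arrangement and the best
alignment is reported, so a table that begins at rrnS instead of trnF is
still recognized as ancestral.

## Codon conventions

The genetic code is NCBI translation table 2 (vertebrate mitochondrial)
throughout, built from Biopython's tables and configurable for reuse. Its
stops are TAA, TAG, AGA, AGG, which makes Ser a 6-codon family (TCN +
AGT/AGC), Met a 2-codon family (ATG/ATA) and Trp a 2-codon family
(TGG/TGA).

Two conventions interact around stop codons:

* **Total codon counts** include complete stop triplets, so the headline
  total equals Σ floor(len/3) over the protein-coding genes — the convention
  under which published per-genome codon totals are computed from gene
  lengths. Truncated-stop remnants ("T"/"TA") are never counted as codons.
  A flag (`include_stops=False`) provides the other convention.
* **RSCU and amino-acid usage** exclude stop codons from every family, the
  standard practice; stops are reported separately as `Ter`.

A family with zero total usage gets RSCU 0 for all its codons and is flagged,
rather than dividing by zero. Codon display defaults to RNA style (CUA) in
exported tables, DNA internally.

## Composition and skew

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), computed from counts;
percentages give the same value because the scale cancels. A zero
denominator yields NaN, never 0 — a sequence with no A or T has no defined
AT-skew. IUPAC ambiguity codes are excluded from all denominators and never
allocated fractionally; `n_effective` records how many bases were counted.

Per-gene skews are measured on the reference (heavy) strand by default.
Published per-gene skew figures rarely state their strand convention; the
reference-strand choice is the default here and is recorded in an
`orientation` column, with `orientation="coding"` flipping light-strand
genes to their coding strand (which exactly negates both skews). Rounding
(2 decimals for percentages, 5 for skews) happens only in the reporting
layer.

The content-skew correlation is a plain Pearson r with the sample size; no
p-value is attached, since panels of a few dozen mitogenomes make the
correlation descriptive at best.

## Nucleotide diversity and variable sites

π is the mean over all unordered row pairs of the proportion of differing
sites. Site filtering follows complete deletion — every column containing a
gap or ambiguity in any row is dropped before any comparison — matching the
default filtering of classic population-genetics software; a
pairwise-deletion mode is provided but is not the default. A variable site
is a retained column with ≥ 2 distinct bases. Alignments with no usable
columns yield NaN markers rather than zeros.

## Nei–Gojobori Ka/Ks

The counting method of Nei & Gojobori (1986) with Jukes–Cantor correction,
the classic estimator used by DnaSP-style analyses:

* **Sites.** Each codon position contributes a synonymous fraction equal to
  the proportion of its possible single-nucleotide changes that preserve the
  amino acid. Changes that would create a stop codon are excluded from the
  position's denominator (a standard refinement; the counting still
  partitions exactly 3 sites per codon into S + N).
* **Differences.** Codon pairs differing at d positions are resolved by the
  d! minimal single-step pathways; pathways passing through a stop codon are
  discarded and the remaining ones weighted equally. In the rare case where
  every pathway crosses a stop, all pathways are averaged rather than
  returning nothing.
* **Correction.** p_s = Sd/S and p_n = Nd/N are corrected with
  d = −(3/4)·ln(1 − (4/3)p). Saturation (p ≥ 3/4) yields NaN, never a
  clamped value.

Site and difference counts are precomputed as 64×64 codon tables per genetic
code, so pairwise computation on long genes is table lookup; the test suite
checks these tables against an independent brute-force enumeration that
translates through Biopython directly.

Per-gene panel values are averaged as **(mean pairwise Ka)/(mean pairwise
Ks)**, not the mean of pairwise ratios: identical or near-identical pairs
have Ks = 0 and undefined ratios, which would otherwise dominate or have to
be dropped asymmetrically. The mean-of-ratios variant is available behind a
flag. Undefined pairwise values (saturated, or zero Ks) propagate as NaN and
are excluded from means without aborting a batch.

Trailing stop codons are trimmed before computation; internal stops are an
error at the pairwise level, and at the alignment level codon columns
containing a gap, ambiguity or stop in any taxon are dropped before the
pairwise sweep.

A known property of the estimator, confirmed by the tests: with equal
pathway weighting, two-position codon pairs whose true history was purely
synonymous (e.g. Leu TTA↔CTC) still contribute fractional nonsynonymous
differences, so Ka does not converge to exactly 0 as ω → 0; and with
transition bias (κ > 1) the unweighted site counting inflates Ks and biases
Ka/Ks slightly downward. Recovery experiments therefore run at κ = 1 when
validating unbiasedness, and use a wider band at κ = 2.

## Supermatrix

Concatenation preserves input gene order; partitions are 1-based inclusive
and tile the matrix without gaps or overlap. The intersection policy keeps
taxa present in every gene; the union policy fills a taxon's missing genes
with `?`, deliberately distinct from the alignment gap `-`. Partition files
are emitted in RAxML ("DNA, ND1 = 1-300") and NEXUS charset dialects with
byte-stable output. Alignment trimming (Gblocks-style) is out of scope: the
pipeline consumes pre-trimmed alignments, so published supermatrix lengths
that depend on external trimming are not reproduced here.

## The simulator

The generator emulates a passerine mitogenome study end to end:

* **Layout** from the bundled *T. indicus* table: 37 genes + control region
  in the ancestral avian order, 28 heavy / 9 light strand, template gene
  lengths, GTG starts on COX1/ND2, truncated stops on ND2/COX3/ND4. Template
  overlaps are flattened to abutting genes (independent random sequences
  cannot satisfy two reading frames at once); the control region absorbs
  whatever length reaches `genome_length_target`, mirroring the fact that
  control-region length drives genome-size differences between relatives.
* **Composition** defaults to the C/A-biased whole-genome composition
  measured for *T. indicus* (29.63% A, 32.88% C, 14.73% G, 22.75% T).
  Non-coding regions draw bases i.i.d. from it; coding interiors draw sense
  codons with probability proportional to the product of base probabilities,
  renormalized after excluding stops, so every generated gene is a valid ORF.
* **Evolution.** Coding genes evolve under a codon model: each single-
  nucleotide neighbour is accepted at relative rate 1 (synonymous), ω
  (nonsynonymous), 0 (to a stop), with transitions scaled by κ. Structural
  RNAs and non-coding regions evolve under HKY with the stationary
  composition. Simulation is per-site Gillespie (exponential waiting times)
  — exact for this model class and fast at mitogenome scale; no matrix
  exponentiation is needed.
* **Calibration.** Branch lengths are expected substitutions per nucleotide
  site. The HKY process is normalized exactly at stationarity; the codon
  process is calibrated against the root sequence's mean total rate (3b
  expected codon events per codon), which is exact at the root and drifts
  only slightly as composition evolves.
* **Defaults as study conditions**: 25 taxa (a family-panel size), star tree
  with root-to-tip branch length 0.04 (pairwise divergence ≈ 0.08,
  mid-range for a congeneric/confamilial mitogenome panel), κ = 2, and a
  per-gene ω staircase from COX1 = 0.015 to ATP8 = 0.135 — the universally
  observed purifying regime with its canonical slowest/fastest genes.
  rRNA/tRNA genes evolve at 0.3× the neutral rate (`rna_rate_scale`),
  reflecting secondary-structure constraint and placing rRNA diversity at
  the bottom of the per-gene range, where it sits in real panels.
* **Determinism.** One seeded generator drives every draw; fixtures written
  to disk are byte-identical across runs with the same seed.

What the simulator does **not** emulate: indels (evolved regions are
gap-free, so "alignments" are exact), rate heterogeneity among sites within
a gene, strand-asymmetric mutation processes, tRNA cloverleaf constraints,
control-region repeats, and heteroplasmy. Consequently, passing recovery
tests show that the estimators are correct for point-substitution data with
known ω and clean homology; they do not exercise alignment error or indel
handling, which real panels contain.

## Problem sizes in tests and the acceptance script

The test suite validates estimator recovery at 500 codons × 10 taxa with
100 seeded replicates per ω ∈ {0.05, 0.1, 0.5} (mean Ka/Ks within 25% of
truth; Ka/Ks < 1 in ≥ 95% of purifying replicates), and runs panel-level
directional checks on a 12-taxon fixture — sizes at which results are stable
while the whole suite stays fast. The acceptance script uses a 12-taxon
panel and 30 recovery replicates at ω = 0.1 for the same reason.

## Known limitations

* Published panel statistics (per-gene π, variable-site percentages, Ka/Ks
  of specific 25-genome panels) depend on the exact downloaded sequences and
  external alignment/trimming/DnaSP settings; they are treated as
  directional expectations (ordering, purifying bound), not numeric targets.
* The Nei–Gojobori variant here is the classic one; modified-NG (weighted
  pathways) and ML codon-model estimation are out of scope.
* GenBank parsing covers the feature types of mitogenome records (CDS,
  tRNA, rRNA, D-loop/control-region); exotic annotation styles may need the
  TSV route.
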