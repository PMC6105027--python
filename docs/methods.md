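# Methods

## SSR detection model

A simple SSR is a perfect tandem run of a *primitive* motif (a unit that
is not itself a power of a shorter string: `AT` is primitive, `ATAT` is
not).  For each unit length *k*, the miner finds maximal periodic
intervals — runs of positions where `seq[i] == seq[i-k]` — and reports the
whole copies of the unit anchored at the interval's left end, with 1-based
inclusive coordinates on the forward strand.  Runs never span N.

Defaults: unit lengths 2–10 bp with at least 5 copies.  The threshold is
inclusive (≥5) because the validated marker set contains `(GCC)5`-class
loci; a strictly-greater reading (≥6) is one configuration change away.
Mono-nucleotide runs are supported but disabled by default (≥10 copies
when enabled): the marker panel contains `(A)14`-type loci even though the
nominal motif range starts at 2 bp, so the capability exists without
being part of the default inventory.

When candidate runs of different unit lengths overlap, resolution is
greedy and deterministic: longest total run wins, ties go to the shorter
motif, then to the leftmost start.  This makes `(AT)6` outrank any 4-mer
reparse of the same bases and yields byte-identical output across runs.

Consecutive runs separated by ≤25 nt (covering the longest spacer in the
validated panel, 24 nt) merge into a compound locus whose signature
interleaves lowercase spacers: `(GCT)6gggc…gcgg(CTT)5`.

Motif grouping pairs a motif with its reverse complement,
lexicographically smaller first (`AG/CT`); cyclic rotations deliberately
stay distinct (`GA/TC` is its own group), matching how grouped-motif
inventories are conventionally reported.  One consequence documented in
the property tests: when a run carries a partial trailing copy, the
left-anchored motif rotates under reverse complement, so grouped-label
multisets are strand-symmetric only for runs with a whole number of
copies.

The reported motif keeps its observed orientation; canonicalization
happens only in the grouping statistics.

## Read filtering

A read is discarded iff its fraction of N exceeds 0.10 or its fraction of
bases with Phred quality ≤5 exceeds 0.50; both comparisons are strict, so
a read sitting exactly on a threshold is kept.  "Unknown" means N only;
IUPAC ambiguity codes are invalid input rather than unknowns.  FASTQ is
fixed to Phred+33; scores above 62 are taken as evidence of a legacy
Phred+64 file and rejected.  Adapter trimming is out of scope — the
filter implements exactly the two numeric rules.

## Primer design

The designer is self-contained: candidate oligos (18–24 nt) are
enumerated in the flanks, filtered, and paired.

* **Melting temperature**: nearest-neighbor thermodynamics with the
  unified Allawi & SantaLucia (1997) ΔH/ΔS table, the SantaLucia (1998)
  entropic salt correction, 50 mM monovalent cation and 250 nM of each
  strand; Tm window 55–60 °C (optimum 57.5 °C), matching a touchdown PCR
  annealing program.
* **GC content** 40–60%; **homopolymer runs** ≤4 nt inside an oligo.
* **Secondary structure** is screened by maximum perfect complementary
  run — self/cross dimers ≤5 nt, 3'-anchored runs ≤3 nt.  This is an
  intentional approximation of full hairpin/dimer folding: it catches the
  dominant failure modes at a fraction of the complexity, and the
  constraint checker is trivially auditable.
* **Products** span both primer footprints inclusively, must contain the
  repeat run entirely (neither oligo may overlap it), and default to
  100–400 bp.

Pairs are ranked by a weighted penalty: 1.0 per °C of |Tm − optimum| per
oligo, 0.2 per % of |GC − 50| per oligo, 0.02 per bp of |product −
mid-range|, and 0.5 per nt of the worst complementarity run.  The weights
put ~2 °C of Tm deviation on par with ~10% of GC deviation, reflecting
the usual dominance of annealing temperature in PCR failure.  Binding in
product-size prediction is exact-match only; more than one feasible
pairing within the allowed size range flags the pair non-specific.
Marker names are serial: `TJIB.Eo_001`, `TJIB.Eo_002`, …

## Screening semantics

Amplification matrices store '+', '−' and missing; missing collapses to
'−' for counting (the published table records only +/−).  Classification
from band profiles uses dominant-type scoring: a marker is *failed* when
nothing amplified, *polymorphic* when band-size multisets differ **or**
amplification is present in some but not all accessions, else
*monomorphic*.  Band intensity is not modelled.  Note that the published
polymorphism flags encode the authors' gel reading, which this rule does
not claim to reproduce row-by-row; the flags ship as data.

## Diversity statistics

Allele frequencies are direct counts over typed individuals,
P<sub>i</sub> = count/(2·n); missing genotypes leave the denominator.
Ne = 1/ΣP², He = 1 − ΣP², I = −ΣP ln P (natural log, the GenAlEx
convention), Ho = heterozygous/typed.  Two PIC variants are reported:
the simple 1 − ΣP² (identical to He, widespread in marker-development
reports) and the Botstein et al. (1980) form
1 − ΣP² − Σ<sub>i&lt;j</sub>2P<sub>i</sub>²P<sub>j</sub>², which is never
larger (fuzz-tested as an algebraic identity).  The published per-marker
PIC values sit below 1 − 1/Ne, consistent with the stronger formula
having produced them, so both are exposed; the simple form is the
default `pic` column.

Allele sharing partitions locus-scoped alleles into collection-specific
(exactly one accession carries it) vs shared; the two counts always sum
to ΣNa.

## Genetic distance and clustering

Nei (1972): D = −ln I with I = J<sub>xy</sub>/√(J<sub>x</sub>J<sub>y</sub>),
each J the per-locus mean gene identity.  The 1978 "unbiased" variant
corrects within-population identities to (2nΣx² − 1)/(2n − 1) and needs
sample sizes.  Clustering individual accessions treats each as a
population of one diploid (frequencies in {0, 0.5, 1}); loci missing in
either member of a pair are dropped from that pair's sums
(pairwise-complete; a global complete-case mode exists).  When two
frequency sets share no allele at any compared locus, I = 0 and D is
undefined: the default is an error, with `inf` and a finite cap
(default 10, far above any realistic Nei distance between conspecific
accessions) as explicit alternatives so clustering stays defined on
strongly diverged single-individual data.

UPGMA merges the closest cluster pair, with size-weighted mean update and
node height d/2; ties break on the smallest (row, column) index pair in
cluster-creation order, making trees byte-reproducible.  Bootstrap
resamples **loci** with replacement (the only unit that preserves the
taxon set when each accession is a single individual); a node's support
is the percentage of replicate trees containing its leaf set as a clade;
replicates with undefined distances are skipped and counted.  Newick
output orders children deterministically (smaller subtree first, then
lexicographic leaf name) and writes branch length = parent height − node
height; round-tripping through the bundled parser preserves topology,
heights (to ~1e-8; branch lengths are printed at 10 significant digits)
and supports.

## Synthetic data

`plant_ssrs` writes requested repeats at known coordinates into random
uniform ACGT sequence and resamples the spacers until the miner, run
under the same configuration, detects exactly the planted loci — planted
truth equals detectable truth by construction.  `simulate_genotypes`
draws two alleles per individual per locus independently from specified
frequency vectors (Hardy–Weinberg proportions) and masks cells at a given
missing rate.  Both are fully determined by their seeds.

What the simulations do **not** emulate: linkage, population structure
beyond divergent frequency vectors, genotyping artefacts (null alleles,
stutter, allelic dropout), assembly errors, or PCR failure.  Passing
tests therefore demonstrate correctness of the statistics and algorithms
under their model assumptions, not robustness to real-data artefacts.

## Packaged panels

The screening panel (100 markers × 4 accessions) and diversity panel
(50 markers × Na/Ne/Ho/I/PIC) are verbatim transcriptions of the
published validation tables for the TJIB.Eo marker set, shipped as TSV
and pinned by checksum in the tests.  One internal inconsistency of the
published summary row is worth knowing: the means of the printed
per-marker I and PIC values are exactly 1.1750 and 0.5692 (rounding to
1.18 and 0.57), while the published means read 1.17 and 0.58 — the
summary was evidently computed from unrounded per-locus values.  Tests
and the acceptance script report what the printed rows actually yield.

## Problem sizes used in validation

The oracle-equivalence suite checks the miner against a quadratic
brute-force scanner on 1,000 seeded sequences of 50–2,000 nt mixing
uniform, repeat-rich and N-containing stretches; UPGMA is checked against
brute-force re-agglomeration on 8-taxon matrices and against average
linkage from an independent library; diversity parameter recovery uses
500 simulated diploids; bootstrap demonstrations use 12 accessions ×
25 loci × 200 replicates.  These sizes give stable results while keeping
the whole suite in the low minutes.
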