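# Methods

`prica` re-implements the analysis of a high-throughput pri-miRNA cleavage
assay (HT-priCA) in which Microprocessor (the DROSHA–DGCR8 complex, "MP")
cleaves randomized pri-miRNA variant libraries in vitro, alone or together
with the SR proteins SRSF7 or SRSF3, and both the uncleaved substrates (OS)
and the 3'-cleavage products (F3 fragments) are sequenced.  This note
documents the models, conventions and numerical choices the package makes.

## Library design

A backbone is a pri-miRNA scaffold with up to three randomized groups of
exactly four nucleotides — one on the CNNC motif of the 3' flank, one
immediately upstream, one immediately downstream.  Enumerating all 4^4
substitutions per group and collapsing identical full-length sequences
yields 3×256 − 2 = 766 unique variants per backbone (the wild type arises
once per group and is kept once, tagged `wt`), hence 1,532 reference records
for the two-backbone assay and 256 for a single group.  Sequences are
normalized to RNA (U) internally; FASTA references and all read-level work
use DNA (T).

The shipped backbones are synthetic 103-nt hairpins reproducing the
published group layout (the complete assay scaffolds are not available as
machine-readable text).  Their 3' flanks carry exactly one wild-type CNNC
inside the detection window and no 17-CRC, so motif gains and losses are
driven entirely by the randomized groups.

## Coordinates

`cl0_ref` is the 1-based index of the first nucleotide of the canonical F3
fragment, i.e. the nucleotide immediately 3' of the canonical 3'-strand cut.
A product fragment whose 5' end maps at `start` reports the cleavage site
CLx with **x = cl0_ref − start**: positive x runs toward the apical loop.
This is the only orientation consistent with apical cleavage appearing at
CL8–CL14 while CL0 sits at the basal cut.  Flank offsets are negative:
offset −k is the k-th nucleotide 3' of the cut (index `cl0_ref + k − 1`).
CNNC is detected with its full span inside offsets [−22, −15]; the 17-CRC
motif (C-(A|G)-C) occupies offsets −17…−19 exactly.  When several CNNC
occurrences fall in the window, all are reported and the one closest to −17
is primary for structure classification.

Cleavage categories partition the integers: basal CL−3…CL3 (canonical if in
the backbone's canonical set — {CL0, CL1} for the miR-142-like backbone,
{CL0} for the miR-191-like one — alternative otherwise), apical CL8…CL14,
everything else "other".

## Read processing

Stage order is fixed and counts are conserved across stages:

1. **Adapter trimming** — mismatch-only search (≤10% of the overlap, no
   indels) for the 3' adapter on each mate; the occurrence closest to the 3'
   end wins; pairs with a mate shorter than 10 nt after trimming are
   discarded.
2. **Pair merging** — R1 is aligned against the reverse complement of R2 at
   every overlap ≥10 nt.  Exact overlaps are preferred (longest first),
   otherwise the longest overlap with ≤10% mismatches; at conflicting
   positions the higher-quality base wins (R1 on ties).  This tie-break is a
   package choice; the contract only requires a single admissible overlap.
3. **Quality filter** — keep reads with ≥90% of bases at phred ≥20
   (boundary inclusive).
4. **Deduplication** — one representative per exact sequence string, before
   barcode stripping, so the random-mer still separates molecules.
5. **Barcode stripping** — leading 6-mer (products) or 4-mer (OS).
6. **Assignment** — a fragment is assigned iff exactly one
   (variant, start) placement attains the minimum Hamming distance and that
   distance is ≤ `d_max` (default 2, a documented choice; the source
   analysis used aligner defaults).  Ties are unassigned; in particular a
   fragment that does not span a randomized group ties across all 256
   group-mates.  Two equivalent implementations exist: an exhaustive
   placement scan (reference semantics, used as the oracle target) and a
   backbone-decomposition assigner that splits the distance into a
   group-masked backbone term plus per-group terms and is used by the
   pipeline; their equivalence is tested on mutated and N-containing reads.

## Scoring

Counts are CPM-normalized independently within each sequencing library (OS
and product, per condition and replicate).  Per variant and condition:

    E_P = log2(N_P + 0.1) − log2(N_S + 0.1)
    E_X = log2(N_X + 0.1) − log2(N_S + 0.1)
    A_X = N_X / N_P              (undefined when N_P = 0)

with the 0.1 pseudocount applied on the CPM scale (the package's reading of
"normalized counts"; configurable in `prica.scoring.PSEUDOCOUNT`).  N_P sums
products over **all** sites, so Σ_x A_X = 1 whenever N_P > 0.  Scores are
averaged cell-wise over replicates; cells undefined in a replicate are
excluded from that cell's mean (`n_defined` records how many contributed).
Cofactor effects are plain differences against MP alone:
ΔA_X = A_X[MP+cofactor] − A_X[MP], and likewise ΔE_P, ΔE_X; undefined cells
propagate.  Variants are kept when they exceed 100 OS reads in at least one
replicate (configurable).

Homogeneity of an externally scored pri-miRNA is the maximum per-site read
fraction over the productive window (±3 nt of the annotated sites); the
human-library selection keeps rows with efficiency > 1 **and** homogeneity
> 0.1, both strict.

## Structure classification

A CNNC occurrence is classified by the number of base-paired motif
nucleotides (S0–S4).  For two or more pairs the class is "a" when the paired
motif positions form one contiguous block **and** their partners are a
strictly contiguous antiparallel run (a single uninterrupted helix), "b"
otherwise.  This is the strictest reading of the published pictorial
definition; it depends only on the pairing pattern, never on nucleotide
identity, and its image over all pairing patterns is exactly the eight
classes.  Structures are supplied as dot-bracket strings (file-based
provider by default); folding engines are injectable, never a dependency.

## Synthetic data generator

The generator defines the study conditions for all recovery tests.

* **Read anatomy.** OS reads: 4-nt random barcode + full variant.  Product
  reads: 6-nt random barcode + F3 fragment (a suffix of the variant starting
  at the drawn site).  Both are emitted as 76-nt paired-end reads with the
  RA3 adapter after R1's insert and the reverse-complement RA5 adapter after
  R2's, guaranteeing ≥10-nt mate overlap, with per-base substitution errors
  (default 0.1%) and PCR duplicates (default 5%, byte-identical pairs).
* **Count model.** Sequencing depth is fixed per library, as it is at real
  library preparation: product counts are
  Multinomial(product_depth, shares ∝ p·β) and OS counts
  Multinomial(os_depth, shares ∝ 1 − p·β) across variants; sites within a
  variant are Multinomial(π).  Defaults: 10^5 product and 1.5×10^5 OS pairs
  per condition and replicate, three replicates, basal cleavage probability
  p0 = 0.3.  The OS depth is chosen so that the >100-OS-reads coverage
  filter is met for every variant despite the 4-nt OS barcode space (256)
  collapsing some duplicates.
* **Site distribution.** π0 gives 0.45 to the canonical sites (CL0
  double-weighted when two are canonical), 0.27 to basal alternatives
  (CL−2-heavy), 0.21 uniformly to apical CL8…CL14 and 0.07 to the outlying
  sites CL−4 and CL5.
* **Effect model.** Cofactor conditions multiply both the cleavage
  probability and the canonical-site mass (renormalized) by β:
  β_CNNC = 1.8 > β_CRC = 1.4 > β_none = 1, and β is forced to 1 when the
  variant's CNNC adopts the fully paired S4a structure.  The magnitudes are
  free parameters chosen once to make the qualitative ordering visible at
  the default depth; the source data give no numeric effect sizes.
* **Structures.** Each CNNC variant draws a structure class from a
  configurable distribution (S4a weight 0.14, the fraction reported for
  human CNNC hairpins) and the class is realised as a concrete dot-bracket
  string, so the annotation stage recovers exactly the classes the effect
  model used.
* All randomness flows from one seeded generator; outputs are
  byte-identical per seed.

What the generator does **not** emulate: ligation and PCR sequence bias,
indels, quality degradation along the read, folding of the actual variant
sequences (classes are assigned, not folded), and carry-over between
conditions.  Passing recovery tests therefore demonstrate correctness of
the analysis pipeline under the stated generative model, not performance on
real sequencing data.

## Problem sizes and tolerances

The end-to-end recovery check runs one backbone (766 variants) at the full
default depth — 10^5 product pairs × 3 conditions × 3 replicates — and
requires replicate-averaged A_X within ±0.03 of the true π for ≥95% of
cells, the Δ-strata ordering CNNC > 17-CRC > none at CL0, and
|median ΔA_CL0| < 0.02 for S4a.  Unit oracles (brute-force assignment,
regex motif scan, dictionary tallies) run at 10^4 random inputs.  The
single-CPU suite completes in minutes; sizes were fixed with the study
conditions, not tuned to outcomes.

## Known limitations

* Assignment is substitution-only; indel reads are dropped as unassigned.
* The 5p-strand cut is not called — the assay reads only the 3'-strand cut
  via F3 5' ends.
* Statistical significance testing on score distributions is out of scope;
  the package emits tidy tables consumable by standard statistics tooling.
* The genome-set annotation operates on user-supplied hairpin records and
  structures; it does not download genomes or annotation databases.
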