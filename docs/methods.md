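# Methods

This note documents the models, conventions and parameter choices
behind mitokit, and what the synthetic-data tests do and do not show.

## Coordinates and annotation arithmetic

All public interfaces use 1-based inclusive coordinates on the
reference (J, majority) strand, the convention of published mitogenome
annotation tables; conversion to GenBank's 0-based half-open locations
happens only inside `mitokit.io`. A feature with end < start wraps the
origin and is legal only on circular genomes. Strand is J/N (equivalent
to H/L); N-strand features read as the reverse complement, with IUPAC
ambiguity codes complemented per their definitions.

The intergenic count before feature *i* is
`IGN_i = start_i − end_{i−1} − 1` in table order; the first feature of
a circular genome gets the wrap boundary
`start_0 + L − end_last − 1`. Summing all feature lengths and all IGNs
(including the wrap) telescopes exactly to the genome length; this
identity is asserted on the packaged *K. wangi* table and on every
synthetic genome.

Validation reports findings, never exceptions, and never rewrites the
input. The packaged *K. wangi* annotation contains an internally
inconsistent row: COII is listed with length 686 and IGN 56, but its
own coordinates (3010–3705, preceded by a feature ending at 3004) give
span 696 and IGN 5 — these two printed cells also disagree with the
telescoping identity that all other 74 length/IGN cells satisfy, so the
package treats them as typographical, flags them, and reports the
coordinate-derived values. The same applies to the published tRNA and
rRNA nucleotide totals (1484 vs summed 1485; 2221 vs summed 2212).

## Composition and skew

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed from raw counts
and rounded last (half-up, 1 decimal for percentages, 2 for skews,
matching printed precision; raw values always retained). A zero
denominator yields a missing value, not zero. Ambiguity codes are
counted separately and excluded from all denominators.

Two conventions the published tables leave unstated, fixed here and
recorded in output:

* The pooled protein-coding-gene rows use each gene's **coding-sense**
  sequence (N-strand genes reverse-complemented), because the codon
  position rows require reading frames. A reference-strand pooling
  would flip the sign of the skews contributed by the four N-strand
  PCGs.
* Start and stop codons are **included** in codon-position pooling; no
  trimming is applied.

Against the published *K. wangi* / *P. princeps* composition table, all
36 skew cells reproduce from the printed proportions to ±0.01; the
*P. princeps* 2nd-codon-position AT-skew is the one boundary case
(printed −0.01; the proportions give −0.005, which rounds to −0.00).

## Codon usage

RSCU(c) = n_c · |F| / Σ_{c′∈F} n_{c′} over the synonymous family *F*
derived from the genetic code in force. The default code is NCBI
transl_table 5 (invertebrate mitochondrial); its reassignments are
load-bearing for the published table: UCA's printed value 2.02 requires
the 8-codon serine family (AGA/AGG = Ser), AUA's 1.56 the two-codon
methionine family, and UAA's 1.56 the two-codon stop family {UAA, UAG}
(UGA translates as Trp). Stop codons are counted and form their own
RSCU family; initiators are counted as ordinary codons. A family with
zero total count has undefined RSCU, reported missing. All 64 published
RSCU values reproduce from the published counts to ±0.01.

The study's printed amino-acid usage percentages (Ile 8.12%, Leu
11.61%, Ser 11.99%, Thr 7.03%) are not derivable from the published
codon counts under any obvious denominator (e.g. serine's family total
is 305 of 3741 = 8.2%, or 305/3615 = 8.4% stop-free); mitokit reports
count-derived percentages and makes no attempt to match those figures.

## Control-region scanning

Defaults (all configurable and echoed in every report): poly-tract
minimum 10 nt (the length of the observed poly-T stretch), stem ≥ 6,
loop 3–20, at most 1 mismatched stem pair, G·T wobble pairs not counted
(DNA-level scan). A stem-loop candidate (arm start, stem k, loop l) is
valid when the mismatch budget holds and both terminal stem pairs are
true Watson–Crick pairs; only *maximal* candidates — not extendable
outward or inward while remaining valid — are reported. This
definition is deliberately simple enough to brute-force: the scanner is
tested for exact agreement with exhaustive enumeration on a thousand
short random sequences. "Downstream of the poly-T tract" means higher
reference-strand coordinate within the region; stem-loops are searched
there, poly-tracts and motifs in the whole region.

No thermodynamic folding is attempted; a reported stem-loop is a
sequence-level inverted repeat, i.e. a candidate structure.

## Neighbor joining and bootstrap

Classic Saitou–Nei agglomeration on the Q-matrix with two
determinism-fixing choices: ties in the Q-matrix minimum break on the
lowest index pair in the current working order, and negative branch
lengths (possible on non-additive input) are clamped to zero with the
deficit moved to the sister edge; the clamp count is kept in the tree's
annotations. On additive matrices NJ provably recovers the generating
tree; the tests assert exact recovery (topology and path lengths) on
100 random 4–10-taxon trees, and cross-check against an independent NJ
implementation (scikit-bio).

Distances are uncorrected amino-acid p-distances over columns where
neither sequence is gapped; a pair with no comparable columns is an
error rather than a guessed value. Bootstrap resampling draws alignment
columns with replacement over the concatenated supermatrix (not per
partition), taxa sorted canonically first so supports are invariant to
input order; supports are bipartition frequencies on the full-data NJ
tree, and a 50% majority-rule consensus is also returned. The original
description of the *K. wangi* genome additionally ran Bayesian and
maximum-likelihood analyses in external tools (MrBayes, MEGA) under
GTR+I+G; those are out of scope
here, but the supermatrix, partition table and PHYLIP/FASTA writers
provide the export path to re-run them externally.

## Synthetic data

The genome generator's defaults mirror the *K. wangi* measurements:
the 37-gene + control-region arrangement with its exact
intergenic/overlap profile (coordinate-derived, so COII spans 696 nt),
the published start/stop codon of each gene, and per-class AT targets
of 68.0% (PCGs), 72.4% (tRNAs), ~71% (rRNAs) and 78.2% (control
region). A single integer seed drives all randomness; outputs embed the
seed and a hash of the spec.

PCG interiors are sampled codon-wise, either from a user-supplied codon
distribution (for planting RSCU profiles) or base-wise at an AT level
analytically adjusted so that rejecting the two stop codons leaves the
class AT target unbiased. Start/stop codons are stamped last and
protected; overlapping genes are then repaired to a fixpoint so no PCG
contains an internal stop — overlaps shared between two genes' protected
codons raise an error rather than being silently resolved.

The control region plants, left to right with jittered gaps of at least
25 nt: one poly-T tract (10 nt), two perfect hairpins (stems 8 and 7,
loops 10 and 16 — chosen within the scanner's default ranges since the
published figure gives no parameters), one (TA)₄ run and two GAAT
motifs. Each element is boxed by CC flanks so runs cannot extend and
hairpin stems cannot grow outward; hairpin loops are drawn so the stem
cannot grow inward; payloads are re-drawn until internally free of
competing structure. After planting, the background is iteratively
scrubbed (with AT-preserving substitutions) until the region contains
no poly-tract, (TA)n run or GAAT occurrence beyond the planted ones, so
scans recover those element sets exactly. Background **hairpins are
not scrubbed**: at ~78% AT a 1251-nt region intrinsically contains on
the order of a hundred qualifying stem-6 inverted repeats — as real
control regions do — and eliminating them all would require rewriting
the background wholesale and distorting its composition. The
guarantee for hairpins is therefore exact recovery of every planted
hairpin at its planted coordinates among the scan's hits, which is what
the planted-structure tests assert.

The protein evolver is intentionally minimal: along a branch of length
*t* each site is replaced with probability 1 − (1 − μ)^t (μ = 0.05 per
unit length by default), drawing uniformly from the other 19 residues;
no rate heterogeneity, no substitution matrix, no indels. It is
adequate for validating distance and tree-building code — clean
tree-like signal with binomial noise — and says nothing about
performance under realistic protein evolution, alignment error or
compositional heterogeneity. The default 13-taxon guide tree embeds a
(stonefly_A, stonefly_B) + mayfly clade among ten other insect-order
tips with a dragonfly outgroup, mirroring the study's taxon sampling;
per-gene lengths equal the published amino-acid lengths of the 13
PCGs (3768 positions concatenated). Likewise, passing composition
tests on iid-sampled synthetic genomes shows the estimators are
correct, not that real genomes are iid.

## Problem sizes in the test suite

The suite regenerates all data at run time: three default 16,179-nt
genomes, a 13-taxon × 3768-column alignment, 500 bootstrap replicates
for the clade-support check, 100 random additive matrices for NJ
recovery, and 1000 random ≤40-nt sequences for the brute-force
stem-loop comparison (stem ≥ 4, loops 3–12 there, to pack more
structure into short sequences). The whole suite runs in well under a
minute on one CPU.

## Known limitations

* De novo annotation (tRNA detection, gene boundary inference) is out
  of scope; the package consumes annotations.
* The stem-loop scanner reports sequence-level candidates, not folded
  structures with energies.
* Wrap-around (origin-spanning) features are supported in coordinate
  arithmetic and sequence extraction, but the IGN table assumes
  non-wrapping features, and the GenBank writer does not emit compound
  locations.
* Bootstrap supports are NJ supports; they are not comparable to the
  Bayesian posterior probabilities reported alongside NJ/ML values in
  published figures.
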