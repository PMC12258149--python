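# Methods

This note documents the models, estimators and design choices behind
`zwscan`, and what the synthetic generator does and does not emulate.

## The system being modelled

A young female-heterogametic (ZW) sex chromosome: females carry one Z and
one W, males two Z's. The Z is partitioned into a pseudo-autosomal region
(PAR) that still recombines and two evolutionary strata that stopped
recombining at different times — Stratum 2 (younger, lower W–Z divergence)
and Stratum 1 (older, higher divergence). Once recombination stops, the W
copy of each gene accumulates substitutions independently of the Z and
begins to degenerate: whole-sequence loss, exon loss, open-reading-frame
disruptions (start-codon loss, premature stops, frameshifts) and splice-site
mutations. Loss of W expression may be followed by female-specific
upregulation of the Z allele (dosage compensation), which moves a gene's
Z<sub>female</sub>/ZZ<sub>male</sub> expression ratio from 0.5 toward 1.

## Synthetic generator (`zwscan.simulate`)

All randomness flows from one `numpy.random.Generator` seeded from
`SimConfig.seed`; submodules draw in a fixed documented order (sequence,
genes, W derivation, cohort, coverage, expression, trees, reads), so the
same seed and config give byte-identical output files.

**Defaults and what they emulate.** 2 Mb chromosome with PAR 0–0.7 Mb,
Stratum 2 0.7–1.4 Mb, Stratum 1 1.4–2.0 Mb; 20 genes per region (CDS
600–1500 bp, 2–6 exons, introns 200–800 bp, GT…AG termini); per-region W–Z
synonymous divergence 0.016 / 0.020 / 0.035 and Ka/Ks 0.31 / 0.45 / 0.50 —
the per-region statistics of a recently described fish ZW system, with the
physical scale reduced roughly 20-fold so generation takes seconds;
loss-of-function probabilities 0 / 0.271 / 0.544 with class weights
(80, 30, 151, 71)/332; cohort 12 females + 12 males (half the study-scale
cohort, keeping the same per-sex ascertainment logic); sequencing depth 10;
per-site heterozygosity 0.005 in recombining regions (a typical marine-fish
value) and 20% of that for Z-linked polymorphism inside the SLR; missing
genotypes 2% and genotype errors 0.5% by default (tests of exact truth
recovery set both to 0, as the corresponding claims assume error-free
calls); expression with negative-binomial counts (dispersion size = 10, mild
overdispersion that does not destabilise ratio statistics at desk scale) and
a configurable compensated fraction (default 0.1 of hemizygous-like genes);
gene-tree class counts (164, 20, 6).

**Coding-sequence divergence.** `evolve_cds` draws Poisson(S·dS) synonymous
and Poisson(N·dS·ω) nonsynonymous substitution events, where S and N are the
ancestor's fractional NG86 site counts, and applies them sequentially,
uniformly over the currently available single-base changes of the matching
kind. Every admissible target nucleotide is equally likely (Jukes–Cantor
behaviour), stop codons are never created, and the start and stop codons are
frozen (start-codon loss is a *planted* event, not background divergence).
Multiple hits at a site occur naturally, which makes the downstream NG86+JC
estimator's multiple-hit correction the exact inverse of the generative
process; the calibration tests verify <5% relative bias for dS in
[0.01, 0.08] and the acceptance script reproduces the stratum means within
±0.003.

**Planted loss of function.** `sequence_loss` deletes a contiguous genomic
chunk covering ≥55% of the CDS; `exon_loss` removes one complete exon;
`orf_disrupt` picks one of start-codon mutation, a planted in-frame stop, or
an indel of length 1, 2 or 4; `splice` breaks exactly one GT donor or AG
acceptor. Background intron/intergenic divergence protects splice
dinucleotides so intact genes can never be misread as splice-disrupted.

**Cohort genotypes.** W-specific substitutions make females heterozygous
and males homozygous-reference; PAR and autosomal sites are Hardy–Weinberg
draws with allele frequency ~ U(0.1, 0.9) at a segregating-site density
matched to the target heterozygosity; Z-linked SLR polymorphism gives
females a single Bernoulli Z dose. Genotype errors shift the dosage
uniformly; missingness is applied afterwards.

**Coverage.** Window depth is Poisson around `depth_mean`, with female depth
scaled by 1 − 0.5·(deleted fraction of the window) over spans missing from
the W. One large (120 kb) W deletion is planted in a gene-free stretch of
Stratum 1 so that at least one 50-kb window is fully deleted (log2 F:M = −1).

**What the generator does *not* emulate.** Read-level errors and quality
strings; recombination within the PAR; linked selection and demography;
inversion breakpoints at nucleotide resolution; mapping bias and paralogy.
Passing tests therefore demonstrate the correctness and calibration of the
estimators under the stated generative model, not robustness to alignment
artefacts in real data. No published generative model exists for these
quantities; the distributional choices are stand-ins, flagged as such in the
truth table.

## Estimators and numerical choices

**Sex-linked variants.** Missing genotypes never count as heterozygous or
homozygous. `hom_policy="all"` (every individual of the homozygous sex
observed homozygous) matches the ascertainment used for degeneration
analysis; `"min_count"` (≥ `min_het` homozygotes) is the discovery-scan
variant. The heterogamety call requires an 80% majority of qualifying
variants.

**Weir–Cockerham F<sub>ST</sub>.** The two-population diploid estimator with
variance components a (among populations), b (among individuals within
populations), c (within individuals); windows report the weighted estimator
Σa/Σ(a+b+c). Monomorphic variants and variants with an all-missing sex are
skipped. Windows tile physically (fixed bp, half-open), not by SNP count.

**Changepoint.** Segment cost n·log(σ̂²_MLE) with a variance floor of 1e-12;
`force_one` returns the arg-min split with ties broken toward the smaller
index; `penalized` additionally requires the cost drop to exceed 3·log(n)
(three extra parameters: one mean, one variance, one boundary). The split is
exhaustive, so it trivially equals the exhaustive oracle; a constant series
is returned flagged with zero improvement.

**RBH.** Global protein alignment (BLOSUM62, gap open −11 / extend −1).
A pair must be mutually unique-best (score ties dropped), have ≥0.6 aligned
fraction both ways, and score at least 0.2 of the smaller self-alignment
score — a normalised floor that removes chance reciprocal pairings between
unrelated sequences (observed ≈0.00 on decoys vs ≈0.99 on gametologs).

**NG86+JC.** Fractional site counts per codon averaged over the two
sequences; multiple-substitution codons averaged over shortest pathways with
equal weights, pathways through stop codons excluded (all pathways used if
every one is blocked); gap codons and codons that are stops in either
sequence excluded pairwise; proportions ≥ 3/4 flagged saturated. Saturated
or length-mismatched (defective) pairs are excluded from stratum means by
default. The Jukes–Cantor form is the standard correction for NG86 and is
the one implemented; the PAR mean is reported but labelled
diversity-dominated, since a haplotype comparison in a recombining region
measures polymorphism, not divergence.

**Dating.** rate = interspecies K<sub>s</sub> / split time — a
pairwise-divergence-per-year convention with no factor of two, i.e. W–Z
pairs are assumed to accumulate pairwise divergence at the same rate as the
species pair. Degeneration rates: %/MY = %LoF / age; %/Mgen = %/MY × years
per generation. The strata report flags that published per-stratum %/Mgen
figures with the reverse stratum assignment are inconsistent with this
arithmetic; the implementation follows the arithmetic.

**W-allele classification.** Per-exon local alignment (match 2, mismatch −3,
gap open −5, extend −2), searched left-to-right so exon order is preserved.
An exon is *lost* when the local score is below the exon length (a genuine
homolog scores near twice its length; spurious hits in a few kb of unrelated
sequence stay far below it) or when <20% of its bases align. Up to 4 trimmed
terminal bases are re-extended so splice termini line up after terminal
mismatches. Classes are assigned with the fixed precedence sequence_loss →
exon_loss → orf_disrupt → splice_disrupt → intact, making counts exclusive
and exhaustive; "exon loss" means ≥1 complete exon (configurable
`min_lost_exons`, default 1). A premature stop is an in-frame stop at least
one codon before the annotated stop. Non-GT/AG termini are only reported
from aligned exon boundaries, so unaligned regions cannot create splice
calls.

**TPM and ratios.** tpm = (count/length_kb) · 1e6 / Σ(count/length_kb) per
sample. Female allele expression = allele fraction × gene TPM (allele
fractions are not re-normalised to TPM separately); replicates aggregate by
arithmetic mean; per-sample W:Z terms with zero Z counts are dropped from
that gene's mean; genes with mean male TPM < 1 are excluded (an expression
floor — no floor is inherent in the definition, so it is configurable).
Category boundaries 0.256 and 0.667 are fixed configuration defaults.

**Dip statistic.** Computed from the definition: the dip is the smallest d
such that some unimodal CDF lies within the sup-norm band F̂ ± d. On unique
points with cumulative fractions c_j, the node bands are [c_j − d,
c_{j−1} + d]; a convex nondecreasing piece fits a prefix iff the greatest
convex minorant of the upper band clears the lower band (the mode node is
exempt, since a unimodal CDF may jump at its mode), and symmetrically for
the concave suffix via the least concave majorant; the mode may also sit
between two nodes, in which case both junction jumps must be ≤ 2d. d is
found by bisection (50 iterations) with numba-compiled feasibility checks.
The implementation is verified against an independent linear-programming
feasibility oracle on small samples and against exact values (a balanced
two-point sample gives 0.25; n evenly spaced points give 1/(2n)). The
p-value is the Monte-Carlo fraction of uniform(0,1) samples of the same size
with dip ≥ observed; calibration and power are test-verified.

**GMM.** 1-D EM with tolerance 1e-8 on the log-likelihood, ≤500 iterations,
variance floor 1e-6, best of 10 random initialisations per k; BIC =
−2·logL + (3k−1)·log n; k chosen by minimum BIC. The per-iteration
log-likelihood trace is retained (and tested to be non-decreasing); an
all-equal sample returns k=1 with a zero-variance flag. The mixture is run
only on the low-W:Z categories, where a compensated subgroup appears as a
second mode near 1. `scikit-learn`'s GaussianMixture serves as an
independent cross-check in the test suite.

**Gene trees.** Trees are pruned to the four decisive taxa and rooted on the
outgroup; the smallest clade containing Z and W decides Z–W sister, else the
sister species' pairing with exactly one of Z/W decides W loss or Z loss;
polytomies that leave this unresolved are unclassifiable rather than being
resolved arbitrarily. No support filter is applied by default
(`min_support` exists for annotated trees). Percentages are reported to the
nearest whole percent.

## Conventions and problem sizes

Coordinates are 1-based inclusive everywhere (VCF/GFF convention); windows
are half-open [start, start + size). The VCF dialect is v4.2 with GT-only
FORMAT and "." for missing; phased separators are accepted with phase
ignored. The k-mer store is an exact hash set; at desk scale this needs no
probabilistic approximation.

The test suite and the acceptance script run simulations at deliberately
small sizes chosen as the package's own desk-scale defaults: a 2 Mb
chromosome with 60 genes, 300-pair estimator-recovery runs, 1,200–2,000
Monte-Carlo null draws for the dip, and a few hundred replicates for
calibration checks. These sizes give Monte-Carlo errors comfortably inside
the asserted tolerances (e.g. the 300-pair mean K<sub>s</sub> has a standard
error ≈ 0.0006 against a ±0.003 tolerance).

## Known limitations

- The CDS-to-region aligner is a simplified exon-aware nucleotide aligner;
  it does not do spliced alignment across megabases or frameshift-aware
  protein alignment, and defective pairs are classified rather than entering
  K<sub>s</sub> averages.
- The dip p-value null is uniform(0,1), the standard calibration for the
  dip test; heavy-tailed unimodal alternatives are conservative cases.
- Variant-effect annotation is reduced to the five W-allele classes; no
  full transcript-effect ontology is attempted.
- The generator emits + strand genes only; strand handling in readers is
  validated but reverse-strand gene models are untested territory.
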