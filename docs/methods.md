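# Methods

## Overview

`keycontrib` implements an unsupervised three-step analysis of population
structure for genotyped (livestock) populations:

1. **Relationship matrix.** A symmetric n×n genomic relationship matrix
   **G**, by default the identity-by-descent (IBD) sharing proportion:
   entry (i, j) is the summed length of IBD segments between i and j over
   the total autosome length. Alternatives: VanRaden method-1 allele
   sharing, and the pedigree numerator matrix **A**.
2. **Key contributors.** The eigendecomposition **G** = **UΛU**ᵀ, the number
   *k* of significant components by Horn's parallel analysis, standardized
   eigenvectors **s**ᵢ = **u**ᵢ/√λᵢ, projections r᙮ij = **s**ᵢᵀ**g**ⱼ, and the
   genetic contribution score gcⱼ = Σᵢ₌₁ᵏ r᙮ij². The top-*k* individuals by
   gc are the key contributors: the individuals spanning the subspace that
   carries most of the variance of the relationship structure.
3. **Network.** Genetic distances **D** = 1 − **G**, a mutual k-NN graph
   (k = 10 default), nodes annotated with gcⱼ, admixture proportions aⱼ and
   key-contributor flags, exported as GraphML.

A selection module compares reference-set strategies (Con = key
contributors, Rel = greedy captured-relationship-variance, Ped =
pedigree marginal gene contributions, Ran = random), and an evaluation
module provides the haplotype switch-error rate and genomic inbreeding.

## IBD relationship matrices

Segment detection is a seed-and-extend scheme over phased haplotypes in the
GERMLINE style: each chromosome is cut into consecutive non-overlapping
slices of `bits` SNPs (default 9); haplotype pairs with identical slice
words (exact hashing) are match seeds; maximal runs of consecutive matching
slices become segments. A single non-matching slice flanked by matching
ones is bridged when the two individuals conflict at ≤ `err_hom` (default
1) opposite-homozygote sites within it. Segments shorter than
`min_length_bp` (default 3 Mb, the usual GERMLINE-scale minimum; the
original parameterization is in cM, ≈ Mb at 1 cM/Mb) are dropped.

Per individual pair, haplotype-level segments are **unioned**, so a region
shared by several haplotype combinations counts once. Consequences worth
knowing: every parent–offspring pair has G = 1 exactly (the transmitted
gamete matches one parental haplotype everywhere), half sibs ≈ 0.5, full
sibs ≈ 0.75. This scale differs from the numerator matrix (0.5/0.25/0.5)
but is what "summed segment length over genome length" yields. The
diagonal is 1 plus the within-individual sharing (genomic inbreeding),
mirroring the exact oracle below.

On simulated data the detector is validated against an *exact* IBD oracle:
gene dropping tracks every chromosome segment back to its founder
haplotype, so true sharing can be computed from ancestry labels either
exactly (segment arithmetic) or on a 1 Mb grid (numba kernel, used at
population scale). Detected vs exact off-diagonals correlate > 0.99 at
desk scale; over-calling is bounded by a few slices per segment end.

## Number of significant components

Horn's parallel analysis compares the observed eigenvalue at each rank with
the Monte-Carlo distribution of eigenvalues of structure-free data of the
same dimensions, retaining leading components while the observed eigenvalue
exceeds the 1 − α null quantile (α = 0.01 default; iterations default 100 —
the rank-wise quantiles stabilize quickly, and the classic recommendation
of 10⁴ iterations changes k by at most ±1 on these designs).

Two deliberate choices:

* **The matrix is analyzed as data.** G enters the parallel analysis as an
  n-observation × n-variable data matrix whose PCA spectrum is compared to
  that of n×n standard-normal data, exactly how the *paran* procedure
  treats an input data frame. The raw eigenvalues of the IBD G itself
  spread structure too thinly for a variance-proportion reading (20 family
  components hold only ~26% of trace on the founder design); the PCA-of-G
  spectrum concentrates them (~93%), which is the scale on which the
  variance-proportion results of this method are interpretable.
* **Columns are scaled but not centered.** Centering projects out the
  grand mean, so q disjoint family blocks leave only q−1 contrasts;
  without centering each family contributes its own component, and the
  founder design yields exactly the 20 components that correspond to its
  20 sire families. The null replicates receive the identical treatment,
  so the comparison stays rank-faithful (for standard-normal data the
  column means are ~0 and centering is immaterial for the null).

The retention rule is contiguous (stop at the first rank inside the null
band). A plain count of all ranks exceeding the null is wrong in practice:
a structured spectrum dips below the Marchenko–Pastur-like null bulk in the
deep tail and re-crosses it near rank n, which a count would book as
hundreds of spurious "significant" components.

A permutation null is available as an option (`null="permutation"`): each
replicate permutes every SNP column of the dosage matrix independently
(destroying relatedness and LD, preserving allele frequencies) and rebuilds
a VanRaden matrix. It requires genotypes and is much more expensive; the
Gaussian null is the default and is what the reported results use.

For n > 3,000 the spectra are computed in single precision and the null
iterations are reduced (30 for the full 5,100-individual panel); eigenvalue
magnitudes are O(1)–O(n), far above float32 resolution, and the variance
proportion uses the exact trace so partial spectra lose nothing.

## Contribution scores

r᙮ij = **s**ᵢᵀ**g**ⱼ is implemented literally as the projection of
individual j's relationship profile, not as a Pearson correlation.
Closed forms used as test oracles: r᙮ij = √λᵢ·u᙮ij, hence gcⱼ → G᙮jj as
k → n and Σⱼ gcⱼ = Σᵢ≤ₖ λᵢ. Ranking ties break by stable input order.
For large n only the leading eigenpairs are computed (Lanczos); gc needs
just the retained components.

## Selection strategies

* **Rel** maximizes v(S) = meanⱼ G₍ⱼ,S₎ G₍S,S₎⁻¹ G₍S,ⱼ₎ greedily; the
  implementation is a pivoted-Cholesky-style rank-one residual update with
  a 10⁻⁸·tr ridge, so near-duplicate candidates add ~zero gain and are
  never picked twice. Greedy is not globally optimal in general; on
  family-structured matrices it coincides with exhaustive search (tested).
* **Ped** iterates marginal expected gene contributions: each round scores
  candidate a by the expected share of reference genes whose transmission
  path reaches a without passing through an already-selected individual,
  times the fraction of a's own genome not descending from selected
  ancestors. The two factors make successive scores a partition of the
  reference gene pool (their sum never exceeds 1).
* **Con**/**Ran** are top-gc and seeded uniform sampling.

## Simulated study design

The built-in generator reproduces a five-generation random-mating design:
F0 = 20 males + 1,000 unrelated females; each later generation mates every
sire to 50 dams, each dam leaving one female except 20 dams (redrawn per
generation) leaving a male + a female — 1,020 individuals per generation,
5,100 total. Genome: 5 chromosomes × 100 Mb × 2,000 equally spaced SNPs.
Recombination is Haldane (Poisson crossovers at 1 Morgan/100 Mb, uniform
positions, no interference). Founder haplotypes carry independent alleles
at Uniform(0.05, 0.95) frequencies; a single seed drives pedigree, founder
and meiosis substreams.

What the generator does **not** emulate: founder linkage disequilibrium and
background relatedness. Founder genomes produced by historical-population
simulations (the usual source for this kind of design) carry background IBD
sharing that (a) fattens the spectrum bulk of the founder-generation panel
and (b) amplifies inbreeding in later generations, making highly inbred
individuals stand out as extra significant components. With clean founders
the component count equals the number of sire families in the panel (20
for F0-males+F1; 40 for +F2; ~86 on the full population) and the top-k
variance share of the founder panel is higher (~93%) than with noisy
backgrounds. Passing tests therefore demonstrate that the method resolves
exactly the relatedness structure the data contains — not any particular
reference magnitudes; the founder-male recovery, the strict containment of
all 80 sires in the top 115, and the Con ≤ Ran phasing ordering are
structure-driven and robust to this difference.

## Switch-error evaluation

Phase orientation is compared at heterozygous sites only; a switch is an
orientation change between consecutive het sites within a chromosome; the
rate is s/Σ_c(h_c − 1) pooled over chromosomes (no phantom switches across
chromosome boundaries). Global haplotype swaps score 0. Individuals with
fewer than two het sites are excluded from the cohort mean. The cohort
statistic is the mean of per-individual rates; a pooled-count rate is also
reported.

Since re-implementing production phasers is out of scope, strategy
comparisons use a pluggable phaser interface with two built-ins: a
constant-rate orientation flipper (calibration: measured rate ≈ ε), and a
relatedness-informed noiser whose per-individual flip rate is
ε_max/(1 + 0.2·Σⱼ Gᵢⱼ) — individuals with many close relatives are phased
more accurately, the empirical behaviour of pedigree/population phasers.
The strategy-ordering result (Con ≤ Ran) follows from the selection
geometry given that monotonicity assumption, and is what the harness
verifies; absolute switch-error percentages reported for production
phasers are phaser-specific and not reproduced.

## Numerical choices and edge cases

* Eigenvalues ≤ 10⁻¹⁰·λ₁ are treated as zero; standardized vectors are
  undefined there and raise.
* Distances 1 − G are clamped at 0 (inbred diagonals exceed 1) with a
  clamp count reported.
* k-NN ties at the k-th neighbour break by stable input order; mutual mode
  may isolate nodes (kept, degree 0).
* Monomorphic SNPs are excluded from VanRaden scaling and inbreeding
  expectations; missing genotypes are wildcards inside detection slices.
* HWE filtering uses the exact conditional test; the Mendelian screen
  counts opposite-homozygote parent–offspring conflicts per SNP.

## Problem sizes used in validation

Desk-scale checks run on a 200-individual two-generation version of the
design (4 sires × 96 dams, 2 × 50 Mb chromosomes). Study-scale runs use
the full 1,040/2,060/5,100-individual panels with 100/100/30
parallel-analysis iterations and partial spectra (top 250) at n = 5,100;
the exact-IBD oracle is evaluated on a 1 Mb grid at these sizes.
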