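# Methods

## Scope

The package implements a weighted single-step GWAS pipeline for a single
quantitative trait: quality control, relationship matrices, mixed-model
solving, iterative SNP reweighting, window-variance decomposition, window
selection, and gene/miRNA network summaries.  Variance components are
inputs, never estimated — the pipeline assumes `sigma_a2` and `sigma_e2`
come from a prior (pedigree-based) analysis.  Multi-trait models,
dominance, permanent-environment effects, REML/Gibbs estimation, APY-type
large-scale G inversions and metafounders are out of scope.

## The animal model and H inverse

The model is `y = Xb + Za + e` with breeding values for every pedigree
animal, `a ~ N(0, H sigma_a^2)`, `e ~ N(0, I sigma_e^2)`.  The equations
are solved with `lambda = sigma_e^2 / sigma_a^2` multiplying `H^-1`.

* **A** is built by the tabular method in topological order (diagonal
  `1 + F`); its sparse inverse uses Henderson's rules with
  Mendelian-sampling variances from parental inbreeding, so `A^-1 A = I`
  holds on inbred pedigrees too.  The pedigree container completes
  missing parents as founders and rejects cycles.
* **G** is VanRaden's method 1, optionally SNP-weighted:
  `G = M D M' / (2 sum p(1-p))`.  Allele frequencies are the observed
  frequencies of the genotyped, QC-passed set (base-population
  frequencies are unavailable in practice); missing dosages are imputed
  to the column mean before centering.  No rescaling of `G` to the
  `A22` means is applied before blending.
* The blend `0.95 G + 0.05 A22` (coefficients configurable) restores
  invertibility: with observed-frequency centering the ones-vector lies
  in the kernel of raw `G`, so raw `G` is never invertible on its own.
  Inversion is by Cholesky with an explicit failure (eigenvalue range
  reported) rather than a silent pseudo-inverse; near-zero pivots are
  rejected at a relative threshold of 1e-7.
* `H^-1` adds the genotyped-block correction `(G_blend^-1 - A22^-1)` to
  `A^-1` and equals `A^-1` exactly elsewhere; with no genotyped animals
  the pipeline is pedigree BLUP.

Fixed effects use reference coding: the first factor keeps all level
dummies (absorbing the intercept), later factors drop their first level.
Crossed contemporary-group factors are inherently confounded with the
intercept, so individual level estimates are not estimable functions;
everything used downstream (fitted values, GEBV, DGV) is
constraint-invariant, which the tests assert by comparing against full
dummy coding.  The solver is a sparse symmetric factorization with a
dense minimum-norm least-squares fallback for rank-deficient systems;
solutions are checked against a relative residual of 1e-8.

## The weighted scan

Each iteration back-solves SNP effects `u = (1/c) D M' G^-1 a` from the
direct genomic values (default) or raw GEBV.  DGV are preferred because
genotyped animals enter the evaluation with heterogeneous accuracies;
`DGV_i = -(sum_{j!=i} g^{ij} GEBV_j)/g^{ii}` with `g^{ij}` from the
blended-G inverse.

The `1/c` scalar is not part of the commonly printed back-solve formula
but is included by default so that `M u` algebraically reconstructs `a`
whenever `G` is full rank (`M D M' = c G`), making the window variances
live on the scale of `sigma_a2`.  `backsolve_scaling=False` reproduces
the literal formula; it changes `u` by the global factor `c` only.

Weights: every SNP in a block of 20 adjacent SNPs (consecutive in map
order, restarting at chromosome boundaries; the final block per
chromosome may be shorter) receives the common weight `sum(u_i^2)` over
the block, and the weight vector is rescaled to keep its trace equal to
the SNP count — total genetic variance is preserved exactly, which the
tests assert to 1e-9.  An all-zero effect vector falls back to uniform
weights.  The loop runs two iterations by default; later iterations are
known to degrade breeding-value accuracy.

Window variance is the empirical variance (denominator n-1) across
genotyped animals of the window score `sum_i M_i u_i`, divided by
`sigma_a2`, times 100.  Selection keeps windows at or above 1%
(inclusive, "1% or more").  Because the back-solve distributes signal
across correlated SNPs, per-window shares do not sum to the total
genetic variance — window scores are correlated through family
structure and LD.

## Quality control

Filters are per-unit predicates; the surviving set is order-independent,
but each removed unit is attributed to the first filter it fails, so the
per-filter counts plus survivors always sum to the input size.

* SNP order: unknown position (chromosome "0"), sex chromosome ("X"/"Y"),
  call rate < 0.98, MAF < 0.01, Hardy-Weinberg.  The HWE rule is the
  literal frequency deviation `|het_obs - 2p(1-p)| > 0.15`, not a
  chi-square test.
* Animal order: missing rate > 0.10; parent-progeny opposing-homozygote
  rate > 0.01 (the progeny is removed — the source material does not say
  which member was dropped); pedigree-genomic deviation; no phenotype
  for any analyzed trait (the "all traits missing" reading of an
  ambiguous exclusion; configurable).
* Animal filters run before SNP filters, and allele frequencies for
  MAF/HWE are computed from the post-animal-filter genotypes.
* The deviation rule compares `G` and `A22` on a deterministic subsample
  of at most 5000 informative autosomal SNPs (observed MAF >= 0.05):
  diagonal deviations > 0.25 are flagged first, then pairwise deviations
  > 0.5 among the remaining animals.  Flagging diagonally aberrant
  samples first matters because one grossly deviant sample distorts
  every pairwise entry it touches.  Thresholds are configurable; no
  values for them are published.

Yearling weight is the linear extrapolation of the final test-period
gain to day 365: `YW = (W_t - W_prev)/(t - t_prev) * (365 - t_prev) +
W_prev`.  Marbling-score records before 2005 are dropped by default
(pre-2005 scores used an incompatible scale).

## Synthetic data

The generators emulate the statistical structure the model assumes, not
bovine genome biology:

* **Pedigree**: discrete generations, random mating among the previous
  generation, sexes alternating at birth.
* **Genotypes**: gene dropping from founder frequencies drawn uniformly
  from a MAF range.  By default loci segregate independently — which
  keeps every oracle tractable but gives window statistics little power,
  since a causal SNP's 19 window-mates are then pure noise.  The
  `ld_block_size` mode draws founder haplotypes from one uniform variate
  per block and transmits parental haplotypes per block (complete
  linkage within, free recombination between): a crude LD surrogate
  under which window-based detection behaves like it does on real dense
  panels.  Real LD decays smoothly with distance and is not block
  diagonal; passing detection tests here shows the machinery works, not
  that power on cattle data is as high.
* **Phenotypes**: fixed-effect levels drawn per record, a QTL part
  (centered dosage times effect), a polygenic part generated down the
  pedigree with Mendelian-sampling variance `sigma_a2/2 (1 - (F_s +
  F_d)/2)` using inbreeding from the A recursion, and i.i.d. residuals.
  True components are retained for recovery tests.  `sigma_a2` in the
  simulation config is the polygenic variance; QTL add to it.
* **Detection-power conditions**: the one-QTL study uses 500 animals
  (100 founders, 4 generations), 2000 SNPs in 20-SNP LD blocks, QTL
  variance pinned at 25% of the total additive variance via the realized
  allele frequency, heritability 0.4, all animals genotyped and
  phenotyped, 20 replicate seeds.  The null study is identical but with
  no QTL, 1700 SNPs and the default independent-locus genome.  With LD
  blocks a two-iteration null scan can push a lucky window above a few
  percent (the reweighting amplifies whatever leads after iteration
  one — a winner's-curse effect), which is why the null bound is stated
  for the default genome and why reported GV% of selected windows should
  be read as conditionally biased upward.
* **QC fixture**: a panel in which exactly the specified number of units
  trips each filter and nothing else does.  Genotype counts per column
  are pinned exactly in the surviving-animal block (random row
  permutations of a fixed count vector), which makes the fixture stable
  at any panel size; failure classes are constructed disjoint (e.g.
  low-MAF columns have full call rate, all-heterozygote columns carry
  MAF 0.5).  The study-scale spec (45,304 SNPs / 1,679 animals in;
  34,460 / 1,540 out) reproduces the published per-filter accounting.

## Printed-table fixtures

The packaged window table transcribes the published summary of selected
windows: 42 (trait, window) rows, 33 distinct windows, 7 pleiotropic.
One EMA window on chromosome 6 lists no annotated genes and is kept with
an empty member list.  The single lowercase `bta-mir-2379` entry is
typed miRNA; uppercase MIR symbols (MIR124A-2, MIR3064) are gene nodes —
the only assignment consistent with the published per-trait counts.

Counting conventions matter: per-trait totals of 100/136/72/50/128 and
the 486-edge network arithmetic are **entry-level** (a symbol recurring
in two windows of one trait counts twice), while trait-overlap counts
(e.g. 88 genes shared by CW and YW) are unique-symbol counts.  The table
yields 362 distinct symbols; published dedup totals quoted elsewhere
(371, 366) cannot be derived from the printed rows and are therefore not
asserted anywhere in the package.  The miRNA-target fixture lists the 42
genes reported as suppressed by the three detected miRNAs; no per-miRNA
assignment was published, so the edge helper pairs every miRNA with
every gene (the coarsest consistent graph), and the two symbols that
appear in no selected window (PPM1L, SLC31A1) carry a provenance flag.

Enrichment replaces the external annotation services used in the
original analysis with a generic exact hypergeometric over-representation
test on user-supplied gene sets (GMT), Benjamini-Hochberg adjusted;
published p-values are database-version-dependent and not reproduced.

## Numerical choices

* Symmetry tolerance on relationship matrices: 1e-8 (enforced), stored
  symmetrized.
* Mixed-model residual check: 1e-8 relative; Cholesky pivot rejection at
  1e-7 relative; oracle agreement asserted at 1e-6.
* Reweighting: trace conservation exact to 1e-9; reconstruction
  `M u = a` to 1e-8 on full-rank G.
* Ties at the 1% selection threshold are kept (inclusive rule).
* Every stochastic routine takes an explicit seed; the pipeline seed
  fans out deterministically to sub-generators via stable label hashes.
  Identical seeds give byte-identical pipeline outputs (checksummed
  manifests).

## Problem sizes

Tests and the acceptance script run the full QC accounting at study
scale (45,304 SNPs x 1,679 animals, G-subsample 5,000 SNPs), oracle
comparisons on 10-50 animal pedigrees, and 20 + 20 replicate detection
studies at 500 animals x 2,000/1,700 SNPs — sizes at which every dense
oracle is exact and the whole suite runs in about a minute.

## Known limitations

* No within-chromosome recombination model beyond the block surrogate;
  no selection, assortative mating, genotyping error or map error.
* Window GV% of selected windows is conditionally biased upward
  (selection + reweighting); the package reports final-iteration values
  without bias correction.
* The G-blend is applied for invertibility only; no tuning of G to the
  A22 means, no metafounders.
* The CLI solves dense-ish systems via sparse LU; truly large evaluations
  (hundreds of thousands of equations) would need iterative solvers and
  APY-type approximations that are deliberately out of scope.
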