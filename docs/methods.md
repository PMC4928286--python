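# Methods

## Model

A methylation study on a heterogeneous tissue measures, for each of `n`
specimens, the methylated fraction ("beta value", in [0, 1]) at each of `m`
CpG sites.  Because every specimen is a mosaic of cell types with distinct
methylomes, the observed matrix `Y` (CpGs x specimens) is modelled as a
constrained mixture

    Y = M Omega'

where `M` (m x K) holds the methylomes of `K` putative constituent cell
types, with every entry in [0, 1], and `Omega` (n x K) holds per-specimen
mixture weights on the sub-simplex: non-negative, each row summing to at
most one (the slack absorbs unmodelled constituents).  Unlike PCA-based
surrogate methods, both factors retain their biological meaning: columns of
`M` are candidate cell-type methylomes and rows of `Omega` are composition
vectors.  `K = 1` is a valid model — a homogeneous tissue with no relevant
constituent structure.

## Fitting

`deconvolve` alternates two families of exact convex subproblems:

* **proportions** — for each specimen, least squares of its observed betas
  on the current `M`, subject to non-negativity and a unit sum bound;
* **methylomes** — for each CpG, least squares of its observed betas on the
  current `Omega`, subject to box bounds [0, 1].

Each half-step solves its block to optimality, so the residual sum of
squares (over observed entries only; missing cells are simply excluded from
every subproblem) is non-increasing — this is asserted by the test suite on
every recorded trace.  The K-dimensional QPs are solved by block principal
pivoting on the normal equations (`_qp.py`); all subproblems in a half-step
share one Gram matrix, so the linear solves are batched by active-set
pattern, which is what makes bootstrap resampling affordable.  Solutions
are verified against a KKT tolerance of 1e-8, with SLSQP polishing as a
safety net (grid-search, BVLS and SLSQP serve as independent oracles in the
tests).

Initialization uses Ward clustering of specimens (Euclidean distance on
complete-data CpGs) with per-cluster mean profiles; additional restarts
jitter that start by +-0.05 uniform noise (5 restarts by default).  The
default 25 outer iterations refer to the alternating loop, with early stop
when the relative rss change falls below 1e-6.  Fitted columns are ordered
by descending mean proportion so runs are reproducible.  Zero-signal input
yields all-zero proportions (the sub-simplex permits it), a deterministic
tie-break.

### Identifiability

The factorization is identifiable only up to column order (handled by
`match_columns`, exact bipartite matching on column RMSE).  Two further
caveats are inherent to the constraints and documented because they shape
the tests:

* if all rows of `Omega` sum strictly below one, each column of `M` can be
  rescaled against its proportion column — recovery of a scale is only
  meaningful when compositions genuinely reach the sum-one boundary;
* even with sum-one rows and "anchor" CpGs (sites fully methylated in one
  type and unmethylated in the rest), an exact-fit ambiguity survives when
  no specimen approaches a simplex vertex: columns can be expanded slightly
  toward the vertices with all constraints still satisfied.  The noiseless
  recovery tests therefore draw proportions from a sparse Dirichlet(0.3),
  whose draws approach the vertices (while remaining strictly interior),
  making the construction identifiable to the asserted 0.02.

## Choosing the number of cell types

`select_K` scans `K = 1..K_max` (default `K_max = 10`, capped at `n - 2`
and at the sparsest resample's distinct-specimen count).  For each of
`n_boot` bootstrap resamples of specimens (default 50; the tests use 20)
the model is refit on the resample — warm-started from the full-data fit
and limited to 10 inner iterations, which in practice converges because the
start is already near-optimal — and scored on the out-of-bag specimens by a
Gaussian deviance: each held-out specimen's proportions are re-solved
against the bootstrap methylomes (the methylomes are not refit), and

    dev = sum_j sum_{i oob} [ log(2 pi sigma_j^2) + r_ij^2 / sigma_j^2 ]

with per-CpG variances `sigma_j^2` estimated from the bootstrap fit's
residuals (rss over residual degrees of freedom, floored at 1e-9 so
perfectly fitted CpGs cannot send the deviance to minus infinity).  `K = 1`
is scored against the bootstrap row-mean model.  The same resamples are
shared across the whole K grid, removing between-K resampling noise from
the profile; `K_hat` minimizes the mean bootstrap deviance (median
available), with ties broken toward smaller K.  On simulated three-type
mixtures the profile drops sharply to `K = 3` and flattens beyond; on
homogeneous data it is minimized at `K = 1`.

## Phenotype association

Each proportion column (cell type) is regressed on the phenotype design
with a quasi-binomial GLM — logit link, variance proportional to
mu(1 - mu), dispersion by Pearson chi-square — fit by IRLS (cross-checked
against statsmodels GLM in the tests).  To keep conclusions independent of
any single choice of K, the omnibus statistic for a covariate averages over
the grid:

    T = mean_K ( D_K / K ),   D_K = sum over the K proportion columns of the
                              quasi-deviance explained by the covariate
                              given the other covariates

with `K = 1` contributing zero.  Inference is by permutation (default 1000
permutations; the covariate's raw values are shuffled across specimens with
`Omega` fixed) and the add-one rule, so p-values are never zero.  The 1/K
normalization prevents large-K fits from dominating the average; permuting
raw values (rather than residuals) is exact under the strong null and is a
documented limitation when covariates are strongly correlated.  Reduced
models do not involve the permuted covariate and are fitted once.

## Mediation by cell composition

CpG-wise regressions of M-values (`log2(beta/(1-beta))`, clipped at 1e-6)
on the phenotype design are compared with and without the `Omega` columns
(`K* = max(2, K_hat)`; the last canonical proportion column is dropped
because near-unit row sums make the full set collinear with the intercept).
Per-CpG variances are moderated empirical-Bayes style: the excess spread of
log residual variances beyond their chi-square sampling noise determines
prior degrees of freedom `d0` (trigamma-inverse method of moments), and
variances shrink toward the prior `s0^2`; moderated t/F statistics use
`d0 + d` degrees of freedom.  One deliberate choice: when no excess spread
is observed, variances are left unshrunk at their geometric-mean target, so
equal-variance input reproduces ordinary t statistics exactly.

The proportion of null CpGs `pi0` is estimated by the Storey profile
`pi0(lambda) = #{p > lambda} / (m (1 - lambda))` on the grid 0.05..0.95,
smoothed by a cubic polynomial extrapolated to `lambda -> 1` and clamped to
[0, 1]; q-values use the standard step-up transform.  A rise in `pi0` after
adjustment quantifies how much of the epigenome-wide association is
mediated by composition; the omnibus `Omega` F-test's `pi0` measures how
much of the methylome tracks composition at all (below 0.2 in heterogeneous
simulations, mirroring heterogeneous tissues).

Two behaviors observed while validating this component are worth knowing
about.  At `n = 60`, the chance in-sample correlation between a covariate
and an independently drawn composition is of order 1/sqrt(n) and can induce
pervasive weak associations — a form of chance confounding that adjustment
correctly removes.  Conversely, when a covariate affects CpGs directly, the
reference-free fit can absorb part of that signal into `Omega`
(over-adjustment).  The no-mediation test therefore uses a
composition-matched design (both covariate groups share the same proportion
rows) adjusted by the generating proportions, isolating the regression
property from both phenomena; the moderated tests themselves are verified
to be exactly calibrated when the variance prior is correctly specified.

## Interpreting fitted methylomes

CpGs that discriminate cell types have high row-variance
`s_j^2 = var(mu_j1, ..., mu_jK)` (sample variance, divisor K - 1).  CpGs
above the 75th percentile of `s^2` (type-7 linear-interpolation quantile,
strict inequality) are cross-tabulated against membership in annotation
sets; the association is reported as the sample cross-product odds ratio
(Haldane +0.5 applied to every cell if and only if some cell is zero) with
a two-sided exact hypergeometric p-value computed on the uncorrected table.

When purified reference methylomes are unavailable, DMP sets can be derived
from a whole-tissue WGBS pseudo-reference: CpGs with fewer than three
missing tissues are ranked by variance, the top 15,000 retained, and the 25
closest tissue pairs (Manhattan distance on pairwise-complete entries,
rescaled by the pair's completeness) each contribute the CpGs whose
methylation differs by strictly more than 0.70 between the two tissues;
pairs with ten or fewer DMPs are dropped.  `project_to_reference` projects
specimens (or fitted methylomes, giving the mixing matrix `Psi`) onto a
reference by the same constrained solver; `residualize_against_reference`
returns `M1 - M0 Psi`, whose entries may be negative.

## The synthetic-data generator

`simulate_mixture` emulates the structure the model assumes: cell-type
methylomes with a fraction of type-pure anchor CpGs (0.95 own type / 0.05
others; uniform elsewhere), Dirichlet compositions summing to one, and
beta-distributed microarray noise `Y ~ Beta(mu nu, (1-mu) nu)` around the
mixed mean (clipped to [0.001, 0.999]), so `var(Y|mu) = mu(1-mu)/(nu+1)`.
Defaults — m = 2,000 CpGs, n = 60 specimens, K = 3 types, symmetric
Dirichlet(2), precision nu = 200 (noise sd about 0.03 at mu = 0.5), 10 %
anchors — describe a moderately heterogeneous tissue at array scale; a
single global nu is the default, with a per-CpG vector accepted.  An
optional binary covariate scales the first Dirichlet concentration by
`exp(effect)`, creating a purely composition-mediated phenotype.

What the generator does **not** emulate: probe-type (Infinium I/II)
chemistry and normalization artefacts, spatial/genomic correlation between
CpGs, cell-type-specific noise, batch effects, or covariates with direct
CpG effects (those are constructed explicitly in tests).  Passing tests
demonstrate correctness of the algorithms under the model's own
assumptions, not robustness to everything real arrays do.

## Numerical choices

* QP KKT tolerance 1e-8; active-set linear solves fall back to
  minimum-norm least squares on rank-deficient Gram blocks (duplicated
  methylome columns), matching the documented "minimum-norm optimum with a
  warning" contract.
* Alternating-fit early stop at relative rss change 1e-6; bootstrap refits
  warm-started, 10 iterations.
* Variance floor 1e-9 in the bootstrap deviance; dispersion floor via
  residual-df clamping in the GLM.
* Beta values are validated into [0, 1] with tolerance 1e-9 on read, then
  clipped exactly.
* Deterministic seeding throughout (`numpy.random.default_rng`); identical
  seeds give bit-identical tables, which the pipeline tests assert.

## Problem sizes used in the test and acceptance runs

Simulation-backed checks use the generator defaults (m = 2,000, n = 60)
for recovery, K selection (20 replicates, 20 bootstraps, K grid 1..5),
power and mediation; calibration uses 100 runs at m = 500 with 199
permutations; the acceptance script reports the same quantities at 10
K-selection replicates and 50 calibration runs.  These sizes were chosen as
the smallest at which the stochastic assertions are stable across seeds.

## Known limitations

* The method recovers the major axes of compositional variation, not
  necessarily nameable cell types; interpretation rests on the enrichment
  toolkit and external annotation.
* Input is assumed normalized (e.g. BMIQ-aligned probe types); the toolkit
  documents but does not enforce this.
* The permutation scheme permutes raw covariate values; with strongly
  correlated covariates a residual-permutation scheme would be preferable.
* Empirical-Bayes moderation assumes a single log-F variance prior; the
  mean-variance trend of M-values near the boundaries of [0, 1] can make
  nulls mildly conservative (a robust/trended prior is future work).
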