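# Methods

## The model and the test statistic

`mantapy` tests the association between an n x q matrix of quantitative
responses **Y** and terms of a multivariate multiple regression (MMR)

    Y = X beta + E,

where **X** is the n x p design built from the user's model formula
(intercept always included, categorical variables expanded with full-rank
treatment contrasts) and the rows of **E** are independent with a common
q x q covariance Sigma.  No distributional form is assumed for **E**.

A tested term defines a reduced design X0 (X minus the term's columns; how
the remaining terms enter depends on the sums-of-squares type, see below).
With H and H0 the hat matrices of X and X0, the statistic is the trace
pseudo-F

    F = [ tr{Y'(H - H0)Y} / rank(H - H0) ] / [ tr{Y'(I - H)Y} / rank(I - H) ],

which for q = 1 is the classical partial F and for Euclidean distances
equals Anderson's distance-based PERMANOVA pseudo-F (module
`permutation.gower_pseudoF` implements the distance form and the test suite
asserts the identity to 1e-8 relative).

## Asymptotic null distribution

Under the null hypothesis on the tested term, the numerator trace converges
in distribution to a weighted sum of q independent chi-square variables,
each with rank(H) - rank(H0) degrees of freedom, with weights the
eigenvalues lambda_j of Sigma; the denominator converges in probability to
sum_j lambda_j.  In practice the lambda_j are the eigenvalues of the sample
covariance of the full-model residuals, Y'(I-H)Y / (n - rank(H)), clipped
at zero against round-off.  The p-value is the survival function of the
weighted mixture evaluated at the observed numerator.

Two engines compute that survival function:

* **Farebrother/Ruben series** (default): the mixture CDF expanded as an
  infinite series of central chi-square CDFs with mixing parameter
  beta = 2 lambda_min lambda_max / (lambda_min + lambda_max).  The series
  coefficients sum to one; summation stops when the unassigned mixture mass
  falls below max(tol, 8 eps sqrt(K)) (tol = 1e-16, K the series length) —
  the round-off floor of a K-term accumulation.  The engine is monotone in
  the statistic down to a reporting floor of 1e-14; smaller values are
  reported as 1e-14 with an `at_precision_limit` flag rather than 0.
* **Imhof inversion** (cross-check and fallback): the characteristic-
  function inversion integral, split into a head interval covering at
  least one oscillation period (integrated adaptively) plus sine/cosine
  Fourier tails handled by QUADPACK's oscillatory-weight routine.  The
  engines agree to ~1e-13 for p >= 1e-9; below ~1e-10 the inversion can
  return values <= 0, which are flagged, never silently clipped.

Weights with lambda_j / sum(lambda) < 1e-3 are dropped before the series is
evaluated: they slow convergence dramatically while moving the p-value by
less than the series tolerance.  Degenerate limits (a single weight; all
weights equal) reduce to exact chi-square survival functions and are tested
against `scipy.stats.chi2` to 1e-12.

## Sums of squares and transformations

Type I builds the reduced model from the intercept plus all terms preceding
the tested one (sequential; order-dependent, and the convention used for
GWAS: covariates first, genotype last, tested via `subset`).  Type II
excludes higher-order relatives of the tested term from the full model;
Type III drops only the tested columns from the complete design.  For
Type I and II the denominator uses the residual of that partition's full
model (the partial-F convention); when the tested term is last, this is the
complete-model residual and the table matches classical sequential ANOVA
exactly (cross-checked against vegan::adonis2 in the tests).  With
treatment coding, Type III main-effect tests in models with interactions
are coding-sensitive; this is inherent to non-orthogonal codings and
documented rather than hidden.

Square-root and logarithm response transformations are supported; for
multivariate proportions the square root makes the Euclidean statistic
identical to the Hellinger-distance PERMANOVA, which the tests assert.
When n/q < 20 results carry a `low_n_over_q` flag: the asymptotic p-values
are conservative in that regime (they remain valid, just less powerful).

## Permutation test

The permutation engine shuffles raw rows of **Y** (not residuals; for
terms adjusted on continuous covariates this is an approximate test, as in
classical PERMANOVA practice) and recomputes the pseudo-F from fixed design
bases, so one permutation costs O(n p q).  Free and within-stratum schemes
are provided; the within-stratum scheme yields an exact test for a term
when the stratum factor is the only other source of signal.  p = (number
of permuted F >= observed F + 1) / (P + 1), ties counted as exceedances;
the smallest achievable value is 1/(P+1).  Permutations are drawn
independently with a seeded generator (never enumerated exhaustively, even
when n! is small), making results bit-reproducible for a fixed seed.

## Synthetic data generator

The generator reproduces the study conditions of the simulation framework
the package is validated under:

* **Two-factor design**: A (2 levels) x B (3 levels), completely crossed
  and balanced.  Under the alternative for B, levels 1 and 2 are shifted
  by +delta and -delta on every trait (zero overall mean); an optional
  zero-sum cell pattern generates interaction effects.
* **Genotypes**: binomial SNPs (dose ~ Binomial(2, MAF)), or mosaic
  cohorts: each individual is a block mosaic (1000-variant blocks by
  default) of A ancestors drawn from synthetic Balding-Nichols founder
  populations (ancestral frequencies U(0.05, 0.95), F_ST = 0.01).  The
  founders are a synthetic stand-in for reference-panel haplotypes; A = 2
  gives strong relatedness, A = 10 approximately unrelated cohorts, and
  sampling ancestors within one founder population gives stratification.
* **Residual families**: multivariate normal (equicorrelation r in
  {0, 0.2, 0.5, 0.8} or random AA' covariance; unit or equally spaced
  variances); multivariate t with 3 df; Gaussian copulas with uniform,
  beta(0.5, 0.5) or gamma(1, 10) marginals (centered and scaled per
  trait); simplex compositions; multinomial counts (N = 1000).
* **Genotype-group heterogeneity**: residual covariances Sigma,
  (tau+1)/2 Sigma, tau Sigma by genotype 0/1/2, or correlation-only
  scaling R, 2/(tau+1) R, 1/tau R with variances held fixed.
* **Phenotypes**: Y = x beta' + U + E with
  U ~ MatrixNormal(0, K, Sigma_U = AA') and K = (1/g) G G' on the
  centered, scaled dose matrix.  Effect patterns: equal (beta = 1 on t
  traits), spaced (equally spaced in [1, beta_max]), proportions
  (beta_1 = 1, beta_j = -1/(q-1)) and null.
* **Simplex sampler**: location p with p_1 = L/(q+L-1), p_j = 1/(q+L-1);
  samples are vertex-directed displacements y = p + delta (e_j - p) with
  vertex j chosen with probability p_j and delta = min(|N(0, sigma_g)|, 1).
  Since sum_j p_j e_j = p, E(y) = p exactly and samples stay in the
  simplex.  This is one concrete realization of the stated mean contract;
  the displacement law itself is a design choice.  Genotype effects on
  compositions move p along the Hellinger-sphere geodesic toward a vertex
  by an arc fraction delta (the -delta shift mirrors it), our reading of a
  "geodesic" displacement on the simplex.
* **Outliers**: a configurable fraction of rows (default 0.5%) with
  residuals scaled x10 — a deliberately simple heavy-contamination recipe,
  exposed through `SimScenario`.

**Variance fractions are global and exact.**  h2_v and h2_g are the
fractions of the *total* phenotypic variance (summed over the q traits)
carried by the variant and the structure terms.  Components are rescaled so
the realized sample-variance fractions — not their expectations — hit the
targets exactly.  With one affected trait out of q unit-variance traits, a
global fraction h2_v corresponds to a per-trait fraction q h2_v on the
affected trait; this convention is what makes a variant at h2_v = 0.005
detectable with power ~0.95 after Bonferroni correction at n = 2504,
q = 5 (univariate noncentrality ~ n q h2_v = 63).

What the generator does *not* emulate: linkage disequilibrium beyond the
block-mosaic structure, MAF spectra of real panels, genotyping error, and
trait distributions with trait-specific (rather than family-wide) shapes.
Passing tests therefore demonstrate calibration and power under controlled
exchangeable-error conditions, not under every failure mode of real
cohorts (in particular, strong relatedness still requires mixed models —
a stated limitation of the method).

## GWAS front end

Per variant: biallelic check, per-variant sample dropping for missing
calls (no imputation; MAF and missingness computed on called genotypes),
filters MAF >= 0.01, missingness < 0.05, >= 10 individuals per observed
genotype group (each skip logs exactly one primary reason); additive dose
coding by default (categorical optional), covariates + genotype fitted with
Type I SS and the genotype term tested.  Genotype PCs use a deterministic
sign convention (largest-magnitude loading positive).  The genotype x
condition interaction test treats both as categorical, requires >= 10
samples per observed interaction cell, residualizes the responses on the
covariates *before* testing, and reports per condition the maximum
absolute difference (MD) in adjusted mean trait value between genotype
groups, maximizing over genotype pairs and traits (the maximizing trait
may differ between conditions; we report the per-condition overall
maximum).  Bonferroni and Benjamini-Hochberg adjustments are provided.

## Numerical choices

* Rank decisions use singular values above max(n, p) * eps * sigma_max.
* Projections are never materialized at n x n in the testing path; all
  traces come from orthonormal design bases (QR/SVD), so a statistic costs
  O(n p q).  Tests materialize H where the contract is about H itself.
* Numerator traces within 1e-12 (relative to the total SS) of zero are
  treated as exact zeros; larger negative values raise.
* Residual-covariance eigenvalues are clipped at zero before use as
  weights.

## Problem sizes used in validation

The validation suite uses the study's stated sizes where they matter
statistically: m = 10000 replicates for type I error (3 binomial SE
resolution ~0.0065), 500 datasets / 10^4 permutations (with a 50-dataset
10^5-permutation subset) for the asymptotic-vs-permutation comparison,
10^5 permutations against 10^5 null draws for the distribution match, and
2000 replicates for power at n = 2504.  Smaller Monte-Carlo sizes are used
only for properties whose resolution requirements are coarser
(directional inflation checks, KS uniformity at the 1e-3 level).

## Known limitations

* No relatedness correction: strong family structure inflates type I
  error; only principal components of the genotype matrix are offered.
* No effect-size estimate accompanies the p-value.
* Heterogeneous per-component degrees of freedom in the weighted
  chi-square null are not supported (all tested columns share one df), and
  non-Euclidean distances are supported only through response
  transformations.
* Davies's inversion method is omitted: it shares Imhof's failure mode in
  the deep tail and adds no independent information.
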