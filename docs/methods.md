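# Methods

## Plasticity traits

All analysis operates on replicate-averaged leaf-number trajectories
(arithmetic mean over replicates per RIL × treatment × week; missing
replicate values are ignored, and a RIL is dropped from a treatment
panel when any week has no observed replicate).  A plasticity trait is
the elementwise per-RIL difference between the trajectories of two
treatments, restricted to RILs present in both panels.  The sign
conventions are fixed: pWPP = L − H, oWPP_H = HL − HH, oWPP_L = LL − LH,
TPP_H = HH − H, TPP_L = LL − L, MPP_H = HH − LH, MPP_L = LL − HL.
Because every contrast is a difference of raw panels, the telescoping
identities TPP_L − TPP_H = MPP_L + oWPP_H − pWPP and
MPP_L + oWPP_H = LL − HH hold exactly per RIL, and the test suite
asserts them at machine precision.

## Growth curves

Leaf-number trajectories are fitted with the three-parameter logistic
a / (1 + b e^{−rt}); a is the asymptotic leaf number (leaves), b the
initial-growth shape (dimensionless), r the specific growth rate
(week⁻¹).  Time enters as the raw integer week 1..8 — the measurement
design is weekly from one week after planting, so no centring or
rescaling is applied.  Fitting is least squares on log-parameters
(positivity for free), multi-started from data-seeded points (a₀ from
the trajectory maximum, r₀ and b₀ from a log-linearised fit) plus a
coarse grid; the best RSS wins, with ties broken toward the smaller
asymptote.  The mean-curve loss is least squares rather than maximum
likelihood — with a single trajectory per treatment the two coincide up
to the residual covariance, which is not identifiable at that level.

"Asymptotic leaf number" in summaries is operationalised as the fitted
a, with the final-week value as fallback when the fit does not
converge; the across-RIL standard error describes line-to-line
variation.  For significance summaries across contrasts, per-RIL
asymptotic plasticity values feed a two-sided one-sample t-test (mean
≠ 0), Welch t-tests for the configured contrast pairs, and
Benjamini–Hochberg adjustment over the whole family, with compact
letters derived from the adjusted pairwise matrix by insert-and-absorb.
Welch/BH is a deliberate choice of a robust, reproducible default; the
choice is recorded in the run metadata.

## The mapping likelihood

At each SNP the plasticity vectors are modelled as T-variate normal.
Genotype-class means are differences of two logistic curves (six
parameters per class).  The residual covariance is the sum of two
SAD(1) matrices — one per source environment, the two environments
treated as independent.  For occasions t₁ ≤ t₂ (indexed 1..T),

    Σ(t₁,t₂) = ν² φ^{t₂−t₁} (1 − φ^{2t₁}) / (1 − φ²),

with determinant ν^{2T} and tridiagonal inverse in closed form; the
composite sum has no closed inverse and is handled by generic
factorisation.  One covariance is shared across genotype classes and
re-estimated per SNP under both hypotheses.

Maximisation alternates generalized-least-squares curve updates
(damped Gauss–Newton on log-parameters, analytic Jacobians) with
gradient updates of the four unconstrained covariance parameters
(φ = tanh η, ν² = e^λ; Adam on the profile objective
log|Σ| + tr(Σ⁻¹S)).  Because the model depends on the data only through
genotype-class mean trajectories and class scatter matrices, the whole
scan is expressed in sufficient statistics and batched across SNPs;
identical budgets are used for observed and permuted scans so the
permutation calibration sees the same estimator.  Two numerical
safeguards matter:

* the covariance start point is deliberately asymmetric in the two
  SAD(1) blocks — the objective is symmetric under swapping them, so a
  symmetric start sits on a saddle that gradient descent cannot leave;
* the no-QTL solution is feasible under the QTL model, and its
  log-likelihood is used as an exact floor for log L₁, so LR ≥ 0 by
  construction (residual optimiser noise of order ±1 LR unit remains on
  a flat covariance ridge; it affects observed and permuted scans
  alike and is far below genome-wide thresholds, which sit at 20–90 in
  the simulations here).

Identifiability: from the difference trait alone the two component
curves are only weakly identified (adding a constant-in-t family to
both leaves z unchanged); component curves are therefore initialised
from per-environment fits to the paired source panels, which the trait
object carries, and only the difference curve is treated as the
estimand.

Classes with fewer than `n_min = 5` RILs are dropped and their RILs
excluded for that SNP; with one retained class the models coincide and
LR = 0.  SNPs with no retained class are skipped with a logged reason.

## Permutation calibration

The permutation unit is the whole RIL phenotype vector (trajectory),
reshuffled against genotype rows: this breaks all SNP–trait association
while preserving the trait's temporal covariance.  Each permutation
re-runs the full scan and records the genome-wide maximum LR; the
threshold is the empirical upper (1−α) quantile of the maxima (the
`higher` order statistic, so all-equal maxima give that value exactly),
and the per-SNP empirical P is the fraction of maxima at or above the
SNP's LR.  Per-SNP asymptotic chi-square P values are not used — the
likelihood-ratio null distribution under curve models with estimated
covariance is not a textbook chi-square, and the genome-wide maximum is
the quantity of interest.  The default is 100 permutations at α = 0.05
(the 0.95 quantile); fewer than 20 permutations, or an α·n_perm product
below one, is rejected.

## Module clustering

Each significant QTL is summarised by its genetic standard deviation
curve: the weighted (n_j/n) across-class standard deviation of fitted
mean plasticity at each week, computed from the maximum-likelihood
curve parameters.  GSD is the primary clustering feature because it is
invariant to class relabelling; a signed two-class effect curve is a
reasonable alternative but is not the default.  Curves are clustered
with a mixture of T-variate normals: module means are Legendre
polynomials (default order 4, five coefficients) on the grid mapped to
[−1, 1], one SAD(1) covariance shared across modules, multinomial
mixing proportions.  EM is initialised by k-means++ on the raw curves,
multi-started (default 10 seeds), run to relative log-likelihood change
< 1e-8 or 500 iterations; the Σ M-step keeps the previous parameters
whenever the numerical update would not improve the complete-data
objective, so the observed log-likelihood is monotone by construction
and asserted at every iteration.  BIC = −2 log L + d log S with
d = L(order+1) + 2 + (L−1) free parameters selects the module count,
ties toward the smaller L.  Hard assignments are maximum
responsibility.

## The simulator

The generator emulates the study conditions: 100 RILs from two inbred
founders after 10 generations of selfing, five chromosomes of SNPs,
eight weekly measurements, 20 replicates per RIL per treatment.
Gametes follow a Markov walk per chromosome with Haldane recombination
fractions r = (1 − e^{−2d/100})/2 (no interference — standard for
selfing RIL construction); selfing starts from a uniformly
heterozygous F1, and residual heterozygotes (expected rate 2⁻⁹ ≈ 0.2%
at F10) are retained with code 1 so the generic-J_s likelihood is
exercised.

Treatment baselines are logistic curves chosen to reproduce the
qualitative pattern of the experiment: low light raises the parental
asymptote by ~7 leaves (H: a=10, L: a=17), offspring of low-light
mothers gain ~4 leaves in low light (LH: 12, LL: 16), offspring of
high-light mothers ~3 (HH: 11, HL: 14).  Maternal effects exist in the
simulator only through these treatment-specific baselines — the
experiment observes maternal influence only through treatment
contrasts, so an explicit inherited state variable would add nothing
testable.  A planted QTL perturbs the baseline additively by the
difference between its genotype-specific curve and the baseline curve,
so effects from multiple QTLs add and a lone QTL reproduces its curves
exactly.  Replicate noise is multivariate normal with SAD(1) covariance
per final light environment (H: φ=0.70, ν²=0.8; L: φ=0.75, ν²=1.0 —
late-week replicate SD ≈ 1.3–1.5 leaves, low light noisier), drawn
independently per replicate.

What the simulator does not emulate: genotyping error and missing
calls, segregation distortion, selection during line construction,
non-Gaussian measurement error, epistasis, and any molecular mechanism
of the maternal effect.  Passing tests therefore demonstrate that the
estimator recovers the model it assumes under realistic dimensions and
noise — not that real leaf-count data meet those assumptions.

## Problem sizes in the test suite

Simulation-based checks run at a desk scale chosen to keep the whole
suite comfortably reproducible on a single CPU: genome-wide
calibration uses 100 replicates of a 50-RIL × 200-SNP null experiment
with 100 permutations each; power and parameter recovery use 20
replicates at 100 RILs × 200 SNPs; clustering recovery uses 60 curves
from three families.  The acceptance script runs one 100-RIL, 200-SNP
experiment with three planted QTLs plus five recovery replicates.

## Known limitations

* The covariance profile has a near-flat ridge in the decomposition of
  the composite SAD(1)+SAD(1); the two blocks' individual (φ, ν²) are
  reported but should not be over-interpreted — only their sum is well
  identified.
* The scan assumes one shared covariance across genotype classes per
  SNP; class-specific covariances are not supported.
* Permutation P values are granular at 1/n_perm; with the default 100
  permutations the smallest attainable P is 0.01.
* The per-SNP model treats RILs as independent given genotype; kinship
  beyond the mosaic structure of a biparental RIL panel is not
  modelled.
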