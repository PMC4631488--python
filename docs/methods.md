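# Methods

## The model

All genetic inference rests on the single-trait animal model

    y = X b + Z_a a + Z_m f + e

where `y` holds one record per animal per measurement occasion, `b` the
fixed effects (intercept, measurement year, sampling order — possibly
nested in year — or exact age as a covariate), `a ~ N(0, V_A·A)` the
additive genetic effects with `A` the pedigree-derived numerator
relationship matrix, `f` any identity-structured random effects
(family/common-environment `V_C`; permanent environment `V_PE` for repeated
records), and `e ~ N(0, V_R·I)`.  Derived quantities are

- heritability `h² = V_A / V_P`, `V_P = V_A + V_C + V_PE + V_R`;
- repeatability `R = (V_A + V_C + V_PE) / V_P` — all permanent
  between-individual variance, hence an upper bound for `h²`;
- evolvability coefficients `CV_A = 100·√V_A/X̄` and
  `CV_R = 100·√(V_P − V_A)/X̄`.  `CV_R` deliberately uses the non-additive
  remainder `V_P − V_A` rather than the residual component alone, so
  `CV_A² + CV_R² = (100·σ_P/X̄)²` holds exactly and the pair decomposes the
  phenotypic CV;
- predicted response to truncation selection `G = i·h²·σ_P` with
  `i = φ(z)/p` (upper-`p` truncation under normality).  `σ_P` is taken as
  `√V_P` from the fitted model, not the raw phenotypic SD; with published
  table inputs this choice reproduces the printed response percentages
  where the raw SD does not.

## Relationship matrix

`A` is built by the tabular method in a parents-first topological order
(stable sort, so matrices are reproducible for any input row order).
Missing parents are unrelated, non-inbred founders — appropriate here
because the broodstock was randomly sampled from a large base population;
nothing is known about founder relatedness beyond that sampling, so no
founder kinship is imposed.  The matrix is kept dense: the design never
exceeds a few thousand animals, and sparse inverse-A machinery is a
non-goal.  An independent pairwise-recursion oracle
(`relationship_oracle`) cross-checks the tabular construction entry by
entry in the test suite.

## REML

The restricted log-likelihood

    lR = -1/2 [ log|V| + log|X'V⁻¹X| + y'Py + (n−p)·log 2π ]

is maximised over non-negative components by average-information (AI)
updates.  Numerical choices:

- **Initialisation** deterministic at the equal partition of the sample
  phenotypic variance over all components — no solver randomness anywhere.
- **AI step with Levenberg–Marquardt damping.**  The raw AI (quasi-Newton)
  step overshoots when two components are nearly confounded (e.g. family
  vs additive in a small half-sib design).  The update tries damping
  factors λ ∈ {0, 0.1, 1, 10, 100} on the AI diagonal and takes the first
  candidate that does not decrease `lR`; failing that, a (step-halved)
  EM-REML update is taken.  EM steps are guaranteed-ascent but linearly
  convergent, so they serve only as fallback.
- **Boundary handling by projection.**  Negative proposals are clamped to
  zero.  A component sitting at zero whose gradient points outward
  (KKT condition) is pinned for the remaining iterations and reported as a
  clean `0` with a boundary flag (published tables show values like 7e-7;
  we report the boundary explicitly instead).
- **Convergence** when the relative `lR` change is below 1e-8 and the
  maximum component change below 1e-6 of the phenotypic variance;
  iteration cap 200, non-convergence raises with the trajectory attached.
- **Two algebra kernels.**  Models with one non-residual component use a
  spectral reparameterisation (single symmetric eigendecomposition of
  `Z G Z'`, then O(n·p²) per iteration); general models use dense Cholesky
  algebra.  Both produce identical likelihoods; the spectral path makes
  the 1000-replicate calibration studies cheap.
- **Standard errors** of components from the inverse AI matrix at
  convergence; ratio SEs (h², R) by the first-order delta method on that
  covariance.  Boundary components get zero SE and are excluded from the
  inverse.

Fixed-effect terms are encoded as full dummy blocks (all cells for nested
terms like `order(year)`) and pruned to a full-rank X by sequential
orthogonalisation; pruned columns are reported.  The **Wald F** for a term
tests the joint nullity of its retained coefficients at the converged
components, with denominator df `n − rank(X)` (residual convention,
declared in output; exact small-sample ddf algorithms are out of scope).
A single-covariate Wald F equals the squared Wald z up to the F-vs-χ²
denominator, which the tests verify.

The **likelihood-ratio test** for one variance component uses the boundary
null ½χ²₀ + ½χ²₁ (Self–Liang): p = ½·P(χ²₁ > LR), so an LR of exactly zero
reports p = 0.5 under the declared convention; plain χ²₁ is available for
comparability with software that ignores the boundary.

## Phenotypic comparisons

The challenge-effect and age × fraction ANOVAs are fixed-effects only (as
in the source analysis; they do not account for family structure, which is
screened separately in the mixed model).  Type-III sums of squares are
computed as Wald quadratic forms on an effects-coded full-rank
parameterisation, which coincides with sequential SS on balanced data and
with LS-means logic on unbalanced data.  Levene's test defaults to the
median-centred (Brown–Forsythe) variant for robustness, mean-centring
available; Shapiro–Wilk delegates to the standard published algorithm in
scipy.  "Sequential Bonferroni" is implemented as Holm step-down with
monotonicity enforcement.  The compact-letter display is built by greedy
insertion on the non-significance graph, processing groups in ascending
mean order.

## Synthetic data

The generator draws the study design: 20 sires × 3 dams (60 full-sib
families), family sizes uniform on 5–10 (the source reports only that
range), founders unrelated.  Phenotypes follow the generative counterpart
of the animal model: founder breeding values `N(0, V_A)`, offspring
mid-parent plus Mendelian sampling `N(0, V_A/2)` (no inbreeding in this
design), family effects `N(0, V_C)`, permanent-environment effects
`N(0, V_PE)` per animal × fraction, residuals `N(0, V_R)` per record.
Records cover all offspring at age ~3 (year 1) and a simple random ~73%
subset at age ~4 (year 2), matching the reported attrition 492 → 357; the
selection mechanism of the remeasured animals was not described, so random
attrition is a declared stand-in.  Default trait scale: means 16.40/32.27
(haemocyte fraction) and 26.59/30.87 (serum) µg HSP70/mg protein by age
class, `V_A = 5`, `V_R = 46` (phenotypic variance ≈ 51, the young-adult
haemocyte scale).  Sampling order is a 4-level factor assigned by random
permutation within year with a linear effect of 2 units/level in year 2
only (the order effect was detectable only at the second measurement);
exact age gets ±0.125 yr jitter (family production spanned ~3 months).
The challenge-screen generator uses control baselines of one third of the
challenged means (5.5/8.9 µg/mg), a ×3 zymosan multiplier, lognormal noise
(σ_log = 0.35) and group sizes uniform on 6–10.

Traits are Gaussian by default — the estimator's assumption, and the right
scale for validating it; an optional lognormal mode exists for realism
checks but is not the test default.  What the generator does **not**
emulate: genotype-by-environment interaction, non-additive genetic
variance, selection-biased attrition, assay measurement error structure,
or survival/growth.  Passing tests therefore demonstrate estimator
correctness under the design's own assumptions, not robustness to their
violation.

One `SeedSequence` per dataset with spawned substreams per stage (pedigree,
breeding values, family, permanent environment, residuals, order,
attrition, age), so adding a stage never perturbs earlier draws and equal
seeds give byte-identical output.

## Validation strategy and problem sizes

The raw phenotypes behind the published estimates were never deposited, so
the package validates by (a) exact reproduction of all *derived* statistics
from the printed components and means, and (b) property-based checks at
sizes chosen to keep the full suite fast while leaving no statistical
ambiguity:

- relationship matrix vs pairwise oracle: 50 random pedigrees ≤ 200
  animals, every entry, tolerance 1e-12;
- REML vs closed-form ANOVA on balanced sire data: 20 sires × 15
  offspring, 500 datasets, interior solutions, tolerance 1e-6;
- heritability recovery at the study design (60 families × 8 offspring,
  two years, V_P = 51): 200 replicates at true h² 0.05 and 0.30, mean
  within one Monte-Carlo SE; reported h² SEs at h² = 0.05 are the same
  order as the estimate itself (the design cannot separate such a
  heritability from zero — with two-year repeated records the
  likelihood-ratio test still rejects in roughly 60% of replicates, more
  than a single-year stratum achieves);
- test calibration: 1,000-replicate nulls for the boundary LRT
  (50 sires × 6, V_s = 0) and the Wald F (4-level factor with no effect,
  V_s = 0.3·V_P), both within binomial 95% bounds of α = 0.05.  Fifty
  groups keep the ½χ² mixture asymptotics accurate.

`scripts/acceptance.py` re-runs all of the above from a single `--seed`
(the balanced-ANOVA check at 200 datasets there; 500 in the test suite).

## Known limitations

- Single-trait only; no genetic correlations, random regression or
  multi-trait REML.
- Wald F uses a residual ddf convention, not numerically derived ddf; its
  p-values are approximate in small samples.
- The h² point estimate is a ratio of estimates and carries a small
  finite-sample (Jensen) bias, visible only with many replicates.
- LS-means are fixed-effects only; mixed-model LS-means with non-identity
  covariance are out of scope.
- The combined-years models support an optional permanent-environment
  term; with only two records per animal its estimate is often pinned at
  the boundary, in which case R collapses to h² — both model variants are
  provided and neither is asserted to be the source analysis's exact
  specification, which was not stated.
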