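# Methods

## Model and estimation

The Partial Credit Model (PCM) treats each ordinal item as a sequence of
adjacent-category steps: the probability of scoring `h` on item `i` is
`exp(h·θ − β_ih) / Σ_l exp(l·θ − β_il)` with `β_i0 = 0` and cumulative
step parameters `β_ih = Σ_{j≤h} δ_ij`. The Andrich threshold `δ_ij` is
the ability at which categories `j−1` and `j` are equally likely.

**Conditional maximum likelihood (CML).** Conditioning on each person's
raw score eliminates the person parameters; the conditional pattern
probability is `exp(−Σ_i β_{i,x_i}) / γ_r`, where `γ_r` is the
elementary symmetric function of the `ε_ih = exp(−β_ih)` over all
patterns with total `r`. Because the raw score is sufficient for θ, the
resulting item-parameter estimates do not depend on the ability
distribution — the property the whole validation workflow leans on.

Identification: the conditional likelihood is flat along a uniform shift
of all thresholds; we optimize with one parameter fixed and report
estimates re-centered to the mean-zero normalization (mean of all δ_ij
equals 0), which makes item locations directly comparable across fits.

**Numerics.** The public γ table is computed by the log-space recursion
with log-sum-exp, and the brute-force pattern enumeration in the test
suite checks it to 1e-10. The optimizer evaluates γ and its derivatives
in linear space after scaling each item's ε to a maximum of one
(equivalent for all parameter magnitudes that arise; an automatic
log-space fallback guards the sub-1e-280 regime). The negative
conditional log-likelihood is the log-partition of an exponential family
in −β, hence convex; we solve it by damped Newton with the exact Hessian
(conditional covariance of the category-indicator counts, assembled from
prefix/suffix convolutions), which converges in about five iterations to
gradient norms below 1e-8. Count-based adjacent-category log-odds give
the starting values.

**Category supports.** Validated input requires every category 0..m_i
observed (gapped codes are re-coded consecutively, with a warning and a
recorded map). Internal fits on subgroups — Andersen score groups,
Martin-Löf subsets, bootstrap draws — restrict an item's category
support to what the subgroup observed: an unobserved category's step
parameter diverges at the boundary, and the support-restricted fit
equals the supremum of the unrestricted likelihood, so the likelihood
ratio remains valid with degrees of freedom counted over the parameters
actually estimated.

**Person estimation.** Given item parameters, θ̂_v solves
`r_v = Σ_i E[X_vi | θ]` over the person's answered items (safeguarded
Newton on a monotone score function); `SE = (Σ_i Var[X_vi | θ̂])^{−1/2}`.
Extreme raw scores (0 or maximum) have no finite ML estimate and are
pulled 0.3 score points toward the interior before solving, flagged, and
excluded from PSI and from the residual matrix.

## Diagnostics

**Residual fit.** Standardized residuals
`z_vi = (x_vi − E_vi)/√W_vi` use conditional moments at θ̂_v. Outfit is
the unweighted mean of `z²`, infit the information-weighted version
`Σ(x−E)²/ΣW`; both are standardized by the Wilson–Hilferty cube-root
transformation `t = (MSQ^{1/3} − 1)(3/q) + q/3` with the moment-based
`q²` (outfit: `Σ(C/W²)/N² − 1/N`; infit: `Σ(C − W²)/(ΣW)²`, `C` the
fourth conditional moment). Item chi-square is `Σ_v z²` with `df = N−1`
(per-person residuals are not grouped into class intervals; this is
configurable territory noted as a limitation). Cut-offs: MSQ outside
(0.7, 1.3) or |t| > 2.

Because residuals are evaluated at per-person ML ability estimates, the
null expectation of the mean squares sits slightly below one — about
`1 − 1/k` for `k` items (≈ 0.91 for nine items), since each person's
estimate absorbs one degree of freedom. This matches the behaviour of
the classical formulas in standard Rasch software and is the reason
well-fitting items typically show mean squares near 0.9 rather than
exactly 1.0; the misfit cut-offs are far outside this bias.

**Person-fit QC.** `χ²_v = Σ_i z²_vi`, `df = k_v − 1`; persons with
p < 0.05 (uncorrected) are removed once, before all other diagnostics.
Under the null this removes about 5% of the sample by construction.

**Local independence.** Pairwise Pearson correlations of the residual
columns; any pair above 0.3 is flagged. Under the model these
correlations are small and slightly negative (the residuals share the
estimated θ̂).

**Unidimensionality.** The first principal component of the residual
correlation matrix splits items by loading sign (largest-magnitude
loading fixed positive; zero loadings go with the positive set; an
all-one-sign solution falls back to a median split, tagged). Person
abilities are then estimated on each subset with item parameters
anchored at the full fit — anchoring, rather than re-estimating per
subset, keeps the two estimates on one scale — and compared by
`t = (θ̂_A − θ̂_B)/√(SE_A² + SE_B²)` against the standard normal (an
approximation; subset information is moderate). Fewer than 5%
significant supports one dimension.

The Martin-Löf-type likelihood ratio compares the unidimensional model
(full-set CML plus a free raw-score distribution) against a two-scale
model (CML per subset plus a free joint subscore distribution):
`T = 2[ℓ_A + ℓ_B + Σ n_ab log(n_ab/N) − ℓ_full − Σ n_r log(n_r/N)]`,
`df = R_A·R_B − 1` by parameter counting (this reduces to the known
dichotomous form `k_A·k_B − 1`). With 9 polytomous items the joint
subscore table is sparse at realistic n, so the default p-value is a
parametric bootstrap (B = 200): simulate complete cohorts at the fitted
thresholds and ability estimates, refit, recompute T. One caveat
documented from our own calibration runs: the test is calibrated for a
*given* split; feeding it the PCA-derived split of the same data selects
the most contrastive partition and is anti-conservative. Calibration
experiments therefore evaluate a fixed split, while the pipeline reports
the PCA-split result as the workflow diagnostic it is.

**Invariance / DIF.** Per item, a two-way unbalanced ANOVA
(least-squares model comparison, type-II) of the residuals on person
group and on four equal-count θ̂ class intervals (strata reduce
automatically when cells empty). The DIF flag is the Bonferroni-adjusted
(across items) group *main effect* — the definition of DIF as a group
shift at equal ability; the group×class interaction is reported as
non-uniform DIF but does not drive the flag. Default groupings: sex, and
age dichotomized at 45 years.

**Global fit.** Andersen's LR test with G = 2 groups split at the median
raw score (ties low; mean split and G > 2 quantile splits available).
Persons with extreme raw scores carry no conditional information and are
excluded. Groups under 30 persons trigger an asymptotics warning.

**Reliability.** `PSI = (V − M)/V`, clipped at zero, over non-extreme
persons; acceptable above 0.7.

**Category structure.** Disorder is flagged on the Andrich thresholds
(not strictly increasing), with the offending adjacent pairs listed.
The verbal definition of a category threshold via cumulative probability
0.5 describes the Thurstonian thresholds, which are strictly ordered for
every parameter vector (the test suite confirms this on 1000 random
items) and therefore cannot express disorder; both kinds are reported.
Under-/over-selection of a category is reported as the ratio of observed
to model-expected frequency (expected averaged over the θ̂ distribution),
with defaults 0.5 / 1.5. Collapse maps are order-preserving surjections
onto consecutive codes; the comparison report refits and contrasts PSI,
infit t and disorder counts.

## Synthetic cohorts

The generator emulates a 9-item, 0–4 scale whose item locations span
2.33 logits — re-centered to the mean-zero normalization, with equally
spaced steps (spread 0.6 logits) around each location — administered to
a cohort mixing mild/moderate/severe severity with weights
(0.17, 0.73, 0.10), component means (−1.5, 0.3, 2.0) and SD 0.5. The
weights mirror a real cohort's 47/201/29 split; the component means and
SDs are the package's own choice of a clinically plausible severity
spread. Covariates (sex, age and its 45-year dichotomy, and a balanced
binary DIF group) are drawn independently of ability, so they are true
null groupings unless a violation ties them to the items.

Violations: a DIF shift adds δ logits to one item's thresholds for group
1; a second dimension draws a correlated trait (default r = 0.3) and
routes items 6–9 to it; discrimination misfit samples from a
generalized-PCM numerator `exp(a_i(hθ − β_h))`; disorder injection swaps
an item's two middle adjacent thresholds — the smallest perturbation
that disorders the Andrich sequence.

What the generator does **not** emulate: missing-data mechanisms tied to
severity, rater effects, longitudinal change, or floor/ceiling behaviour
beyond what the PCM itself produces. Passing tests therefore show the
pipeline is correct and well calibrated *for PCM-generated data*; they
do not certify any particular clinical instrument.

## Experiment sizes and reference results

All replicated experiments fix their seeds and derive per-replicate
seeds from one `SeedSequence`. The sizes below are the package's chosen
desk-scale study conditions:

- Targeting: 500 replicates of n = 150 well-targeted persons (abilities
  normal around the mean item location, SD 1). Result: ≥ 99% of item
  locations within ±0.5 logit — the basis for the "at least 150
  well-targeted persons" design rule.
- Null calibration (100 replicates each, n = 1000): Andersen LR,
  fixed-split bootstrap Martin-Löf (B = 99 inside the calibration loop;
  the pipeline default is B = 200), per-person subset t-tests, and the
  DIF main-effect F test all hold rejection rates within [1%, 9%] at the
  nominal 5% level.
- Power (25 replicates each, n = 1000): DIF of +0.8 logit, second
  dimension at trait correlation 0.3, discrimination slope 2.0 and
  threshold disorder are each detected by their matched diagnostic in
  ≥ 80% of replicates.
- Unidimensionality null rate: mean percentage of significant subset
  t-tests over 20 cohorts of n = 1000, expected ≤ 5%.

## Known limitations

- CML requires every category observed (globally); the automatic recode
  changes category meaning and is warned about, not silent.
- Residuals use θ̂ point estimates without bias correction; see the
  `1 − 1/k` mean-square effect above.
- The per-person subset t-test reference is the standard normal, an
  approximation that degrades for very short subsets (mass exclusions of
  subset-extreme persons are warned about).
- The Martin-Löf asymptotic χ² reference is unreliable when the subscore
  table is sparse; use the bootstrap (default).
- Degrees-of-freedom conventions (N−1 for item chi-square, k−1 for
  person chi-square) follow common Rasch-package practice; other
  software groups persons into class intervals before the item
  chi-square and will not agree numerically.
- No joint or marginal maximum likelihood estimation, no rating-scale
  constraint, and no 2-PL/generalized-PCM *estimation* (the generalized
  PCM appears only in the simulator as a misfit source).
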