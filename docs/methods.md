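# Methods

`cagesurv` estimates direct and indirect genetic effects (DGE, IGE) on the
survival of laying hens kept in small groups, where mortality is driven
largely by cannibalistic pecking: a hen's survival depends on her own genes
and on the genes of her cage mates. The package implements four mixed
models for this trait, a censoring-aware cross-validation of their
estimated breeding values (EBV), and the algebra that places all genetic
parameters on a common survival-time (days) scale. Because the layer-line
data this class of analysis was developed on are proprietary, the package
ships a synthetic-data generator that emulates their structure; every
quantitative claim the test suite makes is made about that synthetic data.

## The four models

All models share the DGE-IGE core: the phenotype of hen *i* in cage *k*
carries her own direct effect `A_D,i` and the summed indirect effects
`sum_j A_I,j` of her `n - 1` cage mates (cage size `n = 4`). The pair
`(A_D, A_I)` is multivariate normal with covariance `C (x) A`, where `C`
holds the direct variance, indirect variance and their covariance, and `A`
is the pedigree numerator relationship matrix.

* **STM** (survival-time model): a linear mixed model for survival time in
  days, `y = fixed + A_D + sum A_I + cage + e`, animal parameterization,
  one-hot house-row-level fixed classes, a random cage intercept, and a
  single residual variance. Hens alive at the 416-day cutoff enter at 416
  days, i.e. censoring is ignored. The random cage effect is the standard
  stand-in for a positive residual correlation `rho` among cage members:
  `sigma^2_cage = rho sigma^2_e = 2 sigma_E_DI + (n-2) sigma^2_E_I` in
  terms of non-heritable direct-indirect environmental (co)variances; the
  package fits the single cage variance and makes no attempt to decompose
  it into those environmental components. A fixed cage effect is not
  offered, since it would make the indirect genetic variance
  unidentifiable.
* **RMM.t**: monthly survival 0/1 (survival-function coding: records stay
  0 after death) analysed as repeated measures with random *regressions on
  time* `t_m = 1..13`: genetic sire-dam slopes (no genetic intercepts,
  since there is no variation at housing), two cage terms (an iid
  cage-month intercept and a cage slope on time), a permanent-environment
  slope per hen, and a separate residual variance per month. Fixed effects
  are house-row-level classes crossed with a degree-6 polynomial of time
  (orthogonalized for conditioning; fitted values are unchanged).
* **RMM.p**: identical to RMM.t except the slope covariate is
  `x_m = sqrt(p_m (1 - p_m))`, with `p_m` the mean survival of the
  record's fixed-effect class at month `m`, so fitted variances follow the
  binomial variance profile rather than `t^2`. Degenerate cells are
  handled by flooring/capping `p_m` at `1/(2N)` for a cell of `N` records.
* **GLMM**: monthly 0/1 with a logit link; genetic, permanent-environment
  and cage-month *intercepts* only — the nonlinear link supplies the
  change of variance over time. Fitted by penalized quasi-likelihood
  (PQL): iterated REML on the working linearized response with binomial
  weights, dispersion fixed at 1. PQL is the classical approximation used
  by standard animal-breeding REML software; it is known to shrink
  variance components for binary data, which the tests acknowledge with a
  widened tolerance.

Monthly models use the sire-dam parameterization (separate sire and dam
effect columns, each carrying 1/4 of the additive variance) to avoid the
extreme-category problem of binary data in animal models; the day-scale
STM uses the animal model, and a sire-dam STM variant exists to verify
that the two give near-identical EBV rankings. Whether one fits separate
sire + dam effects or one combined couple effect changes only the scale
bookkeeping (x4 vs x2 back to the animal scale), not the phenotypic
covariance model, so the choice is exposed as the `sire_dam_factor` knob
of the translation context with x4 (separate effects) as the default.

**Time-dependent IGE.** Optionally the IGE incidence at month `m` includes
only cage mates alive at the start of `m`; after the focal hen's own death
her cage composition is frozen as of the month she died, since later
changes cannot have influenced her records.

**Hazard coding.** As an option, records in months strictly after an
individual's death can be set to missing (dead/alive/missing coding),
which approximates the hazard rather than the survival function.

## The REML/BLUP engine

Variance components are estimated by average-information (AI) REML with
exact analytic score and AI matrices, and BLUP solutions come from
Henderson's mixed-model equations at the estimates. Two linear-algebra
strategies compute the same restricted likelihood:

* **Dense-V**: the phenotypic covariance `V = sum_i theta_i K_i` is formed
  from precomputed n x n kernels (`Z_D A Z_D'`, the symmetrized cross
  kernel, `Z_I A Z_I'`, `Z_cage Z_cage'`, `I`). Each iteration costs one
  Cholesky factorization and one explicit inverse. Used for day-scale
  animal-model fits, where records are few (thousands) but genetic
  equations would be many.
* **Absorbed MME**: every random term whose levels are nested within cages
  (cage, cage-month, cage slope, permanent environment) is folded into a
  block-diagonal residual covariance with one small block per cage
  (52 x 52 for 4 hens x 13 months), leaving compact mixed-model equations
  over the fixed effects and the sire-dam genetic effects. Scores use
  `tr(P V_i) = tr(R*^-1 V_i) - tr(C^-1 W' R*^-1 V_i R*^-1 W)` with the
  small coefficient matrix `C` inverted densely; the absorbed terms' BLUP
  are recovered afterwards as `sigma^2_t Z_t' R*^-1 (y - W theta_hat)`.

The two strategies agree to machine precision on shared instances, which
the suite checks explicitly; a third, independent oracle (explicit
inversion of the full dense V, GLS, conditional means) pins down
correctness on small instances.

**Optimization.** AI steps are taken in a transformed parameter space: the
genetic 2 x 2 matrix is stepped through its Cholesky factors, which keeps
it positive semidefinite by construction and lets estimates sit stably on
the correlation bound (a common outcome, since the direct-indirect
covariance is weakly identified). Variances are floored at 1e-8 of the
phenotypic scale; parameters at the floor with an outward gradient are
frozen out of the step. If a damped AI step fails to improve the
likelihood, the update falls back first to an AI step with the genetic
block frozen, then to an EM step, which cannot decrease the restricted
likelihood (verified as a property test). Convergence requires a
likelihood change below 1e-8 and a relative parameter change below 1e-6;
heavy replicated fits in the test-suite use 1e-6 on the likelihood, which
changes none of the reported digits. A fit that exhausts its iteration
budget returns the best iterate flagged non-converged. Standard errors of
components come from the inverse AI matrix.

## Cross-validation and approximate accuracy

Cages are assigned at random to 5 folds (re-drawn until every fixed-effect
class is present in every training set; a class with a single cage is a
configuration error). Variance components are estimated once on the full
data; each fold then removes its cages' phenotypes and re-solves the
mixed-model equations at those components, so the held-out hens' EBV flow
only through the pedigree. This replaces a full REML re-fit per fold; at
the fold level the components barely move and the solve is two orders of
magnitude cheaper. Predicted phenotypes combine the hen's own estimated
DGE with the estimated IGE of her three start-of-experiment cage mates;
for RMM.t the slope EBV are first mapped to days (a positive scalar, so
ranks are unaffected), and for RMM.p and the GLMM the predictions are used
rank-only.

Observed phenotypes are survival days adjusted for fixed effects by an
OLS fit on *uncensored* records only (including censored records at their
cutoff value would attenuate class means); censored hens are assumed to
die in random order after the cutoff and all share the average of the top
ranks they jointly occupy. The fold-stratified Spearman correlation is the
Pearson correlation of fold-mean-centred within-fold ranks pooled over
folds — the fixed-fold-effect analogue of a bivariate analysis of ranks —
with a delete-one-fold jackknife SE. Dividing by the upper bound
`sqrt(r^2) = sqrt((sigma^2_AD + (n-1) sigma^2_AI) / sigma^2_P)` (day-scale
STM components) gives the approximate EBV accuracy. The robustness
scenario that censors half the survivors at month `ceil(T/2)` alters only
the training data; observed ranks are always computed against the
unaltered phenotypes so that correlations are comparable across scenarios.

## Day-scale translation

Survival time is the day-sum of the monthly survival indicators,
`ST = c * sum_m S_m` with `c = 30.4` days/month. Under RMM.t a slope
effect `a` contributes `a * t_m` to month `m`, hence `c * S * a` to `ST`
with `S = sum t_m = 91`; slope variances therefore map with `(cS)^2` and
iid per-month variances (cage-month, monthly residuals) with
`c^2 * sum_m`. Sire-dam variances are rescaled to the animal scale first
(factor above). By this package's convention the day-scale cage variance
collects both cage terms and the day-scale residual collects the
permanent-environment slope and the monthly residuals; the derived
quantities (`sigma_TBV`, `sigma_P`, `T^2`, `r_A`) follow from

    sigma^2_TBV = sigma^2_AD + 2(n-1) sigma_ADI + (n-1)^2 sigma^2_AI
    sigma^2_P   = sigma^2_AD + (n-1) sigma^2_AI + sigma^2_cage + sigma^2_e
    T^2         = sigma^2_TBV / sigma^2_P .

The map is validated against a Monte-Carlo oracle that simulates the
generative equation and forms `ST` directly (2 % relative tolerance). No
day-scale translation is offered for RMM.p or the GLMM — it has no closed
form — and requesting one is an explicit error.

## The synthetic-data generator

`popsim` emulates a purebred White Leghorn layer experiment: a sire-dam
pedigree (default 36 sires x 8 dams x Poisson(12.3) female offspring per
dam, two batches, five generations, with ancestral generations carrying
only the selected breeding animals, which is all that matters for the
covariance of the phenotyped generation), random allocation of hens to
four-bird cages nested in laying-house x row x level classes (house 2
lacks the top level), 13 months of 30.4 days, and right-censoring of all
survivors at day 416.

The default mortality engine is a *logistic monthly hazard*: each month a
live hen survives with probability
`expit(mu_m + class + A_D + sum_{j alive} A_I,j + cage + PE)`, deaths
applied simultaneously at month end; dead mates stop contributing IGE the
following month. Defaults were calibrated once, as part of the generator's
design, so that the emulated population resembles the published layer
lines: baseline monthly survival (0.95 x 4 months, 0.972 x 9) with the
default variances yields ~59 % survivors at 13 months, and logit-scale
variances (`sigma^2_AD = 0.15`, `sigma^2_AI = 0.02`, `sigma_ADI = 0.01`,
cage 0.02, PE 0.02, class SD 0.1) put day-scale analyses in the
neighbourhood of the reported line-W1 parameters (direct SD ~28 d,
indirect SD ~10-13 d, rank-correlation bound ~0.25-0.3). Because this
generator is logistic, *all four fitted models are approximations to it*,
mirroring the situation with real data; parameter-recovery claims are
therefore tested against the linear-Gaussian engines instead:
`simulate_gaussian_days` draws directly from the STM's generative form and
`simulate_gaussian_monthly` from RMM.t's (continuous monthly records with
the day view formed by the day-sum identity), with day-scale targets set
to the line-W1 magnitudes (genetic SDs 28 and 10 days, covariance 57
days^2, cage 1000 days^2, residual 9365 days^2, i.e. phenotypic SD 107
days). In the monthly Gaussian engine all genetic variance sits on the
slopes and the cage and residual targets are split half/half between
slope-type and iid per-month terms.

Deaths from causes other than pecking (predators etc.) are not simulated;
the generator emulates the analysed dataset, from which such records had
been removed. For real data carrying such deaths,
`popsim.drop_records_retain_ids` removes an individual's own records while
keeping her identity in the cage mates' IGE bookkeeping, and the design
layer keeps the retained ids among the genetic levels. What the generator does **not** emulate: the 2-week age
staggering within batches (a single 416-day cutoff is applied), behavioural
feather-pecking dynamics, and any non-genetic similarity between
neighbouring cages. Passing tests therefore demonstrate correctness of the
estimation machinery under the stated generative models, not the realism
of any particular biological claim about layers.

## Problem sizes used by the test suite

The replicated validation runs use sizes chosen to make the Monte-Carlo
noise small relative to the tested tolerances: parameter recovery and
cross-model consistency use 20 replicates of ~3000 hens in ~750 cages
(30 sires x 10 dams x Poisson(10)); the zero-indirect-variance boundary
check uses 20 replicates of ~1000 hens, counting an estimate as "at the
bound" when it is below twice its own asymptotic SE (an estimate cannot
sit exactly at zero more than about half the time, so the meaningful
calibration statement is that no *significant* indirect variance is ever
invented); the censoring-robustness contrast uses 20 replicates of ~650
hens with 5-fold cross-validation per scenario and a one-sided sign test
across replicates.

## Known limitations

* PQL underestimates variance components for binary data; the GLMM is
  intended for EBV ranking, not for parameter reporting (consistent with
  the absence of a day-scale translation for it).
* The time-dependent IGE incidence conditions on survival outcomes, which
  is known to inflate indirect-variance estimates; the option reproduces
  that behaviour rather than correcting it.
* The engine targets the model family above; it is not a general-purpose
  REML program (no multi-trait models beyond the DGE-IGE pair, no
  proportional-hazards likelihoods, no genomic relationship matrices).
* Estimates of the direct-indirect covariance frequently sit on the
  correlation bound in small samples; they are reported as such (with the
  genetic matrix bent minimally when numerically singular) rather than
  hidden.
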