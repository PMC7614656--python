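# Methods

This note documents the statistical models behind `compmi`, the choices made
where the design was genuinely open, and what the synthetic generators do and
do not emulate.

## The problem

A binary composite endpoint y is a monotone Boolean combination (OR, or
AND-of-OR) of binary components z_1, ..., z_K measured on each trial
participant. When components can be missing non-simultaneously, three broad
strategies exist: restrict to complete records (CRA), *derive* the endpoint
from the observed components where they determine it and drop the rest
(Deriv), or multiply impute. The package quantifies, analytically and by
simulation, when each strategy is valid.

## Closed-form bias of the derived endpoint (`compmi.analytic`)

Setting: two components, z1 always observed, z2 missing completely at random
with observation probability α; composite y = z1 OR z2; per-arm joint cell
probabilities p_jk = P(z1=j, z2=k). The endpoint is underivable exactly when
z2 is unobserved and z1 = 0, so

    P(underivable) = (1−α)(p00+p01),
    P(y=1 | underivable) = p01/(p00+p01),
    P(y=1 | derivable)  = (α·p01+p10+p11) / (α+(1−α)(p10+p11)).

The two conditionals differ in general: the derived endpoint's missingness
depends on the (possibly unobserved) outcome, i.e. it is MNAR even though the
component is MCAR. Writing σ and τ for each arm's *event share carried by z2
alone*, p01/(p01+p10+p11), the multiplicative bias of the derived-endpoint
odds ratio is

    OR_deriv / OR_full = [1−(1−α)σ] / [1−(1−α)τ],

always within [α, 1/α]. Complete records are exempt under MCAR: conditioning
on z2 observed does not change the outcome distribution, so `cra_outcome_dist`
is constant in α.

A note on the worked example reproduced in the tests: with independent
components at probability 0.7 in one arm and 0.2 in the other, the event
shares are 0.23 and 0.44 (2 dp). The σ/τ labels attach to whichever arm sits
in the OR numerator; the well-known "22% overestimation" at α = 0.3 arises
with the 0.7 arm in the numerator (the opposite labelling gives the
reciprocal, an 18% underestimate). `bias_ratio` therefore exposes σ and τ as
labelled per-arm shares rather than hard-coding an arm convention.

## Log-linear component generator (`compmi.dgm`)

Three components per arm are drawn from the saturated log-linear cell model
p_c ∝ exp(LP_c) over the 8 combinations, LP_c = Σ λ_l z_l + Σ λ_lm z_l z_m +
λ_123 z1 z2 z3 (reference cell (0,0,0)). Softmax normalization subtracts the
maximum linear predictor first, so finite coefficients never overflow.

**Calibration.** Arm event rates are the primary constraint: control
expit(0.3) ≈ 0.574 and treatment expit(0.3+1.35) ≈ 0.839, making the
composite treatment log OR exactly 1.35 by construction, for both composite
definitions. With interactions held fixed, the common (exchangeable) main
effect m is solved by Brent's method on [−20, 20]; the simple-composite event
probability is 1 − p_(0,0,0), strictly increasing in m, and the complex
composite is likewise monotone over the bracket (verified by a bracketing
check), so the root is unique.

**Interaction defaults.** The package's default study conditions use
arm-specific exchangeable pairwise interactions λ12 = λ13 = λ23 = 1.0
(control) / 0.2 (treatment). The arm difference is essential, not cosmetic:
if the pairwise associations were equal across arms, the true conditional
distribution of one component given the others and treatment would contain
no component-by-treatment interaction, and an imputation model with only
main effects (MIC-main) would be *correctly* specified — the study would
have no mis-specification to detect in case I. Arm-varying association
(e.g. symptoms clustering more strongly without effective treatment) is the
realistic regime the three-case structure is about. The three-way
interaction λ123 defines the cases: case I 0/0 (control/treatment), case II
0.5/0, case III 0.6/0.3. All values are configuration, not constants.

**Randomization.** Treatment is i.i.d. Bernoulli(0.5) per participant
(simple randomization); arm sizes are random.

## Missingness mechanisms (`compmi.missingness`)

Components z2 and z3 get independent response indicators from
logit P(r_l=1 | x, z1) = α0 + αx·x + αz1·z1 + αxz1·x·z1. Presets:
MCAR (α0=0.7, rest 0; observation probability expit(0.7) ≈ 0.668), MAR1
(1.05, −0.75, 0.25, 0), MAR2 (1.05, −0.75, 0.25, 0.25). Response never
depends on the component's own value, so the components are at worst MAR —
the point of the package is that the *derived composite* can still be MNAR.
Under MCAR the probability that both incomplete components are observed is
expit(0.7)² ≈ 0.446. Each component has its own random stream spawned from
the master seed, so changing one mechanism leaves the other mask unchanged.

## Three-valued composite logic (`compmi.composite`)

Definitions are negation-free AND/OR trees evaluated under Kleene logic; the
derived endpoint is the evaluation result, derivability its definedness.
Monotonicity (no negation) guarantees that a derivable value never changes
when more components are observed; attempting a negated definition raises an
error rather than silently producing non-monotone derivability. Rows with
all components missing are retained with an unknown endpoint — dropping them
is an analysis-method decision, not a data-model one.

## Imputation engine (`compmi.mi`)

**Fitting.** All conditional models are binary logistic regressions fit by a
dedicated weighted Newton–Raphson routine with step-halving (`_logit.py`).
It detects perfect prediction (constant outcome, singular information, or
coefficients diverging past |β| = 15) and raises a typed error instead of
returning a corrupt fit; it accepts fractional observation weights, which
the augmentation scheme requires. Unit tests pin its coefficients and
covariance to statsmodels GLM.

**Proper imputation.** Each imputation draws a coefficient vector from
N(MLE, inverse observed information) before drawing Bernoulli values, so
between-imputation variance reflects parameter uncertainty.

**Composite level.** MI-CRA treats y as missing whenever any component is
missing; MI-Deriv first derives y and imputes only underivable rows. Both
use y ~ x, matching the substantive model (compatible by construction).

**Component level.** Chained equations over z2 and z3, visit sequence fixed
(z2 then z3; order effects vanish with burn-in), initial fill drawn from
each column's observed marginal. Strategy layouts: MIC-main (x, z1, other
component as main effects), MIC-x (z1 + other component, fit separately per
treatment arm — equivalent to the model with all treatment interactions),
MIC-x-z1 (other component only, fit per (x, z1) stratum — the saturated
model, never mis-specified but most exposed to separation). y is passively
recomputed from the completed components in every dataset (exact identity,
tested).

**Augmentation.** Under perfect prediction the engine can append, for each
design column, a pair of pseudo-observations carrying both outcomes (weight
0.01 each) at the reference point and at each unit design point. Any nonzero
coefficient direction then changes the linear predictor at an augmented
point carrying both outcomes, making the weighted likelihood coercive and
the MLE finite; as the weight → 0 the fit approaches the plain MLE when the
latter exists. With the default weight, the total added weight (2p × 0.01)
is far below 1% of any realistic fitting set. Augmented likelihoods are
optimized with the divergence guard disabled, since their finite optimum can
be legitimately extreme (order log(n/w)).

**Pooling.** Rubin's rules: T = W̄ + (1+1/M)B, df = (M−1)(1+W̄/((1+1/M)B))²,
normal quantiles when B = 0.

**Defaults.** M = 25 imputations / 20 burn-in cycles for standalone analyses,
M = 50 / 20 in the block pipeline. The simulation harness's scaled profile
uses M = 8 / burn-in 8: with two incomplete binary columns the chained
sampler mixes geometrically fast, and pooled point estimates are unbiased in
M, so bias conclusions are unaffected while each scenario stays inexpensive;
the full profile (25/20) is a config switch.

## Analysis models (`compmi.analysis`)

Logistic y ~ x with Wald intervals (simulation estimand: the treatment log
OR, true value 1.35 under the calibrated generator), and the difference in
proportions with SE √(p̂1(1−p̂1)/n1 + p̂0(1−p̂0)/n0) — the closed form of the
identity-link binomial GLM with one binary covariate, used directly to avoid
that GLM's convergence fragility (statsmodels' identity-link fit is the test
oracle). Analysis models are never augmented; a treatment arm with constant
outcome raises a separation error. Confidence levels: 95% for the
simulation estimand, 90% for the risk-difference (block) pipeline.

## Simulation harness (`compmi.simstudy`)

Factorial grid {I, II, III} × {MCAR, MAR1, MAR2} × {simple, complex}.
Replicate seeds are spawned from the master `SeedSequence`, giving
independent, reproducible, parallelizable streams. Failed replicates are
recorded with their reason and excluded from summaries (n_converged
reported); systematic failure (>10% of replicates for a method) raises.
Performance measures and their Monte Carlo errors follow standard
simulation-study practice: bias, empirical SE, average model SE
(√mean(se²), MCSE by the delta method), and coverage. The scaled profile
(N_rep = 500, n = 2000) makes 3-MCSE bias checks sensitive to |bias| ≳ 0.02
on the log-OR scale, which the default study conditions comfortably exceed
for every method asserted to be biased; the full design uses N_rep = 2000.

## Block pipeline (`compmi.blocks`)

Thirty daily binary indicators per participant are grouped into six
five-day blocks. Completeness approach 1 marks a block missing if any day
is missing; approach 2 only if ≥3 of 5 days are missing, otherwise deriving
the block value from observed days (1 if any observed event, else 0 — a
deliberately lenient within-block derivation, flagged in config). The
composite is an OR over blocks; the substantive model is the risk
difference with a 90% CI. Block-level MICE variants: main effects,
stratified-by-treatment with all five other blocks, and
stratified-by-treatment with two adjacent blocks (interior block b uses
b−1/b+1; end blocks use their single neighbour plus the next-nearest, a
declared choice since end-block conditioning has no canonical rule). There
is no fully observed block, so stratifying on a block value is not
available.

**Synthetic cohort.** Daily indicators follow a two-state Markov chain per
participant: the onset hazard h solves 1−(1−h)^30 = p_arm in closed form
(targets 0.43 control, 0.50 treatment), and an ongoing event persists next
day with probability 0.4 — chosen once as a realistic within-episode
continuation rate; persistence shapes day-to-day correlation (what makes
adjacent-block conditioning informative) without affecting the composite
rate. Missingness is generated at block level: 77% of participants fully
complete, 2% with all days missing, the rest with 1–5 incomplete blocks
whose within-block missing-day count is light (1–2 days) with probability
0.9 — implying ~92% of participants are complete under the lenient rule.
The generator reproduces published *marginal* structure (rates, completeness
fractions); it does not emulate real covariate-driven dropout, minimization
variables, or bleed-count severity, so block-pipeline results demonstrate
method mechanics and internal consistency, not clinical conclusions.

## Numerical choices

- Probability-sum tolerance 1e-12; closed-form vs oracle tolerance 1e-10
  (pure arithmetic); calibration tolerance 1e-10 via Brent.
- Degenerate odds cells, zero-probability conditioning events, empty
  analysis sets, and separation all raise typed errors — never silent NaN
  or infinities.
- Missing values are pandas NA in nullable Int8 columns; CSV serializes
  them as empty fields (the package's single tabular dialect).

## Known limitations

- The closed-form engine covers two components; three or more are handled
  by simulation only.
- MNAR mechanisms for the components themselves are out of scope (only the
  induced MNAR-ness of the derived composite is studied).
- Joint-model (multivariate normal) imputation and time-to-first-event
  composites are not implemented.
- The block pipeline imputes blocks as binary; proportional-odds imputation
  of within-block event counts is not replicated.
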