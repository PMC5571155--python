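# Methods

This note records the model, the algorithmic choices, and the places
where the design was genuinely open, in enough detail to re-derive what
the code computes.

## Kinetic model

A pathway is a directed acyclic graph over compounds.  Each edge is a
first-order transformation: abiotic edges remove mass at `k_abio · C`
(`k_abio` in d⁻¹) and biotic edges at `k_bio · X_TSS · C` (`k_bio` in
L gTSS⁻¹ d⁻¹, `X_TSS` the total-suspended-solids concentration in
gTSS L⁻¹ standing in for active biomass).  Stoichiometric yields default
to 1, so with unknown-TP sinks tracked as explicit state variables total
mass is conserved — the property the pathway-gap diagnostics exploit.
Sorption, pH/temperature dependence and non-first-order kinetics are out
of scope.

Because every rate is linear in concentration, the system is
`dC/dt = A(k) C` and `simulate()` evaluates `exp(A t) C₀` exactly, via
eigendecomposition with an `expm`-per-time fallback whenever the
eigenvector matrix is ill-conditioned (near-defective `A`, e.g. repeated
rates).  An LSODA path (`method="ode"`, rtol 1e-8 / atol 1e-10) exists
as an independent numerical cross-check; the two agree to the ODE
solver's tolerance in the test suite.  Trajectory round-off below
−1e-8 µg/L is clipped to zero.

Biotic batch experiments are modelled with **both** edge sets active
("combined" phase): an inoculated reactor still hydrolyses.  This is
why abiotic posteriors are subsidiary inputs to every biotic level.
Whether real biotic data should instead be pre-corrected for abiotic
loss is a judgement call; this package models jointly and flags the
choice here.

## Level planning

Parameters are estimated in levels that follow the mass flow:

1. A compound's abiotic level is 1 + the maximum level of its abiotic
   precursors (roots at level 1).  A compound whose measurements show no
   abiotic transformation carries a frozen zero rate (still counted in
   the parameter tally).
2. A compound with two branches gets a *combinatorial* total at its own
   level, with the branch edges lumped into a single sink edge for
   simulation.  The split into branch members is scheduled at the
   earliest later level at which some observed branch product's own
   removal parameter is primary — before that point the branch flux
   cannot be separated from the product's onward transformation.  (The
   same rule governs both phases; for a branch whose only product is an
   unknown TP the split follows one level after the total.)
3. Biotic parameters are scheduled one level after the compound's
   abiotic level, so the abiotic subsidiaries exist first.  In networks
   with no abiotic edges the biotic topological order is used directly.

Each level's objective includes the measured series of **every**
compound whose removal is resolved (at total- or member-level) up to
that level — cumulative, not just the newly added compound — provided
all of its upstream sources are member-level resolved (a lumped
ancestor diverts flux away from its products, so those products wait).
Parameters of compounds downstream of the objective never influence it
(feed-forward structure), so they are simply absent from the stage.

On the six-biomarker case study this produces the four-level plan
1(A) → 2(A) → 2(B) → 3(A) → 3(B) → 4(B), pinned as a regression test.

## Estimation

**Objective.** Range-normalised SSE over all included series, equal
weights.  Normalising by the measured range makes the objective
invariant to each series' units; it also means points far below a
series' range (censored tails) carry almost no weight, which matters
for the diagnostics below.

**Likelihood.** `ℓ = −(N/2)·ln(SSE/N)` with `N` the number of
measurements — a Gaussian likelihood with the error variance profiled
out.  It is monotone in SSE, so the MAP coincides with the
least-squares optimum; the spread of the posterior is then governed by
the data size and the SSE curvature rather than an assumed noise level.

**Sampler.** DE-MC with sampling from the past (ZS): 5 chains by
default, proposals built from differences of two archive states with
jump factor `γ = 2.38/√(2·d_eff)` (10% of jumps at `γ = 1` for mode
hopping), a snooker update with probability 0.1, archive appended every
10 generations, and DREAM-style subspace crossover — each proposal
updates a random subset of dimensions (crossover fraction drawn from
0.1…1.0), with `d_eff` the subset size.  Chains start at the best
points of the log-density-screened initial archive; without the
crossover and screened starts the 9–15-dimensional wide-prior stages of
the lumped benchmark stall at the 20k-evaluation budget.  Burn-in is
the first half of each chain; a Gelman-Rubin statistic per dimension is
reported.  A single run seed fans out deterministically to per-stage
seeds.

**TIC filter.** After sampling, each draw is re-simulated and kept only
if the Theil inequality coefficient
`√mean((y−ŷ)²) / (√mean(ŷ²) + √mean(y²))` is ≤ 0.3 for every series
(max over series by default; mean available).  Rejecting every draw is
an error that deliberately points the user at structure re-evaluation.

**Budgets.** The full-scale budget is 20 000–50 000 evaluations per
estimation; the package's own studies run Method 1 at 5 000 evaluations
per stage (six stages for the six-biomarker fixture) and the lumped
Method 2 at 20 000 per stage, sizes at which the whole benchmark suite
completes in a few minutes on one core while leaving every acceptance
property reproducible.

## Uncertainty propagation

A posterior is summarised by its median and central 95% credibility
interval (2.5th/97.5th percentile, linear-interpolation rule — stated
because these edges become hard bounds downstream).  The best-fitting
parametric family by BIC among {normal, lognormal, gamma, Weibull,
exponential, logistic, loglogistic, generalized extreme value, beta
rescaled to the sample range} is attached; positive-support families
are fitted with the location pinned at zero, since free-location ML
fits are unstable on rate-constant samples and corrupt the BIC
comparison.

* **Method 1** turns an upstream posterior into a subsidiary prior by
  truncating the fitted distribution to the 95% CrI (uniform on the CrI
  if no family attained a finite fit) — range and shape both propagate,
  marginally; joint (copula) propagation is a known limitation.
  Branch members after a combinatorial estimate get uniform priors on
  [0, CrI upper bound of the total] plus a hard indicator keeping their
  sum inside the total's CrI (the "soft" constraint: soft relative to
  Method 3's exact equality, not a penalty).
* **Method 2** (lumped benchmark) fits all abiotic parameters at once
  against the abiotic data with wide uniform priors ([0, 100] by
  default, i.e. 10× the largest expected rate; results are known to be
  sensitive to this choice, which is part of what the benchmark
  demonstrates), then all biotic parameters with abiotic subsidiaries
  uniform over their CrIs.
* **Method 3** (no-propagation benchmark) freezes upstream parameters
  at their posterior medians and reparameterises each branch pair as
  `member₁ = total − member₂`, sampling only `member₂ ∈ [0, total]`.
  The pair is then perfectly anti-correlated by construction — the
  structural non-identifiability the sequential method avoids.

## Assessment

Per compound and phase: RMSE and MAE of the calibrated model's
prediction; 95% Monte-Carlo prediction bands from joint posterior draws
(≥ 200, resampled rows so correlations survive); ARIL (mean band width
relative to the measured value, zero-concentration points excluded);
coverage (fraction of measurements inside the closed band); and
ILTC = ARIL/coverage (infinite at zero coverage, flagged).  Posterior
Pearson correlations (LCC) above 0.7 in magnitude flag non-identifiable
pairs, and a parameter is relative-CrI-identifiable when both CrI arms
stay within 50% of the median.  Global sensitivity uses standardised
regression coefficients (SRC_j = b_j·σ_j/σ_y from a multivariate linear
fit) with R² reported and a warning below 0.7; the scalar output is the
user's choice (concentration at a time point, or SSE).

## Pathway-gap discovery

After a converged fit, three explicit triggers operationalise
"systematic deviation" per compound: |t-statistic of the mean signed
residual| > 2; Wald-Wolfowitz runs test on residual signs at p < 0.05;
and a mass-balance deficit (observed accumulation rate minus
model-implied net flux, evaluated at the measured concentrations) that
is one-signed at every interior point with a time-integrated magnitude
above 5% of the compound's concentration scale.  Residuals where the
measured value is below 2% of the series maximum are excluded from the
sign-based triggers: below that quantification limit the
range-normalised objective carries no weight, so tiny residuals inherit
the sign of the local fit bias and would fake long runs (without the
exclusion the null false-positive rate roughly doubles above its
nominal ~0.1; with it, the measured rate over 20 seeded well-specified
replicates is 0.08).

For each systematically **over-predicted** compound, every upstream
source gains a candidate branch to an unknown TP in the diagnosed
phase (sources already feeding an unobserved sink are skipped — two
parallel sink edges are structurally unidentifiable), ranked by
|deviation| × flux share.  Candidates are re-fitted by the caller;
a genuine gap shows as a lower minimal SSE (model nesting).

Diagnostics should run on a **sequentially** calibrated model: in a
joint all-at-once fit, downstream rate constants absorb misrouted flux
and dilute the signature.  With upstream rates pinned by their own
levels, a missing branch shows up exactly as the canonical signature:
the parent fits, its product is persistently over-predicted.

## Synthetic data

The generator simulates each experiment phase under known rates and
corrupts with proportional Gaussian noise (default σ = 5%) above a
detection floor (0.01 µg/L); additive noise is available.  Same seed,
same bytes.  The six-biomarker fixture mirrors the wastewater pathway
of heroin and codeine biomarkers: HER → 6MAM → MOR, COE → {MOR, NCOE},
MORG → MOR (biotic only; the abiotic rate is frozen at zero), terminal
sinks for MOR and NCOE, and the two discovered biotic branches
HER → TP and MORG → TP — 7 abiotic and 9 biotic rate constants, four
calibration levels.  Its rate constants are package defaults chosen
once for well-separated timescales (fast HER hydrolysis at 6 d⁻¹ down
to slow MOR turnover at 0.25 d⁻¹, TSS 0.4 gTSS/L) so that recovery
experiments are informative; they are **not** literature estimates.
The 13-point sampling schedule is dense over the first few hours to
catch the fast hydrolysis.

What passing tests on this generator do and do not show: the data are
exactly first-order, noise is uncorrelated and proportional, all six
biomarkers are measured on a common schedule, and the true structure is
in the model class.  Real batch experiments violate all four to some
degree (sorption, quantification error structure, missed compounds), so
recovery rates here are an upper bound on field performance.  One
consequence is measured honestly by the benchmark suite: on data this
informative, all three calibration methods reach point estimates at the
noise floor, so the methods separate on uncertainty metrics (CrI
widths, ARIL, ILTC) rather than on raw RMSE.

## Numerical choices and degenerate inputs

Strictly increasing times required; t = 0 allowed.  Constant measured
series are rejected by the objective (zero range).  Point-mass priors
are excluded from the proposal geometry.  A TIC filter that rejects
everything, a sampler with zero acceptance inside the adaptation
window, and more than 1% failed Monte-Carlo simulations are hard
errors, not warnings.  Percentiles are linear-interpolation throughout.
Seeds derive from a single integer and stay below 2³¹.
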