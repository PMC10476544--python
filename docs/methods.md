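# Methods

## Model

`dsemcfa` fits a two-level dynamic factor model to long panels of item
responses. Writing y_itk for item k of person i at occasion t:

- **Measurement, between level.** The person's stable item score is
  b_ik = ν_k + λ_b,k η_b,i + ε_b,ik with ε_b,ik ~ N(0, θ_b,k) drawn once
  per person-item. η_b,i is the trait factor.
- **Measurement, within level.** y_itk = b_ik + λ_w,k η_w,it + ε_w,itk
  with occasion-level error ε_w,itk ~ N(0, θ_w,k). Item residuals are
  uncorrelated at both levels (diagonal Θ), the usual CFA default.
- **State dynamics.** η_w,it = φ_i η_w,i(t−1) + ζ_it, ζ_it ~ N(0, σ²_ζ,i),
  initialized at the stationary law N(0, σ²_ζ,i/(1−φ_i²)). Sessions are
  treated as equally spaced consecutive occasions; skipped mid-series
  sessions are compressed to observed rows (a sensitivity caveat — the
  alternative of inserting missing occasions changes the effective lag).
- **Random effects.** u_i = (η_b,i, φ_i, log σ²_ζ,i) ~ N(γ + β'x_i, Σ_b).
  Modeling the innovation variance on the log scale keeps it positive and
  lets volatility be person-specific. In the conditional model x_i holds
  person-constant covariates (dummy-coded), so β rows are differences
  from the reference group.

**Identification.** One anchor item has λ_w = λ_b = 1; all intercepts ν_k
are free and the trait grand mean is fixed at 0 (the grand mean and the
intercepts are otherwise additively confounded). With a covariate, β_η is
identified against the reference-group mean 0.

**Missing data.** Missing item cells are skipped in the observation
update of the filter (MAR integration); rows with every item missing are
dropped at load time, and persons with fewer than two retained sessions
are excluded — a lag-1 model has no information about them.

## Priors

N(0, 10⁶) on loadings, intercepts and fixed effects; inverse-gamma
(0.001, 0.001) on residual variances; and, on Σ_b, the Huang–Wand
hierarchy (inverse-Wishart mixed over per-dimension inverse-gamma
scales; ν = 2, scale A = 10), giving each random-effect SD a half-t(2)
marginal and each correlation a near-uniform one. The scale-adaptivity
matters: the three variance components differ by two orders of magnitude
(trait ≈0.25, carryover ≈0.07, log-volatility ≈1–2), and no fixed
inverse-Wishart scale is weakly informative for all of them at once —
an identity scale measurably inflates the small components at N in the
hundreds, while a near-zero scale puts exploding density on singular
corners (|Σ|^−(df+p+1)/2) and drags the volatility–trait correlation
toward ±1. A fixed inverse-Wishart (scale, df) remains available in
``PriorSpec`` for sensitivity analyses.

## Sampler

Per sweep, in order:

1. **(φ_i, log σ²_ζ,i)** — joint random-walk Metropolis whose target is
   the within likelihood with the latent states integrated out
   analytically by a scalar Kalman filter (the K item observations at an
   occasion collapse to one pseudo-observation by a rank-one reduction).
   Proposals follow the Cholesky shape of the conditional random-effect
   prior with a per-person scale adapted during burn-in only (frozen
   afterwards, preserving detailed balance); the step repeats twice per
   sweep because this is the slowest-mixing block. Proposals with
   |φ| ≥ 1 are rejected outright.

   Two families of global moves supplement the per-person step. *Funnel
   (ASIS) moves* jointly rescale a component's conditional residuals
   u_ij − E[u_ij | u_i,−j] by e^ε and the matching conditional variance
   of Σ_b by e^2ε — an exact deterministic-expansion Metropolis step in
   which the Gaussian density change cancels against the residual
   Jacobian, leaving the pooled data term, the Σ_b prior ratio, and a
   +2ε coordinate Jacobian. These traverse the classic hierarchical
   variance funnels. *Translation moves* shift every person's carryover
   (or log variance) and the corresponding fixed effect together against
   the pooled likelihood: when a spread is near zero the person values
   are pinned to the grand mean and would otherwise move only by a
   collective random walk.
2. **Latent states** — forward-filtering backward-sampling, vectorized
   across persons (padded to the longest series with an observation
   mask). Placing this immediately after step 1 keeps the partially
   collapsed scan valid.
3. **Between item scores b_ik** — conjugate normal.
4. **Recentering move** — the item scores and the state's sample mean
   are nearly collinear at short series, so the sampler adds an exact
   Gibbs draw along the likelihood-invariant direction
   (η_w,i· + δ, b_i· − λ_w δ); δ has a closed-form normal conditional
   from the AR prior and the b prior. Without this move the carryover
   mean is biased low at any feasible chain length; with it, recovery
   is clean (the move is itself verified against brute-force conditional
   densities in the tests).
5. **Trait scores, loadings, intercepts, residual variances** —
   conjugate normal / inverse-gamma draws (anchor loadings pinned at 1).
6. **Fixed effects (γ, β)** — one constrained conjugate multivariate
   normal draw (the trait grand-mean coordinate dropped); **Σ_b** —
   inverse-Wishart draw, then the Huang–Wand auxiliary scales.

Chains start over-dispersed (jittered moment-based values; carryover
uniform on (−0.6, 0.6)). Two chains by default; the first half of each
chain is burn-in; PSR = sqrt((W+B)/W) with W the mean within-chain
variance and B the variance of chain means — identical chains give
exactly 1. `converge_and_rerun` doubles the iteration count until every
monitored parameter's PSR clears the threshold (default 1.05), then
re-estimates at `rerun_multiplier` (default 3×) the converged count; a
failed budget is flagged, never silently accepted.

Derived quantities — loading differences, Σ_b correlations, and the
person-average stationary state variance V̄_w = mean_i σ²_ζ,i/(1−φ_i²) —
are recorded per retained draw and summarized by posterior median and
equal-tailed 95% interval; transforms of summaries are never used.

## Psychometric outputs

For each draw, item between-variance = λ_b²·Var(η_b) + θ_b and item
within-variance = λ_w²·V̄_w + θ_w; ICC = between/(between+within); the
level R² drop the residual from the numerator. Using the person-average
V̄_w (default) respects random-effect heterogeneity; a fixed-effects
plug-in mode (exp(γ_lv + Var_lv/2)/(1 − γ_φ²)) is provided for
comparison. The invariance decision is the 95% equal-tailed interval of
λ_b,k − λ_w,k excluding zero, with no multiplicity correction (a
deliberate caveat: with 6 tested items per factor, about one false flag
per three factors is expected under invariance).

**Anchor selection.** A provisional fit (default reference item) gives
per-draw cross-level loading ratios r_k = λ_b,k/λ_w,k; each item pair is
tested for ratio equality by the interval of r_j − r_k; the mutual
invariance graph's largest clique (exhaustive search, K ≤ 10) supplies
the anchor, tie-broken by the highest within-level R². If no pair is
mutually invariant the difference table is refused rather than defended.

## Synthetic data

The generator draws from exactly the estimation model, with defaults
emulating the motivating study's conditions: N = 333 persons; series
lengths 2 + negative-binomial tuned to mean 10.76, SD ≈ 6.3; 7 items;
structural truth (trait variance 0.247, carryover mean 0.454/variance
0.072, log innovation variance mean −3.263/variance 2.35, correlations
0.704/0.647/0.255) and measurement truth reproducing study-like
reliabilities (within R² 0.20–0.39, between R² 0.45–0.84, loadings
0.70–1.10). Item intercepts sit in the 0.6–1.2 range typical of mild
symptom scores. Residual variances are derived from the target
reliabilities via the population within-person latent variance.

Simulated carryover is rejected outside |φ| ≤ 0.97 rather than |φ| < 1:
with carryover SD ≈ 0.27, the population stationary variance
E[σ²/(1−φ²)] log-diverges at the unit boundary, so a small stationarity
margin is required for the population within-variance (and hence the
analytic ICC/R²) to be finite and well-defined. The analytic value is
computed by exact 1-D quadrature with the conditional lognormal mean in
closed form.

Missingness is completely at random only (the motivating data's
missingness was informative, but no mechanism is available to emulate);
responses are continuous by default, with an optional clamp-and-round
mode to the 0–3 grid for realism studies. Ordinal measurement, mid-series
missing occasions, and multi-factor joint dynamics are not generated —
so passing recovery tests demonstrate correctness of the estimator under
the model's own assumptions, not robustness to categorical floors or
informative dropout that real clinic panels exhibit.

## Problem sizes used in the test suite

Replicate studies run at reduced, documented scales chosen to keep a full
run on a single CPU short while preserving the designs: headline
structural recovery at 20 replicates of N=100 (mean series length ~11)
with 2,000-iteration chains; type-I invariance calibration at 100
replicates of N=45 with 500-iteration chains; planted-noninvariance
detection at 20 replicates of N=150 with 800-iteration chains;
conditional-effect recovery at 10 replicates of N=300 with 700-iteration
chains. The recovery truth uses the study-style structural block with
log-volatility variance 1.0: at the study's full 2.35 the carryover mean
is so weakly identified at N=100 (the profiled marginal likelihood is
nearly flat over φ̄ ∈ [0.1, 0.55]) that no estimator could recover it
tightly; this is a property of the design, not of the method, and is
discussed further below.

## Known limitations

These were measured in the package's own replicate studies (the
acceptance suite computes them on every run):

- With ~11 sessions per person and study-like reliabilities, the mean
  carryover γ_φ has posterior SD ≈ 0.1 at N=100; point-estimate errors
  of that order are expected and intervals are wide (though close to
  nominally calibrated). Recovery sharpens markedly with longer series
  or higher within-level reliability.
- Interval coverage for the **carryover variance** Var(φ) is visibly
  below nominal (~70% at N=100, T≈11): a spread of 0.07 sits at the
  noise floor of per-person carryover estimates there, and the posterior
  sometimes collapses it toward zero. Treat Var(φ) at such designs as
  order-of-magnitude information.
- The **cross-level invariance flag is anticonservative in small
  samples**: under invariant truth the nominal-5% flag fires at roughly
  13% for panels of N≈80 and near 29% at N≈45, because the trait
  variance/between-loading scale trade-off biases between-loadings when
  the person-level information is thin. The flag is approximately
  calibrated only for N in the hundreds.
- Power for cross-level differences is modest: a true gap of 0.4 is
  flagged in roughly three-quarters of panels at N=150. Gender-style
  effects on the log innovation variance face a hard floor — the
  group-mean-difference SE cannot beat sd(log σ²)·√(1/n₁+1/n₀) ≈ 0.12
  at N=300 — so an effect of −0.24 is confidently detected only in a
  minority of such panels regardless of estimator.
- The variance of the log innovation variance and its correlation with
  the trait are only weakly separated at short series; do not
  over-interpret the split between them at T ≈ 10.
- Carryover is sampled under a stationarity restriction (|φ_i| < 1); a
  truly nonstationary responder is not representable.
- One factor per fit; the joint multi-factor model with cross-lagged
  innovations is out of scope.
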