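# Methods

## Model and target

Binary randomized treatment X, binary outcome Y (Y=1 desirable), potential
outcomes Y(0), Y(1) with consistency Y = Y(X). Target: the probability of
benefit π = P{Y(0)=0, Y(1)=1}. The identified margins are p₀ = P{Y(0)=1} =
p(Y=1|X=0) and p₁ = P{Y(1)=1} = p(Y=1|X=1); they imply the sharp bounds
max(0, p₁−p₀) ≤ π ≤ min(p₁, 1−p₀).

The joint of (Y(0), Y(1)) is a 2×2 table p_ab with one free parameter beyond
the margins, taken as the log odds ratio α = log(p₁₁p₀₀ / p₁₀p₀₁). Given
(p₀, p₁, α) the table is recovered by solving a quadratic for p₁₁ (a
Plackett-type inversion):

- α = 0 gives p₁₁ = p₀p₁ (independence);
- α → ±∞ give the upper/lower Fréchet extremes min(p₀,p₁) and
  max(0, p₀+p₁−1);
- p₁₁ is strictly increasing and π = p₁ − p₁₁ strictly decreasing in α, with
  the nonparametric bounds as limits.

## The sensitivity parameter

With baseline covariates Z the reference scenario is Y(0) ⊥ Y(1) | Z, under
which π = E[p(Y=1|X=1,Z)·p(Y=0|X=0,Z)]. For a cell (x, y) the parameter

δ_xy = α_xy − β_xy, with α_xy = logit P{Y(x)=1 | Y=y, X=1−x} and
β_xy = logit E{p(Y=1|X=x,Z) | Y=y, X=1−x},

is 0 in every cell under the reference scenario, whatever the dimension of
Z, and any one (δ_xy, β_xy) identifies π through a cell-specific formula
(`pi_from_delta`). The four α_xy are deterministic functions of (p₀, p₁, π),
so cells interconvert through observed margins (`convert_alpha_cell`,
`convert_delta_cell`); feeding the four cells consistent parameters returns
the same π to machine precision, which the tests assert at 1e−10.

No δ_xy is variation independent of the full law p(X, Y, Z) — indeed no
scalar parameter can be (a nonexistence result we document but do not
compute). Practical consequence: a posited δ can be incompatible with the
data, in which case the recovered π leaves [0, 1]. `pi_from_delta` clips
and raises an `IncompatibleValueWarning` rather than returning the raw value
silently. One δ_xy is always variation independent of the (X, Y) margins;
`variation_independent_cell` returns it, with the fixed tie-break precedence
(0,1) > (1,0) > (1,1) > (0,0) at boundary equalities (the underlying result
only guarantees "one of the four", so the tie-break is our convention).

Deliberately not implemented: the probability-scale variant
δ′_xy = expit(α_xy) − expit(β_xy). Its range depends on the observed data,
which defeats the purpose of a data-free anchor; the logit-scale parameter
is the supported one.

## Estimation and inference

`fit_outcome_model` fits a logistic regression of Y by maximum likelihood
(statsmodels GLM). Default: a joint model with main effects of X and all
covariate columns; a patsy right-hand side (e.g. `X + np.log(np.abs(Z))`)
or per-arm fitting (Y ~ Z within each arm) are options. β̂_xy is the logit
of the mean model prediction p̂(Y=1|X=x, Z_i) over the (Y=y, X=1−x) stratum;
π̂ plugs (δ, β̂_xy) and the empirical arm-wise outcome proportions into the
cell formula. Empirical probabilities are unweighted sample proportions
without continuity corrections; an empty (X, Y) cell aborts four-cell
analyses with an explicit message.

δ is treated as **known** in all variance computations: sensitivity
uncertainty (the grid) and statistical uncertainty (the CI at each grid
point) are kept separate by construction.

Sandwich variance: the estimator is an M-estimator stacking (i) the logistic
score, (ii) the stratum-mean equation 1{Y=y, X=1−x}(p̂_i(γ) − e) behind
β̂ = logit(e), (iii) the two arm-wise proportion equations, and (iv) the π
formula. The bread is assembled analytically, the meat empirically, and
Var(π̂) = [J⁻¹ B J⁻ᵀ]/n in the last coordinate. The exact stacking is our
own derivation from standard M-estimation theory; its arbiter in the tests
is (a) the closed-form delta-method variance in the no-covariate case
(agreement to 1e−4 relative) and (b) the nonparametric bootstrap on a fixed
n=2000 dataset (agreement within 10%). The bootstrap (`bootstrap_ci`)
refits the whole pipeline per resample, redraws (and counts) resamples with
an empty stratum, and is the default for per-arm or user-specified models,
where the joint-score sandwich does not apply. Per-cell estimates can be
pooled by inverse-variance weighting; because the four estimates are
computed from the same data their naive pooled SE ignores cross-cell
correlation, so `ivw_combine` reports that SE only as a flagged fallback and
bootstraps the whole combination pipeline when the data are supplied.

Grid calibration: a bound Ã_x on the largest conditional counterfactual risk
difference translates to
logit{expit(β) − Ã} − β ≤ δ_xy ≤ logit{Ã + expit(β)} − β. When a side
condition fails (argument outside (0,1)) that endpoint is replaced by a
±`fallback` sentinel, default 5 log-odds units, always flagged in output —
expit(±5) ≈ 0.007/0.993, so the sentinel spans essentially the whole
compatible range on the probability scale. When both sides fail, both
sentinels are applied (our choice; no canonical prescription exists).
Asymmetric bounds are supported by passing `A=(A_lo, A_hi)`, applying the
two formulas separately. Risk-ratio-scale calibration is out of scope.

## Synthetic data generator and truth engine

`sample_trial` draws Z ~ N(0,1), X ~ Bernoulli(0.5) independent of Z,
conditional margins P{Y(x)=1|Z} = expit(a0 + aX·x + aZ·Z), and the pair
(Y(0), Y(1)) from the conditional joint implied by a user-supplied
conditional log odds ratio α_Z(z); Y = Y(X). Presets:

| scenario | a0 | aX | aZ | α_Z(z)  | feature                          |
|----------|----|----|----|---------|----------------------------------|
| I        | 1  | 1  | 0  | 0       | independent potential outcomes   |
| II       | 1  | 0  | −1 | 0.2 + z | null average effect              |
| III      | 1  | 2  | −2 | 0.2 + z | strong effect, strong dependence |
| IIImis   | —  Scenario III data, analysis covariate misspecified as log\|Z\| |

Defaults are 1,000 replicates of n=500 subjects — the conditions under which
the replication results quoted in the tests were produced.

`truth_by_quadrature` integrates the conditional joint cells and the
β_xy-defining weighted expectations over Z with a Gauss–Hermite rule on the
standard-normal weight (default 201 nodes, verified against 403; drift above
1e−8 raises). The density of Z given (Y=y, X=1−x) is proportional to
p(Y=y|X=1−x, z)φ(z), so β_xy is a ratio of two such integrals. At extreme
nodes the conditional margins saturate to 0/1 in floating point; there the
joint degenerates and p₁₁ = p₀p₁ exactly, which the integrand uses directly.
Structural identities of the presets hold in quadrature to 1e−9 and serve as
oracle checks: β_x1 = β_x0 (I), β_1y = β_0y (II), β_1y − β_0y = aX (III).
The true A_x maximizes the conditional counterfactual risk difference over a
fine z grid on [−8, 8] (4001 points); the difference vanishes in both tails,
so the window is not binding.

What the generator does *not* emulate: multivariate or non-normal Z (the API
accepts arbitrary covariates, but the quadrature truth engine is
univariate-normal; elsewhere fall back to large Monte Carlo samples),
non-logistic outcome laws, block or covariate-dependent randomization, and
missing data. Passing tests therefore demonstrate correctness of the
identification algebra and calibration of the inference under a
correctly-specified (or deliberately misspecified) logistic model — not
robustness to arbitrary real-data violations.

## Numerical choices

- Odds-ratio inversion: for |α| < 1e−6 the independence product is returned
  (the direct formula divides by e^α − 1); |α| ≥ 300 returns the Fréchet
  extreme (the residual is below e⁻³⁰⁰ and e^2α would near overflow). The
  discriminant's dominant term is computed as a square via `hypot` so it
  cannot cancel; results are clipped into the Fréchet box to absorb float
  drift.
- Probabilities are validated with tolerance 1e−12: values within it of
  [0, 1] are clipped, values beyond rejected. All statistical logits route
  through a guard clipping to [1e−12, 1−1e−12] with a `GuardWarning`
  (finite-sample stratum means of 0/1 do occur); the *analytic* δ-range
  computation instead maps boundary arguments (within 1e−12 of 0/1, where
  float association can land a ulp inside) to ±∞.
- RNG: one master seed per study; per-replicate generators are spawned from
  a `SeedSequence`, so replicate r is reproducible in isolation and studies
  are deterministic end to end. Bootstrap draws come from a single
  `default_rng(seed)` stream.
- Replication summaries report means, empirical SDs (ddof=1), mean estimated
  SEs, and 95% Wald coverage; truth values are reported at 3 decimals with
  full precision retained internally.

## Known limitations

- Sandwich inference assumes the joint logistic model is correctly
  specified; under misspecification both π̂ and its coverage degrade (the
  IIImis preset quantifies how much), and the bootstrap inherits the bias.
- Calibrating the δ grid with β̂ estimated from the same data blurs the
  separation between sensitivity and sampling uncertainty; the grid
  endpoints are themselves noisy.
- Bound-based grids give intervals for π, not points; a δ value gives a
  point. Neither is a confidence statement about δ itself.
- Binary treatment and outcome only; categorical/continuous outcomes and
  observational (confounded) settings are out of scope.
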