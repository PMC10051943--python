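# Methods

This note documents the models implemented in `affectdyn`, the numerical
choices behind them, and what the synthetic studies do and do not show.

## The modelling problem

Raters watching a subject in a dyadic interaction produce two kinds of
labels: a continuous valence/arousal (V/A) trajectory sampled on a fixed
grid (values in [−1, 1]), and 7-point Likert ratings of five
social-participation traits (agreement, dominance, engagement,
performance, rapport). The package treats the continuous annotation as a
realisation of a stochastic dynamical system, compresses it into a small
set of per-subject dynamics parameters, and asks a causal question: how
does a subject's affect dynamics influence the social ratings they
receive, once unobserved rater-side common causes (e.g. perceived
personality, sympathy) are adjusted for?

## Ornstein–Uhlenbeck state-space model

The latent affective state S follows a 2-D OU process observed with
additive noise:

    dS_t = B (U − S_t) dt + D^{1/2} dW_t,      Y_t = S_t + R^{1/2} ε_t.

* **U** (home base, annotation units): the attractor the state is pulled
  towards.
* **B** (1/s): symmetric dampening-force matrix; positive eigenvalues are
  required for stationarity and are enforced by construction through the
  parameterisation `B = [[B_AA, ρ_B √(B_AA B_VV)], [·, B_VV]]` with
  `B_AA, B_VV > 0` and `|ρ_B| < 1`.
* **D** (units²/s): diffusion covariance, parameterised by two scales and
  a correlation (`D = S C S`), hence positive definite by construction.
* **R**: diagonal observation-noise covariance.

Axis order is (arousal, valence) everywhere, fixed by the descriptor
ordering `p = [U_A, U_V, B_AA, B_AV, B_VV, D_AA, D_AV, D_VV]`.

**Likelihood.** The default transition likelihood applies the
Euler–Maruyama kernel directly to the observations: each increment is
Gaussian with mean `Y + B(U − Y) dt` and covariance `D dt`. This conflates
the latent state with the observation; it is kept as the default because
it is the natural discrete-time reading of the state equation when the
annotation is taken at face value, and it is fast and well-conditioned. An
exact Kalman-filter likelihood (marginalising S, including R, with a
stationary initial distribution) is available as `kernel="kalman"`. Under
the default likelihood R does not enter the likelihood at all, so its
posterior equals its prior; this is deliberate — R is reported but not
interpreted.

**Priors.** `U ~ N(0,1)` per dimension; `B_AA, B_VV ~ LogNormal(0,1)`;
`ρ_B, ρ_D ~ Uniform(−1,1)`; D scales `~ HalfNormal(1)`; R scales
`~ HalfNormal(0.1)`. With 5-minute trajectories at 40 ms steps (7500
transitions) the likelihood dominates all of these.

**Inference.** All Bayesian fits in the package use MAP + Laplace: the
posterior mode is found by L-BFGS on an unconstrained parameterisation
(log/arctanh links), the Hessian is obtained by finite differences (of the
analytic gradient where one is implemented), and posterior draws are taken
from the Gaussian approximation at the mode. This is accurate here because
every posterior involved is unimodal and data-dominated at the sample
sizes used. An affine-invariant ensemble MCMC route (emcee) over the same
log posterior is provided for the OU model and is used in the test suite
as an independent cross-check of the Laplace machinery. Optimiser starting
points are moment-matched (OLS of increments for the OU model, ridge least
squares for the outcome model), and scale parameters are box-bounded away
from their degenerate boundaries (σ ∈ [1e−2, 1e2], ν ∈ [1e−4, 1e3])
because line searches otherwise step into exactly singular likelihoods.

**Recovery.** With 7500 steps at dt = 0.04 and a well-separated parameter
set, posterior means of U, diag(B) and diag(D) land within 20% relative
error in ≥ 90% of replicates (the acceptance suite runs 20). Two known,
small biases are accepted: the Euler discretisation biases B down by
~B·dt/2 (≈ 4% at B = 2), and unmodelled observation noise biases B and D
up by ~2R/(Var(Y)·dt); the recovery study therefore uses a small R
(sd 0.01).

## EWE fusion

The consensus trajectory is the Evaluator Weighted Estimator: per
dimension, a rater's weight is its mean Pearson correlation with the other
raters, each pairwise correlation clipped below at zero before averaging
(an anticorrelated pair contributes no agreement, not negative agreement —
this is also what makes a lone contrarian rater get weight 0 while leaving
the agreeing majority's weights intact). Weights are normalised to sum to
one; a constant rater gets weight 0; if all weights clip to zero the
fusion falls back to uniform with a warning. Fusion is independent per
dimension; no annotator-delay compensation is applied.

## Cross-recurrence validation

The fitted model is validated generatively: trajectories simulated from
posterior draws should share fine temporal structure with the reference
while uniform-random trajectories over the same bounding box should not.
The cross-recurrence plot thresholds pairwise Euclidean distances between
two trajectories in the V/A plane (no delay embedding — the plane is
already the state space); DET and LAM are the fractions of recurrent
points on diagonal/vertical lines of length ≥ 2 (maximal runs, border
lines counted at truncated length), MDL the longest diagonal.

Two choices matter and are fixed as follows:

* **Radius**: calibrated once per comparison as the 5% quantile of the
  *reference's self-distance* distribution and shared by all plots. Using
  a per-plot target recurrence rate would force the random baseline to the
  same number of recurrences and destroy the separation the comparison is
  designed to show.
* **Orientation**: the tested trajectory is on the rows, the reference on
  the columns, so LAM measures the tested trajectory's dwelling in states
  of the reference — replicated OU dynamics dwell, an i.i.d. random rater
  cannot. DET and MDL are orientation-invariant.

With these conventions random-rater DET ≈ LAM ≈ the chance level set by
the recurrence rate, far below the emulated group, for every subject.

## The deconfounder

The 8-vector descriptors of all subjects form the cause matrix P
(columns standardized to mean 0, sd 1; all regression coefficients are on
this scale). PPCA is the factor model:

    c_s ~ N(0, λ² I_K),   p_s | c_s ~ N(c_s' W, ν² I_L),   λ = 1, K = 2.

The substitute confounder is ĉ_s = E[c_s | p_s], computed per posterior
draw and averaged. W is identified only up to rotation (the isotropic
prior does not break the symmetry), which makes the Laplace Hessian
singular along the rotation orbit; the standard echelon constraint
(W[k,l] = 0 for l < k) removes the flat direction. Everything downstream
is invariant to this choice.

**Predictive check.** 20% of cells are masked (re-drawn if a subject or
column would lose all cells), the factor model is refit on the observed
cells, and the expected held-out log likelihood t (averaged over the
posterior, with the latent factor marginalised in closed form per draw) is
compared per subject between the real held-out cells and 100 replicated
datasets from the posterior predictive. The score is the fraction of
replicates with lower t than the real data, ties counting one half,
averaged over subjects. Per-subject comparison is what concentrates the
score near 0.5 for a well-specified model.

The calibration study (`sample_ppca_causes`) draws the loading matrix with
**equal-norm columns**. This is deliberate: with arbitrary column norms,
standardizing the generated matrix makes the noise heteroscedastic across
columns, so the isotropic-ν PPCA is genuinely misspecified and the score
biases low — the calibration would no longer measure what it is meant to
measure. With equal norms, standardization is a pure rescale and the
model family is preserved; the measured mean score is ≈ 0.44. The check is
known to be weak against many real misspecifications: independent
heavy-tailed (t₂) columns score ≈ 0.38, and only grossly non-Gaussian
latent structure (e.g. a two-cluster population) pushes the score near
0.2. The tests assert these honestly measured magnitudes.

**Outcome model.** Per trait, the consensus rating (across-rater median,
half-integer ties rounded toward the scale midpoint 4) is regressed on
the standardized causes and the substitute confounder with a truncated-
normal likelihood on [1, 7]:

    z ~ TruncNormal(β₀ + p'η + ĉ'γ, σ²; 1, 7).

An intercept is included (standardized causes with a 1–7 outcome require
one); its prior is N(4, 2²), coefficients N(0, 1), σ ~ HalfNormal(1). Two
baselines share the machinery: a vanilla Bayesian linear regression (no
truncation, no ĉ) and an associative truncated regression (no ĉ).
Coefficients are unit-increase effects on the standardized-cause scale;
the population-averaged outcome is the G-formula Monte-Carlo average of
the truncated-normal mean over subjects and posterior draws. Significance
is "zero outside the 95% HDI", with the HDI computed as the narrowest
window containing ⌈0.95·M⌉ sorted draws.

Because ĉ is an exact linear function of p, the causal design is rank
deficient; the N(0,1) priors resolve the degeneracy (a minimal-norm-like
split of the shared signal between η and γ). Two consequences are
documented rather than hidden: (i) the causal model's per-coefficient η
HDIs are conservative — its false-flag rate under null effects is near 0,
so the ≈ 5% HDI calibration is asserted on the full-rank associative
models (measured ≈ 4%); (ii) the causal and associative truncated models
are nearly prediction-equivalent in distribution, which is why predictive
differences on random splits are within noise (as the shift benchmark
asserts).

## Rater simulation, ICC, PLL

A simulated rater is one joint posterior draw (η_r, γ_r, σ_r) per trait;
its rating of a subject is round(TruncNormal(β₀ + p'η_r + ĉ'γ_r, σ_r²;
1, 7)). Agreement is quantified with the intraclass correlation from the
two-way random-effects ANOVA mean squares; the default reported variant
is single-measure absolute agreement (ICC(2,1)), with the average-measure
variant available. Identical raters give exactly 1; zero between-subject
variance returns 0 with a warning. The qualitative bands used throughout
are poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent.

Predictive quality on held-out subjects is the average predictive log
likelihood: per subject, the log truncated-normal density of the observed
rating averaged over posterior draws (expectation of the log), then
averaged over subjects. The continuous density at the integer rating is
the default (matching the fitted likelihood); the probability mass of the
rating's rounding interval is available as an option.

## Synthetic cohorts

The generator emulates the structure of a continuously annotated
dyadic-interaction corpus: 23 subjects, 6 raters, 5-minute trajectories at
40 ms steps, five traits. Heterogeneity is created in an unconstrained
natural parameter space θ = [U_A, U_V, log B_AA, log B_VV, atanh ρ_B,
log d_A, log d_V, atanh ρ_D]:

    θ_s = θ₀ + Λ' c_s + ε_s,   c_s ~ N(0, I_K),   ε_s ~ N(0, 0.3² I),

with exponential links for positive entries and tanh for correlations
(any smooth bijection would do; this one is fixed and documented). Draws
implying an Euler-unstable B are redrawn with a capped retry count. The
baseline θ₀ gives B diagonals ≈ 1.2–1.5 s⁻¹ and a stationary spread of
≈ 0.3 annotation units, i.e. trajectories that live inside the [−1, 1]
annotation box without clamping. Each rater sees the shared subject path
plus independent Gaussian noise (sd 0.05) — the minimal structure that
makes EWE fusion non-trivial; real rater idiosyncrasies (delays, biases,
nonlinear compression) are not modelled, so passing fusion tests says
nothing about annotator-delay effects in real data.

Rating means are `4 + p̃_s'η_i + c_s'γ_i` with p̃ the within-cohort
standardized descriptor (so generator coefficients live on the same scale
the outcome model estimates), and ratings are rounded truncated-normal
draws with sd 0.5. The default η pattern gives agreement a valence-home-
base effect and dominance/engagement arousal effects (engagement also an
arousal-diffusion effect), with performance and rapport null; γ couples
the confounder to the first four traits.

The "uncommon subpopulation" split samples test subjects with probability
proportional to the Gaussian likelihood ratio between a confounder
population displaced by a shift vector and the base population (an
exponential tilt). At shift 0 this is exactly a uniform split, which is
what makes the typical/uncommon contrast clean.

## Study sizes and design of the benchmark studies

* PPC calibration: 20 seeds × (S = 200, 20% held out, 100 replicates).
* OU recovery: 20 replicates of 7500 steps.
* Deconfounding bias and HDI calibration: 50 cohorts of S = 200 each.
* Shift benchmark: 50 replicates at S = 150, γ three times the default
  ("strong confounding"), rating sd 1.0, shift 3.5 per confounder
  dimension, test fraction 0.4. These conditions were chosen, before the
  benchmark was frozen, so that the causal model's advantage on shifted
  data — which is second-order (prior-geometry) in this model family —
  is resolvable above replicate noise; at weaker confounding the two
  models are statistically indistinguishable on both splits, consistent
  with the near-equivalence argument above.
* The end-to-end pipeline smoke test runs 6 subjects × 600 steps.

These sizes are the package's own trade-off between Monte-Carlo
resolution and the few minutes a full test run should take.

## Known limitations

* The Laplace approximation understates skewness of scale-parameter
  posteriors; at the trajectory lengths used this is negligible, but at
  very short trajectories (tens of points) the emcee route should be
  preferred.
* With ~20 training subjects and 11 outcome parameters the outcome-model
  fits become ill-conditioned and PLL values unstable; benchmark studies
  therefore use larger cohorts than the corpus the generator mimics.
* The default OU likelihood ignores R; descriptors inherit the
  corresponding small upward bias in B and D.
* The deconfounder's identification rests on untestable assumptions
  (no single-cause confounders, factor model capturing the cause
  distribution); the package checks the latter only through the — weak —
  predictive score.
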