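# affectdyn

Affect-dynamics modelling and multi-cause causal analysis of social-trait
ratings.

## The problem

In observational studies of social interaction, third-person raters
produce two kinds of annotation for each observed subject: a
time-continuous valence/arousal (V/A) trajectory (values in [−1, 1] on a
fixed sampling grid) and ordinal 7-point ratings of social-participation
traits (agreement, dominance, engagement, performance, rapport). These
labels are usually treated as ground truth, but they are the output of a
rating *process* that mixes the subject's behaviour with rater-side
factors — perceived personality, sympathy, cultural priors — that
influence both annotations at once. `affectdyn` builds a statistical
emulator of that process and asks the causal question directly: *how does
a subject's perceived affect dynamics change the social ratings they
receive, once shared unobserved causes are adjusted for?*

The pipeline has four stages:

1. **Fusion** — multiple raters' V/A trajectories are combined by the
   Evaluator Weighted Estimator (agreement-weighted average; weights from
   pairwise Pearson correlations, clipped at zero).
2. **Dynamics** — the consensus trajectory is modelled as an
   Ornstein–Uhlenbeck state-space process,
   `dS = B (U − S) dt + D^{1/2} dW`, `Y = S + R^{1/2} ε`:
   home base `U`, dampening force `B` (symmetric, positive eigenvalues)
   and diffusion `D`. Bayesian inference yields the 8-dim descriptor
   `p = [U_A, U_V, B_AA, B_AV, B_VV, D_AA, D_AV, D_VV]` per subject,
   validated generatively by cross-recurrence analysis (DET/LAM/MDL)
   against random-rater baselines.
3. **Deconfounding** — the descriptors of all subjects form a cause
   matrix; a PPCA factor model (`c ~ N(0, λ²I)`, `p|c ~ N(c'W, ν²I)`,
   K = 2) supplies a per-subject substitute confounder `ĉ = E[c|p]`,
   checked by a held-out posterior predictive score (≈ 0.5 when the
   factor model captures the cause distribution). The causal outcome
   model is a truncated Bayesian regression on [1, 7]:
   `z ~ TruncN(β₀ + p'η + ĉ'γ, σ²)`; `η` are unit-increase causal
   effects, significance is "0 outside the 95% HDI", and population
   averages come from the G-formula.
4. **Validation** — simulated raters drawn from the outcome posterior are
   compared with human raters via the intraclass correlation (two-way
   random effects), and causal vs associative models via held-out
   predictive log likelihood, including a covariate-shifted ("uncommon"
   subpopulation) stress test.

A synthetic-cohort generator with known ground truth (OU parameters,
latent confounder, causal coefficients) makes every stage testable
without access to restricted corpora.

## Worked example

Fit the OU model to one simulated 5-minute annotation trace (7500 steps
at 40 ms) and read off the dynamics descriptor:

```python
import numpy as np
from affectdyn import OUModel, OUParams, simulate

true = OUParams.from_natural(u=(0.4, -0.3), b_diag=(2.0, 1.5), rho_b=0.3,
                             d_scales=(0.55, 0.45), rho_d=0.2,
                             r_scales=(0.01, 0.01))
traj = simulate(true, n_steps=7500, dt=0.04, seed=1)
res = OUModel(traj).fit(draws=1000, seed=0)
print(res.summary().loc[["U_A", "U_V", "B_AA", "B_VV", "D_AA", "D_VV"]].round(3))
```

```
        mean     sd  hdi_lo  hdi_hi
param
U_A    0.391  0.017   0.357   0.422
U_V   -0.325  0.017  -0.358  -0.293
B_AA   2.010  0.112   1.798   2.241
B_VV   1.641  0.098   1.450   1.824
D_AA   0.302  0.005   0.291   0.311
D_VV   0.205  0.003   0.199   0.211
```

The posterior means sit on the generating values (home base (0.4, −0.3),
dampening diagonal (2.0, 1.5), diffusion diagonal (0.3, 0.2)): the rater's
perceived dynamics are identified from a single trace.

Then run the causal stage on a synthetic cohort of 100 subjects whose
ratings are confounded by a 2-dim latent factor:

```python
from affectdyn import (CauseMatrix, CohortSpec, PPCAModel, RatingOutcomeModel,
                       consensus_ratings, generate_cohort, ppc_score,
                       significance_table)

spec = CohortSpec(n_subjects=100, seed=7)
gt, _, ratings = generate_cohort(spec, with_trajectories=False)
P = CauseMatrix.from_raw(gt.descriptors, subject_ids=spec.subject_ids)
print("ppc score:", round(ppc_score(P, k=2, seed=0), 3))

chat = PPCAModel(P, k=2).fit(n_draws=500, seed=0).confounders()
cons = consensus_ratings(ratings).loc[spec.subject_ids]
models = {t: RatingOutcomeModel(cons[t].to_numpy(float), P,
                                confounders=chat).fit(draws=1000, seed=i)
          for i, t in enumerate(cons.columns)}
print(significance_table(models)[["trait", "coefficient", "mean",
                                  "hdi_lo", "hdi_hi"]].round(2).to_string(index=False))
```

```
ppc score: 0.517
     trait coefficient  mean  hdi_lo  hdi_hi
 agreement       eta_1  0.46    0.05    0.92
engagement       eta_0  0.56    0.05    1.05
```

The predictive score near 0.5 says the K = 2 factor model captures the
joint distribution of the causes. The significance table recovers the
two strongest generating effects — agreement caused by the valence home
base (`eta_1`, true 0.5) and engagement by the arousal home base
(`eta_0`, true 0.6) — with HDIs excluding zero; coefficients the
generator set to zero are not flagged.

The same analysis is available from the shell:

```bash
affectdyn simulate --n-subjects 23 --seed 1 --out-dir cohort/
affectdyn fuse --trajectories cohort/trajectories.csv --out cohort/fused.csv
affectdyn fit-ou --trajectories cohort/fused.csv --draws 1000 --seed 1 --out cohort/descriptors.json
affectdyn deconfound --descriptors cohort/descriptors.json --ratings cohort/ratings.csv --k 2 --seed 1 --out cohort/report.json
affectdyn validate --descriptors cohort/descriptors.json --ratings cohort/ratings.csv --seed 1 --out cohort/validation.json
# or everything at once from a YAML config:
affectdyn run-all --config config.yaml --out-dir run/
```

`docs/methods.md` documents the models, priors, numerical choices and the
design of the synthetic studies.

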