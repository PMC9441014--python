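# wbec — whole-brain effective connectivity, classification, and ignition

`wbec` is a Python library for analyzing parcellated resting-state brain
recordings acquired before and after an intervention (e.g. a neurofeedback
training session) in a two-group design. It answers three questions:

1. **How do regions drive each other?** Directed effective connectivity
   (EC) is estimated with a multivariate Ornstein–Uhlenbeck (MOU) model

       dx_i = ( -x_i/τ + Σ_{j≠i} C_ji x_j ) dt + dB_i

   whose stationary covariance Q0 obeys the Lyapunov equation
   `J Q0 + Q0 Jᵀ + Σ = 0` with `J = -I/τ + Cᵀ`. The coupling matrix `C`
   (restricted to a binary structural-connectivity mask) and the nodal
   noise variances `Σ` are tuned by iterative gradient descent until the
   model reproduces the empirical zero-lag (FC0) and one-TR-lag (FC1)
   covariances of the band-passed signal.

2. **Do the sessions/groups differ, and where?** Per-session EC/FC/SC
   feature vectors are classified with a linear SVM and a
   correlation-metric 1-nearest-neighbour rule over repeated random
   splits, against label-shuffled surrogates (Wilcoxon rank-sum
   comparison). SVM recursive feature elimination then extracts the
   *support network*: the smallest set of directed EC edges that carries
   the discrimination.

3. **Does the intervention change spatiotemporal dynamics?** The
   intrinsic-ignition analysis detects per-region events (+1 SD crossings),
   binarizes the pairwise phase-lock matrix
   `P_jk = exp(-3 |φ_j − φ_k|)` in a 4-TR window after each event, and
   measures the largest connected component: its mean over events is the
   intrinsic-driven mean integration (IDMI), its standard deviation the
   metastability.

Because suitable cohorts are rarely shareable, the package ships a
first-class synthetic-data module (`wbec.synthetic`) that generates
two-group, two-session cohorts from ground-truth MOU models — sparse
skeletons, a shared connectome backbone with per-subject jitter, and a
small set of planted coupling changes in the trained group — so every
stage of the chain is testable end to end.

## Worked example

```python
import numpy as np
from wbec import (CohortSpec, FitOptions, generate_cohort,
                  covariance_pair, estimate_tau, fit_mou)

spec = CohortSpec(n_group_a=4, n_group_b=0, n_regions=10, n_volumes=500,
                  perturbation_scale=1.0, seed=1)
dataset, truth = generate_cohort(spec)

ts = dataset[0]                       # subject nfb01, pre session
emp = covariance_pair(ts, lag_trs=1)  # FC0 and FC1
tau = estimate_tau(ts)
model, report = fit_mou(emp, truth.mask, tau_init=tau,
                        opts=FitOptions(max_iterations=3000, patience=100))

on = truth.mask.mask
true_ec = truth.true_models[(ts.subject_id, ts.session_label)].ec
print(f"tau = {tau:.2f} s")
print(f"fit r = {report.best_pearson_r:.3f} after {report.iterations} iterations")
print(f"EC recovery r = {np.corrcoef(true_ec[on], model.ec[on])[0, 1]:.3f}")
```

prints

```
tau = 3.56 s
fit r = 0.972 after 479 iterations
EC recovery r = 0.653
```

`tau` is the decay constant estimated from the autocovariance slope — the
generator's nodal constant is 2 s, but network coupling slows the observed
decay, so the estimate sits above it. The fit `r` is the Pearson
correlation between the model's and the empirical FC0/FC1 entries (how
well the MOU reproduces the data); the recovery `r` correlates the fitted
coupling weights with the generator's ground truth — 0.65 from a single
500-volume session is what EC estimation noise allows at this sample
size (fitting model-exact covariances instead recovers the truth with
r ≈ 1.0; see the acceptance script).

The `examples/` directory has one short script per capability (cohort
simulation, EC fitting, classification with surrogates, support-network
extraction, ignition analysis, and the full pipeline); each prints the
numbers it computes and a line on what they mean. A thin CLI mirrors the
pipeline: `wbec run --out results --seed 1`, plus `simulate`, `fit-ec`,
`classify`, `rfe`, and `ignition` subcommands.

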