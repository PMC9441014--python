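"""Fit a MOU effective-connectivity model to one simulated session.

The fit tunes directed couplings (on the structural mask) and nodal noise
variances until the model's stationary zero-lag and one-lag covariances
reproduce the empirical FC0/FC1 — then we check the estimate against the
generator's ground truth.
"""

import numpy as np

from wbec import (CohortSpec, FitOptions, covariance_pair, estimate_tau,
                  fit_mou, generate_cohort)

spec = CohortSpec(n_group_a=4, n_group_b=0, n_regions=10, n_volumes=500,
                  perturbation_scale=1.0, seed=1)
dataset, truth = generate_cohort(spec)

ts = dataset[0]
emp = covariance_pair(ts, lag_trs=1)
tau = estimate_tau(ts)
model, report = fit_mou(emp, truth.mask, tau_init=tau,
                        opts=FitOptions(max_iterations=3000, patience=100))

on = truth.mask.mask
true_ec = truth.true_models[(ts.subject_id, ts.session_label)].ec
print(f"estimated tau   : {tau:.2f} s (nodal truth 2 s; coupling slows "
      "the observed decay)")
print(f"fit quality r   : {report.best_pearson_r:.3f} over "
      f"{report.iterations} iterations (model vs empirical covariances)")
print(f"EC recovery r   : {np.corrcoef(true_ec[on], model.ec[on])[0, 1]:.3f} "
      "(fitted vs ground-truth couplings; limited by one session's "
      "sampling noise)")
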