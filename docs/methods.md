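# Methods

## The model

`wbec` treats the parcellated resting-state signal `x(t)` of `n` brain
regions as a multivariate Ornstein–Uhlenbeck (MOU) process

    dx_i = ( -x_i / tau  +  sum_{j != i} C_ji x_j ) dt + dB_i

where `tau` is a common nodal decay time constant (seconds), `C` the
directed effective-connectivity (EC) matrix (`C_ji` = influence of region
`j` on region `i`, stored as `ec[source, target]`), and `dB` white noise
with diagonal covariance `Sigma`. Writing the Jacobian
`J = -I/tau + C^T`, the stationary zero-lag covariance `Q0` solves the
continuous Lyapunov equation `J Q0 + Q0 J^T + Sigma = 0` and the lagged
covariance is `Q(l) = Q0 expm(J^T l)`.

The model is fitted to the empirical covariances FC0 (zero lag) and FC1
(one TR lag) of the band-passed signal. Starting from `C = 0` and
`Sigma = 2 diag(FC0)/tau`, each iteration solves the Lyapunov equation for
the current iterate, forms the mismatches `dQ0 = FC0 - Q0` and
`dQ1 = FC1 - Q1`, and applies

    dC      = rate_ec    * Q0^{-1} (dQ0 + dQ1 expm(-J^T l))   restricted to the SC mask, clipped at 0
    dSigma  = rate_sigma * diag( -J^T dQ0 - dQ0 J )           floored at 1e-6

The anatomical skeleton enters only as a binary mask: EC is constrained to
zero off-mask and on the diagonal. `tau` is estimated once per session
from the slope of log autocovariance over lags 1..2 and held fixed. The
best-error iterate is retained; optimization stops when the normalized
error (summed squared covariance mismatch over summed squared empirical
entries) fails to improve for a patience window. A step that overshoots
into the unstable region triggers a backtrack: the best iterate is
restored and the EC rate halved (at most 8 times).

Tunable optimizer parameters (defaults in `FitOptions`): `rate_ec = 5e-4`,
`rate_sigma = 0.05`, `max_iterations = 10000`, `patience = 50`,
`min_improvement = 1e-6` (relative). The rates are on the scale of
unit-variance covariances; they were chosen so that ground-truth coupling
matrices are recovered exactly from model-exact covariances (entrywise
correlation 1.0 for 10-region skeletons), and they are deliberately small —
the fit is gradient descent on a smooth landscape, and robustness across
problem sizes matters more than step count.

A caveat on filtering: the pipeline band-passes the signal (0.01–0.07 Hz)
before computing FC0/FC1, because narrow-band covariances are the standard
input for resting-state modeling. Filtering, however, introduces temporal
autocorrelation of its own, which the MOU fit partly misattributes to
coupling and to a longer `tau`: on synthetic (unfiltered OU) sessions,
fitting the raw covariances recovers the ground-truth coupling markedly
better than fitting filtered ones (entrywise r ≈ 0.65 versus ≈ 0.2 for a
10-region, 500-volume session). The ground-truth recovery benchmark
therefore fits raw covariances, while the cohort pipeline keeps the
filter — the distortion is common to all sessions and does not prevent
between-session discrimination.

## Classification and support-network extraction

Per session, connectivity is vectorized (lower triangle for symmetric
FC/SC, masked directed entries for EC) and z-scored within the session.
Two classifiers are evaluated over repeated random 80/20 splits: a linear
SVM (`C = 1`) and a 1-nearest-neighbour rule under distance `1 - r`
(Pearson), ties broken by the lowest training index. Chance level comes
from label-shuffled surrogates (fresh permutation per split); accuracy
distributions are compared with the two-sided Wilcoxon rank-sum test.

Splits are session-level by default. A subject-level split mode
(`split_unit="subject"`) keeps both sessions of a subject on the same side
of the split. This matters: with paired pre/post designs, session-level
splits let the classifier see the held-out subject's other session during
training, which biases accuracy even when the labels carry no information.
The package's own acceptance checks use subject-level splits for exactly
this reason.

SVM-RFE ranks EC features by repeatedly fitting the linear SVM and
discarding the features with the smallest absolute hyperplane weights — 5%
of the remainder per round while more than 200 features survive, then one
per round — yielding a strict rank permutation (ties within a discarded
batch are ordered by |weight|). Over `n_repetitions = 10` random splits,
held-out accuracy is traced over rank-ordered feature prefixes (every size
up to 200, geometric steps above); the support network is the smallest
prefix whose mean accuracy across repetitions is maximal (no larger
evaluated prefix exceeds it by more than 1e-6), with edges resolved
through the consensus (mean) ranking. Known limitation: when single
features saturate the classifier the rule legitimately selects very small
subsets, and when the effect is weak the accuracy trace is flat and the
rule selects very large ones — subset recall of planted effects is
therefore not monotone in effect size, although the ranking itself is.

## Intrinsic ignition

Signals are band-passed to 0.04–0.07 Hz, demeaned, and Hilbert-transformed
to instantaneous phases. Events are rising crossings of +1 SD of the
per-region standardized signal (one event per excursion). For each event,
over a window of 4 TRs starting at the event sample, the pairwise
phase-lock matrix `P_jk = exp(-3 |phi_j - phi_k|)` (circular distance
wrapped to [0, pi]) is binarized at `P >= 0.5` and the largest connected
component of the resulting graph measured, normalized by the number of
analyzed nodes. Per region, the mean over its events is the
intrinsic-driven mean integration (IDMI) and the standard deviation the
metastability. Regions with no events are flagged NaN; metastability needs
at least two events. Session/group comparisons aggregate each profile to
its nan-mean over the node subset and use the Wilcoxon signed-rank
(paired) or rank-sum (unpaired) test.

Two thresholds appear in this analysis and they are deliberately separate
parameters: the event threshold is a z-score of the signal (+1 SD), while
the binarization threshold applies to phase-lock values in (0, 1] — a
z-score is not well defined for the latter, so it defaults to 0.5 and is
exposed in the configuration.

## The synthetic cohort generator

No resting-state cohort is bundled; the generator emulates the statistical
structure the analysis assumes, with known ground truth.

* **Skeleton** — a symmetric binary mask retaining `round(0.30 * n(n-1)/2)`
  random undirected pairs (30% density).
* **Couplings** — a cohort-level template with weights uniform(0, 1) drawn
  independently per direction (reciprocal connections are genuinely
  asymmetric), jittered per subject by a multiplicative uniform(0.7, 1.3)
  factor — subjects share a connectome backbone, as real cohorts do — and
  rescaled per subject so the Jacobian's spectral abscissa is `-0.25/tau`.
  That margin is an identifiability trade-off: near-critical dynamics mix
  too slowly for a session's worth of samples to constrain the fit, while
  weak coupling leaves the directional covariance signal below sampling
  noise.
* **Noise** — per-region variances uniform(0.8, 1.2); `tau = 2 s`.
* **Design** — 17 trained + 16 sham subjects, two sessions of 235 volumes
  at TR = 2 s. In the trained group's post session, five directed edges
  drawn from the top 40% of template weights (training modulates
  established pathways; multiplying a near-zero weight is a no-op) are
  scaled by `1 + perturbation_scale`. The sham group's sessions come from
  identical models with independent noise.
* **Effect size** — `perturbation_scale = 5` by default. The calibration
  criterion is that each planted EC feature should be partially but not
  perfectly informative after estimation noise (standardized class shift
  around 1.3–1.5): much smaller and the sessions are indistinguishable,
  much larger and a single feature saturates the classifier, truncating
  the support network.
* **Simulation** — Euler–Maruyama at `dt = TR/100` (stationary-variance
  bias ~1%, lag-1 autocorrelation bias ~2%), with a 20-tau burn-in
  discarded; identical seeds give bit-identical series, and every
  subject-session has an independently spawned stream.
* **Phase fixtures** — for the ignition stage, narrow-band signals with a
  controllable shared-phase component: region `i` carries
  `c*S + sqrt(1-c^2)*n_i` scaled by a random amplitude, so pairwise phase
  locking grows monotonically with the coupling `c`.

What the generator does **not** emulate: hemodynamic convolution (the MOU
output is treated directly as the parcellated signal, which matches the
model being fitted but not BOLD physiology), scanner noise and motion
artefacts, spatial autocorrelation of parcels, non-stationarity within a
session, and any relationship between the planted EC change and ignition
dynamics. Passing tests therefore demonstrate that the chain of methods
recovers what it assumes, at realistic sample sizes — not that the
assumptions hold for real fMRI.

## Problem sizes and numerical choices

* Cohort-level analyses (classification, RFE, the pipeline driver's
  defaults in the acceptance script) run on a 40-region parcellation with
  the full 17+16-subject design. At 116 regions with 235 volumes the
  per-session covariance estimates are so noisy that EC estimates are
  dominated by sampling error (entrywise recovery correlation ~0.02), and
  no stable planted effect survives; 40 regions keeps all design
  quantities while the whole chain runs in minutes. The default
  `CohortSpec`/`PipelineConfig` keep `n_regions = 116` for users emulating
  the full-size design.
* The coupling-recovery benchmark uses 10-region skeletons, exact
  covariances and 500-sample simulations.
* Lyapunov equations are solved with `scipy.linalg.solve_continuous_lyapunov`
  (residual checked against 1e-8); matrix exponentials with
  `scipy.linalg.expm`; a singular model `Q0` falls back to a pseudo-inverse
  and is flagged in the fit report.
* Band-pass filters are 2nd-order Butterworth run forward and backward
  (zero phase). Filtering is idempotent for passband-centred content
  (re-filtering changes a mid-band sinusoid by <1% RMS) but keeps
  attenuating band-edge energy of broadband input, which is inherent to
  low-order filters.
* SC-mask thresholds break ties by the lexicographically smallest
  (row, column) pair, so masks are deterministic; the achieved density is
  exact to one pair.
* All randomness flows from explicit integer seeds; pipeline stage seeds
  are SHA-256 hashes of (global seed, stage name), and the JSON report is
  byte-identical across runs with the same config and seed.
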