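"""Extract the support network — the minimal discriminative EC edge set —
with SVM recursive feature elimination, and compare it to the planted
ground truth.
"""

from wbec import (CohortSpec, FitOptions, annotate_support, bandpass,
                  build_features, covariance_pair, estimate_tau, fit_mou,
                  generate_cohort, make_parcellation,
                  select_support_network)

spec = CohortSpec(n_group_a=12, n_group_b=0, n_regions=25, n_volumes=235,
                  seed=5)
dataset, truth = generate_cohort(spec)

models, labels, subjects = [], [], []
for ts in dataset:
    filtered = bandpass(ts, 0.01, 0.07)
    emp = covariance_pair(filtered, lag_trs=1)
    model, _ = fit_mou(emp, truth.mask, tau_init=estimate_tau(filtered),
                       opts=FitOptions(max_iterations=1500, patience=80))
    models.append(model)
    labels.append(ts.session_label)
    subjects.append(ts.subject_id)

fs = build_features(models, "ec", mask=truth.mask, labels=labels,
                    subject_ids=subjects)
net = select_support_network(fs, n_repetitions=10, test_fraction=0.2, seed=7)
table = annotate_support(net, make_parcellation(spec.n_regions))

planted = set(map(tuple, truth.perturbed_edges))
found = {(s, t) for (s, t, _) in net.edges}
print(f"selected support network: {len(net.edges)} edges over "
      f"{len(net.node_set)} regions (held-out accuracy "
      f"{net.selected_accuracy:.1%})")
print(f"planted-edge recall {len(planted & found) / len(planted):.0%}, "
      f"precision {len(planted & found) / max(len(found), 1):.0%}")
print(table.to_string(index=False))
# Each row is one directed edge (source -> target = direction of
# influence) with region names and functional networks; low ranks carried
# the most discriminative weight.
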