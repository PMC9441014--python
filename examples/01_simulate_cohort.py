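"""Generate a synthetic two-group resting-state cohort and write it to disk.

The generator emulates a pre/post intervention design: every subject is a
stable MOU model on a shared structural skeleton, and in the trained
group's post session a handful of directed couplings are strengthened.
"""

from wbec import CohortSpec, generate_cohort, make_parcellation
from wbec.io import write_cohort

spec = CohortSpec(n_group_a=4, n_group_b=4, n_regions=20, n_volumes=120,
                  perturbation_scale=2.0, seed=42)
dataset, truth = generate_cohort(spec)

print(f"sessions generated : {len(dataset)} "
      f"({spec.n_group_a}+{spec.n_group_b} subjects x 2 sessions)")
print(f"series shape       : {dataset[0].values.shape} (volumes x regions)")
print(f"mask density       : {truth.mask.density:.3f}")
print(f"planted edges      : {truth.perturbed_edges}")

write_cohort(dataset, truth, "example_cohort",
             parcellation=make_parcellation(spec.n_regions))
print("cohort written to example_cohort/<group>/<subject>/<session>.csv "
      "with a ground-truth manifest")
# The planted edges are the directed couplings that differ between the
# trained group's sessions; downstream stages try to rediscover them.
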