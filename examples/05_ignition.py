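"""Intrinsic-ignition analysis: how broadly does a local event integrate
the network, and how variable is that integration?

Two phase-coupled signal sets are compared: strongly coupled regions
should show high integration (IDMI), weakly coupled ones low integration;
metastability measures switching between integration states.
"""

from wbec import ignition_profile, simulate_phase_signals

for coupling in (0.9, 0.3):
    ts = simulate_phase_signals(n_regions=12, coupling=coupling,
                                n_volumes=400, tr_seconds=2.0, seed=8)
    prof = ignition_profile(ts, window_trs=4)
    print(f"coupling {coupling:.1f}: "
          f"mean IDMI = {prof.mean_idmi():.3f}, "
          f"mean metastability = {prof.mean_metastability():.3f}, "
          f"events/region = {prof.n_events.mean():.1f}")
# IDMI near 1 means events recruit almost the whole network into one
# phase-locked component within 4 TRs; lower coupling fragments the
# component and raises the variability of event-wise integration.
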