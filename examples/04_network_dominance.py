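"""Which networks drive a complex's mapped response profile?

Decomposes the body complex's activity-flow map into its 12 per-network
components (which sum exactly to the full map) and ranks the networks
by dominance analysis of the actual 24-condition response profile.
"""

import numpy as np

import activityflow as af

cfg = af.SimulationConfig(seed=3, n_participants=1, local_fraction=0.25)
model = af.generate_ground_truth(cfg)
ds = af.simulate_task(model, cfg, include_bold=False)
act = ds.truth_activations[0]

cx = model.complexes["EBA_FBA"]
comps = af.network_restricted_maps(act, model.weights, model.partition,
                                   targets=cx["units"])
full = af.map_activity(act, model.weights, targets=cx["units"]).mapped
print("max |sum of 12 network components - full map| ="
      f" {np.abs(sum(comps.values()) - full).max():.2e}")

profiles = {lab: c.mean(axis=0) for lab, c in comps.items()
            if np.ptp(c.mean(axis=0)) > 0}
actual_profile = act[cx["units"]].mean(axis=0)
res = af.dominance(profiles, actual_profile)

print(f"\nfull model R2 = {res.full_r2:.4f}  "
      f"({res.n_candidate_models} candidate models enumerated)")
print(f"{'network':<8} {'partial R2':>11} {'importance':>11}")
for lab in sorted(res.partial_r2, key=res.partial_r2.get, reverse=True)[:5]:
    print(f"{lab:<8} {res.partial_r2[lab]:>11.3f} "
          f"{res.relative_importance_pct[lab]:>10.1f}%")
print(f"sum of partial R2 = {sum(res.partial_r2.values()):.3f} "
      "(equals the full R2 by construction)")
print()
print("The decomposition is exact (components sum to the full map), and")
print("dominance analysis splits the explained variance into per-network")
print("partial R2 values that sum to the full-model R2; networks hosting")
print("the complex's preferred sources rank highest.")
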