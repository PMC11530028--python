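"""Activity-flow mapping recovers held-out activations on synthetic truth.

Builds a ground-truth network, simulates rest and task data, maps each
target complex's activations as connectivity-weighted sums of source
activations — once with the true weights and once with combinedFC
estimated from rest — and scores the mappings.
"""

import numpy as np

import activityflow as af

cfg = af.SimulationConfig(seed=1, n_participants=1, local_fraction=0.0,
                          n_timepoints_rest=5000, n_runs_rest=2)
model = af.generate_ground_truth(cfg)
ds = af.simulate_task(model, cfg, include_bold=False)
rest = af.simulate_rest(model, cfg)[0]

targets = model.target_units
act = ds.truth_activations[0]

mapped_true = af.map_activity(act, model.weights, targets=targets).mapped
rep_true = af.accuracy(act[targets], mapped_true)

fc = af.combinedfc(rest)
mapped_est = af.map_activity(act, fc, targets=targets).mapped
rep_est = af.accuracy(act[targets], mapped_est)

print(f"targets mapped: {len(targets)} complex units x "
      f"{cfg.n_conditions} conditions")
print(f"true weights:      r={rep_true.pearson_r:.4f}  "
      f"MAE={rep_true.mae:.2e}  R2={rep_true.r_squared:.4f}")
print(f"combinedFC (rest): r={rep_est.pearson_r:.4f}  "
      f"MAE={rep_est.mae:.4f}  R2={rep_est.r_squared:.4f}")
print()
print("With a purely distributed generative truth (local_fraction=0) the")
print("true-weight mapping is exact to machine precision; connectivity")
print("estimated from 10,000 rest timepoints reproduces it to r > 0.99.")
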