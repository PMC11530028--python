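# activityflow

Generative activity-flow modeling of localized category selectivity in
visual cortex, with a fully synthetic ground truth.

## The problem

Regions such as the fusiform face area respond far more strongly to
their preferred visual category (faces, bodies, places, tools) than to
others. Is that localized selectivity computed within the region, or
generated by task-evoked activity *flowing in* over the region's
distributed connectivity fingerprint? This package implements the
activity-flow answer to that question as a reusable, tested pipeline for
researchers in network neuroscience: estimate intrinsic (resting-state)
connectivity, map held-out task activations as connectivity-weighted
sums of source activations, and quantify how much of the observed
selectivity the distributed model reproduces.

The central generative model maps the activity of a held-out target
region *j* from all source regions *i*:

    mapped_j = Σ_{i≠j} act_i · w_ij            (activity-flow mapping)

where `w_ij` are resting-state connectivity weights. Around this core
the package provides:

- **`synth`** — a ground-truth world: 12-network weight matrices with
  category-selective "functional complexes" and a V1 source set;
  stationary rest series from a contemporaneous linear SEM
  (`x = (I−W)⁻¹ e`); block-design task BOLD whose target activations are
  a *known* mixture `(1−λ)·flow + λ·local`, so the distributed share is
  recoverable by construction.
- **`glm`** — canonical double-gamma HRF, convolved block designs, OLS
  betas, and the standard 64-column nuisance set (24 motion + 40
  aCompCor).
- **`connectivity`** — three-stage combinedFC (partial-correlation
  skeleton → bivariate collider pruning → per-target regression
  scaling) and a lasso variant with leave-one-run-out cross-validation
  for vertex-scale data, both honoring source-exclusion masks.
- **`actflow`** — the mapping itself in four variants: fully
  distributed, V1-initialized (stimulus-driven, with cross-V1 mean
  centering), multi-step propagation to a settling threshold, and the
  two-step stimulus-driven + fully distributed model; accuracy scored by
  Pearson r, MAE and R².
- **`selectivity`** — min-max normalization, category-selectivity ratios
  (1.0 = no selectivity), percent distributed contribution
  (`100·mapped/actual`), MAD outlier removal, benchmark contrasts.
- **`network`** — exact per-network decomposition of a mapping and
  dominance analysis (partial R² over all 4095 candidate models for 12
  networks).
- **`nulls`** — connectivity-fingerprint substitution nulls,
  degree/strength-preserving rewired architectures, and max-T
  permutation inference for family-wise error control.
- **`pipeline`** — end-to-end orchestration with an independent
  discovery/replication split, plus a thin CLI
  (`activityflow simulate|run`).

## Worked example

`examples/03_selectivity_contribution.py` simulates 30 participants
whose target complexes generate 25% of their activation locally, fits
the GLM, maps activity over the ground-truth connectivity, and
estimates each complex's selectivity and distributed contribution:

```
complex    actual sel mapped sel  contribution
EBA_FBA         1.916      1.467         76.6%
FFA_pSTS        2.056      1.578         76.8%
PPA_RSC         1.840      1.394         75.7%
LOC             2.834      2.127         75.1%
```

Actual selectivity ~1.9 means category responses are ~1.9× non-category
responses after normalization. The mapped (connectivity-only) model
reproduces ~76% of that selectivity — recovering the true distributed
share of 75% built into the simulation. The other examples demonstrate
exact generative recovery (`01`), collider-aware connectivity
estimation (`02`), network dominance (`04`), and null-fingerprint
inference with max-T correction (`05`).

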