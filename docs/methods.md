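# Methods

## The generative model

Activity-flow mapping treats a held-out target unit's task-evoked
activation as the sum of all other units' activations weighted by their
intrinsic connectivity with the target:

    mapped_j(c) = Σ_{i≠j} act_i(c) · w_ij

per condition c. The model is deliberately linear: it asks how much of
a localized response pattern distributed network interactions alone can
generate, with everything unexplained attributed to within-region
processing or estimation error. The target is always excluded from its
own source set (circularity guard), and at vertex scale a spatial
exclusion mask additionally removes sources near the target so that
spatial autocorrelation cannot masquerade as distributed flow.

Four network-interaction variants are implemented. *Fully distributed*
uses all other units as sources. *V1-initialized* restricts sources to
the V1 set, after subtracting the cross-V1 mean of the mapped condition
from each V1 source — removing any uniform component that could carry
fed-back category information. *Multi-step propagation* re-maps the
subsystem repeatedly with the stimulus-driven input re-injected at each
step, `x_{k+1} = W x_k + x_0`, stopping when the maximum absolute
change falls below the settling tolerance; for subsystem spectral
radius < 1 the settled state equals the closed form `(I−W)⁻¹ x_0`, and
a pure-relaxation mode (`inject=False`) is available for the decaying
recurrence `x_{k+1} = W x_k`. *Two-step* runs the V1-initialized map at
vertex level, averages vertices into regions (unweighted mean), and
applies one fully distributed region-level step.

## Synthetic ground truth

The generator builds the world the pipeline is validated against.

**Network structure.** `n_units` (default 48) are partitioned into 12
equal networks. Four complexes — body, face, place and tool analogues,
each `complex_size` units (default 2) — are carved out of host networks
(secondary visual, language, default-mode, dorsal-attention analogues);
a V1 source set occupies the primary visual network. Each category also
gets a disjoint set of preferred source units. Source-to-source weights
are block structured (within-network |N(0.3, 0.08)|, sparser/weaker
between networks); each complex row weights its own category's sources
at 1.0 per-unit, other categories' at 0.3, and V1 through a
category-specific pattern — its connectivity fingerprint. Fingerprint
distinctiveness (pairwise cosine < 0.9) is enforced by rejection
sampling, and the whole matrix is rescaled to spectral radius 0.6
(high global coupling, zero self-coupling, stationary).

**Complexes are sinks.** Target columns are zeroed: complexes receive
flow but send none. This makes the multiple-regression row of a target
equal its true weight row in population under the rest model (the
regression coefficients of a unit with no outgoing edges coincide with
its incoming weights), so connectivity estimation is exactly testable,
and it removes target→source feedback from the task model.

**Rest.** A contemporaneous linear SEM rather than a lagged VAR: each
time point solves `x = W x + e`, i.e. `x = (I−W)⁻¹ e` with i.i.d.
Gaussian innovations (`noise_sd`, default 0.2; FC estimates are
invariant to its scale). Runs are concatenated per participant. The
analytic covariance `(I−W)⁻¹(I−W)⁻ᵀ σ²` is the oracle the simulator is
tested against.

**Task.** 24 conditions, of which 8 encode the four categories as
0-back/2-back pairs. Category conditions drive V1 (with the category's
pattern) and that category's preferred sources; the 16 generic
conditions weakly drive only non-preferred sources, which anchors the
normalization minimum near zero at the complexes. Source activations
solve the source subsystem `x_S = W_SS x_S + D_S`. Each target unit's
true amplitude is the mixture

    truth = (1−λ)·flow + λ·local,    flow = Σ_i x_i · w_ij

with λ = `local_fraction`. The local component is a category-tuned
template whose amplitude equals the target's flow-driven category mean
and whose non-category response is zero. That calibration is the
generator's definition of a within-region process: because the min-max
reference is anchored near zero, it makes the group-mean percent
contribution identify `100·(1−λ)` exactly in the noiseless limit — the
property the recovery tests exercise. The mixture identity holds at
target units; source units are self-consistent SEM solutions for which
a λ-mixture is not defined. BOLD is the block design (two
counterbalanced passes, 10-timepoint blocks, 5-point gaps) convolved
with the canonical HRF, scaled by the true amplitudes, plus Gaussian
noise. Participants differ in drive gains (`act_noise_sd`), local
components, and noise; everything is determined by `seed`.

**What the generator does not emulate:** hemodynamic nonlinearity,
physiological noise and motion structure, lagged dynamics, surface
geometry (a 2-D grid with a configurable exclusion radius stands in for
cortical distance), individual differences in topography, and the
empirical network taxonomy behind the 12 labels. Passing tests
therefore certify the estimators and the algebra of the method under a
linear, stationary world — not the validity of those assumptions in
real fMRI data.

## Connectivity estimation

**combinedFC** (region scale, more timepoints than units): (1) partial
correlations from the inverse covariance, kept when significant by a
two-sided Fisher-z test at `alpha_partial` (df corrected for the n−2
conditioned variables); (2) kept edges whose bivariate Pearson
correlation fails to reject r = 0 at `alpha_zero` are removed as
collider-induced; (3) each target is regressed on its surviving
sources, and those betas scale the edges. Both alphas default to 0.01
and are exposed; the significance conventions are this package's
defaults, declared rather than inferred. Stage 3 can only remove or
rescale edges, never add them.

**Regularized variant** (vertex scale): per target, lasso over 100
log-spaced penalties spanning four orders of magnitude down from the
smallest all-zero penalty, chosen by leave-one-run-out cross-validation.
The default selection takes the sparsest penalty within one standard
error of the CV minimum; the plain CV minimizer systematically
over-selects (support-recovery F1 ≈ 0.59 vs ≈ 0.93 on the 5-of-200
benchmark) and is available as `penalty_rule="min"`.

## Selectivity and contribution

Activations are min-max normalized to [a, b] = [0, 1] using reference
extrema from the *actual* activations across all 24 conditions, applied
identically to actual and mapped data (a mapped-referenced variant
exists as a flag). Category selectivity is the ratio of mean normalized
category to non-category responses, the non-category set being the
other three categories' n-back conditions only; 1.0 is the null value.
The 0-back/2-back pair is averaged before selectivity. Aggregation over
a complex is either ratio-of-averaged-responses (region-level fully
distributed model) or per-unit-then-average (vertex-level stimulus-
driven models). The distributed contribution is `100·mapped/actual` per
participant, averaged across participants after flagging scores more
than 5 scaled MADs from the median (MAD × 1.4826; a zero MAD flags
nothing and warns). Per-participant ratios are averaged (random
effects) rather than taking a ratio of group means.

## Network decomposition and dominance

Because the mapping is linear in its sources, restricting the sum to
one network at a time yields 12 components that sum *exactly* to the
full map — the decomposition is an identity, not an approximation.
Dominance analysis regresses the actual 24-condition response profile
on the 12 network components, enumerating all 2¹² − 1 = 4095 non-empty
predictor subsets; each predictor's incremental R² is averaged within
each subset size and then across sizes (general dominance), giving
partial R² values that sum to the full-model R² and relative
importances that sum to 100%. Subset R² values are computed from the
correlation matrix (one small solve per subset), and constant
components are rejected explicitly.

## Null models and inference

**Fingerprint substitution:** a target complex's FC rows are replaced
by a donor complex's rows; the target self-block is zeroed, and the
donor-column entries (zero in the donor's own rows) are filled with the
transposed original target→donor estimates. Requires equal-sized,
disjoint complexes; donor = target degenerates to zeroing the
self-block.

**Permuted architectures:** double-edge swaps on the directed
nonzero-edge set preserve every unit's binary in/out degree; edge
weights are then reassigned as a random permutation of the original
nonzero weight multiset, preserving total strength. Exact preservation
of per-unit weighted strength sequences jointly with degree is not
generally possible; this degree + weight-multiset reading is the
implemented interpretation. Swaps that would create self-loops,
duplicate or masked edges are rejected; graphs too dense to rewire
raise.

**Max-T:** per permutation all t statistics are recomputed and the
family maximum recorded; corrected p = (1 + #{max-T ≥ t}) / (1 +
n_perm), one-tailed. Paired contrasts permute by condition-label
exchange (sign-flipping the paired differences); one-sample tests
against non-zero null means (selectivity vs 1.0, contribution vs 50%)
sign-flip the deviations from the null mean, since label shuffling is
undefined there. Default permutation counts are 100,000 for selectivity
tests and 10,000 for network comparisons, both configurable; the test
suite and acceptance script use 1,000 at their smaller problem sizes.

## Pipeline

`run_pipeline` simulates a cohort, splits it into discovery and
replication halves analyzed identically but independently, and runs
GLM → FC → mapping → selectivity → dominance → nulls → max-T, writing
TSV/JSON results, a config-hashed report and a text summary comparing
the halves. Reports are byte-identical under a fixed config and seed.

## Numerical choices and problem sizes

- Settling tolerance 0.5e-4: half-ULP of rounding to four decimals.
- Divergence guard at 1e12 with the spectral radius reported.
- Flat (zero-range) activation vectors normalize to the constant lower
  bound with a warning instead of propagating NaN.
- Rank-deficient GLM designs raise, naming the collinear columns.
- Default problem sizes are desk scale, chosen so the full suite and
  the acceptance script each run in well under a minute: 48 units, 24
  conditions, 2×500 rest timepoints, and cohorts of 3–50 participants
  depending on the check (10,000 rest timepoints where estimation
  consistency is the point; 50 participants for group-level recovery
  and null-direction checks; 200 Monte-Carlo replicates × 1,000
  permutations for the family-wise error calibration).

## Known limitations

- The contribution estimate is exactly calibrated only under the
  generator's matched-amplitude local template; other local processes
  would make `100·mapped/actual` a lower bound, as in empirical use.
- combinedFC inherits the faithfulness assumptions of constraint-based
  estimation; weak edges below the significance thresholds vanish,
  which biases mapped non-category responses (and hence selectivity
  ratios) upward when connectivity is estimated from short rest runs.
- Dominance with 12 predictors on 24-condition profiles is nearly
  saturated; full-model R² near 1 is expected on noiseless synthetic
  profiles.
- The permuted-architecture null preserves binary degree and the weight
  multiset but not per-unit weighted strength exactly.
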