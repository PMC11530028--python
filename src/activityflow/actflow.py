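"""Activity-flow mapping: held-out activations as connectivity-weighted sums.

The generative model maps the task-evoked activity of a held-out target
unit j as

    mapped_j = sum_{i != j} actual_i * w_{ji}

over source units i, for each condition. Four network-interaction
variants are provided: fully distributed (all other units as sources),
V1-initialized (stimulus-driven sources only, with cross-V1 mean
centering), multi-step propagation through a restricted subsystem until
a settling threshold, and the two-step stimulus-driven + fully
distributed mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
from sklearn.metrics import r2_score

from .config import DivergenceError
from .connectivity import FCMatrix

ArrayLike = Union[np.ndarray, "FCMatrix"]


def _weights(fc: ArrayLike) -> np.ndarray:
    return fc.weights if isinstance(fc, FCMatrix) else np.asarray(fc, float)


@dataclass
class ActivityFlowsMap:
    """Flow products and their sum (the mapped activations).

    ``flows[t, i, c] = actual[i, c] * w[target_t, i]`` for each target t,
    source i and condition c; ``mapped`` is the sum over sources, and
    ``targets`` gives the unit index of each mapped row.
    """

    targets: np.ndarray
    flows: np.ndarray  # n_targets x n_units x n_conditions
    mapped: np.ndarray  # n_targets x n_conditions
    source_mask: np.ndarray  # n_targets x n_units, True = used as source


@dataclass
class PropagationTrace:
    """Per-step activations of iterated activity-flow mapping."""

    steps: List[np.ndarray]
    settle_step: int  # first step with max abs change < tolerance (1-based)
    settle_tolerance: float
    settled: bool

    @property
    def final(self) -> np.ndarray:
        return self.steps[-1]


@dataclass
class AccuracyReport:
    """Mapping accuracy: Pearson r, MAE and unscaled-variance R^2."""

    pearson_r: float
    mae: float
    r_squared: float


def map_activity(
    activations: np.ndarray,
    fc: ArrayLike,
    targets: Optional[Sequence[int]] = None,
    sources: Optional[Sequence[int]] = None,
    exclude_sources: Optional[Sequence[int]] = None,
) -> ActivityFlowsMap:
    """Map held-out targets as connectivity-weighted sums of sources.

    ``sources`` restricts to a named subset (e.g. V1-only); by default
    all other units act as sources (fully distributed).
    ``exclude_sources`` drops additional units (e.g. held-out
    category-responsive controls). A target is always excluded from its
    own source set; a target explicitly listed in ``sources`` raises.
    """
    W = _weights(fc)
    activations = np.asarray(activations, dtype=float)
    n_units = W.shape[0]
    if activations.shape[0] != n_units:
        raise ValueError("activations and fc index different unit sets")
    tgt = np.arange(n_units) if targets is None else np.asarray(targets)

    allowed = np.ones(n_units, dtype=bool)
    if sources is not None:
        allowed[:] = False
        allowed[np.asarray(sources)] = True
        overlap = np.intersect1d(tgt, np.asarray(sources))
        if overlap.size:
            raise ValueError(
                f"targets {overlap.tolist()} appear in their own source set"
            )
    if exclude_sources is not None:
        allowed[np.asarray(exclude_sources)] = False

    source_mask = np.tile(allowed, (len(tgt), 1))
    source_mask[np.arange(len(tgt)), tgt] = False  # circularity guard

    flows = (
        W[tgt][:, :, None] * activations[None, :, :]
    ) * source_mask[:, :, None]
    mapped = flows.sum(axis=1)
    return ActivityFlowsMap(
        targets=tgt, flows=flows, mapped=mapped, source_mask=source_mask
    )


def v1_initialized_map(
    activations: np.ndarray,
    fc: ArrayLike,
    v1_units: Sequence[int],
    targets: Sequence[int],
    center_conditions: Optional[Iterable[int]] = None,
) -> np.ndarray:
    """Stimulus-driven mapping from V1 sources only.

    For each condition in ``center_conditions`` (typically the mapped
    category's own conditions), the cross-V1 mean activation of that
    condition is subtracted from every V1 source before the
    activity-flow sum, removing any uniform component potentially fed
    back to V1. Other conditions are mapped without centering. Returns a
    targets x conditions matrix.
    """
    v1 = np.asarray(v1_units)
    if v1.size == 0:
        raise ValueError("v1_units is empty")
    tgt = np.asarray(targets)
    if np.intersect1d(v1, tgt).size:
        raise ValueError("v1_units must be disjoint from targets")
    acts = np.asarray(activations, dtype=float).copy()
    if center_conditions is not None:
        for c in center_conditions:
            acts[v1, c] = acts[v1, c] - acts[v1, c].mean()
    return map_activity(acts, fc, targets=tgt, sources=v1).mapped


def propagate(
    initial: np.ndarray,
    fc: ArrayLike,
    tolerance: float = 0.5e-4,
    max_steps: int = 200,
    inject: bool = True,
    overflow_guard: float = 1e12,
) -> PropagationTrace:
    """Iterate activity-flow mapping over a restricted subsystem.

    Step k+1 re-maps every unit from all others at step k. With
    ``inject=True`` (default) the initial stimulus-driven activations
    re-enter at each step, ``x_{k+1} = W x_k + x_0``, so that with
    subsystem spectral radius < 1 the trace settles — the first step
    where the maximum absolute change drops below ``tolerance``
    (half-ULP of four-decimal rounding by default) — at the closed-form
    fixed point ``(I - W)^{-1} x_0``. With ``inject=False`` the pure
    relaxation ``x_{k+1} = W x_k`` is iterated (which decays to zero for
    spectral radius < 1). Divergence raises :class:`DivergenceError`
    reporting the spectral radius.
    """
    W = _weights(fc)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    W = W.copy()
    np.fill_diagonal(W, 0.0)  # each target excludes itself as a source
    x0 = np.asarray(initial, dtype=float)
    steps = [x0]
    settle_step, settled = max_steps, False
    for k in range(1, max_steps + 1):
        x_next = W @ steps[-1] + (x0 if inject else 0.0)
        if not np.all(np.isfinite(x_next)) or np.max(np.abs(x_next)) > overflow_guard:
            rho = max(abs(np.linalg.eigvals(W)))
            raise DivergenceError(
                f"propagation diverged at step {k}; subsystem spectral "
                f"radius {rho:.3f}"
            )
        delta = np.max(np.abs(x_next - steps[-1]))
        steps.append(x_next)
        if delta < tolerance:
            settle_step, settled = k, True
            break
    return PropagationTrace(
        steps=steps,
        settle_step=settle_step,
        settle_tolerance=tolerance,
        settled=settled,
    )


def two_step_map(
    activations: np.ndarray,
    fc_vertex: ArrayLike,
    fc_region: ArrayLike,
    v1_units: Sequence[int],
    vis_units: Sequence[int],
    vertex_to_region: Dict[int, int],
    region_activations: np.ndarray,
    region_targets: Sequence[int],
    center_conditions: Optional[Iterable[int]] = None,
) -> np.ndarray:
    """Stimulus-driven + fully distributed two-step mapping.

    Step 1: V1-initialized mapping at the vertex level across the visual
    subsystem. Vertex maps are averaged (unweighted mean) into their
    regions, replacing those regions' activations. Step 2: fully
    distributed region-level mapping of the held-out targets using all
    cortical sources. Returns targets x conditions.
    """
    vis = np.asarray(vis_units)
    step1 = v1_initialized_map(
        activations, fc_vertex, v1_units, targets=vis,
        center_conditions=center_conditions,
    )
    missing = [int(v) for v in vis if int(v) not in vertex_to_region]
    if missing:
        raise ValueError(f"no region aggregation for vertices {missing}")
    region_acts = np.asarray(region_activations, dtype=float).copy()
    by_region: Dict[int, list] = {}
    for row, v in enumerate(vis):
        by_region.setdefault(vertex_to_region[int(v)], []).append(row)
    for region, rows in by_region.items():
        region_acts[region] = step1[rows].mean(axis=0)
    return map_activity(region_acts, fc_region, targets=region_targets).mapped


def accuracy(
    actual: Union[np.ndarray, Sequence[np.ndarray]],
    mapped: Union[np.ndarray, Sequence[np.ndarray]],
) -> AccuracyReport:
    """Pearson r, MAE and R^2 between actual and mapped activations.

    R^2 is the coefficient of determination against the actual values
    (unscaled variance), so incorrectly scaled mappings go negative.
    When given per-participant sequences, statistics are computed per
    participant and then averaged.
    """
    if isinstance(actual, np.ndarray):
        actual, mapped = [actual], [mapped]  # type: ignore[list-item]
    rs, maes, r2s = [], [], []
    for a, m in zip(actual, mapped):
        a = np.asarray(a, float).ravel()
        m = np.asarray(m, float).ravel()
        if a.size < 2:
            raise ValueError("need at least 2 entries to score accuracy")
        if np.ptp(a) == 0:
            raise ValueError("actual activations have zero variance")
        rs.append(np.corrcoef(a, m)[0, 1])
        maes.append(np.mean(np.abs(a - m)))
        r2s.append(r2_score(a, m))
    return AccuracyReport(
        pearson_r=float(np.mean(rs)),
        mae=float(np.mean(maes)),
        r_squared=float(np.mean(r2s)),
    )
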