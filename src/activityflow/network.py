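"""Network decomposition of activity flows and dominance analysis.

Mapped activity is linear in its sources, so restricting Eq.-1 sums to
one network at a time parses a mapping into 12 components that sum
exactly to the fully distributed map. Dominance analysis then decomposes
the variance a regression of the actual response profile on those
components explains into per-network partial R^2 values (averaging each
predictor's incremental R^2 over all candidate subsets), which sum to
the full-model R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Sequence

import numpy as np

from .actflow import ActivityFlowsMap, ArrayLike, map_activity


def flows_by_network(
    flows_map: ActivityFlowsMap, partition: np.ndarray
) -> Dict[str, np.ndarray]:
    """Mean flow product per source network.

    Returns network label -> (n_targets x n_conditions) array of the
    source-averaged flow products. Weighted by member counts, these
    means sum back to the mapped values.
    """
    partition = np.asarray(partition)
    if partition.shape[0] != flows_map.flows.shape[1]:
        raise ValueError("partition does not label every source unit")
    out = {}
    for lab in dict.fromkeys(partition.tolist()):
        members = np.flatnonzero(partition == lab)
        out[lab] = flows_map.flows[:, members, :].mean(axis=1)
    return out


def network_restricted_maps(
    activations: np.ndarray,
    fc: ArrayLike,
    partition: np.ndarray,
    targets: Sequence[int],
) -> Dict[str, np.ndarray]:
    """Eq.-1 maps with sources restricted to one network at a time.

    The components sum exactly (linearity) to the fully distributed map
    of the same targets.
    """
    partition = np.asarray(partition)
    full = map_activity(activations, fc, targets=targets)
    if partition.shape[0] != full.source_mask.shape[1]:
        raise ValueError("partition does not cover all source units")
    components = {}
    for lab in dict.fromkeys(partition.tolist()):
        members = np.flatnonzero(partition == lab)
        components[lab] = full.flows[:, members, :].sum(axis=1)
    return components


@dataclass
class DominanceResult:
    """Per-predictor partial R^2 decomposition of a regression's R^2."""

    full_r2: float
    partial_r2: Dict[str, float]
    relative_importance_pct: Dict[str, float]
    n_candidate_models: int


def n_candidate_models(n_predictors: int) -> int:
    """All non-empty predictor subsets (includes the full model)."""
    return 2**n_predictors - 1


def _subset_r2(R: np.ndarray, r_y: np.ndarray, n_predictors: int) -> np.ndarray:
    """R^2 of every predictor subset, indexed by bitmask.

    With standardized variables, R^2(S) = r_yS' R_SS^{-1} r_yS.
    """
    r2 = np.zeros(2**n_predictors)
    for mask in range(1, 2**n_predictors):
        idx = [i for i in range(n_predictors) if mask >> i & 1]
        sub = R[np.ix_(idx, idx)]
        try:
            coef = np.linalg.solve(sub, r_y[idx])
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(sub, r_y[idx], rcond=None)[0]
        r2[mask] = float(r_y[idx] @ coef)
    return r2


def dominance(
    predictors: Dict[str, np.ndarray], actual: np.ndarray
) -> DominanceResult:
    """General dominance analysis of ``actual`` on the named predictors.

    For each predictor, its incremental R^2 is averaged over all subsets
    of the other predictors within each subset size, then across sizes;
    these partial R^2 values sum to the full-model R^2 and divide by it
    to give relative importance percentages. All 2^p - 1 non-empty
    subsets are enumerated as candidate models.
    """
    names = list(predictors)
    p = len(names)
    X = np.column_stack([np.asarray(predictors[k], float).ravel() for k in names])
    y = np.asarray(actual, float).ravel()
    if y.shape[0] <= p:
        raise ValueError(
            f"need more observations ({y.shape[0]}) than predictors ({p})"
        )
    sx = X.std(axis=0)
    sy = y.std()
    if np.any(sx == 0) or sy == 0:
        bad = [names[i] for i in np.flatnonzero(sx == 0)]
        raise ValueError(
            f"degenerate (constant) predictor or response: {bad or 'response'}"
        )
    Xs = (X - X.mean(axis=0)) / sx
    ys = (y - y.mean()) / sy
    n = y.shape[0]
    R = (Xs.T @ Xs) / n
    r_y = (Xs.T @ ys) / n

    r2 = _subset_r2(R, r_y, p)
    full_mask = 2**p - 1
    full_r2 = r2[full_mask]
    if not np.isfinite(full_r2):
        raise ValueError("full model is singular")

    partial = {}
    others = list(range(p))
    for i, name in enumerate(names):
        rest = [j for j in others if j != i]
        size_means = []
        for size in range(p):
            incs = [
                r2[_mask(s) | (1 << i)] - r2[_mask(s)]
                for s in combinations(rest, size)
            ]
            size_means.append(np.mean(incs))
        partial[name] = float(np.mean(size_means))

    rel = {
        k: (100.0 * v / full_r2 if full_r2 > 0 else np.nan)
        for k, v in partial.items()
    }
    return DominanceResult(
        full_r2=float(full_r2),
        partial_r2=partial,
        relative_importance_pct=rel,
        n_candidate_models=n_candidate_models(p),
    )


def _mask(subset) -> int:
    m = 0
    for j in subset:
        m |= 1 << j
    return m
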