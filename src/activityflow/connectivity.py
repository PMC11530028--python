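"""Resting-state functional connectivity estimation.

Implements the three-stage combinedFC procedure (partial-correlation
skeleton, bivariate-correlation collider pruning, regression-based edge
scaling) at the region level, and an L1-regularized variant with
cross-validation across rest runs for the vertex level where sources
outnumber time points. Both honour source-exclusion masks emulating the
dilated spatial mask around each target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm
from sklearn.linear_model import LassoCV


@dataclass
class ExclusionMask:
    """Boolean target x source matrix; True = source excluded."""

    mask: np.ndarray
    radius: float

    def sources_for(self, target: int) -> np.ndarray:
        return np.flatnonzero(~self.mask[target])


@dataclass
class FCMatrix:
    """Target x source regression weights with estimation metadata."""

    weights: np.ndarray
    mask: Optional[np.ndarray] = None  # True = excluded
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("FC weights must be square (target x source)")
        if not np.all(np.isfinite(w)):
            raise ValueError("FC weights contain non-finite entries")

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]


def build_exclusion_mask(geometry: np.ndarray, radius: float) -> ExclusionMask:
    """Exclude sources within Euclidean ``radius`` of each target.

    The target's own unit is always excluded. ``radius=0`` excludes only
    the unit itself; an infinite radius excludes everything.
    """
    d = cdist(geometry, geometry)
    mask = d <= radius
    np.fill_diagonal(mask, True)
    return ExclusionMask(mask=mask, radius=radius)


def _self_only_mask(n: int) -> np.ndarray:
    return np.eye(n, dtype=bool)


def combinedfc(
    rest: np.ndarray,
    mask: Optional[ExclusionMask] = None,
    alpha_partial: float = 0.01,
    alpha_zero: float = 0.01,
) -> FCMatrix:
    """Three-stage combinedFC estimate from a unit x time rest series.

    Stage 1 computes the partial correlation of every pair conditioning
    on all other units (from the inverse covariance) and keeps edges
    significant at ``alpha_partial`` (two-sided Fisher-z test). Stage 2
    removes kept edges whose bivariate Pearson correlation is
    statistically equal to zero at ``alpha_zero`` — spurious edges
    created by conditioning on colliders. Stage 3 regresses each target
    on its remaining connected sources; the fitted coefficients scale the
    edges. Masked sources never enter a target's regression.
    """
    rest = np.asarray(rest, dtype=float)
    n_units, n_time = rest.shape
    if n_time <= n_units:
        raise ValueError(
            f"combinedfc needs more timepoints ({n_time}) than units "
            f"({n_units}); use regularized_fc for vertex-level data"
        )
    excl = mask.mask if mask is not None else _self_only_mask(n_units)

    X = rest.T - rest.mean(axis=1)
    cov = (X.T @ X) / (n_time - 1)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular covariance; consider the regularized (lasso) variant"
        ) from err
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 0.0)

    # Fisher z for partial correlation: df correction for the n-2 conditioned
    # variables
    n_cond = n_units - 2
    z_pc = np.arctanh(np.clip(pcorr, -0.999999, 0.999999)) * np.sqrt(
        max(n_time - n_cond - 3, 1)
    )
    crit_pc = norm.ppf(1 - alpha_partial / 2)
    skeleton = np.abs(z_pc) > crit_pc

    # Stage 2: collider pruning on the kept edges
    r = np.corrcoef(rest)
    z_r = np.arctanh(np.clip(r, -0.999999, 0.999999)) * np.sqrt(n_time - 3)
    crit_r = norm.ppf(1 - alpha_zero / 2)
    bivariate_nonzero = np.abs(z_r) > crit_r
    skeleton &= bivariate_nonzero

    skeleton &= ~excl

    weights = np.zeros((n_units, n_units))
    for j in range(n_units):
        sources = np.flatnonzero(skeleton[j] & ~excl[j])
        if sources.size == 0:
            continue
        beta, *_ = np.linalg.lstsq(X[:, sources], X[:, j], rcond=None)
        weights[j, sources] = beta
    np.fill_diagonal(weights, 0.0)

    return FCMatrix(
        weights=weights,
        mask=excl,
        meta={
            "method": "combinedfc",
            "alpha_partial": alpha_partial,
            "alpha_zero": alpha_zero,
            "n_timepoints": n_time,
            "n_stage1_edges": int(np.count_nonzero(np.abs(z_pc) > crit_pc) // 2),
            "n_final_edges": int(np.count_nonzero(skeleton) // 2),
        },
    )


def lasso_penalty_grid(X: np.ndarray, y: np.ndarray, n_penalties: int = 100,
                       span: float = 1e4) -> np.ndarray:
    """Log-spaced penalties from the all-zero penalty down ``span``-fold."""
    n = X.shape[0]
    alpha_max = np.max(np.abs(X.T @ y)) / n
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(
        np.log10(alpha_max), np.log10(alpha_max / span), n_penalties
    )


def regularized_fc(
    rest_runs: List[np.ndarray],
    mask: Optional[ExclusionMask] = None,
    n_penalties: int = 100,
    penalty_rule: str = "1se",
    targets: Optional[np.ndarray] = None,
    seed: int = 0,
) -> FCMatrix:
    """L1-regularized (lasso) FC for vertex-level data.

    Per target, the penalty is chosen by leave-one-run-out
    cross-validated prediction error over ``n_penalties`` log-spaced
    values; the selected coefficients fill the target's row. Requires at
    least two rest runs. An all-zero target series yields a zero row
    with a warning.

    ``penalty_rule``: "min" takes the CV-error minimizer; "1se" (default)
    takes the sparsest penalty whose CV error is within one standard
    error of the minimum, the standard guard against the over-selection
    of CV-minimizing lasso. ``targets`` restricts estimation to a subset
    of rows (other rows stay zero).
    """
    if len(rest_runs) < 2:
        raise ValueError(
            "regularized_fc needs >= 2 rest runs for cross-validation"
        )
    if penalty_rule not in ("min", "1se"):
        raise ValueError(f"unknown penalty_rule {penalty_rule!r}")
    n_units = rest_runs[0].shape[0]
    excl = mask.mask if mask is not None else _self_only_mask(n_units)

    data = np.concatenate(rest_runs, axis=1)  # unit x time
    run_id = np.concatenate(
        [np.full(r.shape[1], k) for k, r in enumerate(rest_runs)]
    )
    X_all = data.T - data.mean(axis=1)
    folds = [
        (np.flatnonzero(run_id != k), np.flatnonzero(run_id == k))
        for k in range(len(rest_runs))
    ]

    rows = np.arange(n_units) if targets is None else np.asarray(targets)
    weights = np.zeros((n_units, n_units))
    chosen = np.zeros(n_units)
    for j in rows:
        sources = np.flatnonzero(~excl[j])
        y = X_all[:, j]
        if np.allclose(y, 0.0):
            warnings.warn(f"target {j} has an all-zero series; zero FC row")
            continue
        Xs = X_all[:, sources]
        grid = lasso_penalty_grid(Xs, y, n_penalties=n_penalties)
        model = LassoCV(alphas=grid, cv=folds, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, y)
        alpha = model.alpha_
        if penalty_rule == "1se":
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(
                model.mse_path_.shape[1]
            )
            k_min = int(np.argmin(mse))
            within = mse <= mse[k_min] + se[k_min]
            # alphas_ are sorted descending: first within-1se index is sparsest
            k_1se = int(np.flatnonzero(within)[0])
            alpha = model.alphas_[k_1se]
            if alpha != model.alpha_:
                from sklearn.linear_model import Lasso

                refit = Lasso(alpha=alpha, max_iter=5000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    refit.fit(Xs, y)
                model = refit
        weights[j, sources] = model.coef_
        chosen[j] = alpha
    np.fill_diagonal(weights, 0.0)

    return FCMatrix(
        weights=weights,
        mask=excl,
        meta={
            "method": "lasso",
            "n_penalties": n_penalties,
            "chosen_penalty": chosen,
            "seed": seed,
        },
    )
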