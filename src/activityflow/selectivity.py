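"""Category-selectivity statistics.

Selectivity is the ratio of mean normalized category responses to mean
normalized non-category responses (1.0 = no selectivity); activations
are first min-max normalized to [a, b] using reference extrema taken
from the *actual* activations across all conditions, applied identically
to actual and mapped data. The percent contribution of distributed
processes is 100 * mapped / actual selectivity per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats

MAD_SCALE = 1.4826  # consistency constant for Gaussian data


@dataclass
class NormalizationParams:
    """Min-max feature-scaling bounds and reference extrema."""

    a: float = 0.0
    b: float = 1.0
    min_ref: float = 0.0
    max_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= self.a:
            raise ValueError("upper bound b must exceed lower bound a")


class FlatActivationWarning(UserWarning):
    """All-equal activations: normalization degenerates to the constant a."""


def normalization_params(
    actual: np.ndarray, a: float = 0.0, b: float = 1.0
) -> NormalizationParams:
    """Reference extrema from the actual activations across conditions."""
    x = np.asarray(actual, dtype=float)
    return NormalizationParams(
        a=a, b=b, min_ref=float(x.min()), max_ref=float(x.max())
    )


def minmax_normalize(x: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """``a + (x - min_ref)(b - a)/(max_ref - min_ref)``.

    Values outside the reference range (possible for mapped data, whose
    reference comes from the actual data) map outside [a, b]. A flat
    reference (max_ref == min_ref) returns the constant ``a`` with a
    :class:`FlatActivationWarning`.
    """
    x = np.asarray(x, dtype=float)
    span = params.max_ref - params.min_ref
    if span == 0:
        warnings.warn(
            "flat activation vector: returning constant lower bound",
            FlatActivationWarning,
        )
        return np.full_like(x, params.a)
    return params.a + (x - params.min_ref) * (params.b - params.a) / span


def selectivity_ratio(
    normalized: np.ndarray,
    category_conditions: Sequence[int],
    noncategory_conditions: Sequence[int],
) -> float:
    """mean(category responses) / mean(non-category responses)."""
    cat = np.mean(normalized[..., list(category_conditions)])
    non = np.mean(normalized[..., list(noncategory_conditions)])
    if non <= 0:
        raise ValueError(
            f"non-category mean {non:.4g} <= 0: selectivity undefined "
            "(normalize activations first)"
        )
    return float(cat / non)


def category_selectivity(
    actual: np.ndarray,
    mapped: np.ndarray,
    category_conditions: Sequence[int],
    noncategory_conditions: Sequence[int],
    units: Sequence[int],
    unit_aggregation: str = "per-unit-then-average",
    a: float = 0.0,
    b: float = 1.0,
) -> Tuple[float, float]:
    """(actual, mapped) selectivity of a complex for one participant.

    ``actual`` and ``mapped`` are unit x condition matrices indexed
    identically; ``units`` selects the complex. Non-category conditions
    must be the other categories' conditions only. Normalization
    reference extrema always come from the actual activations.

    ``unit_aggregation``:
      - "per-unit-then-average": selectivity per unit, then averaged
        (used for vertex-level stimulus-driven models);
      - "average-then-ratio": responses averaged across the complex
        first, then one ratio (used for the region-level fully
        distributed model).
    """
    units = np.asarray(units)
    act = np.asarray(actual, float)[units]
    mp = np.asarray(mapped, float)[units]
    if unit_aggregation == "average-then-ratio":
        act_prof, map_prof = act.mean(axis=0), mp.mean(axis=0)
        params = normalization_params(act_prof, a=a, b=b)
        act_sel = selectivity_ratio(
            minmax_normalize(act_prof, params),
            category_conditions, noncategory_conditions,
        )
        map_sel = selectivity_ratio(
            minmax_normalize(map_prof, params),
            category_conditions, noncategory_conditions,
        )
        return act_sel, map_sel
    if unit_aggregation != "per-unit-then-average":
        raise ValueError(f"unknown unit_aggregation {unit_aggregation!r}")
    act_sels, map_sels = [], []
    for k in range(len(units)):
        params = normalization_params(act[k], a=a, b=b)
        act_sels.append(selectivity_ratio(
            minmax_normalize(act[k], params),
            category_conditions, noncategory_conditions,
        ))
        map_sels.append(selectivity_ratio(
            minmax_normalize(mp[k], params),
            category_conditions, noncategory_conditions,
        ))
    return float(np.mean(act_sels)), float(np.mean(map_sels))


def distributed_contribution(
    mapped_sel: np.ndarray, actual_sel: np.ndarray
) -> np.ndarray:
    """Percent of actual selectivity captured by the mapped selectivity."""
    mapped_sel = np.asarray(mapped_sel, float)
    actual_sel = np.asarray(actual_sel, float)
    if np.any(actual_sel <= 0):
        raise ValueError("actual selectivity must be positive")
    return 100.0 * mapped_sel / actual_sel


def remove_outliers(
    scores: np.ndarray, n_mad: float = 5.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Flag scores more than ``n_mad`` median absolute deviations out.

    The MAD is scaled by 1.4826 for consistency with the Gaussian SD.
    Returns (filtered scores, boolean outlier flags). A zero MAD flags
    nothing and warns.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 participants for outlier removal")
    med = np.median(scores)
    mad = MAD_SCALE * np.median(np.abs(scores - med))
    if mad == 0:
        warnings.warn("zero MAD: no outliers removed")
        flags = np.zeros(scores.shape, dtype=bool)
    else:
        flags = np.abs(scores - med) / mad > n_mad
    return scores[~flags], flags


@dataclass
class ContrastResult:
    t: float
    p: float
    cohens_d: float
    df: int


def benchmark_contrast(
    category_responses: np.ndarray, noncategory_responses: np.ndarray
) -> ContrastResult:
    """One-tailed paired t-test (category > non-category) with Cohen's d.

    Inputs are per-participant response amplitudes; the non-category
    value should be the average of the other three categories.
    """
    cat = np.asarray(category_responses, float)
    non = np.asarray(noncategory_responses, float)
    if cat.shape != non.shape:
        raise ValueError("paired inputs must have identical shapes")
    n = cat.size
    if n < 2:
        raise ValueError("need at least 2 participants")
    diff = cat - non
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:  # identical inputs: no effect
            return ContrastResult(t=0.0, p=0.5, cohens_d=0.0, df=n - 1)
        raise ValueError("zero variance in paired differences: t undefined")
    t = diff.mean() / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return ContrastResult(
        t=float(t), p=p, cohens_d=float(diff.mean() / sd), df=n - 1
    )


def noncategory_conditions(
    category_conditions: Dict[str, Sequence[int]], category: str
) -> list:
    """The other three categories' condition indices (the ratio denominator)."""
    out = []
    for cat, conds in category_conditions.items():
        if cat != category:
            out.extend(conds)
    return sorted(out)
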