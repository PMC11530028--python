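"""Null connectivity models and max-T permutation inference.

Two null network models probe whether a complex's connectivity
fingerprint drives its mapped selectivity: fingerprint substitution
(swap a target complex's FC rows with another complex's) and
degree/strength-preserving random rewiring. Family-wise error across
multiple comparisons is controlled with the max-T permutation approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .connectivity import FCMatrix


@dataclass
class NullFCSet:
    """A family of null FC matrices with provenance."""

    variants: List[FCMatrix]
    null_kind: str  # "substitution" | "permuted-architecture"
    provenance: dict = field(default_factory=dict)


def substitute_fingerprint(
    fc: Union[FCMatrix, np.ndarray],
    target_units: Sequence[int],
    donor_units: Sequence[int],
) -> FCMatrix:
    """Replace a target complex's connectivity fingerprint with a donor's.

    Rows of the target complex are replaced by the donor complex's rows
    (unit-for-unit, so the complexes must be disjoint and equal-sized);
    the target self-connection block is set to zero; and the entries at
    (target row, donor column) — zero in the donor's own rows — are
    filled with the transposed original estimates
    ``fc[donor row, target column]``.
    """
    W = fc.weights if isinstance(fc, FCMatrix) else np.asarray(fc, float)
    t = np.asarray(target_units)
    d = np.asarray(donor_units)
    if np.array_equal(np.sort(t), np.sort(d)):
        # identity substitution: original fingerprint, self-block zeroed
        out = W.copy()
        out[np.ix_(t, t)] = 0.0
        np.fill_diagonal(out, 0.0)
        mask = fc.mask if isinstance(fc, FCMatrix) else None
        return FCMatrix(weights=out, mask=mask,
                        meta={"null_kind": "substitution",
                              "target_units": t.tolist(),
                              "donor_units": d.tolist()})
    if np.intersect1d(t, d).size:
        raise ValueError("target and donor complexes overlap")
    if t.size != d.size:
        raise ValueError(
            f"complex sizes differ ({t.size} vs {d.size}); row-for-row "
            "substitution undefined"
        )
    out = W.copy()
    out[t, :] = W[d, :]
    out[np.ix_(t, t)] = 0.0
    out[np.ix_(t, d)] = W[np.ix_(d, t)].T
    np.fill_diagonal(out, 0.0)
    mask = fc.mask if isinstance(fc, FCMatrix) else None
    if mask is not None:
        out[mask] = 0.0
    return FCMatrix(
        weights=out, mask=mask,
        meta={"null_kind": "substitution",
              "target_units": t.tolist(), "donor_units": d.tolist()},
    )


def permute_architecture(
    fc: Union[FCMatrix, np.ndarray],
    n_perms: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
    max_tries_factor: int = 100,
) -> NullFCSet:
    """Degree- and strength-preserving random rewiring of the FC graph.

    Each null applies double-edge swaps to the directed nonzero-edge set
    — preserving every unit's binary in/out degree — and then reassigns
    edge weights as a random permutation of the original nonzero weight
    multiset. The zero diagonal and any exclusion mask are respected
    throughout (swaps that would create self-loops, duplicate edges or
    masked edges are rejected).
    """
    W = fc.weights if isinstance(fc, FCMatrix) else np.asarray(fc, float)
    mask = fc.mask if isinstance(fc, FCMatrix) else None
    edges = np.argwhere(W != 0)
    if len(edges) < 2:
        raise ValueError("graph has too few edges to rewire")
    weights_multiset = W[edges[:, 0], edges[:, 1]]
    rng = np.random.default_rng(seed)
    variants = []
    n_swaps = swaps_per_edge * len(edges)
    for k in range(n_perms):
        edge_set = {(int(i), int(j)) for i, j in edges}
        edge_list = list(edge_set)
        done = tries = 0
        max_tries = max_tries_factor * n_swaps
        while done < n_swaps and tries < max_tries:
            tries += 1
            a, b = rng.integers(0, len(edge_list), size=2)
            if a == b:
                continue
            (u, v), (x, y) = edge_list[a], edge_list[b]
            # rewire u->v, x->y  to  u->y, x->v
            if u == y or x == v:
                continue
            if (u, y) in edge_set or (x, v) in edge_set:
                continue
            if mask is not None and (mask[u, y] or mask[x, v]):
                continue
            edge_set.discard((u, v))
            edge_set.discard((x, y))
            edge_set.add((u, y))
            edge_set.add((x, v))
            edge_list[a], edge_list[b] = (u, y), (x, v)
            done += 1
        if done < n_swaps // 2:
            raise ValueError(
                "graph too dense or degenerate to rewire: only "
                f"{done}/{n_swaps} swaps succeeded"
            )
        new_edges = np.array(edge_list)
        null = np.zeros_like(W)
        perm = rng.permutation(len(weights_multiset))
        null[new_edges[:, 0], new_edges[:, 1]] = weights_multiset[perm]
        variants.append(FCMatrix(weights=null, mask=mask,
                                 meta={"null_kind": "permuted-architecture",
                                       "perm_index": k}))
    return NullFCSet(
        variants=variants,
        null_kind="permuted-architecture",
        provenance={"seed": seed, "n_perms": n_perms,
                    "swaps_per_edge": swaps_per_edge},
    )


@dataclass
class MaxTResult:
    """Max-T corrected inference over a family of comparisons."""

    observed_t: np.ndarray
    corrected_p: np.ndarray
    threshold: float  # (1 - alpha) quantile of the max-T null
    maxt_distribution: np.ndarray
    n_permutations: int
    alpha: float
    seed: Optional[int]

    @property
    def significant(self) -> np.ndarray:
        return self.corrected_p <= self.alpha


def maxt_test(
    data: np.ndarray,
    null_mean: Union[float, np.ndarray] = 0.0,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    scheme: str = "sign_flip",
    seed: Optional[int] = None,
) -> MaxTResult:
    """Max-T nonparametric permutation test over multiple comparisons.

    ``data`` is participants x comparisons. Schemes:

    - ``"paired"``: columns are per-participant paired differences;
      permutations exchange the two condition labels per participant,
      i.e. flip the sign of each difference.
    - ``"sign_flip"``: one-sample tests versus ``null_mean`` (e.g. 1.0
      for selectivity, 50 for contribution percentages); permutations
      flip the sign of each participant's deviation from the null mean.

    Per permutation all t statistics are recomputed and the maximum
    recorded; corrected p = (1 + #{max-T >= t_obs}) / (1 + n_perm)
    (one-tailed, greater).
    """
    if scheme not in ("sign_flip", "paired"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    dev = data - null_mean  # for "paired", null_mean defaults to 0
    n, m = dev.shape
    if n < 2:
        raise ValueError("need at least 2 participants")

    def tstats(x: np.ndarray) -> np.ndarray:
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return x.mean(axis=0) / (sd / np.sqrt(n))

    t_obs = tstats(dev)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    # vectorized: flipped[k] = signs[k][:, None] * dev
    flipped_mean = signs @ dev / n
    flipped_sq = (signs**2) @ (dev**2) / n  # = column means of dev^2
    var = (flipped_sq - flipped_mean**2) * n / (n - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    sd = np.where(sd == 0, np.inf, sd)
    t_null = flipped_mean / (sd / np.sqrt(n))
    maxt = t_null.max(axis=1)

    corrected_p = (1 + (maxt[:, None] >= t_obs[None, :]).sum(axis=0)) / (
        1 + n_perm
    )
    threshold = float(np.quantile(maxt, 1 - alpha))
    return MaxTResult(
        observed_t=t_obs,
        corrected_p=corrected_p,
        threshold=threshold,
        maxt_distribution=maxt,
        n_permutations=n_perm,
        alpha=alpha,
        seed=seed,
    )
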