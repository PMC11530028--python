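"""Task GLM: canonical HRF, design construction, OLS betas, nuisance set."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma


@dataclass
class DesignMatrix:
    """Time x regressor matrix with labeled columns."""

    matrix: np.ndarray
    labels: List[str]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


def canonical_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
    duration: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response kernel.

    Difference of two gamma densities (response peaking near 6 s, an
    undershoot near 16 s, response/undershoot amplitude ratio 6),
    sampled at ``dt`` and normalized to unit peak.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t = np.arange(0.0, duration + dt / 2, dt)
    h = (
        gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
        - gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
        / ratio
    )
    return h / h.max()


def build_design(
    timing: pd.DataFrame,
    n_timepoints: int,
    dt: float,
    hrf: Optional[np.ndarray] = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Convolve block timing with the HRF, one regressor per condition.

    ``timing`` has columns ``condition``, ``onset``, ``duration`` (onset
    and duration in the same time units as ``dt``). Overlapping blocks of
    the same condition simply add. Pass ``hrf=np.array([1.0])`` for an
    identity kernel (regressor equals the boxcar).
    """
    if hrf is None:
        hrf = canonical_hrf(dt)
    conditions = sorted(timing["condition"].unique()) if len(timing) else []
    cols, labels = [], []
    for c in conditions:
        box = np.zeros(n_timepoints)
        for _, row in timing[timing["condition"] == c].iterrows():
            i0 = int(round(row["onset"] / dt))
            i1 = int(round((row["onset"] + row["duration"]) / dt))
            if i0 < 0 or i0 >= n_timepoints:
                raise ValueError(
                    f"block onset {row['onset']} outside run of "
                    f"{n_timepoints} timepoints"
                )
            box[i0: min(i1, n_timepoints)] += 1.0
        cols.append(np.convolve(box, hrf)[:n_timepoints])
        labels.append(f"cond_{c}")
    if intercept:
        cols.append(np.ones(n_timepoints))
        labels.append("intercept")
    matrix = (
        np.column_stack(cols) if cols else np.empty((n_timepoints, 0))
    )
    return DesignMatrix(matrix=matrix, labels=labels)


def estimate_betas(bold: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """OLS condition amplitudes per unit.

    ``bold`` is unit x time. Returns unit x condition betas (nuisance and
    intercept columns are fit but dropped). Raises on rank deficiency,
    naming the collinear columns.
    """
    X = design.matrix
    if bold.shape[1] != X.shape[0]:
        raise ValueError(
            f"bold has {bold.shape[1]} timepoints but design has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for k in range(X.shape[1]):
            others = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(design.labels[k])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    betas, *_ = np.linalg.lstsq(X, bold.T, rcond=None)
    keep = [i for i, lab in enumerate(design.labels) if lab.startswith("cond_")]
    return betas[keep, :].T


def _expand(block: np.ndarray, names: Sequence[str]):
    """base -> base + first-difference derivatives + squares of both."""
    deriv = np.diff(block, axis=0, prepend=block[:1, :] * 0 + block[0:1, :])
    deriv[0, :] = 0.0  # zero-padded first sample
    expanded = np.concatenate([block, deriv], axis=1)
    quad = expanded**2
    cols = np.concatenate([expanded, quad], axis=1)
    labels = (
        [f"{n}" for n in names]
        + [f"{n}_dt" for n in names]
        + [f"{n}_sq" for n in names]
        + [f"{n}_dt_sq" for n in names]
    )
    return cols, labels


def build_nuisance_set(
    motion: np.ndarray, tissue_pcs: np.ndarray
) -> DesignMatrix:
    """Standard fMRI nuisance design: 24 motion + 40 aCompCor columns.

    ``motion`` is time x 6 rigid-body parameters; ``tissue_pcs`` is
    time x 10 (five principal components from each of two tissue
    compartments, white matter and ventricles). Each block is expanded
    with first-difference derivatives and the quadratics of the expanded
    set, giving 6 -> 24 and 10 -> 40 columns, 64 in total.
    """
    motion = np.asarray(motion, dtype=float)
    tissue_pcs = np.asarray(tissue_pcs, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"expected 6 motion series, got shape {motion.shape}")
    if tissue_pcs.ndim != 2 or tissue_pcs.shape[1] != 10:
        raise ValueError(
            f"expected 10 tissue PC series (5 x 2 compartments), got shape "
            f"{tissue_pcs.shape}"
        )
    if motion.shape[0] != tissue_pcs.shape[0]:
        raise ValueError("motion and tissue series lengths differ")
    mcols, mlabels = _expand(motion, [f"motion_{i}" for i in range(6)])
    tcols, tlabels = _expand(tissue_pcs, [f"acompcor_{i}" for i in range(10)])
    return DesignMatrix(
        matrix=np.concatenate([mcols, tcols], axis=1),
        labels=mlabels + tlabels,
    )
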