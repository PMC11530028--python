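"""Ground-truth synthetic data: networks, resting state, and task BOLD.

The generator emulates the structure of a parcellated cortex: units are
partitioned into 12 functional networks, four category-selective
"functional complexes" (body, face, place, tool) receive distributed
input through distinctive connectivity fingerprints, and a designated V1
set provides stimulus-driven input. Resting-state series follow a
contemporaneous linear structural equation model (SEM), so that
multiple-regression connectivity estimated on rest recovers the true
weight rows of target units. Task activations of target complexes are a
controllable mixture of distributed activity flow and a within-region
(local) component with known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import (
    CATEGORIES,
    COMPLEX_SPECS,
    NETWORK_LABELS,
    InvalidConfigError,
    NonStationaryError,
    SimulationConfig,
)

# Fingerprint geometry: a complex weights its own category's preferred
# sources at OWN_SOURCE_WEIGHT (per-unit, before global rescaling) and the
# other categories' sources at CROSS_SOURCE_WEIGHT, so mapped responses to
# non-preferred categories stay positive but clearly lower.
OWN_SOURCE_WEIGHT = 1.0
CROSS_SOURCE_WEIGHT = 0.3
V1_FINGERPRINT_WEIGHT = 0.5
FINGERPRINT_COSINE_MAX = 0.9


@dataclass
class GroundTruthModel:
    """Simulation truth: weights, partition, complexes, V1, geometry."""

    weights: np.ndarray  # (target unit, source unit), zero diagonal
    partition: np.ndarray  # unit -> network label (str array)
    complexes: Dict[str, dict]  # name -> {"units": array, "category": str}
    v1_units: np.ndarray
    geometry: np.ndarray  # unit -> 2-D coordinate
    category_sources: Dict[str, np.ndarray] = field(default_factory=dict)
    v1_patterns: Dict[str, np.ndarray] = field(default_factory=dict)
    spectral_radius: float = 0.0

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    @property
    def target_units(self) -> np.ndarray:
        """All complex units, sorted (the held-out mapping targets)."""
        return np.sort(
            np.concatenate([c["units"] for c in self.complexes.values()])
        )

    def complex_units(self, name: str) -> np.ndarray:
        return self.complexes[name]["units"]

    def fingerprint(self, name: str) -> np.ndarray:
        """Mean outgoing-source weight pattern of a complex's rows."""
        rows = self.weights[self.complexes[name]["units"], :]
        return rows.mean(axis=0)


@dataclass
class SyntheticDataset:
    """Per-participant rest/task series with generative ground truth.

    ``truth_activations = (1 - local_fraction) * truth_flow_component +
    local_fraction * truth_local_component`` holds entrywise at the
    complex (target) units by construction; source units are the
    self-consistent solutions of the stimulus-driven source subsystem.
    """

    config: SimulationConfig
    model: GroundTruthModel
    design: pd.DataFrame  # columns: condition, onset, duration
    task_bold: List[np.ndarray]
    truth_activations: List[np.ndarray]  # unit x condition, per participant
    truth_flow_component: List[np.ndarray]
    truth_local_component: List[np.ndarray]
    rest_timeseries: Optional[List[np.ndarray]] = None


def _allocate(config: SimulationConfig):
    """Deterministic unit allocation: networks, V1, complexes, sources."""
    n = config.n_units
    sizes = np.full(12, n // 12)
    sizes[: n % 12] += 1
    partition = np.concatenate(
        [np.full(s, lab) for s, lab in zip(sizes, NETWORK_LABELS)]
    )
    net_units = {
        lab: np.flatnonzero(partition == lab) for lab in NETWORK_LABELS
    }
    v1_units = net_units["VIS1"].copy()

    host_sizes = [len(net_units[host]) for host, _ in COMPLEX_SPECS.values()]
    complex_size = max(1, min(host_sizes) // 2)
    complexes = {}
    taken = set(v1_units.tolist())
    for name, (host, category) in COMPLEX_SPECS.items():
        units = net_units[host][:complex_size]
        if set(units.tolist()) & taken:
            raise InvalidConfigError("cannot allocate disjoint complexes")
        taken.update(units.tolist())
        complexes[name] = {"units": units, "category": category}

    pool = [u for u in range(n) if u not in taken]
    # preferred sources live in visual/attention networks first
    priority = {lab: i for i, lab in enumerate(
        ["VIS2", "PMM", "VMM", "DAN", "SMN", "CON", "FPN", "AUD",
         "LAN", "DMN", "OAN", "VIS1"]
    )}
    pool.sort(key=lambda u: (priority[partition[u]], u))
    n_per_cat = max(2, len(pool) // 8)
    category_sources = {}
    idx = 0
    for cat in CATEGORIES:
        category_sources[cat] = np.array(pool[idx: idx + n_per_cat])
        idx += n_per_cat
    if any(len(v) == 0 for v in category_sources.values()):
        raise InvalidConfigError("n_units too small for category source sets")
    generic_sources = np.array(pool[idx:]) if idx < len(pool) else np.array(
        pool[-4:]
    )
    return partition, net_units, v1_units, complexes, category_sources, generic_sources


def _grid_geometry(n: int) -> np.ndarray:
    ncols = math.ceil(math.sqrt(n))
    u = np.arange(n)
    return np.column_stack([u % ncols, u // ncols]).astype(float)


def generate_ground_truth(config: SimulationConfig) -> GroundTruthModel:
    """Build a block-structured weight matrix with complex fingerprints.

    Within-network connections are stronger than between-network ones;
    each complex's rows form a distinctive fingerprint preferentially
    weighting its own category's sources and a category-specific V1
    pattern. Complex units are pure sinks (zero outgoing columns), so
    regression-based connectivity recovers their rows exactly in
    population. Fingerprint distinctiveness (pairwise cosine < 0.9) is
    enforced by rejection sampling. Deterministic under ``config.seed``.
    """
    (partition, net_units, v1_units, complexes,
     category_sources, generic_sources) = _allocate(config)
    n = config.n_units
    targets = np.sort(np.concatenate([c["units"] for c in complexes.values()]))
    is_target = np.zeros(n, dtype=bool)
    is_target[targets] = True

    for attempt in range(20):
        rng = np.random.default_rng([config.seed, 11, attempt])
        W = np.zeros((n, n))
        # source-to-source block structure, stronger within-network
        for lab in NETWORK_LABELS:
            members = net_units[lab]
            for i in members:
                if is_target[i]:
                    continue
                for j in members:
                    if i != j and not is_target[j]:
                        W[i, j] = abs(rng.normal(0.3, 0.08))
        between = (rng.random((n, n)) < 0.25) * rng.normal(0.0, 0.06, (n, n))
        same_net = partition[:, None] == partition[None, :]
        src_pair = ~is_target[:, None] & ~is_target[None, :]
        W = np.where(~same_net & src_pair, between, W)

        # complex fingerprints
        v1_patterns = {}
        for cat in CATEGORIES:
            p = np.abs(rng.normal(1.0, 0.4, size=len(v1_units)))
            v1_patterns[cat] = p / p.mean()
        for name, cx in complexes.items():
            cat = cx["category"]
            for t in cx["units"]:
                row = rng.normal(0.0, 0.03, size=n)
                for other_cat in CATEGORIES:
                    srcs = category_sources[other_cat]
                    w = OWN_SOURCE_WEIGHT if other_cat == cat else CROSS_SOURCE_WEIGHT
                    row[srcs] = (w / len(srcs)) * (1 + rng.normal(0, 0.05, len(srcs)))
                row[v1_units] = (
                    V1_FINGERPRINT_WEIGHT * v1_patterns[cat] / len(v1_units)
                )
                W[t, :] = row

        W[:, targets] = 0.0  # complexes are sinks: no outgoing influence
        np.fill_diagonal(W, 0.0)

        rho = max(abs(np.linalg.eigvals(W)))
        if rho > 0:
            W *= config.spectral_radius / rho

        model = GroundTruthModel(
            weights=W,
            partition=partition,
            complexes=complexes,
            v1_units=v1_units,
            geometry=_grid_geometry(n),
            category_sources=category_sources,
            v1_patterns=v1_patterns,
            spectral_radius=float(max(abs(np.linalg.eigvals(W)))),
        )
        if _fingerprints_distinct(model):
            return model
    raise InvalidConfigError(
        "could not generate distinct complex fingerprints in 20 attempts"
    )


def _fingerprints_distinct(model: GroundTruthModel) -> bool:
    names = list(model.complexes)
    for i, a in enumerate(names):
        fa = model.fingerprint(a)
        for b in names[i + 1:]:
            fb = model.fingerprint(b)
            denom = np.linalg.norm(fa) * np.linalg.norm(fb)
            if denom > 0 and fa @ fb / denom >= FINGERPRINT_COSINE_MAX:
                return False
    return True


def simulate_rest(
    model: GroundTruthModel, config: SimulationConfig
) -> List[np.ndarray]:
    """Stationary rest series per participant from the contemporaneous SEM.

    Each time point solves ``x = W x + e`` with i.i.d. Gaussian
    innovations, i.e. ``x = (I - W)^{-1} e``; runs are concatenated per
    participant. Raises :class:`NonStationaryError` if the spectral
    radius of ``W`` is >= 1.
    """
    W = model.weights
    rho = max(abs(np.linalg.eigvals(W)))
    if rho >= 1.0:
        raise NonStationaryError(
            f"spectral radius {rho:.3f} >= 1: stationary rest undefined"
        )
    n = model.n_units
    mixing = np.linalg.inv(np.eye(n) - W)
    out = []
    for p in range(config.n_participants):
        rng = np.random.default_rng([config.seed, 23, p])
        runs = []
        for _ in range(config.n_runs_rest):
            e = rng.normal(0.0, config.noise_sd, size=(n, config.n_timepoints_rest))
            runs.append(mixing @ e)
        out.append(np.concatenate(runs, axis=1))
    return out


def condition_drives(
    model: GroundTruthModel, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Exogenous stimulus drive (unit x condition) for one participant.

    Category conditions inject drive into V1 (category-specific pattern)
    and into that category's preferred sources; the remaining generic
    conditions weakly drive non-preferred sources only, anchoring the
    min-max normalization reference near zero at the target complexes.
    """
    n, n_cond = config.n_units, config.n_conditions
    D = np.zeros((n, n_cond))
    cat_conds = {c: set(v) for c, v in config.category_conditions.items()}
    all_cat_conds = set().union(*cat_conds.values())
    for cat in CATEGORIES:
        for c in cat_conds[cat]:
            gain = 1.0 + rng.normal(0.0, config.act_noise_sd)
            D[model.v1_units, c] += gain * model.v1_patterns[cat]
            srcs = model.category_sources[cat]
            D[srcs, c] += gain * (1.0 + rng.normal(0, config.act_noise_sd, len(srcs)))
    generic = [c for c in range(n_cond) if c not in all_cat_conds]
    pool = np.array(
        [u for u in range(n)
         if u not in model.target_units
         and u not in model.v1_units
         and all(u not in model.category_sources[c] for c in CATEGORIES)]
    )
    for c in generic:
        pat_rng = np.random.default_rng([config.seed, 31, c])
        pattern = np.abs(pat_rng.normal(0.4, 0.15, size=len(pool)))
        D[pool, c] = pattern * (1.0 + rng.normal(0.0, config.act_noise_sd))
    return D


def block_design_table(config: SimulationConfig, block_len: int = 10,
                       gap: int = 5, n_blocks: int = 2) -> pd.DataFrame:
    """Block timing: ``n_blocks`` per condition, counterbalanced order."""
    rows = []
    onset = gap
    orders = [list(range(config.n_conditions))]
    while len(orders) < n_blocks:
        orders.append(list(reversed(orders[-1])))
    for order in orders[:n_blocks]:
        for c in order:
            rows.append({"condition": c, "onset": onset, "duration": block_len})
            onset += block_len + gap
    return pd.DataFrame(rows)


def simulate_task(
    model: GroundTruthModel,
    config: SimulationConfig,
    include_bold: bool = True,
) -> SyntheticDataset:
    """Simulate task data with a known distributed-vs-local mixture.

    Per participant: stimulus drives are injected into condition-preferred
    source units; source activations solve the source subsystem
    ``x_S = W_SS x_S + D_S``; each target complex unit's true amplitude is
    ``(1 - lambda) * flow + lambda * local`` where ``flow`` is the
    connectivity-weighted sum of source activations and ``local`` is a
    within-region category-tuned template of matched amplitude. BOLD is
    the block design convolved with a canonical HRF, scaled by the true
    amplitudes, plus Gaussian noise.
    """
    from .glm import build_design  # local import to avoid cycle

    lam = config.local_fraction
    n = config.n_units
    targets = model.target_units
    W_solve = model.weights.copy()
    W_solve[targets, :] = 0.0  # targets receive nothing during the solve
    mixing = np.linalg.inv(np.eye(n) - W_solve)

    design = block_design_table(config)
    if include_bold:
        n_tp = int(design["onset"].iloc[-1] + design["duration"].iloc[-1] + 20)
        X = build_design(design, n_timepoints=n_tp, dt=1.0, intercept=False)
        regressors = X.matrix  # time x condition

    bold_list, act_list, flow_list, local_list = [], [], [], []
    for p in range(config.n_participants):
        rng = np.random.default_rng([config.seed, 37, p])
        D = condition_drives(model, config, rng)
        x = mixing @ D  # zero at target units
        flow = model.weights @ x  # the pure activity-flow component

        local = np.zeros_like(flow)
        for cx in model.complexes.values():
            conds = list(config.category_conditions[cx["category"]])
            for t in cx["units"]:
                local[t, conds] = flow[t, conds].mean()

        truth = x.copy()
        truth[targets, :] = (1 - lam) * flow[targets, :] + lam * local[targets, :]

        act_list.append(truth)
        flow_list.append(flow)
        local_list.append(local)
        if include_bold:
            bold = truth @ regressors.T
            bold += rng.normal(0.0, config.noise_sd, size=bold.shape)
            bold_list.append(bold)

    return SyntheticDataset(
        config=config,
        model=model,
        design=design,
        task_bold=bold_list,
        truth_activations=act_list,
        truth_flow_component=flow_list,
        truth_local_component=local_list,
    )


def sem_timeseries(
    W: np.ndarray, n_timepoints: int, noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``x = (I - W)^{-1} e`` columns for an arbitrary weight matrix."""
    n = W.shape[0]
    rho = max(abs(np.linalg.eigvals(W)))
    if rho >= 1.0:
        raise NonStationaryError(f"spectral radius {rho:.3f} >= 1")
    e = rng.normal(0.0, noise_sd, size=(n, n_timepoints))
    return np.linalg.solve(np.eye(n) - W, e)


def random_sparse_sem(
    n_units: int,
    density: float,
    rng: np.random.Generator,
    weight_range: tuple = (0.35, 0.65),
) -> np.ndarray:
    """Random sparse acyclic SEM weights with signed magnitudes.

    Edges are placed below the diagonal with the given density and
    weights drawn uniformly from ``weight_range`` with random sign, a
    standard benchmark for skeleton-recovery of connectivity estimators.
    """
    W = np.zeros((n_units, n_units))
    lo, hi = weight_range
    for j in range(n_units):
        for i in range(j):
            if rng.random() < density:
                W[j, i] = rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)
    return W


def simulate_dataset(config: SimulationConfig,
                     include_bold: bool = True) -> SyntheticDataset:
    """Ground truth + rest + task in one call (fully seed-determined)."""
    model = generate_ground_truth(config)
    ds = simulate_task(model, config, include_bold=include_bold)
    ds.rest_timeseries = simulate_rest(model, config)
    return ds
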