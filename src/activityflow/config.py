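"""Simulation configuration and shared error types."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

#: The 12 functional-network labels used to partition units, following the
#: naming of large-scale cortical network partitions (primary/secondary
#: visual, somatomotor, cingulo-opercular, dorsal attention, language,
#: frontoparietal, auditory, default mode, posterior/ventral multimodal,
#: orbito-affective).
NETWORK_LABELS: Tuple[str, ...] = (
    "VIS1", "VIS2", "SMN", "CON", "DAN", "LAN",
    "FPN", "AUD", "DMN", "PMM", "VMM", "OAN",
)

#: Visual categories and the complexes that respond to them.
CATEGORIES: Tuple[str, ...] = ("body", "face", "place", "tool")

#: Complex name -> (host network, category).
COMPLEX_SPECS: Dict[str, Tuple[str, str]] = {
    "EBA_FBA": ("VIS2", "body"),
    "FFA_pSTS": ("LAN", "face"),
    "PPA_RSC": ("DMN", "place"),
    "LOC": ("DAN", "tool"),
}


class InvalidConfigError(ValueError):
    """A simulation configuration that cannot be realized."""


class NonStationaryError(ValueError):
    """Weight matrix has spectral radius >= 1; stationary rest undefined."""


class DivergenceError(RuntimeError):
    """Iterated activity-flow mapping diverged."""


def _default_category_conditions() -> Dict[str, Tuple[int, int]]:
    # 8 of 24 conditions carry category content: a 0-back/2-back pair per
    # category, averaged downstream.
    return {
        "body": (0, 1),
        "face": (2, 3),
        "place": (4, 5),
        "tool": (6, 7),
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic ground-truth world.

    Attributes
    ----------
    n_units:
        Number of cortical units (regions or vertices). Must be >= 24 so
        that 12 networks, 4 category-selective complexes, a V1 source set
        and per-category preferred sources can all be allocated.
    n_timepoints_rest, n_runs_rest:
        Length and count of resting-state runs per participant
        (time-point units).
    n_participants:
        Participants to simulate; each gets independent rest noise, task
        drive jitter and local components.
    n_conditions:
        Task conditions (default 24, of which 8 encode the four visual
        categories as 0-back/2-back pairs).
    category_conditions:
        Map category -> condition indices encoding it.
    local_fraction:
        Fraction (lambda in [0, 1]) of a target complex's activation
        generated within-region instead of by distributed activity flow.
    noise_sd:
        SD of rest innovations and task BOLD measurement noise.
    spectral_radius:
        Target spectral radius the weight matrix is rescaled to. Kept
        below 1 so the stationary rest model is defined (high global
        coupling, no self-coupling).
    act_noise_sd:
        SD of participant-level perturbation added to true activations
        (models idiosyncratic evoked amplitudes).
    seed:
        Seed that fully determines every generated quantity.
    """

    n_units: int = 48
    n_timepoints_rest: int = 500
    n_runs_rest: int = 2
    n_participants: int = 10
    n_conditions: int = 24
    category_conditions: Dict[str, Tuple[int, ...]] = field(
        default_factory=_default_category_conditions
    )
    local_fraction: float = 0.0
    noise_sd: float = 0.2
    spectral_radius: float = 0.6
    act_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 24:
            raise InvalidConfigError(
                f"n_units={self.n_units} too small: need >= 24 to allocate "
                "12 networks, 4 complexes and a V1 source set"
            )
        if not 0.0 <= self.local_fraction <= 1.0:
            raise InvalidConfigError(
                f"local_fraction={self.local_fraction} outside [0, 1]"
            )
        if self.n_conditions < 8:
            raise InvalidConfigError("need at least 8 conditions for 4 categories")
        for cat, conds in self.category_conditions.items():
            if any(c >= self.n_conditions or c < 0 for c in conds):
                raise InvalidConfigError(
                    f"category {cat!r} condition indices {conds} out of range "
                    f"for n_conditions={self.n_conditions}"
                )
        if not 0.0 < self.spectral_radius < 1.0:
            raise InvalidConfigError("spectral_radius must lie in (0, 1)")
        if self.n_runs_rest < 1 or self.n_timepoints_rest < 2:
            raise InvalidConfigError("rest runs/timepoints too small")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["category_conditions"] = {
            k: list(v) for k, v in self.category_conditions.items()
        }
        return d
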