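"""Drug response profiles over the cell-state plane and dosing policies.

Each drug kills cells at a rate proportional to its concentration and to a
state-dependent response profile psi(y) in [0, 1].  BRAF/MEK inhibition is
centered on the proliferative state, stretches into the invasive state and
is attenuated toward the pigmented (NW) region; the hypothetical cancer
treatment (HCT) targets the invasive and URC states with a wider span.

Three dosing policies are provided: continuous single-drug dosing,
sequential two-drug combination with a fixed switch day, and adaptive
(intermittent) dosing that switches off below a lower burden threshold and
back on above an upper threshold, with hysteresis in between.  Decisions
are taken at a fixed cadence (default: daily).  At most one drug is dosed
at any time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ContractViolationError
from .geometry import SubpopulationAtlas, _check_inside

DRUG_IDS = ("BRAF_MEKi", "HCT")
_ALIASES = {
    "braf_meki": "BRAF_MEKi",
    "braf/meki": "BRAF_MEKi",
    "braf": "BRAF_MEKi",
    "hct": "HCT",
}


def canonical_drug_id(drug: str) -> str:
    if drug in DRUG_IDS:
        return drug
    key = str(drug).lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise ConfigurationError(f"unknown drug id {drug!r}; expected one of {DRUG_IDS}")


@dataclass(frozen=True)
class DrugProfile:
    """Gaussian-mixture response profile of one drug, normalized to peak 1.

    ``components`` are (center, weight) or (center, weight, width) tuples;
    centers may be anchor names (resolved against the atlas) or explicit
    structural points, and a component without its own width uses the
    profile-level ``width``.  An optional multiplicative attenuation dip
    carves reduced efficacy around a center.
    """

    components: tuple = (("proliferative", 1.0),)
    width: float = 0.20
    attenuation: tuple | None = None  # (center, width, depth)
    delta: float = 1.0                # kill rate per unit drug per day

    def __post_init__(self):
        if not self.components:
            raise ConfigurationError("drug profile needs at least one component")
        weights = [comp[1] for comp in self.components]
        if any(not (0 <= w <= 1) for w in weights):
            raise ConfigurationError("component weights must lie in [0, 1]")
        if max(weights) != 1.0:
            raise ConfigurationError("profiles are normalized to peak 1: max weight must be 1")
        if not self.width > 0:
            raise ConfigurationError("component width must be > 0")
        if any(len(comp) > 2 and not comp[2] > 0 for comp in self.components):
            raise ConfigurationError("per-component widths must be > 0")
        if self.attenuation is not None:
            _, a_width, a_depth = self.attenuation
            if not a_width > 0:
                raise ConfigurationError("attenuation width must be > 0")
            if not (0 <= a_depth <= 1):
                raise ConfigurationError("attenuation depth must lie in [0, 1]")
        if self.delta < 0:
            raise ConfigurationError("kill coefficient delta must be >= 0")


def default_response_params() -> dict:
    """Reference response profiles for the two modeled drugs."""
    return {
        "BRAF_MEKi": DrugProfile(
            components=(("proliferative", 1.0, 0.18), ("invasive", 0.5, 0.10)),
            width=0.18,
            attenuation=("pigmented", 0.15, 0.5),
            delta=1.0,
        ),
        "HCT": DrugProfile(
            components=(("invasive", 1.0), ("URC", 1.0)),
            width=0.25,
            attenuation=None,
            delta=1.0,
        ),
    }


def _resolve(center, atlas: SubpopulationAtlas) -> np.ndarray:
    if isinstance(center, str):
        return atlas.position(center)
    return np.asarray(center, dtype=float)


def _gauss(y, center, sigma):
    d2 = np.sum((y - center) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * sigma * sigma))


def drug_response(y, drug: str, atlas: SubpopulationAtlas, params: dict) -> np.ndarray:
    """Response psi_drug(y) in [0, 1] at structural point(s) y."""
    drug = canonical_drug_id(drug)
    profile: DrugProfile = params[drug]
    y = _check_inside(y, atlas.extent)
    psi = 0.0
    for comp in profile.components:
        center, w = comp[0], comp[1]
        sigma = comp[2] if len(comp) > 2 else profile.width
        psi = psi + w * _gauss(y, _resolve(center, atlas), sigma)
    if profile.attenuation is not None:
        center, a_width, a_depth = profile.attenuation
        psi = psi * (1.0 - a_depth * _gauss(y, _resolve(center, atlas), a_width))
    return np.clip(psi, 0.0, 1.0)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Dosing policy: which drug(s), when, and at what rate."""

    mode: str = "continuous"  # none | continuous | sequential | adaptive
    drug_order: tuple[str, ...] = ("BRAF_MEKi",)
    dose_rate: dict = field(default_factory=lambda: {"BRAF_MEKi": 0.7, "HCT": 0.8})
    switch_time: float = 110.0
    decision_interval: float = 1.0
    lower_threshold: float = 0.3
    upper_threshold: float = 0.5
    start_time: float = 50.0

    def __post_init__(self):
        if self.mode not in ("none", "continuous", "sequential", "adaptive"):
            raise ConfigurationError(f"unknown treatment mode {self.mode!r}")
        object.__setattr__(
            self, "drug_order", tuple(canonical_drug_id(d) for d in self.drug_order)
        )
        if self.mode == "sequential" and len(self.drug_order) < 2:
            raise ConfigurationError("sequential mode needs two drugs in drug_order")
        if self.mode in ("continuous", "adaptive") and len(self.drug_order) < 1:
            raise ConfigurationError(f"{self.mode} mode needs a drug in drug_order")
        if not (0 < self.lower_threshold < self.upper_threshold):
            raise ConfigurationError(
                "thresholds must satisfy 0 < lower_threshold < upper_threshold"
            )
        if not self.decision_interval > 0:
            raise ConfigurationError("decision_interval must be > 0")
        if self.mode == "sequential" and not self.switch_time > self.start_time:
            raise ConfigurationError("sequential switch_time must exceed start_time")
        if any(r < 0 for r in self.dose_rate.values()):
            raise ConfigurationError("dose rates must be >= 0")


def dose_schedule(t: float, schedule: TreatmentSchedule, adaptive_state: bool = True):
    """Per-drug administration rates (dose_B, dose_H) at day t."""
    if t < 0:
        raise ContractViolationError(f"time must be >= 0, got {t}")
    doses = {d: 0.0 for d in DRUG_IDS}
    if schedule.mode == "none" or t < schedule.start_time:
        return doses["BRAF_MEKi"], doses["HCT"]
    if schedule.mode == "continuous":
        active = schedule.drug_order[0]
    elif schedule.mode == "sequential":
        active = schedule.drug_order[0] if t < schedule.switch_time else schedule.drug_order[1]
    elif schedule.mode == "adaptive":
        active = schedule.drug_order[0] if adaptive_state else None
    if active is not None:
        doses[active] = float(schedule.dose_rate.get(active, 0.0))
    return doses["BRAF_MEKi"], doses["HCT"]


def adaptive_decision(
    current_mass: float,
    initial_mass: float,
    prev_state: bool,
    schedule: TreatmentSchedule,
) -> bool:
    """On/off decision with hysteresis, relative to the initial burden."""
    if not initial_mass > 0:
        raise ContractViolationError("initial mass must be positive")
    if current_mass < 0:
        raise ContractViolationError("current mass must be nonnegative")
    if current_mass > schedule.upper_threshold * initial_mass:
        return True
    if current_mass < schedule.lower_threshold * initial_mass:
        return False
    return bool(prev_state)
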