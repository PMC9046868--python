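"""Scenario configuration: loading, validation, defaults and presets.

A scenario is one structured YAML file.  Missing keys are filled from the
versioned reference parameter set shipped with the package
(``data/reference.yaml``); unknown keys are rejected with a suggestion for
the nearest valid name.  The merged tree round-trips losslessly and its
canonical dump is hashed for provenance.
"""

from __future__ import annotations

import copy
import difflib
import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .environment import EnvironmentParams
from .errors import ConfigurationError
from .geometry import GridSpec, SubpopulationAtlas, build_grids
from .spatial_fluxes import SpatialFluxParams
from .structural_fluxes import StructuralFluxParams
from .treatment import DrugProfile, TreatmentSchedule


def reference_defaults() -> dict:
    """The packaged reference configuration tree (deep copy)."""
    text = resources.files("melsim.data").joinpath("reference.yaml").read_text()
    return yaml.safe_load(text)


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            hint = difflib.get_close_matches(str(key), [str(k) for k in defaults], n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigurationError(f"unknown config key {where!r}{extra}")
        if isinstance(defaults[key], dict) and not _is_leaf_dict(where):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config key {where!r} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = copy.deepcopy(value)
    return out


#: subtrees whose contents are free-form values, not schema-checked key by key
_LEAF_DICTS = (
    "atlas.anchors",
    "drug_response.BRAF_MEKi.attenuation",
    "drug_response.HCT.attenuation",
)


def _is_leaf_dict(path: str) -> bool:
    return any(path == p or path.startswith(p + ".") for p in _LEAF_DICTS)


@dataclass
class ScenarioConfig:
    """A validated scenario: the merged config tree plus typed builders."""

    tree: dict

    # -- provenance ---------------------------------------------------
    def as_dict(self) -> dict:
        return copy.deepcopy(self.tree)

    def dump(self) -> str:
        return yaml.safe_dump(self.tree, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.dump().encode()).hexdigest()[:16]

    def section(self, name: str) -> dict:
        return copy.deepcopy(self.tree[name])

    # -- typed builders ----------------------------------------------
    def grid(self) -> GridSpec:
        return build_grids(self.tree["grid"])

    def atlas(self) -> SubpopulationAtlas:
        return SubpopulationAtlas.from_dict(
            self.tree["atlas"], extent=float(self.tree["grid"]["structural_extent"])
        )

    def structural_params(self) -> StructuralFluxParams:
        return StructuralFluxParams(**self.tree["structural_fluxes"])

    def spatial_params(self) -> SpatialFluxParams:
        return SpatialFluxParams(**self.tree["spatial_fluxes"])

    def environment_params(self) -> EnvironmentParams:
        return EnvironmentParams(**self.tree["environment"])

    def growth_params(self):
        from .solver import GrowthParams

        return GrowthParams(**self.tree["source"])

    def response_params(self) -> dict:
        out = {}
        for drug, spec in self.tree["drug_response"].items():
            att = spec.get("attenuation")
            out[drug] = DrugProfile(
                components=tuple(
                    (c["center"], float(c["weight"]), float(c["width"]))
                    if "width" in c
                    else (c["center"], float(c["weight"]))
                    for c in spec["components"]
                ),
                width=float(spec["width"]),
                attenuation=None if att is None else (att["center"], float(att["width"]), float(att["depth"])),
                delta=float(spec["delta"]),
            )
        return out

    def model_params(self):
        from .solver import ModelParams

        return ModelParams(
            structural=self.structural_params(),
            spatial=self.spatial_params(),
            environment=self.environment_params(),
            growth=self.growth_params(),
            response=self.response_params(),
        )

    def schedule(self) -> TreatmentSchedule:
        t = self.tree["treatment"]
        return TreatmentSchedule(
            mode=t["mode"],
            drug_order=tuple(t["drug_order"]),
            dose_rate=dict(t["dose_rate"]),
            switch_time=float(t["switch_time"]),
            decision_interval=float(t["decision_interval"]),
            lower_threshold=float(t["lower_threshold"]),
            upper_threshold=float(t["upper_threshold"]),
            start_time=float(t["start_time"]),
        )

    def validate(self) -> "ScenarioConfig":
        """Instantiate every typed object once, surfacing any bad value."""
        self.grid()
        self.atlas()
        self.model_params()
        self.schedule()
        return self


def load_config(path=None, overrides: dict | None = None) -> ScenarioConfig:
    """Load and validate a scenario configuration.

    ``path`` may be None (pure reference defaults); ``overrides`` is an
    optional override tree applied after the file.
    """
    tree = reference_defaults()
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        tree = _merge(tree, user)
    if overrides:
        tree = _merge(tree, overrides)
    return ScenarioConfig(tree).validate()


def save_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(config.dump())


def as_scenario(config) -> ScenarioConfig:
    """Coerce a ScenarioConfig, override dict, or None into a ScenarioConfig."""
    if isinstance(config, ScenarioConfig):
        return config
    if config is None:
        return load_config()
    if isinstance(config, dict):
        return load_config(overrides=config)
    return load_config(path=config)


#: The five scenario presets studied with the reference parameter set.
PRESETS: dict[str, dict] = {
    "no-treatment": {"treatment": {"mode": "none"}},
    "continuous-braf": {"treatment": {"mode": "continuous", "drug_order": ["BRAF_MEKi"]}},
    "continuous-hct": {"treatment": {"mode": "continuous", "drug_order": ["HCT"]}},
    "braf-then-hct": {
        "treatment": {"mode": "sequential", "drug_order": ["BRAF_MEKi", "HCT"]}
    },
    "hct-then-braf": {
        "treatment": {"mode": "sequential", "drug_order": ["HCT", "BRAF_MEKi"]}
    },
    "adaptive-braf": {"treatment": {"mode": "adaptive", "drug_order": ["BRAF_MEKi"]}},
}


def preset(name: str, extra: dict | None = None) -> ScenarioConfig:
    """Build a preset scenario, optionally with further overrides."""
    if name not in PRESETS:
        hint = difflib.get_close_matches(name, PRESETS, n=1)
        extra_msg = f"; did you mean {hint[0]!r}?" if hint else ""
        raise ConfigurationError(f"unknown preset {name!r}{extra_msg}")
    overrides = copy.deepcopy(PRESETS[name])
    if extra:
        for key, val in extra.items():
            if key in overrides and isinstance(overrides[key], dict) and isinstance(val, dict):
                overrides[key] = {**overrides[key], **copy.deepcopy(val)}
            else:
                overrides[key] = copy.deepcopy(val)
    return load_config(overrides=overrides)
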