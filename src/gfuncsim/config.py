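"""Scenario configuration: strict YAML schema, presets, model builders.

A scenario fully specifies a run: which G-function family, its
parameters, the initial clones (u0, x0, k), the integration settings and
an optional landscape request.  Presets cover every bundled study
scenario: the control configuration (x0=10, v0=3, K_m=100, r=0.25,
sigma_k2=12.5, k=0.2), its four tripled-parameter variants, the
narrow/broad-niche competition pair, and the drug model with and without
treatment onset at t=600.

The drug presets need a maximal kill rate ``s_m`` and drug generality
``sigma_t2``; these two defaults (s_m=0.2, sigma_t2=0.8) are this
package's own choice, made so that treatment onset turns v=0 from the
fitness peak into a fitness minimum (s_m/sigma_t2 > r*x/(K_m*sigma_k2)
at onset).  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import yaml

from .core import CommunityState, SimulationSpec
from .exceptions import ConfigError
from .models import (
    BasicGrowthModel,
    BasicGrowthParams,
    CompetitionModel,
    CompetitionParams,
    DrugParams,
    DrugResistanceModel,
    GFunctionModel,
)

__all__ = [
    "CloneInit",
    "LandscapeRequest",
    "ScenarioConfig",
    "preset",
    "PRESET_NAMES",
    "build_model",
    "initial_community",
    "run_scenario",
]

ModelParams = Union[BasicGrowthParams, CompetitionParams, DrugParams]

_FAMILIES = ("basic", "competition", "drug")


@dataclass(frozen=True)
class CloneInit:
    u0: float
    x0: float
    k: float


@dataclass(frozen=True)
class LandscapeRequest:
    v_min: float = -10.0
    v_max: float = 10.0
    n_points: int = 401
    times: Optional[tuple[float, ...]] = None

    def grid(self) -> np.ndarray:
        return np.linspace(self.v_min, self.v_max, self.n_points)


@dataclass
class ScenarioConfig:
    model_family: str
    params: ModelParams
    clones: list[CloneInit]
    spec: SimulationSpec
    landscape: Optional[LandscapeRequest] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.model_family not in _FAMILIES:
            raise ConfigError(
                f"unknown model_family {self.model_family!r}; expected one of {_FAMILIES}"
            )
        if not self.clones:
            raise ConfigError("scenario must define at least one clone")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        params: dict = {}
        if self.model_family == "basic":
            b = self.params
        elif self.model_family == "competition":
            b = self.params.base
            params["sigma_a2"] = self.params.sigma_a2
        else:
            b = self.params.base
            params.update(
                s_m=self.params.s_m,
                u_opt=self.params.u_opt,
                sigma_t2=self.params.sigma_t2,
                time_G=self.params.time_G,
            )
        params = {"r": b.r, "K_m": b.K_m, "sigma_k2": b.sigma_k2, **params}
        spec: dict = {
            "t_end": self.spec.t_end,
            "rel_tol": self.spec.rel_tol,
            "abs_tol": self.spec.abs_tol,
        }
        if self.spec.max_step is not None:
            spec["max_step"] = self.spec.max_step
        if self.spec.output_times is not None:
            spec["output_times"] = [float(t) for t in self.spec.output_times]
        if self.spec.strategy_bounds is not None:
            spec["strategy_bounds"] = list(self.spec.strategy_bounds)
        if self.spec.extinction_threshold is not None:
            spec["extinction_threshold"] = self.spec.extinction_threshold
        doc = {
            "name": self.name,
            "model_family": self.model_family,
            "params": params,
            "clones": [{"u0": c.u0, "x0": c.x0, "k": c.k} for c in self.clones],
            "spec": spec,
        }
        if self.landscape is not None:
            ls: dict = {
                "v_min": self.landscape.v_min,
                "v_max": self.landscape.v_max,
                "n_points": self.landscape.n_points,
            }
            if self.landscape.times is not None:
                ls["times"] = list(self.landscape.times)
            doc["landscape"] = ls
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioConfig":
        doc = dict(doc)
        _check_keys("scenario", doc, {"name", "model_family", "params", "clones", "spec", "landscape"})
        family = doc.get("model_family")
        if family not in _FAMILIES:
            raise ConfigError(f"unknown model_family {family!r}; expected one of {_FAMILIES}")
        praw = dict(doc.get("params") or {})
        base_keys = {"r", "K_m", "sigma_k2"}
        extra = {"competition": {"sigma_a2"}, "drug": {"s_m", "u_opt", "sigma_t2", "time_G"}}.get(
            family, set()
        )
        _check_keys("params", praw, base_keys | extra)
        for key in base_keys | extra:
            if key not in praw and key != "time_G":
                raise ConfigError(f"params missing required key {key!r} for family {family!r}")
        base = BasicGrowthParams(
            r=_num(praw, "r"), K_m=_num(praw, "K_m"), sigma_k2=_num(praw, "sigma_k2")
        )
        params: ModelParams
        if family == "basic":
            params = base
        elif family == "competition":
            params = CompetitionParams(base=base, sigma_a2=_num(praw, "sigma_a2"))
        else:
            params = DrugParams(
                base=base,
                s_m=_num(praw, "s_m"),
                u_opt=_num(praw, "u_opt"),
                sigma_t2=_num(praw, "sigma_t2"),
                time_G=_num(praw, "time_G") if "time_G" in praw else math.inf,
            )
        clones = []
        for i, craw in enumerate(doc.get("clones") or []):
            craw = dict(craw)
            _check_keys(f"clones[{i}]", craw, {"u0", "x0", "k"})
            clones.append(CloneInit(u0=_num(craw, "u0"), x0=_num(craw, "x0"), k=_num(craw, "k")))
        sraw = dict(doc.get("spec") or {})
        _check_keys(
            "spec",
            sraw,
            {"t_end", "rel_tol", "abs_tol", "max_step", "output_times",
             "strategy_bounds", "extinction_threshold"},
        )
        spec = SimulationSpec(
            t_end=_num(sraw, "t_end"),
            rel_tol=_num(sraw, "rel_tol") if "rel_tol" in sraw else 1e-8,
            abs_tol=_num(sraw, "abs_tol") if "abs_tol" in sraw else 1e-10,
            max_step=_num(sraw, "max_step") if "max_step" in sraw else None,
            output_times=sraw.get("output_times"),
            strategy_bounds=tuple(sraw["strategy_bounds"]) if "strategy_bounds" in sraw else None,
            extinction_threshold=sraw.get("extinction_threshold"),
        )
        landscape = None
        if doc.get("landscape") is not None:
            lraw = dict(doc["landscape"])
            _check_keys("landscape", lraw, {"v_min", "v_max", "n_points", "times"})
            landscape = LandscapeRequest(
                v_min=_num(lraw, "v_min") if "v_min" in lraw else -10.0,
                v_max=_num(lraw, "v_max") if "v_max" in lraw else 10.0,
                n_points=int(lraw.get("n_points", 401)),
                times=tuple(lraw["times"]) if "times" in lraw else None,
            )
        return cls(
            model_family=family,
            params=params,
            clones=clones,
            spec=spec,
            landscape=landscape,
            name=str(doc.get("name", "")),
        )

    def to_yaml(self, path=None):
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "ScenarioConfig":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" in text or ":" in text:
                doc = yaml.safe_load(text)
            else:
                with open(text) as fh:
                    doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError("scenario document must be a mapping")
        return cls.from_dict(doc)


def _check_keys(where: str, raw: dict, allowed: set) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)!r}")


def _num(raw: dict, key: str) -> float:
    try:
        return float(raw[key])
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"key {key!r} must be a number, got {raw.get(key)!r}") from exc
    except KeyError as exc:
        raise ConfigError(f"missing required key {key!r}") from exc


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: control configuration shared by every preset
_CONTROL = dict(r=0.25, K_m=100.0, sigma_k2=12.5)
_X0, _V0, _K_EVO = 10.0, 3.0, 0.2

#: drug-kill defaults; this package's own choice (see module docstring)
DRUG_S_M = 0.2
DRUG_SIGMA_T2 = 0.8

PRESET_NAMES = (
    "basic-control",
    "basic-high-r",
    "basic-high-Km",
    "basic-high-k",
    "basic-high-sigmak2",
    "competition-narrow",
    "competition-broad",
    "drug-no-treatment",
    "drug-treatment",
)


def preset(name: str) -> ScenarioConfig:
    """Fully populated configuration for one bundled scenario.

    Basic presets: one clone from (u0=3, x0=10, k=0.2); the "high"
    variants triple the named parameter.  Competition presets: two clones
    at u0 = +-3 with sigma_a2 = 2 (narrow niche) or 50 (broad).  Drug
    presets: one clone, horizon 1500, drug targeting u_opt=0, onset at
    t=600 or never.
    """
    if name not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")
    ctrl = dict(_CONTROL)
    clones = [{"u0": _V0, "x0": _X0, "k": _K_EVO}]
    spec = {"t_end": 1500.0}
    doc: dict = {"name": name, "model_family": "basic", "params": ctrl, "clones": clones, "spec": spec}
    if name == "basic-high-r":
        ctrl["r"] = 0.75
    elif name == "basic-high-Km":
        ctrl["K_m"] = 300.0
    elif name == "basic-high-k":
        clones[0]["k"] = 0.6
    elif name == "basic-high-sigmak2":
        ctrl["sigma_k2"] = 37.5
    elif name.startswith("competition"):
        doc["model_family"] = "competition"
        ctrl["sigma_a2"] = 2.0 if name == "competition-narrow" else 50.0
        doc["clones"] = [
            {"u0": _V0, "x0": _X0, "k": _K_EVO},
            {"u0": -_V0, "x0": _X0, "k": _K_EVO},
        ]
    elif name.startswith("drug"):
        doc["model_family"] = "drug"
        ctrl.update(
            s_m=DRUG_S_M,
            u_opt=0.0,
            sigma_t2=DRUG_SIGMA_T2,
            time_G=(600.0 if name == "drug-treatment" else math.inf),
        )
        doc["landscape"] = {"v_min": -6.0, "v_max": 6.0, "n_points": 481,
                            "times": [float(t) for t in np.linspace(0.0, 1500.0, 31)]}
    return ScenarioConfig.from_dict(doc)


# ---------------------------------------------------------------------------
# Builders / runner
# ---------------------------------------------------------------------------

def build_model(config: ScenarioConfig) -> GFunctionModel:
    if config.model_family == "basic":
        return BasicGrowthModel(config.params)
    if config.model_family == "competition":
        return CompetitionModel(config.params)
    return DrugResistanceModel(config.params)


def initial_community(config: ScenarioConfig) -> CommunityState:
    return CommunityState.from_arrays(
        [c.u0 for c in config.clones],
        [c.x0 for c in config.clones],
        [c.k for c in config.clones],
        t=0.0,
    )


def run_scenario(config: ScenarioConfig):
    """Simulate the configured scenario; returns the Trajectory."""
    from .core import simulate

    traj = simulate(build_model(config), initial_community(config), config.spec)
    traj.metadata["scenario"] = config.name or None
    return traj
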