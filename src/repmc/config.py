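"""YAML/JSON run-configuration loading.

A run file holds a ``scenario`` section plus one section per method, e.g.::

    seed: 7
    scenario:
      stochastic: false
      t_total: 10.0
    pmh:
      L: 250
      scale2: 0.04
      n_particles: 50
    npmc:
      M: 50
      K: 10
      n_particles: 50
    abc:
      tolerances: [40, 20, 10, 5, 3]
      J: 100
      max_draws_factor: 50

Unknown keys raise immediately: silently ignored options are a classic
source of irreproducible runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from . import abc_smc, model, npmc, pmh
from .experiments import ScenarioConfig

__all__ = [
    "load_config",
    "build_scenario",
    "build_pmh_config",
    "build_npmc_config",
    "build_abc_config",
]


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must hold a mapping")
    return data


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in [{name}] section: {sorted(unknown)}")


def build_scenario(section: dict | None) -> ScenarioConfig:
    section = dict(section or {})
    _check_keys(
        section,
        {
            "stochastic",
            "dyn_sigma",
            "h",
            "m0",
            "t_total",
            "sigma_y",
            "sigma_0",
            "theta_truth",
            "inference_dyn_sigma",
            "noise_convention",
        },
        "scenario",
    )
    grid = model.SimulationGrid(
        h=section.pop("h", 1e-3),
        m0=section.pop("m0", 20),
        t_total=section.pop("t_total", 80.0),
    )
    if "theta_truth" in section:
        section["theta_truth"] = tuple(float(v) for v in section["theta_truth"])
    return ScenarioConfig(grid=grid, **section)


def build_pmh_config(section: dict | None) -> pmh.PMHConfig:
    section = dict(section or {})
    _check_keys(section, {"L", "scale2", "diag", "n_particles"}, "pmh")
    if "diag" in section:
        section["diag"] = tuple(float(v) for v in section["diag"])
    return pmh.PMHConfig(**section)


def build_npmc_config(section: dict | None) -> npmc.NPMCConfig:
    section = dict(section or {})
    _check_keys(section, {"M", "K", "Mc", "n_particles"}, "npmc")
    return npmc.NPMCConfig(**section)


def build_abc_config(section: dict | None) -> abc_smc.ABCConfig:
    section = dict(section or {})
    _check_keys(
        section,
        {"tolerances", "J", "max_draws_factor", "kernel_scale", "batch_size"},
        "abc",
    )
    if "tolerances" in section:
        section["tolerances"] = tuple(float(v) for v in section["tolerances"])
    if "kernel_scale" in section:
        section["kernel_scale"] = float(section["kernel_scale"])
    return abc_smc.ABCConfig(**section)
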