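"""YAML run configuration: lake geometry, per-nutrient data paths and
priors, sampler settings, planning scenarios and baseline loads.

Example::

    geometry:
      volume: 44.3
    mcmc:
      n_iterations: 50000
      burn_in: 10000
      seed: 1
    nutrients:
      TN:
        data: data/tn.csv
        prior: {s_low: 1.0, s_high: 2.5}
        load: 58336          # current in-lake load, t/a
        baseline_emission: 66082
        uncontrolled_load: 12115
        alpha: 0.84
        targets_mgl: {2015: 2.2, 2020: 2.0}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inference import MCMCConfig, PriorSpec
from .model import LakeGeometry

__all__ = ["ConfigError", "NutrientConfig", "RunConfig", "load_run_config"]


class ConfigError(ValueError):
    """A malformed or incomplete run configuration."""


@dataclass(frozen=True)
class NutrientConfig:
    nutrient: str
    data: Path | None
    prior: PriorSpec
    load: float | None = None
    baseline_emission: float | None = None
    uncontrolled_load: float = 0.0
    alpha: float = 1.0
    targets_mgl: dict[int, float] = field(default_factory=dict)


@dataclass(frozen=True)
class RunConfig:
    geometry: LakeGeometry
    mcmc: MCMCConfig
    nutrients: dict[str, NutrientConfig]


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"missing required field {key!r} in {where}")
    return mapping[key]


def load_run_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    geometry_raw = _require(raw, "geometry", "config")
    try:
        geometry = LakeGeometry(volume=float(_require(geometry_raw, "volume", "geometry")))
        mcmc = MCMCConfig(**raw.get("mcmc", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    nutrients_raw = _require(raw, "nutrients", "config")
    if not nutrients_raw:
        raise ConfigError("config lists no nutrients")
    nutrients = {}
    for name, spec in nutrients_raw.items():
        where = f"nutrients.{name}"
        prior_raw = _require(spec, "prior", where)
        try:
            prior = PriorSpec(
                s_low=float(_require(prior_raw, "s_low", f"{where}.prior")),
                s_high=float(_require(prior_raw, "s_high", f"{where}.prior")),
                sigma_prior_shape=float(prior_raw.get("sigma_prior_shape", 0.001)),
                sigma_prior_rate=float(prior_raw.get("sigma_prior_rate", 0.001)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc
        targets = {int(k): float(v) for k, v in (spec.get("targets_mgl") or {}).items()}
        nutrients[name] = NutrientConfig(
            nutrient=name,
            data=Path(spec["data"]) if "data" in spec else None,
            prior=prior,
            load=float(spec["load"]) if "load" in spec else None,
            baseline_emission=(
                float(spec["baseline_emission"]) if "baseline_emission" in spec else None
            ),
            uncontrolled_load=float(spec.get("uncontrolled_load", 0.0)),
            alpha=float(spec.get("alpha", 1.0)),
            targets_mgl=targets,
        )
    return RunConfig(geometry=geometry, mcmc=mcmc, nutrients=nutrients)
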