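"""YAML run configuration: every unstated physical constant and threshold of
the model chain surfaces here so it can be audited and swept."""

from __future__ import annotations

import copy

import yaml

from .canopy_radiation import RadiationConfig
from .gpp_model import EnvScalarConfig
from .calibration import CalibrationConfig
from .params import ParameterSet
from .sceua import SceUaSettings
from .synthetic_flux import MeteoParams, SyntheticSiteSpec, default_true_params

__all__ = ["DEFAULT_CONFIG", "load_config", "site_spec", "radiation_config",
           "env_config", "calibration_config"]

DEFAULT_CONFIG: dict = {
    "version": 1,
    "seed": 0,
    "site": {
        "latitude": 51.08,
        "longitude": 10.45,
        "canopy_height": 23.0,
        "measurement_height": 44.0,
        "years": 3,
        "lai_curve": [6.0, 120.0, 290.0, 10.0],
        "noise": [1.0, 0.3],
    },
    "meteo": {},           # overrides of MeteoParams fields
    "true_params": None,   # season -> [eps_msu, eps_msh, g_su, g_sh]
    "radiation": {},       # overrides of RadiationConfig fields
    "env_scalars": {},     # overrides of EnvScalarConfig fields
    "calibration": {
        "n_experiments": 50,
        "train_fraction": 0.70,
        "objective": "maximize_d",
        "gs_target": "tc",
        "sceua": {"max_evaluations": 3000, "tol": 1e-6},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Defaults merged with an optional YAML file (file wins)."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def site_spec(cfg: dict, seed=None) -> SyntheticSiteSpec:
    site = cfg["site"]
    true = cfg.get("true_params")
    if true:
        params = {s: ParameterSet(*v, season_label=s) for s, v in true.items()}
    else:
        params = default_true_params()
    return SyntheticSiteSpec(
        latitude=site["latitude"],
        longitude=site["longitude"],
        canopy_height=site["canopy_height"],
        measurement_height=site["measurement_height"],
        years=site["years"],
        true_params=params,
        lai_curve=tuple(site["lai_curve"]),
        meteo_params=MeteoParams(**cfg.get("meteo", {})),
        noise=tuple(site["noise"]),
        seed=cfg["seed"] if seed is None else seed,
    )


def radiation_config(cfg: dict) -> RadiationConfig:
    return RadiationConfig(**cfg.get("radiation", {}))


def env_config(cfg: dict) -> EnvScalarConfig:
    return EnvScalarConfig(**cfg.get("env_scalars", {}))


def calibration_config(cfg: dict, seed=None, **overrides) -> CalibrationConfig:
    c = dict(cfg.get("calibration", {}))
    sce = c.pop("sceua", {})
    c.update({k: v for k, v in overrides.items() if v is not None})
    return CalibrationConfig(
        sceua=SceUaSettings(**sce),
        seed=cfg["seed"] if seed is None else seed,
        **c,
    )
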