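"""TOML configuration loading with strict key validation."""

from __future__ import annotations

import tomllib
from importlib import resources
from pathlib import Path

from .cell_cycle import CellCycleParams
from .nicd import NicdParams

__all__ = ["load_config", "default_config", "cc_from_config", "kinetics_from_config"]

_KNOWN = {
    "cell_cycle": {"d_g1", "d_s", "d_g2", "d_m", "w2", "w1", "release_point",
                   "dispersion", "ramp_width"},
    "kinetics": {"alpha", "delta_n", "delta_p", "k1", "k2", "k_base"},
    "treatments": {"inhibition", "duration"},
    "experiment": {"n_cells", "t_start", "t_stop", "t_step"},
    "clock": {"n_oscillators", "period_ref", "beta", "n_periods"},
    "synth": {"base_period", "wavefront_speed", "commitment_lag", "period_factor",
              "noise_cv", "n_somites"},
}


class ConfigError(ValueError):
    pass


def _validate(cfg: dict) -> dict:
    for section, keys in cfg.items():
        if section not in _KNOWN:
            raise ConfigError(f"unknown config section [{section}]")
        unknown = set(keys) - _KNOWN[section]
        if unknown:
            raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cfg


def default_config() -> dict:
    text = resources.files("nicdclock").joinpath("data/default.toml").read_text()
    return _validate(tomllib.loads(text))


def load_config(path: str | Path | None) -> dict:
    """Load a TOML config, layered over the packaged defaults."""
    cfg = default_config()
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        user = _validate(tomllib.loads(p.read_text()))
        for section, keys in user.items():
            cfg.setdefault(section, {}).update(keys)
    return cfg


def cc_from_config(cfg: dict) -> CellCycleParams:
    c = dict(cfg.get("cell_cycle", {}))
    for w in ("w1", "w2"):
        if w in c:
            c[w] = tuple(c[w])
    return CellCycleParams(**c)


def kinetics_from_config(cfg: dict) -> NicdParams:
    return NicdParams(**cfg.get("kinetics", {}))
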