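"""Run configuration: YAML files with the parameter names of the two models.

A config selects the model kind and overrides any default parameter by its
symbol name (``tau_E``, ``theta_E``, ``J_EA``, ``sigma_E``, ...).  Values may
be plain numbers (interpreted in each parameter's native unit: ms for time
constants and delays, mV for potentials and neuronal couplings, Hz for
gains, s for rate-model couplings) or strings with an explicit unit suffix
(``"10 ms"``, ``"0.5 s"``, ``"3 mV"``, ``"1 Hz"``), which are validated
against the parameter's expected dimension.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path

import yaml

from .rate_model import RateParams
from .spiking_model import SpikingParams

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration (unknown key, bad unit, bad value)."""


# dimension of each parameter family: how a unit suffix must read
_TIME_MS = {"ms": 1.0, "s": 1000.0}
_VOLT = {"mV": 1.0}
_RATE = {"Hz": 1.0}
_COUPLING_S = {"s": 1.0, "ms": 1e-3}
_PLAIN = {}

_RATE_UNITS = {
    **{k: _TIME_MS for k in ("tau_E", "tau_I", "tau_A", "tau_a", "tau_ou")},
    **{k: _PLAIN for k in ("theta_E", "theta_I", "theta_A", "sigma")},
    **{k: _RATE for k in ("g_E", "g_I", "g_A")},
    **{k: _COUPLING_S for k in ("beta", "J_EE", "J_EI", "J_EA", "J_IE", "J_II", "J_IA", "J_AE", "J_AI", "J_AA")},
}

_SPIKING_UNITS = {
    **{k: _TIME_MS for k in (
        "tau_E", "tau_I", "tau_A", "tau_a", "tau_bar_E", "tau_bar_I", "tau_bar_A",
        "tau_r_E", "tau_r_I", "tau_r_A", "tau_d_E", "tau_d_I", "tau_d_A",
        "d_min_E", "d_max_E", "d_min_I", "d_max_I", "d_min_A", "d_max_A", "beta",
    )},
    **{k: _VOLT for k in ("J_EE", "J_EI", "J_IE", "J_II", "J_EA", "J_IA",
                          "sigma_E", "sigma_I", "V_r", "V_th", "V_L_E", "V_L_I")},
    **{k: _PLAIN for k in ("J_AA", "J_AE", "J_AI", "K_a", "sigma_A",
                           "G_r", "G_th", "G_L", "N_E", "N_I", "N_A",
                           "frac_glio_targets", "frac_astro_receivers")},
}

_VALUE_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Z]*)\s*$")


def _parse_value(key: str, raw, units: dict) -> float:
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return float(raw)
    if isinstance(raw, str):
        m = _VALUE_RE.match(raw)
        if not m:
            raise ConfigError(f"cannot parse value {raw!r} for key {key!r}")
        num, suffix = m.groups()
        try:
            val = float(num)
        except ValueError as err:
            raise ConfigError(f"cannot parse number in {raw!r} for key {key!r}") from err
        if not suffix:
            return val
        allowed = units.get(key, {})
        if suffix not in allowed:
            raise ConfigError(
                f"wrong unit suffix {suffix!r} for key {key!r}"
                + (f" (expected one of {sorted(allowed)})" if allowed else " (dimensionless)")
            )
        return val * allowed[suffix]
    raise ConfigError(f"invalid value type for key {key!r}: {type(raw).__name__}")


@dataclass
class RunConfig:
    kind: str  # "rate" | "spiking"
    params: object  # RateParams | SpikingParams
    duration: float = 20_000.0  # ms
    dt: float = 0.1  # ms
    seed: int = 0
    no_astro: bool = False
    out: str | None = None
    overrides: dict = dataclasses.field(default_factory=dict)

    @property
    def effective_params(self):
        return self.params.without_astro() if self.no_astro else self.params


_META_KEYS = {"kind", "duration", "dt", "seed", "no_astro", "out", "duration_s"}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown parameter names, wrong unit suffixes and non-positive time
    constants are rejected with errors naming the offending key.  Defaults
    are the reference parameter sets of the two models.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as err:
            raise ConfigError(f"cannot parse YAML config {path}: {err}") from err
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    kind = data.get("kind", "rate")
    if kind not in ("rate", "spiking"):
        raise ConfigError(f"unknown model kind {kind!r} (expected 'rate' or 'spiking')")
    cls = RateParams if kind == "rate" else SpikingParams
    units = _RATE_UNITS if kind == "rate" else _SPIKING_UNITS
    valid = {f.name for f in dataclasses.fields(cls)}
    overrides = {}
    for key, raw in data.items():
        if key in _META_KEYS:
            continue
        if key not in valid:
            raise ConfigError(f"unknown parameter {key!r} for model kind {kind!r}")
        val = _parse_value(key, raw, units)
        if key.startswith("N_"):
            val = int(round(val))
        overrides[key] = val
    try:
        params = cls(**overrides)
    except ValueError as err:
        raise ConfigError(str(err)) from err

    duration = data.get("duration", 20_000.0)
    if "duration_s" in data:
        duration = float(data["duration_s"]) * 1000.0
    duration = _parse_value("duration", duration, {"duration": _TIME_MS})
    dt = _parse_value("dt", data.get("dt", 0.1), {"dt": _TIME_MS})
    if duration <= 0 or dt <= 0:
        raise ConfigError("duration and dt must be positive")
    return RunConfig(
        kind=kind,
        params=params,
        duration=duration,
        dt=dt,
        seed=int(data.get("seed", 0)),
        no_astro=bool(data.get("no_astro", False)),
        out=data.get("out"),
        overrides=overrides,
    )
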