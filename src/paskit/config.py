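"""Plain-text key-value study configuration.

Format: one ``key = value`` per line, ``#`` comments, blank lines ignored,
and ``include <relative-path>`` to layer another file (included values are
defaults; the including file wins).  Prompt windows are comma-separated
``HH:MM-HH:MM`` strings.  Two presets ship with the package:

* ``pilot1`` — three windows (08-11, 11-14, 14-17), 28 days: the 4-week
  angle-estimation field design.
* ``ostracism`` — two windows (10-16, 16-22), 14 days, and the ostracism
  study's generative parameters for the simulator.
"""

from __future__ import annotations

import importlib.resources
from datetime import date
from pathlib import Path

from .errors import ConfigError
from .scheduler import PromptWindow, parse_window
from .simulator import GenerativeConfig

__all__ = ["load_config", "preset_path", "windows_from", "generative_config_from"]

_MAX_INCLUDE_DEPTH = 8


def load_config(path) -> dict[str, str]:
    """Parse a key-value config file, resolving ``include`` directives."""
    return _load(Path(path), depth=0)


def _load(path: Path, depth: int) -> dict[str, str]:
    if depth > _MAX_INCLUDE_DEPTH:
        raise ConfigError(f"include depth exceeds {_MAX_INCLUDE_DEPTH} at {path}")
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    values: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("include "):
            inc = _load((path.parent / line[len("include "):].strip()).resolve(), depth + 1)
            values = {**inc, **values}
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ConfigError(f"{path}:{lineno}: empty key")
        values[key] = val
    return values


def preset_path(name: str) -> Path:
    """Filesystem path of a shipped preset (``pilot1`` or ``ostracism``)."""
    ref = importlib.resources.files("paskit") / "presets" / f"{name}.cfg"
    if not ref.is_file():
        raise ConfigError(f"unknown preset {name!r}")
    return Path(str(ref))


def windows_from(values: dict[str, str]) -> list[PromptWindow]:
    try:
        spec = values["windows"]
    except KeyError:
        raise ConfigError("config lacks a 'windows' entry") from None
    return [parse_window(w) for w in spec.split(",") if w.strip()]


_FLOAT_KEYS = {
    "beta_baseline", "beta_single", "beta_group",
    "sd_intercept", "sd_single_slope", "sd_group_slope",
    "residual_sd", "target_icc", "rate_single", "rate_group",
    "response_prob", "attrition_hazard", "final_day_nonresponse",
    "angle_noise_sd", "press_jitter_sd", "overpress_rate", "tz_hours",
}
_INT_KEYS = {"n_persons", "n_days", "seed"}
_BOOL_KEYS = {"clip_to_scale", "include_familiarization"}


def generative_config_from(values: dict[str, str]) -> GenerativeConfig:
    """Build a :class:`~paskit.simulator.GenerativeConfig` from config text."""
    kwargs: dict = {}
    for key, val in values.items():
        if key == "windows":
            kwargs["prompt_windows"] = tuple(w.strip() for w in val.split(",") if w.strip())
        elif key == "start_date":
            kwargs["start_date"] = date.fromisoformat(val)
        elif key in _FLOAT_KEYS:
            kwargs[key] = None if val.lower() in ("none", "auto") else float(val)
        elif key in _INT_KEYS:
            kwargs[key] = int(val)
        elif key in _BOOL_KEYS:
            if val.lower() not in ("true", "false", "0", "1", "yes", "no", "on", "off"):
                raise ConfigError(f"cannot parse boolean {key} = {val!r}")
            kwargs[key] = val.lower() in ("true", "1", "yes", "on")
        else:
            raise ConfigError(f"unknown config key {key!r}")
    cfg = GenerativeConfig(**kwargs)
    cfg.validate()
    return cfg
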