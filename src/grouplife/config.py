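"""Flat YAML configuration files mirroring SimulationParams.

A config file is a flat key/value document; omitted keys take the baseline
defaults and unknown keys are rejected by name.  The LP:HP ratio may be
written either as a "L:H" string or a two-element list.  ``dump_config``
and ``load_config`` round-trip exactly, and every run writes an echo of
its effective configuration next to its outputs.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .engine import SimulationParams
from .landscape import AggregationMode, ConfigurationError

#: The recognised configuration keys, in file order.
CONFIG_KEYS: tuple[str, ...] = (
    "width",
    "height",
    "lp_hp_ratio",
    "aggregation_mode",
    "K_H",
    "K_L",
    "r_H",
    "r_L",
    "n_blue",
    "n_red",
    "init_pop",
    "c",
    "c1",
    "fusion_threshold",
    "cc_fraction",
    "decisions_per_year",
    "years",
    "seed",
    "n_reps",
)

_INT_KEYS = {
    "width",
    "height",
    "n_blue",
    "n_red",
    "fusion_threshold",
    "decisions_per_year",
    "years",
    "seed",
    "n_reps",
}
_FLOAT_KEYS = {"K_H", "K_L", "r_H", "r_L", "init_pop", "c", "c1", "cc_fraction"}


def _parse_ratio(value) -> tuple[int, int]:
    if isinstance(value, str):
        parts = value.split(":")
        if len(parts) != 2:
            raise ConfigurationError(f"lp_hp_ratio string must look like 'L:H', got {value!r}")
        value = parts
    try:
        lp, hp = (int(v) for v in value)
    except (TypeError, ValueError) as err:
        raise ConfigurationError(f"cannot parse lp_hp_ratio from {value!r}") from err
    return (lp, hp)


def params_from_mapping(doc: dict) -> SimulationParams:
    """Build validated SimulationParams from a flat mapping."""
    unknown = sorted(set(doc) - set(CONFIG_KEYS))
    if unknown:
        raise ConfigurationError(f"unknown configuration key(s): {', '.join(unknown)}")
    kwargs = {}
    for key, value in doc.items():
        if key == "lp_hp_ratio":
            kwargs[key] = _parse_ratio(value)
        elif key == "aggregation_mode":
            try:
                kwargs[key] = AggregationMode(value)
            except ValueError as err:
                raise ConfigurationError(
                    f"aggregation_mode must be one of "
                    f"{[m.value for m in AggregationMode]}, got {value!r}"
                ) from err
        elif key in _INT_KEYS:
            if not isinstance(value, int) or isinstance(value, bool):
                raise ConfigurationError(f"{key} must be an integer, got {value!r}")
            kwargs[key] = value
        elif key in _FLOAT_KEYS:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigurationError(f"{key} must be a number, got {value!r}")
            kwargs[key] = float(value)
    try:
        params = SimulationParams(**kwargs)
        params.validate()
    except ValueError as err:
        raise ConfigurationError(str(err)) from err
    return params


def params_to_mapping(params: SimulationParams) -> dict:
    """Flat mapping of the configuration keys, ratio as 'L:H'."""
    out = {}
    for key in CONFIG_KEYS:
        value = getattr(params, key)
        if key == "lp_hp_ratio":
            value = f"{value[0]}:{value[1]}"
        elif key == "aggregation_mode":
            value = value.value
        out[key] = value
    return out


def load_config(path: str | Path) -> SimulationParams:
    """Read a YAML config file into validated SimulationParams."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config file {path} must be a flat key/value mapping")
    return params_from_mapping(doc)


def dump_config(params: SimulationParams, path: str | Path) -> None:
    """Write the effective configuration as YAML."""
    Path(path).write_text(
        yaml.safe_dump(params_to_mapping(params), sort_keys=False, default_flow_style=False)
    )
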