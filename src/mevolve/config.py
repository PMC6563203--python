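"""TOML configuration loading with per-subcommand sections.

Precedence everywhere is: command-line flag > config-file value > built-in
default. Unknown sections or keys and type mismatches are rejected up front
so that a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Union

__all__ = ["CONFIG_SCHEMA", "load_config", "resolve"]

# key -> accepted type per section; bool precedes int checks nowhere needed here
CONFIG_SCHEMA: Dict[str, Dict[str, type]] = {
    "simulation": {
        "loci": int,
        "pop_small": int,
        "pop_large": int,
        "max_cycles": int,
        "rng_seed": int,
    },
    "run": {"seed": str, "target": str, "trajectory": str},
    "sweep": {
        "distances": str,
        "replicates": int,
        "mode": str,
        "out": str,
        "runs_out": str,
    },
    "invariance": {
        "distance": int,
        "permutations": int,
        "replicates": int,
        "alpha": float,
        "out": str,
    },
    "network": {
        "loci": int,
        "threshold": int,
        "out": str,
        "edges": str,
        "summary": str,
    },
    "pasc": {
        "fasta": str,
        "bin_width": float,
        "groups": str,
        "method": str,
        "out": str,
    },
    "make_fixture": {
        "clusters": int,
        "per_cluster": int,
        "length": int,
        "within": float,
        "between": float,
        "rng_seed": int,
        "out": str,
        "groups_out": str,
    },
}


def _check_type(section: str, key: str, value: Any, expected: type) -> Any:
    if expected is float and isinstance(value, int) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, expected) or isinstance(value, bool):
        raise ValueError(
            f"config key [{section}].{key} must be {expected.__name__}, "
            f"got {type(value).__name__} ({value!r})"
        )
    return value


def load_config(path: Optional[Union[str, Path]]) -> Dict[str, Dict[str, Any]]:
    """Load and validate a TOML config file; absent path means all defaults.

    Raises ``ValueError`` on unknown sections/keys (listing the valid ones)
    or on a type mismatch, naming the offending key.
    """
    if path is None:
        return {}
    with open(path, "rb") as handle:
        raw = tomllib.load(handle)
    config: Dict[str, Dict[str, Any]] = {}
    for section, values in raw.items():
        if section not in CONFIG_SCHEMA:
            raise ValueError(
                f"unknown config section [{section}]; valid sections: "
                + ", ".join(sorted(CONFIG_SCHEMA))
            )
        if not isinstance(values, Mapping):
            raise ValueError(f"config section [{section}] must be a table")
        schema = CONFIG_SCHEMA[section]
        config[section] = {}
        for key, value in values.items():
            if key not in schema:
                raise ValueError(
                    f"unknown config key [{section}].{key}; valid keys: "
                    + ", ".join(sorted(schema))
                )
            config[section][key] = _check_type(section, key, value, schema[key])
    return config


def resolve(
    config: Mapping[str, Mapping[str, Any]],
    section: str,
    key: str,
    flag_value: Any,
    default: Any,
) -> Any:
    """Apply flag > file > default precedence for one parameter."""
    if flag_value is not None:
        return flag_value
    if section in config and key in config[section]:
        return config[section][key]
    return default
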