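"""Structured configuration, provenance logging, and deterministic table output.

Config files are YAML with a fixed section layout (``units``, ``parameters``,
``scaling``, ``scenario``, ``synthetic``, ``output_dir``, ``log_level``).  The
``units`` header must declare the package-wide convention — time in days,
concentration in nmol/l, volume in l, amount in nmol — or parsing fails;
unknown keys anywhere are rejected rather than silently ignored.  Every
resolved parameter's provenance (published anchor vs surrogate default) is
echoed to the log at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .model import TMDDParameters
from .scaling import ScalingPolicy
from .scenarios import ScenarioSpec
from .synthetic import REFERENCE_PROVENANCE, SyntheticConfig, make_reference_params

__all__ = ["ConfigError", "RunConfig", "load_config", "write_table", "CANONICAL_UNITS"]

logger = logging.getLogger(__name__)

CANONICAL_UNITS: Mapping[str, str] = {
    "time": "day",
    "concentration": "nmol/l",
    "volume": "l",
    "amount": "nmol",
}

_PARAM_KEYS = {"kel", "kon", "koff", "kint", "ksyn", "kdeg", "v1", "v2", "q"}
_SCALING_KEYS = {"cl_exponent", "v_exponent", "reference_bw", "reference_plasma_volume"}
_SCENARIO_KEYS = {
    "ages",
    "per_kg_doses",
    "fixed_doses",
    "target_concentrations",
    "target_amounts",
    "target_policies",
    "dose_policies",
    "model_kinds",
    "molecular_weight",
    "occupancy_threshold",
}
_SYNTHETIC_KEYS = {"seed", "cohort_sizes", "bw_cv", "obs_cv", "schedule"}
_TOP_KEYS = {"units", "parameters", "scaling", "scenario", "synthetic", "output_dir", "log_level"}


class ConfigError(ValueError):
    """Raised for malformed, unit-mismatched, or out-of-range configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration with per-parameter provenance."""

    parameters: TMDDParameters
    scaling: ScalingPolicy
    scenario: ScenarioSpec
    synthetic: SyntheticConfig
    output_dir: Path
    log_level: str
    provenance: Mapping[str, str] = field(default_factory=dict)


def _reject_unknown(section: Mapping, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}; allowed: {sorted(allowed)}")


def _check_units(units: Mapping) -> None:
    _reject_unknown(units, set(CANONICAL_UNITS), "units")
    for dim, expected in CANONICAL_UNITS.items():
        got = units.get(dim)
        if got != expected:
            raise ConfigError(
                f"units.{dim} must be {expected!r} (package-wide convention), got {got!r}"
            )


def load_config(path: Optional[str | Path] = None, seed: Optional[int] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    With no path (or an empty file) every value falls back to the package
    defaults, which carry surrogate provenance tags where they are not
    anchored to published constants.  A ``seed`` argument overrides the
    config's synthetic seed.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    _reject_unknown(raw, _TOP_KEYS, "config root")
    if raw and "units" not in raw:
        raise ConfigError("non-empty config must declare a units block")
    if "units" in raw:
        _check_units(raw["units"] or {})

    # --- parameters -------------------------------------------------------
    overrides = dict(raw.get("parameters") or {})
    _reject_unknown(overrides, _PARAM_KEYS, "parameters")
    defaults = make_reference_params()
    provenance = dict(REFERENCE_PROVENANCE)
    values = {}
    for key in _PARAM_KEYS:
        if key in overrides:
            value = overrides[key]
            if not isinstance(value, (int, float)) or value < 0:
                raise ConfigError(f"parameters.{key} must be a non-negative number, got {value!r}")
            values[key] = float(value)
            provenance[key] = "user config"
        else:
            values[key] = getattr(defaults, key)
    try:
        params = TMDDParameters(**values)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    # --- scaling ----------------------------------------------------------
    scaling_raw = dict(raw.get("scaling") or {})
    _reject_unknown(scaling_raw, _SCALING_KEYS, "scaling")
    try:
        scaling = ScalingPolicy(**scaling_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scaling block: {exc}") from exc

    # --- scenario ---------------------------------------------------------
    scenario_raw = dict(raw.get("scenario") or {})
    _reject_unknown(scenario_raw, _SCENARIO_KEYS, "scenario")
    for key in (
        "ages",
        "per_kg_doses",
        "fixed_doses",
        "target_concentrations",
        "target_amounts",
        "target_policies",
        "dose_policies",
        "model_kinds",
    ):
        if key in scenario_raw:
            scenario_raw[key] = tuple(scenario_raw[key])
    try:
        scenario = ScenarioSpec(**scenario_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scenario block: {exc}") from exc

    # --- synthetic --------------------------------------------------------
    synth_raw = dict(raw.get("synthetic") or {})
    _reject_unknown(synth_raw, _SYNTHETIC_KEYS, "synthetic")
    if seed is not None:
        synth_raw["seed"] = int(seed)
    synth_raw.setdefault("seed", 0)
    if "schedule" in synth_raw:
        synth_raw["schedule"] = tuple(synth_raw["schedule"])
    try:
        synthetic = SyntheticConfig(**synth_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid synthetic block: {exc}") from exc

    config = RunConfig(
        parameters=params,
        scaling=scaling,
        scenario=scenario,
        synthetic=synthetic,
        output_dir=Path(raw.get("output_dir", "pedtmdd_output")),
        log_level=str(raw.get("log_level", "INFO")),
        provenance=provenance,
    )
    for key in sorted(_PARAM_KEYS):
        logger.info("parameter %-5s = %-12.6g [%s]", key, getattr(params, key), provenance[key])
    return config


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as RFC-4180 CSV with deterministic row order.

    Floats are written at full ``repr`` precision so a read round-trip is
    bit-exact; rows are sorted by all non-float key columns so reruns on the
    same config produce byte-identical files.
    """
    path = Path(path)
    out = table.copy()
    key_cols = [c for c in out.columns if out[c].dtype == object or str(out[c].dtype) == "category"]
    if key_cols:
        out = out.sort_values(key_cols, kind="mergesort")
    try:
        out.to_csv(path, index=False, lineterminator="\r\n")
    except OSError as exc:
        raise OSError(f"failed to write table to {path}: {exc}") from exc
    return path
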