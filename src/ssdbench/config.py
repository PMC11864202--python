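"""Run configuration: schema, defaults, and validation.

A run is described by a flat, human-readable YAML mapping. Unknown keys are
rejected so typos cannot silently fall back to defaults. Every knob that
the pipeline exposes — subsample sizes, iteration count, HC fractions,
candidate families, averaging method, quantile convention, bimodality
options, selection thresholds, solubility factor, seed — lives here with
its documented default. The defaults encode the standard study design:
1,000 iterations of size-15 subsamples with at least 3 taxonomic groups,
HC5 (p = 0.05), all five candidate families, arithmetic weighted-average
model averaging, 0.555 bimodality threshold, 5x solubility screen, and
selection of chemicals with at least 51 species from at least 3 groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping, Optional

import yaml

from .averaging import AVERAGING_METHODS
from .benchmark import BIMODALITY_THRESHOLD
from .distributions import FAMILIES, Family
from .exceptions import ConfigError
from .ingest import QUANTILE_METHODS

__all__ = ["RunConfig", "validate_config", "load_config"]

ALLOWED_SIZES = (5, 10, 15)
ALLOWED_P = (0.05, 0.01)


@dataclass(frozen=True)
class RunConfig:
    """Validated study-level configuration with all defaults resolved."""

    # input: either existing toxicity CSVs or a synthetic profile
    inputs: tuple[str, ...] = ()
    synthetic: Mapping = field(default_factory=dict)
    solubility: Optional[str] = None

    # study design
    sizes: tuple[int, ...] = (15,)
    iterations: int = 1000
    p_targets: tuple[float, ...] = (0.05,)
    families: tuple[Family, ...] = FAMILIES
    averaging_method: str = "arithmetic"
    quantile_method: str = "linear_type7"
    min_species: int = 51
    min_groups: int = 3
    solubility_factor: float = 5.0
    bimodality_log_transform: bool = True
    bimodality_threshold: float = BIMODALITY_THRESHOLD
    comparison_percentiles: tuple[str, ...] = ("q025", "q50", "q975")

    seed: int = 0
    outdir: str = "ssdbench_out"


_VALIDATORS = {}


def _validator(key):
    def deco(fn):
        _VALIDATORS[key] = fn
        return fn

    return deco


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"config key {key!r}: {msg}")


@_validator("sizes")
def _v_sizes(v):
    v = tuple(int(x) for x in (v if isinstance(v, (list, tuple)) else [v]))
    _require(len(v) >= 1, "sizes", "must be nonempty")
    for s in v:
        _require(s >= 3, "sizes", f"size {s} below the 3-group constraint")
        if s not in ALLOWED_SIZES:
            import logging

            logging.getLogger(__name__).warning(
                "subsample size %d is outside the standard design sizes %s",
                s,
                ALLOWED_SIZES,
            )
    return v


@_validator("iterations")
def _v_iterations(v):
    v = int(v)
    _require(v >= 1, "iterations", "must be >= 1")
    return v


@_validator("p_targets")
def _v_p(v):
    v = tuple(float(x) for x in (v if isinstance(v, (list, tuple)) else [v]))
    for p in v:
        _require(0.0 < p < 1.0, "p_targets", f"p={p} outside (0, 1)")
    return v


@_validator("families")
def _v_families(v):
    try:
        fams = tuple(Family(x) for x in v)
    except ValueError as exc:
        raise ConfigError(
            f"config key 'families': {exc}; allowed: {[f.value for f in FAMILIES]}"
        ) from None
    _require(len(fams) >= 1, "families", "must be nonempty")
    return fams


@_validator("averaging_method")
def _v_avg(v):
    _require(
        v in AVERAGING_METHODS,
        "averaging_method",
        f"{v!r} not in {AVERAGING_METHODS}",
    )
    return str(v)


@_validator("quantile_method")
def _v_qm(v):
    _require(
        v in QUANTILE_METHODS,
        "quantile_method",
        f"{v!r} not in {sorted(QUANTILE_METHODS)}",
    )
    return str(v)


@_validator("min_species")
def _v_min_species(v):
    v = int(v)
    _require(v >= 1, "min_species", "must be >= 1")
    return v


@_validator("min_groups")
def _v_min_groups(v):
    v = int(v)
    _require(1 <= v <= 4, "min_groups", "must be in 1..4")
    return v


@_validator("solubility_factor")
def _v_sol(v):
    v = float(v)
    _require(v > 0, "solubility_factor", "must be > 0")
    return v


@_validator("seed")
def _v_seed(v):
    v = int(v)
    _require(v >= 0, "seed", "must be >= 0")
    return v


def validate_config(raw: Optional[Mapping]) -> RunConfig:
    """Validate a raw mapping into a RunConfig, injecting defaults.

    Unknown keys raise; type and range violations name the offending key.
    """
    raw = dict(raw or {})
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; allowed: {sorted(known)}"
        )
    out = {}
    for key, value in raw.items():
        if key in _VALIDATORS:
            out[key] = _VALIDATORS[key](value)
        elif key == "inputs":
            out[key] = tuple(str(x) for x in value)
        elif key == "comparison_percentiles":
            v = tuple(str(x) for x in value)
            for pct in v:
                _require(
                    pct in ("q025", "q50", "q975"),
                    "comparison_percentiles",
                    f"{pct!r} not one of q025, q50, q975",
                )
            out[key] = v
        elif key == "bimodality_log_transform":
            _require(
                isinstance(value, bool), "bimodality_log_transform", "must be boolean"
            )
            out[key] = value
        elif key == "bimodality_threshold":
            out[key] = float(value)
        elif key == "synthetic":
            _require(isinstance(value, Mapping), "synthetic", "must be a mapping")
            out[key] = dict(value)
        elif key in ("solubility", "outdir"):
            out[key] = None if value is None else str(value)
        else:  # pragma: no cover
            out[key] = value
    cfg = RunConfig(**out)
    for s in cfg.sizes:
        _require(
            s >= cfg.min_groups, "sizes", f"size {s} smaller than min_groups"
        )
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config file must contain a mapping at top level")
    return validate_config(raw)
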