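"""Declarative pipeline configuration.

One YAML file mirrors every CLI flag; all thresholds live here with the
study defaults (ratio 1.5 / p 0.05 differential gates, motif p < 1e-6 and
support > 20, kinase-score fpr 0.05, NES +/-1 activity gates).  CLI options
override config values; unknown keys are rejected before any stage runs.
"""

from __future__ import annotations

import copy
import hashlib
from pathlib import Path
from typing import Any

import yaml

from .simulate import SimConfig

DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "sim": {},  # SimConfig field overrides
    "differential": {"fc_threshold": 1.5, "alpha": 0.05, "equal_var": True},
    "motifs": {
        "p_threshold": 1e-6,
        "min_occurrences": 20,
        "min_inclusive": False,
        "max_background": 20000,
    },
    "kinase_substrate": {
        "fpr": 0.05,
        "require_ppi": True,
        "n_exemplars": 20,
        "background_windows": 5000,
    },
    "activity": {
        "n_permutations": 1000,
        "weight_exponent": 1.0,
        "min_set_size": 3,
    },
    "network": {"p_threshold": 0.05, "require_significance": True, "top_k": 10},
    "enrichment": {"alpha": 0.05, "top_n": 20},
}

_SIM_FIELDS = set(SimConfig.__dataclass_fields__)


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key == "sim":
            bad = set(value) - _SIM_FIELDS
            if bad:
                raise ConfigError(f"unknown sim config keys: {sorted(bad)}")
            out["sim"] = copy.deepcopy(value)
            continue
        if key not in base:
            raise ConfigError(f"unknown config key {where!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"{where!r} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults merged with an optional YAML file; unknown keys error."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def sim_config_from(config: dict, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from the ``sim`` section (planted activities and
    motif library accept plain-YAML forms)."""
    from .simulate import KinaseMotif

    sim = dict(config.get("sim", {}))
    if "planted_activities" in sim:
        sim["planted_activities"] = tuple(
            (e["kinase"], (e["numerator"], e["denominator"]), float(e["ratio"]))
            if isinstance(e, dict)
            else (e[0], tuple(e[1]), float(e[2]))
            for e in sim["planted_activities"]
        )
    if "motif_library" in sim:
        sim["motif_library"] = tuple(
            KinaseMotif(
                e["kinase"], e["central"],
                tuple((int(o), str(r)) for o, r in e.get("fixed", [])),
            )
            if isinstance(e, dict)
            else e
            for e in sim["motif_library"]
        )
    for tuple_field in ("conditions", "residue_mix", "sites_per_protein_pmf",
                       "protein_length", "baseline_log_intensity"):
        if tuple_field in sim:
            sim[tuple_field] = tuple(sim[tuple_field])
    if seed is not None:
        sim["seed"] = seed
    return SimConfig(**sim)


def config_hash(config: dict) -> str:
    """Stable hash of a config for run manifests."""
    canonical = yaml.safe_dump(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {
            f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__
        }
    return obj
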