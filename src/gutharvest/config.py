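"""Scenario configuration: YAML schema, defaults, validation.

A scenario config is a nested mapping with a versioned ``schema`` key.  Every
key is validated against the default schema before any computation; unknown
keys are rejected so typos fail fast.  ``default_config()`` returns the full
default tree, serializable to YAML and round-trippable.
"""

from __future__ import annotations

import copy

import yaml

from .community import REFERENCE_CARB_DEMAND, REFERENCE_EPSILON_TOT, \
    REFERENCE_PRODUCT_FRACTIONS
from .diet import (
    DEFAULT_FP_YIELD_MMOL_PER_G,
    DEFAULT_ILEAL_PROTEIN_PASSAGE,
    DEFAULT_MUCIN_SECRETION_G,
)
from .energy import DEFAULT_ENTHALPY_KJ_PER_MMOL, MOUSE_ENERGY_GAP_KJ
from .errors import ConfigError
from .fecal import DEFAULT_ALPHA_BAC
from .harvest import DEFAULT_SEED
from .rates import DEFAULT_OD_TO_DW
from .synthetic import BRITISH_WET_G

SCHEMA_VERSION = 1

#: Mouse fecal defaults: wet output and its (constant) dry fraction; the
#: bacterial fraction of dry weight is shared with the human default.
MOUSE_WET_G = 1.6
MOUSE_ALPHA_DW = 0.30
MOUSE_ALPHA_BAC = 0.55


def default_config() -> dict:
    """Full default scenario configuration."""
    return {
        "schema": SCHEMA_VERSION,
        "scenario_name": "british_reference",
        "seed": DEFAULT_SEED,
        "rates": {
            "od_to_dw": DEFAULT_OD_TO_DW,
            "od_window": [0.04, 0.5],
            "min_r_squared": 0.9,
        },
        "community": {
            "level": "genus",
            "mode": "renormalize",
            "epsilon_tot": REFERENCE_EPSILON_TOT,
            "carb_demand": REFERENCE_CARB_DEMAND,
            "product_fractions": dict(REFERENCE_PRODUCT_FRACTIONS),
        },
        "mac": {
            "scenario": "medium",
            "sugar_passage": 0.0,
            "g_per_mmol_hexose": 0.180,
            "mac_rel_sd": 0.15,
        },
        "protein": {
            "ileal_protein_passage": DEFAULT_ILEAL_PROTEIN_PASSAGE,
            "mucin_secretion_g": DEFAULT_MUCIN_SECRETION_G,
            "fp_yield_mmol_per_g": DEFAULT_FP_YIELD_MMOL_PER_G,
        },
        "fecal": {
            "model": "constant",
            "wet_g": BRITISH_WET_G,
            "wet_g_sd": 40.0,
            "alpha_bac": DEFAULT_ALPHA_BAC,
        },
        "energy": {
            "enthalpies_kj_per_mmol": dict(DEFAULT_ENTHALPY_KJ_PER_MMOL),
            "human": {
                "expenditure_kj": 10_000.0,
                "body_mass_kg": 70.0,
                "epithelial_area_m2": 2.14,
            },
            "mouse": {
                "expenditure_kj": 38.0,
                "body_mass_kg": 0.025,
                "epithelial_area_m2": 0.045,
                "wet_g": MOUSE_WET_G,
                "alpha_dw": MOUSE_ALPHA_DW,
                "alpha_bac": MOUSE_ALPHA_BAC,
                "energy_gap_kj": MOUSE_ENERGY_GAP_KJ,
            },
        },
    }


#: Maps whose keys are product names, not schema keys.
_FREE_FORM_KEYS = {"product_fractions", "enthalpies_kj_per_mmol"}


def _validate(user: dict, schema: dict, path: str = "") -> None:
    for key, value in user.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in schema:
            raise ConfigError(f"unknown config key: {here}")
        if (
            isinstance(value, dict)
            and isinstance(schema[key], dict)
            and key not in _FREE_FORM_KEYS
        ):
            _validate(value, schema[key], here)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(source=None) -> dict:
    """Build a validated config from a YAML path, a dict, or nothing.

    Partial configs are merged over the defaults; unknown keys raise
    :class:`ConfigError`; the ``schema`` version must match.
    """
    if source is None:
        return default_config()
    if isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    defaults = default_config()
    _validate(user, defaults)
    merged = _merge(defaults, user)
    if merged["schema"] != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema version {merged['schema']}; "
            f"expected {SCHEMA_VERSION}"
        )
    return merged


def dump_config(config: dict) -> str:
    """Serialize a config to YAML (stable key order)."""
    return yaml.safe_dump(config, sort_keys=True)
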