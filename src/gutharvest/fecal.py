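"""Fecal wet weight -> dry weight -> bacterial biomass, plus transit time.

The dry-mass fraction of feces (alpha_dw) falls as fecal output rises,
because extra output is mostly fiber-bound water.  Three empirical models
are provided:

* ``constant``:  alpha_dw fixed (adequate for narrow, Western-style output);
* ``linear``:    alpha_dw = 1 - (a0 + a1 * M_wet);
* ``nonlinear``: alpha_dw = 1 - (c0 + c1 * sqrt(M_wet) - c2 * M_wet),
  which flattens at high wet weight and acts as an upper-bound model for
  dry (and hence bacterial) mass.

All models are empirical fits valid only on the observed range, so evaluated
fractions are clamped to [0.05, 0.6] with a warning.  The bacterial fraction
of dry weight (alpha_bac) is kept constant by default at 16/30 — the
reference ratio of bacterial to total fecal dry mass — for lack of data on
its variation.  Transit time is inversely proportional to fecal wet weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

#: Bacterial biomass per fecal dry weight (16 g of 30 g/day reference).
DEFAULT_ALPHA_BAC: float = 16.0 / 30.0

#: Clamping bounds for evaluated dry-mass fractions.
ALPHA_DW_BOUNDS: tuple[float, float] = (0.05, 0.6)

#: Default model coefficients.  ``constant`` reproduces ~30 g dry weight at
#: the reference wet weight of ~120 g/day; linear/nonlinear give a dry
#: fraction decreasing from ~0.28 at 100 g/day to ~0.19 at 400 g/day.
DEFAULT_COEFFICIENTS: dict[str, dict[str, float]] = {
    "constant": {"fraction": 0.25},
    "linear": {"a0": 0.69, "a1": 4.63e-4},
    "nonlinear": {"c0": 0.49, "c1": 0.03, "c2": 7e-4},
}

#: Transit-time constant k in tau = k / M_wet, g*hours.  Chosen so the
#: reference wet weight of ~120 g/day corresponds to ~60 h transit.
DEFAULT_TRANSIT_K: float = 7200.0


@dataclass(frozen=True)
class FecalOutput:
    """Daily fecal output decomposed into dry and bacterial mass."""

    wet_g: float  # g/day
    dry_g: float  # g/day
    alpha_dw: float  # dry fraction of wet weight
    alpha_bac: float  # bacterial fraction of dry weight
    bacterial_g: float  # g/day
    model: str = "constant"
    transit_h: float | None = None
    identifier: str = ""

    def __post_init__(self):
        if not 0 < self.alpha_dw < 1:
            raise DomainError(f"alpha_dw must lie in (0, 1), got {self.alpha_dw}")
        if not 0 <= self.alpha_bac <= 1:
            raise DomainError(f"alpha_bac must lie in [0, 1], got {self.alpha_bac}")
        if not (self.bacterial_g <= self.dry_g <= self.wet_g):
            raise DomainError("expect bacterial_g <= dry_g <= wet_g")


def dry_fraction(
    wet_g: float,
    model: str = "nonlinear",
    coefficients: dict[str, float] | None = None,
) -> float:
    """Dry-mass fraction alpha_dw of feces at the given daily wet weight."""
    if wet_g <= 0:
        raise DomainError(f"wet_g must be > 0, got {wet_g}")
    if model not in DEFAULT_COEFFICIENTS:
        raise DomainError(
            f"unknown model {model!r}; expected one of "
            f"{sorted(DEFAULT_COEFFICIENTS)}"
        )
    c = dict(DEFAULT_COEFFICIENTS[model])
    if coefficients:
        c.update(coefficients)
    if model == "constant":
        alpha = c["fraction"]
    elif model == "linear":
        alpha = 1.0 - (c["a0"] + c["a1"] * wet_g)
    else:  # nonlinear
        alpha = 1.0 - (c["c0"] + c["c1"] * np.sqrt(wet_g) - c["c2"] * wet_g)
    lo, hi = ALPHA_DW_BOUNDS
    if alpha < lo or alpha > hi:
        warnings.warn(
            f"alpha_dw({wet_g:g} g) = {alpha:.3f} outside [{lo}, {hi}]; "
            "clamped (empirical model extrapolation)",
            stacklevel=2,
        )
        alpha = min(max(alpha, lo), hi)
    return float(alpha)


def bacterial_biomass(
    wet_g: float,
    model: str = "nonlinear",
    alpha_bac: float = DEFAULT_ALPHA_BAC,
    coefficients: dict[str, float] | None = None,
    transit_k: float | None = None,
    identifier: str = "",
) -> FecalOutput:
    """Full decomposition of daily fecal output into dry and bacterial mass."""
    alpha_dw = dry_fraction(wet_g, model, coefficients)
    dry_g = alpha_dw * wet_g
    return FecalOutput(
        wet_g=float(wet_g),
        dry_g=dry_g,
        alpha_dw=alpha_dw,
        alpha_bac=alpha_bac,
        bacterial_g=alpha_bac * dry_g,
        model=model,
        transit_h=transit_time(wet_g, transit_k) if transit_k else None,
        identifier=identifier,
    )


def transit_time(wet_g: float, k: float = DEFAULT_TRANSIT_K) -> float:
    """Whole-gut transit time, tau = k / wet_g [hours]."""
    if wet_g <= 0:
        raise DomainError(f"wet_g must be > 0, got {wet_g}")
    if k <= 0:
        raise DomainError(f"k must be > 0, got {k}")
    return k / wet_g


def fit_dry_fraction(
    wet_g, dry_g, model: str = "nonlinear"
) -> dict[str, float]:
    """Re-derive alpha_dw model coefficients from paired (wet, dry) data.

    ``constant``: least-squares dry = fraction * wet through the origin.
    ``linear``/``nonlinear``: least squares on 1 - dry/wet against the
    model's basis functions of wet weight.
    """
    wet = np.asarray(wet_g, dtype=float)
    dry = np.asarray(dry_g, dtype=float)
    if wet.shape != dry.shape or wet.size < 2:
        raise DomainError("need >= 2 paired (wet, dry) observations")
    if (wet <= 0).any() or (dry < 0).any() or (dry > wet).any():
        raise DomainError("require 0 <= dry <= wet and wet > 0")
    if model == "constant":
        return {"fraction": float(np.sum(wet * dry) / np.sum(wet**2))}
    water = 1.0 - dry / wet
    if model == "linear":
        design = np.column_stack([np.ones_like(wet), wet])
        (a0, a1), *_ = np.linalg.lstsq(design, water, rcond=None)
        return {"a0": float(a0), "a1": float(a1)}
    if model == "nonlinear":
        design = np.column_stack([np.ones_like(wet), np.sqrt(wet), -wet])
        (c0, c1, c2), *_ = np.linalg.lstsq(design, water, rcond=None)
        return {"c0": float(c0), "c1": float(c1), "c2": float(c2)}
    raise DomainError(f"unknown model {model!r}")


FECAL_CSV_COLUMNS = ["cohort_id", "individual_id", "wet_g_per_day"]


def read_fecal_csv(
    path,
    model: str = "nonlinear",
    alpha_bac: float = DEFAULT_ALPHA_BAC,
    coefficients: dict[str, float] | None = None,
) -> list[FecalOutput]:
    """Fecal CSV: cohort_id, individual_id, wet_g_per_day [, dry_g_per_day]."""
    df = pd.read_csv(path)
    if "wet_g_per_day" not in df.columns:
        raise DomainError("fecal CSV missing column wet_g_per_day")
    return [
        bacterial_biomass(
            float(r["wet_g_per_day"]),
            model=model,
            alpha_bac=alpha_bac,
            coefficients=coefficients,
            identifier=str(r.get("individual_id", i)),
        )
        for i, r in df.iterrows()
    ]


def write_fecal_csv(outputs: list[FecalOutput], path, cohort_id: str = "cohort") -> None:
    pd.DataFrame(
        [
            {
                "cohort_id": cohort_id,
                "individual_id": o.identifier,
                "wet_g_per_day": o.wet_g,
                "dry_g_per_day": o.dry_g,
            }
            for o in outputs
        ]
    ).to_csv(path, index=False)
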