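"""Energy content of the harvest and host energy-budget comparisons.

Fermentation products absorbed by the colonic epithelium are oxidized by
host tissues; their combustion enthalpy is taken as their energy content.
The module converts harvest estimates to kJ/day, expresses them as a
percentage of the host's daily energy expenditure, compares the harvest
route against the germ-free vs. conventional energy-extraction gap in mice,
and normalizes fluxes per kg body mass or per m² of epithelial surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .chemistry import PRODUCTS
from .errors import ConfigError, DomainError
from .harvest import HarvestEstimate

#: Combustion enthalpies, kJ per mmol, standard thermochemical values.
DEFAULT_ENTHALPY_KJ_PER_MMOL: dict[str, float] = {
    "acetate": 0.875,
    "propionate": 1.527,
    "butyrate": 2.184,
    "lactate": 1.368,
    "formate": 0.255,
    "succinate": 1.491,
}


@dataclass(frozen=True)
class EnergyContext:
    """Host parameters for energy-budget comparisons."""

    expenditure_kj: float  # kJ/day
    body_mass_kg: float | None = None
    epithelial_area_m2: float | None = None

    def __post_init__(self):
        if self.expenditure_kj <= 0:
            raise DomainError("expenditure must be > 0")
        for name in ("body_mass_kg", "epithelial_area_m2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} must be > 0")


#: Human defaults: 10 MJ/day expenditure, 70 kg reference adult (assumed, not
#: a measured constant of the framework), colonic epithelial area back-derived
#: from the per-area flux comparison.
HUMAN_CONTEXT = EnergyContext(
    expenditure_kj=10_000.0, body_mass_kg=70.0, epithelial_area_m2=2.14
)
#: Mouse defaults: 38 kJ/day expenditure, 25 g body mass.
MOUSE_CONTEXT = EnergyContext(
    expenditure_kj=38.0, body_mass_kg=0.025, epithelial_area_m2=0.045
)

#: Energy-extraction gap between conventionally colonized and germ-free
#: mice, kJ/day (from calorimetry of the two groups).
MOUSE_ENERGY_GAP_KJ = 8.1


def harvest_energy(
    est: HarvestEstimate,
    enthalpies: dict[str, float] | None = None,
) -> float:
    """Energy content of a harvest, kJ/day: sum of flux_i * dH_i.

    Net-negative product fluxes (possible for acetate) contribute nothing —
    only absorbed flux carries energy to the host.
    """
    table = enthalpies or DEFAULT_ENTHALPY_KJ_PER_MMOL
    missing = [
        p for p, flux in est.fp_by_product.items()
        if flux > 0 and p not in table
    ]
    if missing:
        raise ConfigError(f"enthalpy table missing products: {missing}")
    return sum(
        max(flux, 0.0) * table[p]
        for p, flux in est.fp_by_product.items()
        if p in table
    )


def energy_fraction(energy_kj: float, ctx: EnergyContext) -> float:
    """Percent of daily host energy expenditure supplied by the harvest."""
    return 100.0 * energy_kj / ctx.expenditure_kj


def mouse_energy_gap(
    extraction_conventional_kj: float,
    extraction_germfree_kj: float,
    ctx: EnergyContext = MOUSE_CONTEXT,
) -> tuple[float, float]:
    """Energy gap between colonized and germ-free mice and its percent share.

    Returns (gap in kJ/day, percent of daily expenditure).  A negative gap
    (germ-free extracting more) is allowed but flagged with a warning, as it
    indicates a colonization penalty scenario.
    """
    if extraction_conventional_kj < 0 or extraction_germfree_kj < 0:
        raise DomainError("extractions must be >= 0")
    gap = extraction_conventional_kj - extraction_germfree_kj
    if gap < 0:
        warnings.warn("negative energy gap: colonization penalty scenario",
                      stacklevel=2)
    return gap, 100.0 * gap / ctx.expenditure_kj


def normalize(est: HarvestEstimate, ctx: EnergyContext, by: str = "mass") -> float:
    """Harvest per kg body mass (mmol/kg/day) or per m² epithelium (mmol/m²/day)."""
    if by == "mass":
        if ctx.body_mass_kg is None:
            raise ConfigError("context lacks body_mass_kg")
        return est.fp_tot / ctx.body_mass_kg
    if by == "area":
        if ctx.epithelial_area_m2 is None:
            raise ConfigError("context lacks epithelial_area_m2")
        return est.fp_tot / ctx.epithelial_area_m2
    raise ConfigError(f"unknown normalization {by!r}; expected 'mass' or 'area'")


def read_enthalpy_csv(path) -> dict[str, float]:
    """Two-column CSV: product, kJ_per_mmol."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ConfigError("enthalpy CSV needs columns (product, kJ_per_mmol)")
    table = dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(float)))
    if any(v <= 0 for v in table.values()):
        raise DomainError("combustion enthalpies must be > 0")
    unknown = set(table) - set(PRODUCTS)
    if unknown:
        raise ConfigError(f"unknown products in enthalpy table: {sorted(unknown)}")
    return table
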