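"""Diet to microbiota-available carbohydrates (MACs), plus protein/mucin bound.

Only part of ingested carbohydrate escapes host digestion and reaches the
large intestine in a microbially usable form.  The mapping here is linear:

    M_carb = starch_passage * starch + fiber_digestibility * fiber
             + sugar_passage * sugar        [g/day]

with three named digestion scenarios (low/medium/high) spanning the observed
range of starch passage and microbial fiber digestibility.  Simple sugars are
assumed fully absorbed in the small intestine by default (sugar_passage = 0).

The module also provides an explicit *upper bound* on the fermentation
contribution of dietary protein and mucin (all colonic amino acids assumed
fermented, none assimilated), and the ATP-turnover consistency estimate of
total fermentation product release from daily bacterial biomass production.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chemistry import HEXOSE_G_PER_MMOL
from .errors import ConfigError, DomainError


@dataclass(frozen=True)
class DietRecord:
    """Daily intake of the diet components relevant to colonic fermentation."""

    fiber_g: float
    starch_g: float
    sugar_g: float
    protein_g: float
    identifier: str = ""

    def __post_init__(self):
        for name in ("fiber_g", "starch_g", "sugar_g", "protein_g"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MacMappingParams:
    """Parameters of the diet -> MAC mapping."""

    starch_passage: float
    fiber_digestibility: float
    sugar_passage: float = 0.0
    g_per_mmol_hexose: float = HEXOSE_G_PER_MMOL

    def __post_init__(self):
        for name in ("starch_passage", "fiber_digestibility", "sugar_passage"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")
        if self.g_per_mmol_hexose <= 0:
            raise DomainError("g_per_mmol_hexose must be > 0")


@dataclass(frozen=True)
class MacResult:
    """Daily microbiota-available carbohydrates."""

    mac_g: float  # g/day
    mac_mmol_hexose: float  # mmol hexose equivalents/day
    scenario: str = "custom"


@dataclass(frozen=True)
class ProteinMucinBound:
    """Upper-bound fermentation contribution of colonic protein and mucin."""

    protein_to_colon_g: float  # g/day
    mucin_g: float  # g/day
    fp_from_protein_mmol: float  # mmol/day
    fraction_of_total: float


#: (starch_passage, fiber_digestibility) per digestion scenario.
SCENARIOS: dict[str, tuple[float, float]] = {
    "low": (0.10, 0.30),
    "medium": (0.13, 0.50),
    "high": (0.15, 0.75),
}


def scenario_params(
    name: str,
    sugar_passage: float = 0.0,
    g_per_mmol_hexose: float = HEXOSE_G_PER_MMOL,
) -> MacMappingParams:
    """Named digestion scenario -> mapping parameters.

    low: (0.10, 0.30); medium: (0.13, 0.50); high: (0.15, 0.75).
    """
    try:
        starch, fiber = SCENARIOS[name]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIOS)}"
        ) from None
    return MacMappingParams(
        starch_passage=starch,
        fiber_digestibility=fiber,
        sugar_passage=sugar_passage,
        g_per_mmol_hexose=g_per_mmol_hexose,
    )


def map_to_mac(diet: DietRecord, params: MacMappingParams | str) -> MacResult:
    """Map a diet record to microbiota-available carbohydrates.

    ``params`` may be a scenario name ("low"/"medium"/"high") or explicit
    :class:`MacMappingParams`.
    """
    scenario = "custom"
    if isinstance(params, str):
        scenario = params
        params = scenario_params(params)
    mac_g = (
        params.starch_passage * diet.starch_g
        + params.fiber_digestibility * diet.fiber_g
        + params.sugar_passage * diet.sugar_g
    )
    return MacResult(
        mac_g=mac_g,
        mac_mmol_hexose=mac_g / params.g_per_mmol_hexose,
        scenario=scenario,
    )


#: Fraction of dietary protein escaping ileal absorption.
DEFAULT_ILEAL_PROTEIN_PASSAGE = 0.1
#: Daily mucin secretion reaching colonic microbes, g/day.
DEFAULT_MUCIN_SECRETION_G = 5.0
#: Fermentation products per g of fermented protein, mmol/g (upper bound).
DEFAULT_FP_YIELD_MMOL_PER_G = 2.0


def protein_mucin_bound(
    diet: DietRecord,
    total_fp: float,
    ileal_protein_passage: float = DEFAULT_ILEAL_PROTEIN_PASSAGE,
    mucin_secretion_g: float = DEFAULT_MUCIN_SECRETION_G,
    fp_yield_mmol_per_g: float = DEFAULT_FP_YIELD_MMOL_PER_G,
) -> ProteinMucinBound:
    """Upper bound on the protein+mucin share of fermentation product release.

    All protein reaching the colon (ileal passage of dietary protein plus
    secreted mucin) is assumed fully fermented, none assimilated into new
    bacterial protein — so the returned fraction is a ceiling, not an
    estimate.
    """
    if total_fp <= 0:
        raise DomainError("total_fp must be > 0")
    for name, v in (
        ("ileal_protein_passage", ileal_protein_passage),
        ("mucin_secretion_g", mucin_secretion_g),
        ("fp_yield_mmol_per_g", fp_yield_mmol_per_g),
    ):
        if v < 0:
            raise DomainError(f"{name} must be >= 0")
    protein_to_colon = ileal_protein_passage * diet.protein_g + mucin_secretion_g
    fp_from_protein = fp_yield_mmol_per_g * protein_to_colon
    return ProteinMucinBound(
        protein_to_colon_g=protein_to_colon,
        mucin_g=mucin_secretion_g,
        fp_from_protein_mmol=fp_from_protein,
        fraction_of_total=fp_from_protein / (fp_from_protein + total_fp),
    )


#: ATP turnover to synthesize 1 g of bacterial dry biomass, mmol ATP/g.
#: Consistent with ~13 mmol hexose consumed per g biomass at ~4 ATP per
#: hexose from mixed-acid fermentation.
DEFAULT_ATP_PER_BIOMASS = 52.0
#: ATP gained per mmol of fermentation product released, mmol/mmol.
DEFAULT_ATP_PER_FP = 1.8


def atp_theoretical_harvest(
    biomass_g: float,
    atp_per_biomass: float = DEFAULT_ATP_PER_BIOMASS,
    atp_per_fp: float = DEFAULT_ATP_PER_FP,
) -> float:
    """Fermentation product release implied by the ATP cost of biomass.

    harvest = biomass_g * atp_per_biomass / atp_per_fp   [mmol/day]

    An independent consistency check on the two primary estimators: the ATP
    needed to build the daily bacterial biomass must have been generated by
    fermentation, pinning the accompanying product release.
    """
    if biomass_g < 0:
        raise DomainError("biomass_g must be >= 0")
    if atp_per_biomass <= 0:
        raise DomainError("atp_per_biomass must be > 0")
    if atp_per_fp <= 0:
        raise DomainError("atp_per_fp must be > 0")
    return biomass_g * atp_per_biomass / atp_per_fp


DIET_CSV_COLUMNS = ["individual_id", "fiber_g", "starch_g", "sugar_g", "protein_g"]


def read_diet_csv(path) -> list[DietRecord]:
    """Diet CSV: individual_id (or month), fiber_g, starch_g, sugar_g, protein_g."""
    df = pd.read_csv(path)
    id_col = "individual_id" if "individual_id" in df.columns else "month"
    missing = {"fiber_g", "starch_g", "sugar_g", "protein_g"} - set(df.columns)
    if missing:
        raise DomainError(f"diet CSV missing columns: {sorted(missing)}")
    return [
        DietRecord(
            fiber_g=float(r["fiber_g"]),
            starch_g=float(r["starch_g"]),
            sugar_g=float(r["sugar_g"]),
            protein_g=float(r["protein_g"]),
            identifier=str(r[id_col]) if id_col in df.columns else str(i),
        )
        for i, r in df.iterrows()
    ]


def write_diet_csv(records: list[DietRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": r.identifier,
                "fiber_g": r.fiber_g,
                "starch_g": r.starch_g,
                "sugar_g": r.sugar_g,
                "protein_g": r.protein_g,
            }
            for r in records
        ],
        columns=DIET_CSV_COLUMNS,
    ).to_csv(path, index=False)
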