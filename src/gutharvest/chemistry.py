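"""Shared chemical constants: carbon counts, molar masses, product lists.

Fermentation of hexoses by gut anaerobes yields six major organic acids.
Carbon bookkeeping throughout the package uses the carbon-atom counts below;
masses of carbohydrate are converted to hexose equivalents with a configurable
grams-per-mmol constant (free glucose 180 g/mol by default; 162 g/mol for
anhydroglucose units in polymers).
"""

from __future__ import annotations

#: The six major fermentation products tracked by the framework.
PRODUCTS: tuple[str, ...] = (
    "acetate",
    "propionate",
    "butyrate",
    "lactate",
    "formate",
    "succinate",
)

#: Sugars used as growth substrates in the strain characterization assays.
SUGARS: tuple[str, ...] = ("glucose", "maltose")

#: Carbon atoms per molecule.
CARBON_ATOMS: dict[str, int] = {
    "glucose": 6,
    "maltose": 12,
    "acetate": 2,
    "propionate": 3,
    "butyrate": 4,
    "lactate": 3,
    "formate": 1,
    "succinate": 4,
}

#: g per mmol hexose, free glucose (180 g/mol).
HEXOSE_G_PER_MMOL: float = 0.180
#: g per mmol hexose, anhydroglucose unit in a polymer (162 g/mol).
ANHYDRO_G_PER_MMOL: float = 0.162

#: Molar mass of carbon, g/mol.
CARBON_G_PER_MOL: float = 12.011


def hexose_multiplier(sugar: str) -> int:
    """Hexose units per molecule of *sugar* (maltose counts double)."""
    if sugar == "glucose":
        return 1
    if sugar == "maltose":
        return 2
    raise KeyError(f"unknown sugar {sugar!r}; expected one of {SUGARS}")
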