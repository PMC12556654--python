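"""End-to-end scenario runs: British-style reference and human-mouse comparison.

``run_reference_scenario`` chains the whole framework on the reference
inputs: fecal decomposition and MAC mapping feed the two estimators, whose
agreement is the internal cross-validation; the carbon ledger, the
protein/mucin ceiling, and the energy fraction complete the report.
``run_mouse_comparison`` puts the calorimetric energy-gap route side by side
with the harvest-energy route and normalizes fluxes per kg body mass.

Reports are plain dicts of numbers with unit-suffixed keys (deterministic for
a fixed config); display rounding happens only at the CLI layer.
"""

from __future__ import annotations

import logging
import time

from .community import CommunityProfile
from .config import load_config
from .diet import map_to_mac, protein_mucin_bound, scenario_params
from .energy import (
    EnergyContext,
    energy_fraction,
    harvest_energy,
    mouse_energy_gap,
    normalize,
)
from .fecal import FecalOutput, bacterial_biomass
from .harvest import (
    carbon_flow,
    estimate_via_carbs,
    estimate_via_feces,
    product_sd,
)
from .synthetic import BRITISH_REFERENCE_DIET

logger = logging.getLogger(__name__)


def _community_from_config(cfg: dict) -> CommunityProfile:
    com = cfg["community"]
    fractions = com["product_fractions"]
    e_w = {p: com["epsilon_tot"] * f for p, f in fractions.items()}
    return CommunityProfile(
        epsilon_tot=com["epsilon_tot"],
        e_w=e_w,
        carb_demand=com["carb_demand"],
        coverage=1.0,
        level=com["level"],
        mode=com["mode"],
        provenance={"source": "scenario config community constants"},
    )


def _human_context(cfg: dict) -> EnergyContext:
    h = cfg["energy"]["human"]
    return EnergyContext(
        expenditure_kj=h["expenditure_kj"],
        body_mass_kg=h["body_mass_kg"],
        epithelial_area_m2=h["epithelial_area_m2"],
    )


def run_reference_scenario(config: dict | None = None) -> dict:
    """Reference-scenario report: both estimators, carbon flow, bounds, energy."""
    t0 = time.perf_counter()
    cfg = load_config(config)
    community = _community_from_config(cfg)

    fec_cfg = cfg["fecal"]
    fecal = bacterial_biomass(
        fec_cfg["wet_g"], model=fec_cfg["model"], alpha_bac=fec_cfg["alpha_bac"]
    )
    biomass_sd = fecal.bacterial_g * (
        fec_cfg["wet_g_sd"] / fec_cfg["wet_g"] if fec_cfg["wet_g"] else 0.0
    )
    via_feces = estimate_via_feces(fecal, community, biomass_sd=biomass_sd)

    mac_cfg = cfg["mac"]
    params = scenario_params(
        mac_cfg["scenario"],
        sugar_passage=mac_cfg["sugar_passage"],
        g_per_mmol_hexose=mac_cfg["g_per_mmol_hexose"],
    )
    mac = map_to_mac(BRITISH_REFERENCE_DIET, params)
    via_carbs = estimate_via_carbs(
        mac, community,
        mac_sd_mmol=mac.mac_mmol_hexose * mac_cfg["mac_rel_sd"],
    )

    flow = carbon_flow(mac, via_carbs)
    bound = protein_mucin_bound(
        BRITISH_REFERENCE_DIET,
        total_fp=via_carbs.fp_tot,
        **cfg["protein"],
    )
    ctx = _human_context(cfg)
    enthalpies = cfg["energy"]["enthalpies_kj_per_mmol"]
    energy_kj = harvest_energy(via_feces, enthalpies)
    energy_sd = product_sd(
        energy_kj, [(via_feces.fp_tot, via_feces.fp_tot_sd)]
    )

    report = {
        "scenario_name": cfg["scenario_name"],
        "fecal": {
            "wet_g_per_day": fecal.wet_g,
            "dry_g_per_day": fecal.dry_g,
            "bacterial_g_per_day": fecal.bacterial_g,
        },
        "mac": {
            "mac_g_per_day": mac.mac_g,
            "mac_mmol_hexose_per_day": mac.mac_mmol_hexose,
            "scenario": mac.scenario,
        },
        "via_feces": via_feces.to_dict(),
        "via_carbohydrates": via_carbs.to_dict(),
        "carbon_flow": flow.to_dict(),
        "protein_mucin_upper_bound": {
            "protein_to_colon_g_per_day": bound.protein_to_colon_g,
            "fp_from_protein_mmol_per_day": bound.fp_from_protein_mmol,
            "fraction_of_total": bound.fraction_of_total,
        },
        "energy": {
            "harvest_energy_kj_per_day": energy_kj,
            "harvest_energy_sd_kj_per_day": energy_sd,
            "fraction_of_expenditure_percent": energy_fraction(energy_kj, ctx),
            "per_kg_mmol_per_kg_day": normalize(via_feces, ctx, by="mass"),
            "per_area_mmol_per_m2_day": normalize(via_feces, ctx, by="area"),
        },
    }
    logger.info("reference scenario computed in %.3f s", time.perf_counter() - t0)
    return report


def run_mouse_comparison(config: dict | None = None) -> dict:
    """Mouse report: gap-based vs. harvest-based microbiota energy share."""
    t0 = time.perf_counter()
    cfg = load_config(config)
    community = _community_from_config(cfg)
    m = cfg["energy"]["mouse"]
    ctx = EnergyContext(
        expenditure_kj=m["expenditure_kj"],
        body_mass_kg=m["body_mass_kg"],
        epithelial_area_m2=m["epithelial_area_m2"],
    )
    gap_kj, gap_percent = mouse_energy_gap(
        extraction_conventional_kj=m["energy_gap_kj"],
        extraction_germfree_kj=0.0,
        ctx=ctx,
    )
    fecal = FecalOutput(
        wet_g=m["wet_g"],
        dry_g=m["alpha_dw"] * m["wet_g"],
        alpha_dw=m["alpha_dw"],
        alpha_bac=m["alpha_bac"],
        bacterial_g=m["alpha_bac"] * m["alpha_dw"] * m["wet_g"],
        model="constant",
        identifier="mouse",
    )
    est = estimate_via_feces(fecal, community)
    enthalpies = cfg["energy"]["enthalpies_kj_per_mmol"]
    energy_kj = harvest_energy(est, enthalpies)
    harvest_percent = energy_fraction(energy_kj, ctx)

    human_cfg = cfg["energy"]["human"]
    human_ctx = _human_context(cfg)
    human_fecal = bacterial_biomass(
        cfg["fecal"]["wet_g"], model=cfg["fecal"]["model"],
        alpha_bac=cfg["fecal"]["alpha_bac"],
    )
    human_est = estimate_via_feces(human_fecal, community)

    report = {
        "gap_route": {
            "gap_kj_per_day": gap_kj,
            "percent_of_expenditure": gap_percent,
        },
        "harvest_route": {
            "fp_tot_mmol_per_day": est.fp_tot,
            "harvest_energy_kj_per_day": energy_kj,
            "percent_of_expenditure": harvest_percent,
        },
        "normalization": {
            "mouse_mmol_per_kg_day": normalize(est, ctx, by="mass"),
            "human_mmol_per_kg_day": normalize(human_est, human_ctx, by="mass"),
            "mouse_mmol_per_m2_day": normalize(est, ctx, by="area"),
            "human_mmol_per_m2_day": normalize(human_est, human_ctx, by="area"),
        },
        "expenditures": {
            "mouse_kj_per_day": m["expenditure_kj"],
            "human_kj_per_day": human_cfg["expenditure_kj"],
        },
    }
    logger.info("mouse comparison computed in %.3f s", time.perf_counter() - t0)
    return report


def format_report(report: dict, indent: int = 0) -> str:
    """Human-readable table: keys aligned, numbers to 2 significant figures."""
    lines = []
    pad = "  " * indent
    for key, value in report.items():
        if isinstance(value, dict):
            lines.append(f"{pad}{key}:")
            lines.append(format_report(value, indent + 1))
        elif isinstance(value, float):
            lines.append(f"{pad}{key}: {value:.2g}")
        else:
            lines.append(f"{pad}{key}: {value}")
    return "\n".join(lines)
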