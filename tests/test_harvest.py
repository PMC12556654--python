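"""Harvest estimators, carbon ledger, error propagation, variation summaries."""

import numpy as np
import pandas as pd
import pytest

from gutharvest.chemistry import CARBON_ATOMS, CARBON_G_PER_MOL, PRODUCTS
from gutharvest.community import reference_community_profile
from gutharvest.diet import MacResult, map_to_mac
from gutharvest.errors import DomainError, InsufficientDataError
from gutharvest.fecal import FecalOutput, bacterial_biomass
from gutharvest.harvest import (
    carbon_flow,
    cohort_apply,
    composition_variation,
    estimate_via_carbs,
    estimate_via_feces,
    product_sd,
    propagate_error,
)
from gutharvest.synthetic import (
    BRITISH_REFERENCE_DIET,
    gen_diet_cohort,
    gen_fecal_cohort,
)


def mac_of(mmol, g_per_mmol=0.180, scenario="custom"):
    return MacResult(mac_g=mmol * g_per_mmol, mac_mmol_hexose=mmol,
                     scenario=scenario)


def fecal_of(bacterial_g):
    # alpha_dw chosen freely; only bacterial_g enters the estimator
    dry = bacterial_g / 0.5
    return FecalOutput(wet_g=dry / 0.25, dry_g=dry, alpha_dw=0.25,
                       alpha_bac=0.5, bacterial_g=bacterial_g)


class TestEstimators:
    def test_via_feces_reference_point(self, reference_profile):
        """16 g/day bacterial biomass at 29 mmol/g gives 464 mmol/day."""
        est = estimate_via_feces(fecal_of(16.0), reference_profile)
        assert est.fp_tot == pytest.approx(464.0)
        assert est.method == "via_feces"

    def test_via_feces_zero_biomass(self, reference_profile):
        est = estimate_via_feces(fecal_of(0.0), reference_profile)
        assert est.fp_tot == 0.0

    def test_per_product_additivity(self, community_fixture):
        est = estimate_via_feces(fecal_of(10.0), community_fixture.community)
        assert est.fp_tot == pytest.approx(
            sum(max(v, 0) for v in est.fp_by_product.values()), rel=1e-12
        )

    def test_via_carbs_reference_chain(self, reference_profile):
        """198 mmol hexose/day at 13 mmol/g demand -> ~16 g biomass/day ->
        ~450 mmol/day at 29 mmol/g."""
        est = estimate_via_carbs(mac_of(198.0), reference_profile)
        assert est.biomass_g == pytest.approx(198.0 / 13.0)  # 15.23 g
        assert est.fp_tot == pytest.approx(198.0 / 13.0 * 29.0)  # 441.7

    def test_via_carbs_zero_mac(self, reference_profile):
        est = estimate_via_carbs(mac_of(0.0), reference_profile)
        assert est.fp_tot == 0.0
        assert est.biomass_g == 0.0

    def test_cross_consistency_on_matched_world(self, community_fixture):
        """When fecal bacterial biomass equals Y_carb * M_carb, the two
        estimators agree identically."""
        com = community_fixture.community
        mac = mac_of(198.0)
        biomass = mac.mac_mmol_hexose / com.carb_demand
        via_carbs = estimate_via_carbs(mac, com)
        via_feces = estimate_via_feces(fecal_of(biomass), com)
        assert via_feces.fp_tot == pytest.approx(via_carbs.fp_tot, rel=1e-9)
        for p in PRODUCTS:
            assert via_feces.fp_by_product[p] == pytest.approx(
                via_carbs.fp_by_product[p], rel=1e-9, abs=1e-12
            )

    def test_linearity(self, reference_profile):
        one = estimate_via_feces(fecal_of(1.0), reference_profile)
        seven = estimate_via_feces(fecal_of(7.0), reference_profile)
        assert seven.fp_tot == pytest.approx(7 * one.fp_tot, rel=1e-12)
        m1 = estimate_via_carbs(mac_of(50.0), reference_profile)
        m3 = estimate_via_carbs(mac_of(150.0), reference_profile)
        assert m3.fp_tot == pytest.approx(3 * m1.fp_tot, rel=1e-12)


class TestCarbonFlow:
    def test_ledger_balances_exactly(self, community_fixture):
        mac = mac_of(198.0)
        est = estimate_via_carbs(mac, community_fixture.community)
        flow = carbon_flow(mac, est)
        assert flow.absorbed_fp_carbon_g + flow.fecal_fp_loss_g == \
            pytest.approx(flow.fp_carbon_g, rel=1e-9)

    def test_fp_carbon_from_molar_fluxes(self, reference_profile):
        mac = mac_of(198.0)
        est = estimate_via_carbs(mac, reference_profile)
        expected = sum(
            est.fp_by_product[p] * CARBON_ATOMS[p] * CARBON_G_PER_MOL / 1000
            for p in PRODUCTS
        )
        assert carbon_flow(mac, est).fp_carbon_g == pytest.approx(expected)

    def test_most_mac_carbon_reaches_products(self, community_fixture):
        """On the calibrated synthetic community, >90% of MAC carbon ends up
        in fermentation products."""
        mac = mac_of(198.0)
        est = estimate_via_carbs(mac, community_fixture.community)
        assert carbon_flow(mac, est).fraction_to_fp > 0.90

    def test_zero_harvest(self, reference_profile):
        mac = mac_of(0.0)
        est = estimate_via_carbs(mac, reference_profile)
        flow = carbon_flow(mac_of(10.0), est)
        assert flow.fp_carbon_g == 0.0
        assert flow.absorbed_fp_carbon_g == 0.0

    def test_invalid_fraction(self, reference_profile):
        est = estimate_via_carbs(mac_of(10.0), reference_profile)
        with pytest.raises(DomainError):
            carbon_flow(mac_of(10.0), est, carbon_frac_carb=1.5)


class TestErrorPropagation:
    def test_quadrature_of_two_ten_percent_terms(self):
        rel = propagate_error([(10.0, 1.0), (20.0, 2.0)])
        assert rel == pytest.approx(np.sqrt(0.02), rel=1e-12)  # 14.14%

    def test_zero_sd_contributes_nothing(self):
        assert propagate_error([(10.0, 1.0), (5.0, 0.0)]) == \
            pytest.approx(0.1)

    def test_zero_value_with_sd_rejected(self):
        with pytest.raises(DomainError):
            propagate_error([(0.0, 1.0)])

    def test_matches_monte_carlo_oracle(self):
        """Gaussian propagation vs. a seeded 1e5-draw Monte-Carlo for a
        product of three terms with <= 15% relative SDs."""
        terms = [(16.0, 1.6), (29.0, 2.9), (1.0, 0.12)]
        rng = np.random.default_rng(20250730)
        draws = np.ones(100_000)
        for value, sd in terms:
            draws = draws * rng.normal(value, sd, 100_000)
        mc_rel = draws.std(ddof=1) / draws.mean()
        assert propagate_error(terms) == pytest.approx(mc_rel, rel=0.05)

    def test_product_sd_scales_result(self):
        assert product_sd(464.0, [(16.0, 1.6)]) == pytest.approx(46.4)


class TestVariation:
    def test_identical_samples_zero_cv(self, community_fixture):
        table = community_fixture.abundance
        dup = table.data[[table.sample_ids[0]]].copy()
        dup["copy1"] = dup.iloc[:, 0]
        dup["copy2"] = dup.iloc[:, 0]
        from gutharvest.community import AbundanceTable
        identical = AbundanceTable(data=dup, level="genus")
        summary = composition_variation(
            identical, community_fixture.profiles, mac_of(198.0)
        )
        assert summary.cv_total == pytest.approx(0.0, abs=1e-12)
        for cv in summary.cv_by_product.values():
            assert cv == pytest.approx(0.0, abs=1e-12) or np.isnan(cv)

    def test_total_less_variable_than_products(self, community_fixture):
        """Composition shifts products between types more than they change
        the total release."""
        summary = composition_variation(
            community_fixture.abundance, community_fixture.profiles,
            mac_of(198.0),
        )
        product_cvs = [cv for cv in summary.cv_by_product.values()
                       if not np.isnan(cv)]
        assert summary.cv_total < max(product_cvs)

    def test_cv_matches_brute_force(self, community_fixture):
        summary = composition_variation(
            community_fixture.abundance, community_fixture.profiles,
            mac_of(198.0),
        )
        totals = np.array([e.fp_tot for e in summary.per_sample.values()])
        assert summary.cv_total == pytest.approx(
            totals.std(ddof=1) / totals.mean(), rel=1e-12
        )
        but = np.array([
            max(e.fp_by_product["butyrate"], 0.0)
            for e in summary.per_sample.values()
        ])
        assert summary.cv_by_product["butyrate"] == pytest.approx(
            but.std(ddof=1) / but.mean(), rel=1e-12
        )

    def test_single_sample_rejected(self, community_fixture):
        table = community_fixture.abundance
        from gutharvest.community import AbundanceTable
        single = AbundanceTable(
            data=table.data[[table.sample_ids[0]]].copy(), level="genus"
        )
        with pytest.raises(InsufficientDataError):
            composition_variation(single, community_fixture.profiles,
                                  mac_of(198.0))


class TestCohorts:
    def test_single_record_median(self, reference_profile):
        summary = cohort_apply([BRITISH_REFERENCE_DIET], reference_profile)
        direct = estimate_via_carbs(
            map_to_mac(BRITISH_REFERENCE_DIET, "medium"), reference_profile
        )
        assert summary.median == pytest.approx(direct.fp_tot)
        assert summary.cv_total == 0.0

    def test_us_cohort_median_below_reference(self, reference_profile):
        """Western-style diets harvest less than the fiber-rich reference."""
        cohort = gen_diet_cohort("us", n=200, seed=1)
        summary = cohort_apply(cohort, reference_profile)
        reference = estimate_via_carbs(
            map_to_mac(BRITISH_REFERENCE_DIET, "medium"), reference_profile
        )
        assert summary.median < reference.fp_tot

    def test_percentiles_match_sorting_oracle(self, reference_profile):
        cohort = gen_fecal_cohort("global", n=101, seed=2)
        summary = cohort_apply(cohort, reference_profile)
        totals = np.sort(summary.totals())
        for q, value in summary.percentiles.items():
            # linear interpolation between order statistics
            pos = (len(totals) - 1) * q / 100.0
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expected = totals[lo] + (pos - lo) * (totals[hi] - totals[lo])
            assert value == pytest.approx(expected, rel=1e-12)

    def test_fecal_cohort_uses_feces_route(self, reference_profile):
        cohort = gen_fecal_cohort("british", n=5, seed=3)
        summary = cohort_apply(cohort, reference_profile)
        assert all(e.method == "via_feces" for e in summary.per_sample.values())

    def test_mixed_records_rejected(self, reference_profile):
        records = [BRITISH_REFERENCE_DIET, fecal_of(16.0)]
        with pytest.raises(TypeError):
            cohort_apply(records, reference_profile)

    def test_empty_cohort_rejected(self, reference_profile):
        with pytest.raises(InsufficientDataError):
            cohort_apply([], reference_profile)
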