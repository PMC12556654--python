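"""Rate extraction: growth fits, concentration slopes, carbon balance, pH."""

import math

import numpy as np
import pytest

from gutharvest.errors import (
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
)
from gutharvest.rates import (
    GrowthExperiment,
    GrowthSample,
    StrainRateProfile,
    carbon_balance,
    combine_replicates,
    compute_rate_profile,
    fit_concentration_slopes,
    fit_growth_rate,
    ph_sensitivity,
    profiles_from_experiments,
    read_growth_experiments,
    write_growth_experiments,
)
from gutharvest.synthetic import gen_growth_experiment


def make_experiment(times, ods, conc_fn=None, **kwargs):
    samples = [
        GrowthSample(
            time_h=t, od600=od,
            concentrations=conc_fn(od) if conc_fn else {},
        )
        for t, od in zip(times, ods)
    ]
    defaults = dict(strain_id="test", medium="YCA")
    defaults.update(kwargs)
    return GrowthExperiment(samples=samples, **defaults)


class TestGrowthRate:
    def test_exact_doubling_gives_ln2(self):
        times = [0.0, 1.0, 2.0, 3.0, 4.0]
        ods = [0.05 * 2**t for t in times]
        fit = fit_growth_rate(make_experiment(times, ods))
        assert fit.mu == pytest.approx(math.log(2), rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.is_growing()

    def test_constant_od_flagged_non_growing(self):
        fit = fit_growth_rate(make_experiment([0, 1, 2, 3], [0.1] * 4))
        assert fit.mu == 0.0
        assert not fit.is_growing()

    def test_recovery_from_noisy_synthetic(self):
        exp = gen_growth_experiment(mu=0.30, noise_sd=0.01, seed=1)
        fit = fit_growth_rate(exp)
        # OD itself is noiseless in the generator; mu recovery is exact to
        # numerical precision, well within the 5% recovery requirement.
        assert fit.mu == pytest.approx(0.30, rel=0.05)

    def test_too_few_points_raises(self):
        exp = make_experiment([0.0, 1.0], [0.05, 0.1])
        with pytest.raises(InsufficientDataError):
            fit_growth_rate(exp)

    def test_non_positive_od_rejected(self):
        with pytest.raises(DomainError):
            GrowthSample(time_h=0.0, od600=0.0)


class TestConcentrationSlopes:
    def test_exact_line_recovered(self):
        ods = [0.05, 0.1, 0.2, 0.4]
        exp = make_experiment(
            [0, 1, 2, 3], ods,
            conc_fn=lambda od: {"acetate": 1.0 + 12.0 * od,
                                "glucose": 20.0 - 8.0 * od},
        )
        slopes = fit_concentration_slopes(exp)
        assert slopes["acetate"].slope == pytest.approx(12.0, rel=1e-12)
        assert slopes["glucose"].slope == pytest.approx(-8.0, rel=1e-12)

    def test_noisy_slope_within_3_se(self):
        exp = gen_growth_experiment(
            mu=0.3, u=0.0, e_map={"acetate": 40.0}, od_to_dw=0.5,
            noise_sd=0.2, seed=7,
        )
        slopes = fit_concentration_slopes(exp)
        # generator slope = rate * od_to_dw = 20 mM/OD
        fit = slopes["acetate"]
        assert abs(fit.slope - 20.0) <= 3 * fit.slope_sd

    def test_identical_ods_degenerate(self):
        exp = make_experiment(
            [0, 1, 2, 3], [0.1] * 4, conc_fn=lambda od: {"acetate": 5.0}
        )
        with pytest.raises(DegenerateDesignError):
            fit_concentration_slopes(exp)

    def test_agrees_with_normal_equations_oracle(self):
        """OLS slope must match (X'X)^-1 X'y computed directly."""
        rng = np.random.default_rng(42)
        ods = np.linspace(0.05, 0.45, 6)
        conc = 3.0 + 17.0 * ods + rng.normal(0, 0.3, 6)
        exp = make_experiment(
            np.arange(6.0), ods,
            conc_fn=lambda od: {"acetate": float(conc[np.argmin(np.abs(ods - od))])},
        )
        x = np.column_stack([np.ones_like(ods), ods])
        beta = np.linalg.solve(x.T @ x, x.T @ conc)
        slopes = fit_concentration_slopes(exp, od_window=None)
        assert slopes["acetate"].slope == pytest.approx(beta[1], rel=1e-12)


class TestRateProfile:
    def test_unit_conversion(self):
        ods = [0.05, 0.1, 0.2, 0.4]
        exp = make_experiment(
            [0, 1, 2, 3], ods,
            conc_fn=lambda od: {"acetate": 14.5 * od, "glucose": 20.0 - 6.5 * od},
        )
        profile = compute_rate_profile(exp, od_to_dw=0.5)
        assert profile.e["acetate"] == pytest.approx(29.0, rel=1e-12)
        assert profile.u == pytest.approx(13.0, rel=1e-12)

    def test_noiseless_roundtrip_exact(self):
        e_map = {"acetate": 15.0, "butyrate": 5.0, "formate": 3.0}
        exp = gen_growth_experiment(u=13.0, e_map=e_map, od_to_dw=0.5,
                                    noise_sd=0.0, seed=3)
        profile = compute_rate_profile(exp, od_to_dw=0.5)
        assert profile.u == pytest.approx(13.0, rel=1e-9)
        for product, rate in e_map.items():
            assert profile.e[product] == pytest.approx(rate, rel=1e-9)

    def test_replicate_recovery_and_spread(self):
        profiles = [
            compute_rate_profile(
                gen_growth_experiment(
                    u=13.0, e_map={"acetate": 15.0}, noise_sd=0.1,
                    seed=100 + r, replicate_id=f"r{r}",
                ),
                od_to_dw=0.5,
            )
            for r in range(3)
        ]
        combined = combine_replicates(profiles)
        assert combined.n_replicates == 3
        assert combined.u == pytest.approx(13.0, rel=0.05)
        assert combined.e["acetate"] == pytest.approx(15.0, rel=0.05)
        assert combined.sds["acetate"] >= 0

    def test_u_hexose_doubles_for_maltose(self):
        p = StrainRateProfile(
            strain_id="s", medium="YCA", sugar="maltose", u=6.5,
            e={"acetate": 10.0},
        )
        assert p.u_hexose == pytest.approx(2 * p.u)

    def test_invalid_od_to_dw(self):
        exp = gen_growth_experiment(seed=5)
        with pytest.raises(DomainError):
            compute_rate_profile(exp, od_to_dw=0.0)

    def test_non_growing_replicate_excluded(self):
        growing = gen_growth_experiment(u=13.0, e_map={"acetate": 15.0},
                                        seed=11, replicate_id="r1")
        flat = make_experiment(
            [0, 1, 2, 3], [0.1] * 4,
            conc_fn=lambda od: {"acetate": 1.0, "glucose": 20.0},
            strain_id="synthetic_strain", replicate_id="r2",
        )
        profiles = profiles_from_experiments([growing, flat], od_to_dw=0.5)
        assert len(profiles) == 1
        assert profiles[0].n_replicates == 1


class TestCarbonBalance:
    def test_hand_computed_balance(self):
        p = StrainRateProfile(
            strain_id="s", medium="YCA", sugar="glucose", u=10.0,
            e={"acetate": 15.0, "butyrate": 5.0, "formate": 10.0},
        )
        bal = carbon_balance(p)
        assert bal.carbon_in == pytest.approx(60.0)
        assert bal.carbon_out == pytest.approx(30 + 20 + 10)
        assert bal.ratio == pytest.approx(1.0)
        assert not bal.excess

    def test_zero_excretion_gives_zero_ratio(self):
        p = StrainRateProfile(
            strain_id="s", medium="YCA", sugar="glucose", u=10.0,
            e={p: 0.0 for p in ("acetate", "butyrate")},
        )
        assert carbon_balance(p).ratio == 0.0

    def test_excess_flagged_above_1p1(self):
        p = StrainRateProfile(
            strain_id="s", medium="YCA", sugar="glucose", u=5.0,
            e={"acetate": 20.0},  # 40 mmol C out vs 30 in
        )
        assert carbon_balance(p).excess

    def test_zero_uptake_undefined(self):
        p = StrainRateProfile(
            strain_id="s", medium="YCA", sugar="glucose", u=0.0,
            e={"acetate": 1.0},
        )
        with pytest.raises(DomainError):
            carbon_balance(p)


class TestPhSensitivity:
    @staticmethod
    def make_profiles(slope, value_at_7, phs, noise=None, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for ph in phs:
            val = value_at_7 + slope * (ph - 7.0)
            if noise:
                val += rng.normal(0, noise)
            out.append(StrainRateProfile(
                strain_id="s", medium="YCA", sugar="glucose", u=val,
                e={"acetate": val}, ph=ph,
            ))
        return out

    def test_exact_linear_relative_change(self):
        profiles = self.make_profiles(2.0, 20.0, [5.5, 6.0, 6.5, 7.0, 7.5])
        sens = {s.quantity: s for s in ph_sensitivity(profiles)}
        assert sens["uptake"].slope_per_ph_unit == pytest.approx(2.0, rel=1e-12)
        assert sens["uptake"].relative_change_6_to_7 == pytest.approx(0.10)

    def test_ph_invariant_rates(self):
        profiles = self.make_profiles(0.0, 20.0, [6.0, 6.5, 7.0])
        sens = {s.quantity: s for s in ph_sensitivity(profiles)}
        assert sens["uptake"].slope_per_ph_unit == pytest.approx(0.0, abs=1e-12)
        assert sens["uptake"].relative_change_6_to_7 == pytest.approx(0.0, abs=1e-12)

    def test_noisy_slope_within_2_se(self):
        profiles = self.make_profiles(1.5, 20.0, [5.5, 6.2, 6.9, 7.5],
                                      noise=0.3, seed=4)
        sens = {s.quantity: s for s in ph_sensitivity(profiles)}
        fit = sens["uptake"]
        assert abs(fit.slope_per_ph_unit - 1.5) <= 2 * fit.slope_sd

    def test_too_few_ph_levels(self):
        profiles = self.make_profiles(1.0, 20.0, [6.0, 7.0])
        with pytest.raises(InsufficientDataError):
            ph_sensitivity(profiles)


def test_growth_csv_roundtrip(tmp_path):
    experiments = [
        gen_growth_experiment(seed=s, replicate_id=f"r{s}", ph=6.8)
        for s in (1, 2)
    ]
    path = tmp_path / "growth.csv"
    write_growth_experiments(experiments, path)
    back = read_growth_experiments(path)
    assert len(back) == 2
    for orig, loaded in zip(experiments, back):
        assert loaded.strain_id == orig.strain_id
        assert loaded.ph == pytest.approx(orig.ph)
        assert len(loaded.samples) == len(orig.samples)
        for s0, s1 in zip(orig.samples, loaded.samples):
            assert s1.od600 == pytest.approx(s0.od600)
            assert s1.concentrations == pytest.approx(s0.concentrations)
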