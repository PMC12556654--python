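"""Per-biomass uptake and excretion rates from growth experiments.

During steady exponential growth, metabolite concentrations in a batch
culture change linearly with bacterial density (OD600): the slope of
concentration against OD, divided by the OD-to-dry-weight conversion, is the
per-biomass rate in mmol per g dry biomass.  This module fits growth rates
(OLS on log-OD vs. time), concentration-vs-OD slopes, converts them to
:class:`StrainRateProfile` objects, validates them with a carbon balance,
and quantifies how the rates shift with environmental pH.

Conventions
-----------
* Uptake rates (``u``) are positive; they come from negative
  concentration slopes of the sugar.
* Excretion rates (``e``) are positive for net excretion.  Acetate is
  treated as a *net* rate and may be negative, because the standard growth
  medium contains 10 mM background acetate and acetogens can consume it.
  All other products are clipped at zero (with a warning if the fitted
  slope is significantly negative).
* ``u_hexose`` expresses uptake in hexose equivalents: maltose counts twice.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemistry import CARBON_ATOMS, PRODUCTS, SUGARS, hexose_multiplier
from .errors import DegenerateDesignError, DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Default OD600 window inside which absorbance is linear in biomass.
DEFAULT_OD_WINDOW: tuple[float, float] = (0.04, 0.5)

#: Default OD600 → dry-weight conversion, g dry biomass per litre per OD unit.
#: Not a measured constant of this framework — expose it explicitly and
#: record the value used with every rate profile.
DEFAULT_OD_TO_DW: float = 0.5

#: Replicates with r² below this (or non-positive growth rate) are excluded.
DEFAULT_MIN_R_SQUARED: float = 0.9


@dataclass(frozen=True)
class GrowthSample:
    """One sampling point: time (h), OD600, metabolite concentrations (mM)."""

    time_h: float
    od600: float
    concentrations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.od600 <= 0:
            raise DomainError(f"od600 must be > 0, got {self.od600}")
        for name, conc in self.concentrations.items():
            if conc < 0:
                raise DomainError(f"concentration of {name} is negative: {conc}")


@dataclass
class GrowthExperiment:
    """A batch-culture growth experiment for one strain in one medium.

    ``samples`` must be ordered by strictly increasing time.  Experiments
    destined for rate extraction should carry at least four sampled points
    with concentrations; fits themselves require three.
    """

    strain_id: str
    medium: str
    samples: list[GrowthSample]
    ph: float | None = None
    replicate_id: str = "r1"

    def __post_init__(self):
        if len(self.samples) < 2:
            raise InsufficientDataError(
                f"{self.strain_id}/{self.replicate_id}: need >= 2 samples"
            )
        times = [s.time_h for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError("sample times must be strictly increasing")

    def metabolites(self) -> list[str]:
        names: list[str] = []
        for s in self.samples:
            for n in s.concentrations:
                if n not in names:
                    names.append(n)
        return names


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth-rate fit: OLS slope of ln(OD600) against time."""

    mu: float  # 1/h
    mu_sd: float  # standard error of the slope, 1/h
    r_squared: float

    def is_growing(self, min_r_squared: float = DEFAULT_MIN_R_SQUARED) -> bool:
        return self.mu > 0 and self.r_squared >= min_r_squared


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of concentration (mM) against OD600, with its SE."""

    slope: float
    slope_sd: float


@dataclass
class StrainRateProfile:
    """Per-biomass uptake/excretion rates for one strain in one medium.

    Units are mmol per g dry biomass.  ``u`` is sugar uptake in sugar
    molecules; ``u_hexose`` in hexose equivalents (2x for maltose).  ``e``
    maps each fermentation product to its net excretion rate; ``sds`` holds
    matching standard deviations (keys: ``"u"`` plus the product names).
    """

    strain_id: str
    medium: str
    sugar: str
    u: float
    e: dict[str, float]
    lineage: tuple[str, ...] = ()
    sds: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 1
    ph: float | None = None
    od_to_dw: float = DEFAULT_OD_TO_DW

    def __post_init__(self):
        if self.sugar not in SUGARS:
            raise DomainError(f"unknown sugar {self.sugar!r}")
        if self.u < 0:
            raise DomainError(f"uptake rate must be >= 0, got {self.u}")
        for p, rate in self.e.items():
            if p != "acetate" and rate < 0:
                raise DomainError(f"net excretion of {p} is negative: {rate}")
        for k, sd in self.sds.items():
            if sd < 0:
                raise DomainError(f"sd[{k}] is negative")

    @property
    def u_hexose(self) -> float:
        """Uptake in mmol hexose equivalents per g dry biomass."""
        return self.u * hexose_multiplier(self.sugar)

    @property
    def e_total(self) -> float:
        """Total net fermentation-product excretion, mmol/g (acetate signed)."""
        return sum(
            rate if p == "acetate" else max(rate, 0.0) for p, rate in self.e.items()
        )

    @property
    def genus(self) -> str | None:
        """Genus label from the lineage (second-to-last rank), if present."""
        if len(self.lineage) >= 2:
            return self.lineage[-2]
        return None


@dataclass(frozen=True)
class CarbonBalance:
    """Carbon in consumed sugar vs. carbon in excreted products, per g biomass."""

    carbon_in: float  # mmol C / g dry biomass
    carbon_out: float  # mmol C / g dry biomass
    ratio: float

    @property
    def excess(self) -> bool:
        """Ratio > 1.1 flags likely utilization of other media components."""
        return self.ratio > 1.1


@dataclass(frozen=True)
class PhSensitivity:
    """Linear pH trend of one rate and its relative change from pH 6 to 7."""

    quantity: str  # "uptake" | "excretion_total" | "excretion_<product>"
    slope_per_ph_unit: float  # mmol / g / pH unit
    slope_sd: float
    relative_change_6_to_7: float


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _window_samples(
    exp: GrowthExperiment, od_window: tuple[float, float] | None
) -> list[GrowthSample]:
    if od_window is None:
        return list(exp.samples)
    lo, hi = od_window
    kept = [s for s in exp.samples if lo <= s.od600 <= hi]
    if len(kept) < len(exp.samples):
        logger.debug(
            "%s/%s: %d of %d samples outside OD window [%g, %g] dropped",
            exp.strain_id, exp.replicate_id,
            len(exp.samples) - len(kept), len(exp.samples), lo, hi,
        )
    return kept


def fit_growth_rate(
    exp: GrowthExperiment, od_window: tuple[float, float] | None = None
) -> GrowthFit:
    """Fit the exponential growth rate mu by OLS on ln(OD600) vs. time.

    Returns the slope as ``mu`` (1/h) with its standard error.  A constant
    OD series yields mu = 0 and ``is_growing() == False``.
    """
    samples = _window_samples(exp, od_window)
    if len(samples) < 3:
        raise InsufficientDataError(
            f"{exp.strain_id}/{exp.replicate_id}: need >= 3 OD points, "
            f"have {len(samples)}"
        )
    t = np.array([s.time_h for s in samples])
    log_od = np.log([s.od600 for s in samples])
    res = stats.linregress(t, log_od)
    r2 = res.rvalue**2
    if math.isnan(r2):  # constant log-OD: zero variance in y
        r2 = 0.0
    return GrowthFit(mu=res.slope, mu_sd=res.stderr, r_squared=r2)


def fit_concentration_slopes(
    exp: GrowthExperiment, od_window: tuple[float, float] | None = None
) -> dict[str, SlopeFit]:
    """OLS slope of each metabolite's concentration (mM) against OD600.

    Negative slopes mean net uptake, positive net excretion.  Raises
    :class:`DegenerateDesignError` if all OD values are identical.
    """
    samples = _window_samples(exp, od_window)
    out: dict[str, SlopeFit] = {}
    for met in exp.metabolites():
        pairs = [
            (s.od600, s.concentrations[met])
            for s in samples
            if met in s.concentrations
        ]
        if len(pairs) < 3:
            raise InsufficientDataError(
                f"{exp.strain_id}/{exp.replicate_id}: metabolite {met!r} has "
                f"{len(pairs)} paired points, need >= 3"
            )
        od, conc = map(np.asarray, zip(*pairs))
        if np.ptp(od) == 0:
            raise DegenerateDesignError(
                f"{exp.strain_id}/{exp.replicate_id}: all OD values identical"
            )
        res = stats.linregress(od, conc)
        out[met] = SlopeFit(slope=res.slope, slope_sd=res.stderr)
    return out


def compute_rate_profile(
    exp: GrowthExperiment,
    od_to_dw: float = DEFAULT_OD_TO_DW,
    od_window: tuple[float, float] | None = DEFAULT_OD_WINDOW,
    lineage: tuple[str, ...] = (),
) -> StrainRateProfile:
    """Convert concentration-vs-OD slopes into per-biomass rates.

    ``e_i = slope_i / od_to_dw`` (mM per OD divided by g/L per OD gives
    mmol/g); ``u = -slope_sugar / od_to_dw``.  Exactly one of glucose or
    maltose must be among the measured metabolites.
    """
    if od_to_dw <= 0:
        raise DomainError(f"od_to_dw must be > 0, got {od_to_dw}")
    slopes = fit_concentration_slopes(exp, od_window)
    sugars_present = [s for s in SUGARS if s in slopes]
    if len(sugars_present) != 1:
        raise DomainError(
            f"{exp.strain_id}: expected exactly one sugar among metabolites, "
            f"found {sugars_present}"
        )
    sugar = sugars_present[0]
    u = -slopes[sugar].slope / od_to_dw
    if u < 0:
        if abs(slopes[sugar].slope) > 2 * slopes[sugar].slope_sd:
            warnings.warn(
                f"{exp.strain_id}: significantly negative uptake of {sugar} "
                f"clipped to 0", stacklevel=2,
            )
        u = 0.0
    e: dict[str, float] = {}
    sds: dict[str, float] = {"u": slopes[sugar].slope_sd / od_to_dw}
    for product in PRODUCTS:
        if product not in slopes:
            continue
        rate = slopes[product].slope / od_to_dw
        if product != "acetate" and rate < 0:
            if abs(slopes[product].slope) > 2 * slopes[product].slope_sd:
                warnings.warn(
                    f"{exp.strain_id}: significantly negative net excretion of "
                    f"{product} clipped to 0", stacklevel=2,
                )
            rate = 0.0
        e[product] = rate
        sds[product] = slopes[product].slope_sd / od_to_dw
    return StrainRateProfile(
        strain_id=exp.strain_id,
        medium=exp.medium,
        sugar=sugar,
        u=u,
        e=e,
        lineage=lineage,
        sds=sds,
        n_replicates=1,
        ph=exp.ph,
        od_to_dw=od_to_dw,
    )


def combine_replicates(profiles: list[StrainRateProfile]) -> StrainRateProfile:
    """Unweighted mean across biological replicates, SD across replicates.

    SDs are sample standard deviations (ddof=1), never standard errors;
    with a single replicate the per-fit slope SEs are retained.
    """
    if not profiles:
        raise InsufficientDataError("no replicate profiles to combine")
    if len(profiles) == 1:
        return profiles[0]
    first = profiles[0]
    for p in profiles[1:]:
        if (p.strain_id, p.medium, p.sugar) != (
            first.strain_id, first.medium, first.sugar,
        ):
            raise DomainError("replicates must share strain, medium and sugar")
    products = sorted({p_name for prof in profiles for p_name in prof.e})
    u_vals = np.array([p.u for p in profiles])
    e_mean: dict[str, float] = {}
    sds: dict[str, float] = {"u": float(np.std(u_vals, ddof=1))}
    for product in products:
        vals = np.array([p.e.get(product, 0.0) for p in profiles])
        e_mean[product] = float(np.mean(vals))
        sds[product] = float(np.std(vals, ddof=1))
    return StrainRateProfile(
        strain_id=first.strain_id,
        medium=first.medium,
        sugar=first.sugar,
        u=float(np.mean(u_vals)),
        e=e_mean,
        lineage=first.lineage,
        sds=sds,
        n_replicates=len(profiles),
        ph=first.ph,
        od_to_dw=first.od_to_dw,
    )


def profiles_from_experiments(
    experiments: list[GrowthExperiment],
    od_to_dw: float = DEFAULT_OD_TO_DW,
    od_window: tuple[float, float] | None = DEFAULT_OD_WINDOW,
    min_r_squared: float = DEFAULT_MIN_R_SQUARED,
    lineages: dict[str, tuple[str, ...]] | None = None,
) -> list[StrainRateProfile]:
    """Full extraction pipeline: per-replicate fits, QC, replicate averaging.

    Replicates with non-growing fits (mu <= 0 or r² below ``min_r_squared``)
    are excluded with a logged reason.  Returns one profile per
    (strain, medium) group that retains at least one growing replicate.
    """
    groups: dict[tuple[str, str], list[GrowthExperiment]] = {}
    for exp in experiments:
        groups.setdefault((exp.strain_id, exp.medium), []).append(exp)
    out: list[StrainRateProfile] = []
    for (strain, medium), exps in groups.items():
        replicate_profiles = []
        for exp in exps:
            fit = fit_growth_rate(exp, od_window)
            if not fit.is_growing(min_r_squared):
                logger.info(
                    "excluding %s/%s in %s: mu=%.3g, r2=%.3f (non-growing)",
                    strain, exp.replicate_id, medium, fit.mu, fit.r_squared,
                )
                continue
            lineage = (lineages or {}).get(strain, ())
            replicate_profiles.append(
                compute_rate_profile(exp, od_to_dw, od_window, lineage)
            )
        if replicate_profiles:
            out.append(combine_replicates(replicate_profiles))
        else:
            logger.warning("no growing replicate for %s in %s", strain, medium)
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def carbon_balance(
    profile: StrainRateProfile, carbon_atoms: dict[str, int] | None = None
) -> CarbonBalance:
    """Balance carbon in consumed sugar against carbon in excreted products.

    Only net-positive excretion counts as output.  Ratios near 1 indicate
    that essentially all sugar carbon ends up in fermentation products;
    ratios above 1.1 are flagged (``excess``) as likely utilization of
    other media components.
    """
    atoms = dict(CARBON_ATOMS)
    if carbon_atoms:
        atoms.update(carbon_atoms)
    if profile.u == 0:
        raise DomainError("carbon balance undefined for zero uptake")
    carbon_in = profile.u * atoms[profile.sugar]
    carbon_out = sum(
        rate * atoms[p] for p, rate in profile.e.items() if rate > 0
    )
    return CarbonBalance(
        carbon_in=carbon_in, carbon_out=carbon_out, ratio=carbon_out / carbon_in
    )


def ph_sensitivity(profiles: list[StrainRateProfile]) -> list[PhSensitivity]:
    """Linear pH trends of uptake and excretion rates across pH conditions.

    Each profile must carry ``ph``; at least three distinct pH levels are
    required.  The relative change from pH 6 to 7 is the fitted slope
    divided by the fitted value at pH 7 (sign preserved).
    """
    if any(p.ph is None for p in profiles):
        raise DomainError("all profiles must have ph set")
    phs = np.array([p.ph for p in profiles], dtype=float)
    if len(set(phs.tolist())) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct pH levels, have {len(set(phs.tolist()))}"
        )
    quantities: dict[str, np.ndarray] = {
        "uptake": np.array([p.u for p in profiles]),
        "excretion_total": np.array([p.e_total for p in profiles]),
    }
    for product in PRODUCTS:
        if any(product in p.e for p in profiles):
            quantities[f"excretion_{product}"] = np.array(
                [p.e.get(product, 0.0) for p in profiles]
            )
    out = []
    for name, values in quantities.items():
        res = stats.linregress(phs, values)
        value_at_7 = res.intercept + 7.0 * res.slope
        rel = res.slope / value_at_7 if value_at_7 != 0 else float("nan")
        out.append(
            PhSensitivity(
                quantity=name,
                slope_per_ph_unit=res.slope,
                slope_sd=res.stderr,
                relative_change_6_to_7=rel,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

GROWTH_CSV_COLUMNS = [
    "strain_id", "replicate_id", "medium", "ph",
    "time_h", "od600", "metabolite", "concentration_mM",
]


def read_growth_experiments(path) -> list[GrowthExperiment]:
    """Read long-format growth CSV (one row per sample x metabolite)."""
    df = pd.read_csv(path)
    missing = set(GROWTH_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"growth CSV missing columns: {sorted(missing)}")
    out = []
    for (strain, rep, medium), grp in df.groupby(
        ["strain_id", "replicate_id", "medium"], sort=False
    ):
        ph_vals = grp["ph"].dropna().unique()
        ph = float(ph_vals[0]) if len(ph_vals) else None
        samples = []
        for (t, od), sg in grp.groupby(["time_h", "od600"], sort=True):
            conc = dict(zip(sg["metabolite"], sg["concentration_mM"].astype(float)))
            samples.append(GrowthSample(time_h=float(t), od600=float(od),
                                        concentrations=conc))
        out.append(GrowthExperiment(
            strain_id=str(strain), medium=str(medium), samples=samples,
            ph=ph, replicate_id=str(rep),
        ))
    return out


def write_growth_experiments(experiments: list[GrowthExperiment], path) -> None:
    rows = []
    for exp in experiments:
        for s in exp.samples:
            for met, conc in s.concentrations.items():
                rows.append({
                    "strain_id": exp.strain_id,
                    "replicate_id": exp.replicate_id,
                    "medium": exp.medium,
                    "ph": exp.ph,
                    "time_h": s.time_h,
                    "od600": s.od600,
                    "metabolite": met,
                    "concentration_mM": conc,
                })
    pd.DataFrame(rows, columns=GROWTH_CSV_COLUMNS).to_csv(path, index=False)


def write_rate_profiles(profiles: list[StrainRateProfile], path) -> None:
    """One row per strain x medium; rates, SDs, replicate count, provenance."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "strain_id": p.strain_id,
            "medium": p.medium,
            "sugar": p.sugar,
            "lineage": "|".join(p.lineage),
            "u_mmol_per_g": p.u,
            "u_hexose_mmol_per_g": p.u_hexose,
            "sd_u_mmol_per_g": p.sds.get("u", 0.0),
        }
        for product in PRODUCTS:
            row[f"e_{product}_mmol_per_g"] = p.e.get(product, 0.0)
            row[f"sd_e_{product}_mmol_per_g"] = p.sds.get(product, 0.0)
        row["n_replicates"] = p.n_replicates
        row["od_to_dw_g_per_l_od"] = p.od_to_dw
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rate_profiles(path) -> list[StrainRateProfile]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        e = {p: float(row[f"e_{p}_mmol_per_g"]) for p in PRODUCTS
             if f"e_{p}_mmol_per_g" in row}
        sds = {"u": float(row.get("sd_u_mmol_per_g", 0.0))}
        for p in PRODUCTS:
            col = f"sd_e_{p}_mmol_per_g"
            if col in row:
                sds[p] = float(row[col])
        lineage = tuple(str(row.get("lineage", "")).split("|")) \
            if isinstance(row.get("lineage"), str) and row.get("lineage") else ()
        out.append(StrainRateProfile(
            strain_id=str(row["strain_id"]),
            medium=str(row["medium"]),
            sugar=str(row["sugar"]),
            u=float(row["u_mmol_per_g"]),
            e=e,
            lineage=lineage,
            sds=sds,
            n_replicates=int(row.get("n_replicates", 1)),
            od_to_dw=float(row.get("od_to_dw_g_per_l_od", DEFAULT_OD_TO_DW)),
        ))
    return out
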