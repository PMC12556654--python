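"""Synthetic input generators emulating the statistical structure of the data.

Every stage of the framework can be exercised without downloads: growth
experiments (exponential OD with linearly coupled metabolite trends plus
noise), strain rate archetypes by bacterial family, Dirichlet community
compositions with uneven genus abundances, diet cohorts (right-skewed
US-style, seasonal forager-style, and a fixed British-style reference), and
fecal wet-weight cohorts (narrow 1970s-UK-like vs. heavy-tailed global).

Determinism: every generator derives its own RNG stream from
(seed, generator-name), so outputs are bit-for-bit reproducible and adding a
generator never shifts another's stream.  Calibration: archetype communities
are built so strain carbon balances lie in [0.90, 1.05] and the default
community lands near the measured constants (~29 mmol products/g,
~13 mmol hexose/g, reference MACs ~36 g/day); those constants are targets
of calibration tests, never hard-coded outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import CARBON_ATOMS, hexose_multiplier
from .community import AbundanceTable, CommunityProfile, weight_profiles
from .diet import DietRecord, write_diet_csv
from .errors import ConfigError, DomainError
from .fecal import FecalOutput, bacterial_biomass, write_fecal_csv
from .harvest import DEFAULT_SEED
from .rates import (
    GrowthExperiment,
    GrowthSample,
    StrainRateProfile,
    write_growth_experiments,
    write_rate_profiles,
)


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream per (seed, generator-name)."""
    return np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]
    )


# ---------------------------------------------------------------------------
# Growth experiments
# ---------------------------------------------------------------------------


def gen_growth_experiment(
    mu: float = 0.30,
    u: float = 13.0,
    e_map: dict[str, float] | None = None,
    od_to_dw: float = 0.5,
    n_points: int = 6,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    sugar: str = "glucose",
    sugar_mm: float = 20.0,
    strain_id: str = "synthetic_strain",
    medium: str = "YCA",
    replicate_id: str = "r1",
    ph: float | None = None,
    od_range: tuple[float, float] = (0.05, 0.45),
) -> GrowthExperiment:
    """Exponential growth with metabolite concentrations linear in OD.

    OD grows at rate ``mu`` across ``od_range``; each product concentration
    rises with slope ``e_i * od_to_dw`` (mM per OD unit), the sugar falls
    with slope ``u * od_to_dw``, and Gaussian noise of absolute SD
    ``noise_sd`` (mM) is added to every concentration.
    """
    if mu <= 0:
        raise DomainError("mu must be > 0")
    if n_points < 4:
        raise DomainError("need n_points >= 4")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    e_map = dict(e_map) if e_map else {"acetate": 15.0, "butyrate": 5.0}
    rng = _rng(seed, f"growth:{strain_id}:{replicate_id}")
    ods = np.geomspace(od_range[0], od_range[1], n_points)
    times = np.log(ods / ods[0]) / mu
    samples = []
    for t, od in zip(times, ods):
        conc = {
            sugar: max(
                sugar_mm - u * od_to_dw * od + rng.normal(0.0, noise_sd), 0.0
            )
        }
        for product, rate in e_map.items():
            conc[product] = max(
                rate * od_to_dw * od + rng.normal(0.0, noise_sd), 0.0
            )
        samples.append(GrowthSample(time_h=float(t), od600=float(od),
                                    concentrations=conc))
    return GrowthExperiment(
        strain_id=strain_id, medium=medium, samples=samples,
        ph=ph, replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# Strain archetypes
# ---------------------------------------------------------------------------

#: Family archetypes: genus pool, taxonomy, and molar product split of total
#: excretion.  Splits reflect the field's canonical fermentation types
#: (succinate/propionate producers, butyrate producers, lactate:acetate 3:2
#: heterolactic producers, mixed-acid fermenters).
FAMILY_ARCHETYPES: dict[str, dict] = {
    "Bacteroidaceae": {
        "taxonomy": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales"),
        "genera": ("Bacteroides", "Phocaeicola", "Parabacteroides", "Prevotella"),
        "split": {"acetate": 0.45, "propionate": 0.30, "succinate": 0.25},
    },
    "Lachnospiraceae": {
        "taxonomy": ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales"),
        "genera": ("Blautia", "Roseburia", "Agathobacter", "Dorea",
                   "Lachnospira", "Fusicatenibacter"),
        "split": {"butyrate": 0.45, "acetate": 0.40, "formate": 0.15},
    },
    "Ruminococcaceae": {
        "taxonomy": ("Bacteria", "Bacillota", "Clostridia", "Eubacteriales"),
        "genera": ("Faecalibacterium", "Ruminococcus", "Gemmiger"),
        "split": {"acetate": 0.45, "butyrate": 0.30, "formate": 0.25},
    },
    "Bifidobacteriaceae": {
        "taxonomy": ("Bacteria", "Actinomycetota", "Actinomycetes",
                     "Bifidobacteriales"),
        "genera": ("Bifidobacterium", "Alloscardovia"),
        "split": {"lactate": 0.60, "acetate": 0.40},  # 3:2 molar
    },
    "Enterobacteriaceae": {
        "taxonomy": ("Bacteria", "Pseudomonadota", "Gammaproteobacteria",
                     "Enterobacterales"),
        "genera": ("Escherichia",),
        "split": {"acetate": 0.35, "formate": 0.35, "lactate": 0.20,
                  "succinate": 0.10},
    },
}

#: Typical biomass share of each family among the characterized fraction of
#: a healthy adult gut community.
FAMILY_WEIGHTS: dict[str, float] = {
    "Bacteroidaceae": 0.40,
    "Lachnospiraceae": 0.30,
    "Ruminococcaceae": 0.15,
    "Bifidobacteriaceae": 0.10,
    "Enterobacteriaceae": 0.05,
}

#: Target per-strain hexose demand, mmol hexose equivalents per g biomass.
ARCHETYPE_U_HEXOSE = 13.0
#: Per-strain draw spread around the target (uniform +/- this fraction).
ARCHETYPE_U_SPREAD = 0.30
#: Range of the fraction of sugar carbon recovered in fermentation products
#: (the strain carbon-balance ratio): near unity, as measured.
ARCHETYPE_CARBON_RANGE = (0.91, 1.01)


def _lineage(family: str, genus: str, species: str) -> tuple[str, ...]:
    kingdom, phylum, clazz, order = FAMILY_ARCHETYPES[family]["taxonomy"]
    return (kingdom, phylum, clazz, order, family, genus, species)


def gen_strain_archetypes(
    n_per_family: int = 4,
    seed: int = DEFAULT_SEED,
    families: list[str] | None = None,
) -> list[StrainRateProfile]:
    """Generate strain rate profiles following the family archetypes.

    Each strain draws its hexose demand around 13 mmol/g (+/-30%), a product
    split jittered around its family archetype, and a carbon-conversion
    fraction in [0.91, 1.01]; total excretion follows from carbon
    conservation (so every profile's carbon balance lies inside that range
    by construction, and total excretion lands around ~29 mmol/g).
    Every fourth strain grows on maltose to exercise the hexose doubling.
    """
    chosen = families or list(FAMILY_ARCHETYPES)
    unknown = set(chosen) - set(FAMILY_ARCHETYPES)
    if unknown:
        raise ConfigError(f"unknown families: {sorted(unknown)}")
    rng = _rng(seed, "strain_archetypes")
    profiles: list[StrainRateProfile] = []
    counter = 0
    for family in chosen:
        arch = FAMILY_ARCHETYPES[family]
        genera = arch["genera"]
        base_split = arch["split"]
        for k in range(n_per_family):
            genus = genera[k % len(genera)]
            u_hexose = ARCHETYPE_U_HEXOSE * rng.uniform(
                1 - ARCHETYPE_U_SPREAD, 1 + ARCHETYPE_U_SPREAD
            )
            carbon_frac = rng.uniform(*ARCHETYPE_CARBON_RANGE)
            jitter = rng.normal(1.0, 0.05, size=len(base_split)).clip(0.5)
            raw = np.array(list(base_split.values())) * jitter
            split = dict(zip(base_split, raw / raw.sum()))
            mean_c = sum(frac * CARBON_ATOMS[p] for p, frac in split.items())
            e_tot = carbon_frac * 6.0 * u_hexose / mean_c
            e = {p: frac * e_tot for p, frac in split.items()}
            sugar = "maltose" if counter % 4 == 3 else "glucose"
            u = u_hexose / hexose_multiplier(sugar)
            sds = {"u": 0.05 * u}
            sds.update({p: 0.05 * rate for p, rate in e.items()})
            species = f"{genus.lower()}_sp{k + 1}"
            profiles.append(
                StrainRateProfile(
                    strain_id=f"{genus}_{k + 1}",
                    medium="YCA",
                    sugar=sugar,
                    u=u,
                    e=e,
                    lineage=_lineage(family, genus, species),
                    sds=sds,
                    n_replicates=3,
                )
            )
            counter += 1
    return profiles


def archetype_genera() -> list[str]:
    """All genus names covered by the family archetypes."""
    return [g for arch in FAMILY_ARCHETYPES.values() for g in arch["genera"]]


# ---------------------------------------------------------------------------
# Community compositions
# ---------------------------------------------------------------------------


def _base_measure(n_genera: int) -> tuple[list[str], np.ndarray]:
    """Uneven base abundances: represented genera carry ~84% of biomass
    (family-weighted with within-family geometric decay), filler genera the
    rest."""
    lineages: list[str] = []
    weights: list[float] = []
    for family, arch in FAMILY_ARCHETYPES.items():
        genera = arch["genera"]
        decay = 0.6 ** np.arange(len(genera))
        decay /= decay.sum()
        kingdom, phylum, clazz, order = arch["taxonomy"]
        for genus, w in zip(genera, decay):
            lineages.append(
                f"k__{kingdom}|p__{phylum}|c__{clazz}|o__{order}"
                f"|f__{family}|g__{genus}"
            )
            weights.append(FAMILY_WEIGHTS[family] * w * 0.84)
    n_rep = len(lineages)
    n_filler = n_genera - n_rep
    if n_filler < 1:
        raise ConfigError(f"n_genera must exceed {n_rep}")
    filler_decay = 0.85 ** np.arange(n_filler)
    filler_decay = filler_decay / filler_decay.sum() * 0.16
    for j, w in enumerate(filler_decay):
        lineages.append(
            "k__Bacteria|p__OtherPhylum|c__OtherClass|o__OtherOrder"
            f"|f__OtherFamily{j + 1}|g__OtherGenus{j + 1}"
        )
        weights.append(float(w))
    base = np.array(weights)
    return lineages, base / base.sum()


def gen_abundance_samples(
    n_samples: int = 219,
    n_genera: int = 60,
    concentration: float = 50.0,
    seed: int = DEFAULT_SEED,
) -> AbundanceTable:
    """Dirichlet community compositions with uneven genus abundances.

    The base measure concentrates biomass in a few dominant genera (the
    archetype genera carry ~84% on average); ``concentration`` scales the
    Dirichlet precision — lower values give stronger sample-to-sample
    variation.
    """
    if concentration <= 0:
        raise DomainError("concentration must be > 0")
    if n_samples < 1:
        raise DomainError("n_samples must be >= 1")
    rng = _rng(seed, "abundance_samples")
    lineages, base = _base_measure(n_genera)
    draws = rng.dirichlet(concentration * base, size=n_samples)
    data = pd.DataFrame(
        draws.T, index=lineages,
        columns=[f"S{i + 1:03d}" for i in range(n_samples)],
    )
    data.index.name = "lineage"
    return AbundanceTable(data=data, level="genus")


# ---------------------------------------------------------------------------
# Diet cohorts
# ---------------------------------------------------------------------------

#: British-style reference diet, g/day: fiber-rich 1970s staple diet whose
#: medium-scenario MACs land at ~36 g/day.
BRITISH_REFERENCE_DIET = DietRecord(
    fiber_g=24.0, starch_g=185.0, sugar_g=100.0, protein_g=85.0,
    identifier="british_reference",
)


def gen_diet_cohort(
    kind: str, n: int = 200, seed: int = DEFAULT_SEED
) -> list[DietRecord]:
    """Diet cohorts: ``us`` (right-skewed lognormal intakes with medians
    below the reference), ``hadza_seasonal`` (12 monthly records with a
    sinusoidal carbohydrate cycle well above the reference), or
    ``reference`` (the fixed British-style record)."""
    if kind == "reference":
        return [BRITISH_REFERENCE_DIET]
    rng = _rng(seed, f"diet:{kind}")
    if kind == "us":
        fiber = rng.lognormal(np.log(15.0), 0.45, n)
        starch = rng.lognormal(np.log(125.0), 0.35, n)
        sugar = rng.lognormal(np.log(90.0), 0.40, n)
        protein = rng.lognormal(np.log(80.0), 0.30, n)
        return [
            DietRecord(float(f), float(st), float(sg), float(pr), f"us_{i + 1:04d}")
            for i, (f, st, sg, pr) in enumerate(zip(fiber, starch, sugar, protein))
        ]
    if kind == "hadza_seasonal":
        months = np.arange(12)
        phase = 2 * np.pi * (months - 1) / 12.0
        starch = 260.0 + 90.0 * np.sin(phase) + rng.normal(0, 20.0, 12)
        fiber = 65.0 + 35.0 * np.sin(phase) + rng.normal(0, 8.0, 12)
        sugar = 80.0 + 40.0 * np.sin(phase) + rng.normal(0, 10.0, 12)
        protein = rng.normal(100.0, 10.0, 12)
        return [
            DietRecord(
                max(float(f), 1.0), max(float(st), 10.0),
                max(float(sg), 1.0), max(float(pr), 10.0),
                f"month_{m + 1:02d}",
            )
            for m, (f, st, sg, pr) in enumerate(zip(fiber, starch, sugar, protein))
        ]
    raise ConfigError(
        f"unknown diet cohort kind {kind!r}; expected us|hadza_seasonal|reference"
    )


# ---------------------------------------------------------------------------
# Fecal cohorts
# ---------------------------------------------------------------------------

#: Reference wet weight for the British-style cohort, g/day.
BRITISH_WET_G = 120.0


def gen_fecal_cohort(
    kind: str,
    n: int = 200,
    seed: int = DEFAULT_SEED,
    model: str | None = None,
) -> list[FecalOutput]:
    """Fecal cohorts: ``british`` (narrow lognormal around ~120 g/day wet,
    constant dry-fraction model) or ``global`` (heavy right tail reaching
    several times the British mean, non-linear water-content model)."""
    rng = _rng(seed, f"fecal:{kind}")
    if kind == "british":
        wet = rng.lognormal(np.log(BRITISH_WET_G), 0.25, n)
        chosen_model = model or "constant"
    elif kind == "global":
        wet = rng.lognormal(np.log(130.0), 0.50, n)
        chosen_model = model or "nonlinear"
    else:
        raise ConfigError(
            f"unknown fecal cohort kind {kind!r}; expected british|global"
        )
    return [
        bacterial_biomass(float(w), model=chosen_model,
                          identifier=f"{kind}_{i + 1:04d}")
        for i, w in enumerate(wet)
    ]


# ---------------------------------------------------------------------------
# Bundled default community fixture
# ---------------------------------------------------------------------------


@dataclass
class CommunityFixture:
    """Archetype strains + compositions + the mean-abundance community profile."""

    profiles: list[StrainRateProfile]
    abundance: AbundanceTable
    mean_abundance: pd.Series
    community: CommunityProfile


def default_community(
    seed: int = DEFAULT_SEED,
    n_samples: int = 219,
    n_per_family: int = 4,
) -> CommunityFixture:
    """The default healthy-gut fixture used across tests and scenarios."""
    profiles = gen_strain_archetypes(n_per_family=n_per_family, seed=seed)
    table = gen_abundance_samples(n_samples=n_samples, seed=seed)
    mean_ab = table.mean_abundance()
    community = weight_profiles(profiles, mean_ab, level="genus")
    return CommunityFixture(
        profiles=profiles,
        abundance=table,
        mean_abundance=mean_ab,
        community=community,
    )


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------


def write_fixtures(directory, seed: int = DEFAULT_SEED) -> dict[str, str]:
    """Write all synthetic fixture files (CSV/TSV) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    experiments = []
    for rep in range(1, 4):
        experiments.append(
            gen_growth_experiment(
                mu=0.30, u=13.0, e_map={"acetate": 15.0, "butyrate": 5.0},
                noise_sd=0.05, seed=seed + rep, strain_id="demo_strain",
                replicate_id=f"r{rep}",
            )
        )
    paths["growth_csv"] = str(directory / "growth_experiments.csv")
    write_growth_experiments(experiments, paths["growth_csv"])

    fixture = default_community(seed=seed)
    paths["rates_csv"] = str(directory / "strain_rates.csv")
    write_rate_profiles(fixture.profiles, paths["rates_csv"])
    paths["abundance_tsv"] = str(directory / "abundance.tsv")
    fixture.abundance.to_tsv(paths["abundance_tsv"])

    for kind in ("reference", "us", "hadza_seasonal"):
        path = directory / f"diet_{kind}.csv"
        write_diet_csv(gen_diet_cohort(kind, seed=seed), path)
        paths[f"diet_{kind}_csv"] = str(path)
    for kind in ("british", "global"):
        path = directory / f"fecal_{kind}.csv"
        write_fecal_csv(gen_fecal_cohort(kind, seed=seed), path, cohort_id=kind)
        paths[f"fecal_{kind}_csv"] = str(path)
    return paths
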