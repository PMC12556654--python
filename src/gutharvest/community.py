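"""Abundance-weighted community metabolic profiles.

Relative-abundance tables (MetaPhlAn-style lineage strings x samples) are
aggregated to a chosen taxonomic rank, the biomass coverage of characterized
strains is computed, and strain rate profiles are combined into a community
profile: the abundance-weighted total excretion per g biomass (epsilon_tot),
per-product rates, and the carbohydrate demand per g biomass (whose
reciprocal is the biomass yield per mmol hexose, Y_carb).

The default rank is genus: coverage by characterized strains is already high
there while strain-level metabolic differences are not yet averaged away.
Unrepresented biomass is handled by dropping it and renormalizing over the
represented taxa (implicitly assigning it the represented-set average
behaviour); an alternative ``coverage_discount`` mode multiplies all fluxes
by the covered fraction instead, as a sensitivity analysis.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import PRODUCTS
from .errors import DomainError, NoRepresentationError, RankError
from .rates import StrainRateProfile

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = dict(zip("kpcofgs", RANKS))
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

#: Community constants measured for a typical healthy adult gut community:
#: total excretion ~29 mmol products per g dry biomass and a demand of
#: ~13 mmol hexose equivalents per g biomass produced, with a representative
#: molar product mix.  Used for reference-scenario point estimates.
REFERENCE_EPSILON_TOT = 29.0  # mmol / g dry biomass
REFERENCE_CARB_DEMAND = 13.0  # mmol hexose equivalents / g dry biomass
REFERENCE_PRODUCT_FRACTIONS = {
    "acetate": 0.40,
    "propionate": 0.13,
    "butyrate": 0.17,
    "lactate": 0.10,
    "formate": 0.12,
    "succinate": 0.08,
}


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``k__Bacteria|p__...|g__Bacteroides`` into {rank: name}."""
    out: dict[str, str] = {}
    for part in lineage.split("|"):
        part = part.strip()
        if len(part) >= 3 and part[1:3] == "__" and part[0] in RANK_PREFIXES:
            out[RANK_PREFIXES[part[0]]] = part[3:]
        elif part:
            raise DomainError(f"malformed lineage component {part!r}")
    return out


def lineage_rank(lineage: str) -> str:
    """Deepest rank present in a lineage string."""
    parsed = parse_lineage(lineage)
    if not parsed:
        raise DomainError(f"empty lineage {lineage!r}")
    return RANKS[max(_RANK_INDEX[r] for r in parsed)]


def taxon_name(lineage: str, rank: str) -> str | None:
    return parse_lineage(lineage).get(rank)


def truncate_lineage(lineage: str, rank: str) -> str:
    """Drop lineage components below ``rank``."""
    keep = _RANK_INDEX[rank]
    parts = [
        p for p in lineage.split("|")
        if p and _RANK_INDEX[RANK_PREFIXES[p[0]]] <= keep
    ]
    return "|".join(parts)


@dataclass
class AbundanceTable:
    """Relative abundances: rows are lineage strings, columns sample ids.

    Column sums must lie in [0.97, 1.0001] (fractions) and are renormalized
    to exactly 1.  Use :meth:`from_tsv` for MetaPhlAn-style files, where
    percentage scaling is auto-detected from column sums.
    """

    data: pd.DataFrame
    level: str

    def __post_init__(self):
        if self.level not in RANKS:
            raise RankError(f"unknown rank {self.level!r}")
        if (self.data.values < 0).any():
            raise DomainError("abundances must be >= 0")
        sums = self.data.sum(axis=0)
        bad = sums[(sums < 0.97) | (sums > 1.0001)]
        if len(bad):
            raise DomainError(
                f"per-sample abundance sums outside [0.97, 1.0001]: "
                f"{bad.to_dict()}"
            )
        if (np.abs(sums - 1.0) > 1e-12).any():
            self.data = self.data / sums
        for lin in self.data.index:
            if taxon_name(lin, self.level) is None:
                raise DomainError(
                    f"lineage {lin!r} lacks a {self.level}-level component"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def names(self) -> list[str]:
        """Taxon names at the table's level, aligned with rows."""
        return [taxon_name(lin, self.level) for lin in self.data.index]

    def sample(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def mean_abundance(self) -> pd.Series:
        """Across-sample mean relative abundance per taxon."""
        return self.data.mean(axis=1)

    @classmethod
    def from_tsv(cls, path, level: str | None = None) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sums = df.sum(axis=0)
        if (sums > 50).all():  # percentages
            logger.info("abundance table detected as percentages; dividing by 100")
            df = df / 100.0
        if level is None:
            level = lineage_rank(df.index[0])
        return cls(data=df, level=level)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="lineage")


def aggregate(table: AbundanceTable, target_level: str) -> AbundanceTable:
    """Sum abundances within ``target_level`` groups; totals are preserved.

    Aggregating to the table's own level is the identity; requesting a
    finer rank raises :class:`RankError`.
    """
    if target_level not in RANKS:
        raise RankError(f"unknown rank {target_level!r}")
    if _RANK_INDEX[target_level] > _RANK_INDEX[table.level]:
        raise RankError(
            f"cannot aggregate {table.level}-level table to finer rank "
            f"{target_level}"
        )
    if target_level == table.level:
        return AbundanceTable(data=table.data.copy(), level=table.level)
    grouped = table.data.groupby(
        [truncate_lineage(lin, target_level) for lin in table.data.index]
    ).sum()
    grouped.index.name = table.data.index.name
    return AbundanceTable(data=grouped, level=target_level)


def coverage(
    table: AbundanceTable, represented: set[str]
) -> tuple[pd.Series, float]:
    """Fraction of biomass covered by ``represented`` taxa, per sample.

    ``represented`` holds bare taxon names at the table's level (or full
    lineage strings).  Returns (per-sample series, across-sample mean).
    """
    names = table.names()
    mask = np.array([
        (name in represented) or (lin in represented)
        for name, lin in zip(names, table.data.index)
    ])
    if not mask.any():
        warnings.warn("no represented taxon found in table; coverage is 0",
                      stacklevel=2)
        per_sample = pd.Series(0.0, index=table.sample_ids)
        return per_sample, 0.0
    per_sample = table.data.loc[mask].sum(axis=0) / table.data.sum(axis=0)
    return per_sample, float(per_sample.mean())


@dataclass
class CommunityProfile:
    """Abundance-weighted community rates, per g community dry biomass."""

    epsilon_tot: float  # mmol products / g
    e_w: dict[str, float]  # product -> mmol / g (acetate may be net-negative)
    carb_demand: float  # mmol hexose equivalents / g
    coverage: float
    level: str = "genus"
    mode: str = "renormalize"
    sds: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.carb_demand <= 0:
            raise DomainError("carb_demand must be > 0")
        if not 0 <= self.coverage <= 1:
            raise DomainError("coverage must lie in [0, 1]")

    @property
    def y_carb(self) -> float:
        """Biomass yield, g dry biomass per mmol hexose equivalent."""
        return 1.0 / self.carb_demand

    @property
    def epsilon_tot_sd(self) -> float:
        return float(np.sqrt(sum(
            self.sds.get(p, 0.0) ** 2 for p in self.e_w
        )))

    def to_json(self, path=None) -> str:
        payload = {
            "epsilon_tot_mmol_per_g": self.epsilon_tot,
            "e_w_mmol_per_g": self.e_w,
            "carb_demand_mmol_per_g": self.carb_demand,
            "y_carb_g_per_mmol": self.y_carb,
            "coverage_fraction": self.coverage,
            "level": self.level,
            "mode": self.mode,
            "sds_mmol_per_g": self.sds,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CommunityProfile":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            epsilon_tot=d["epsilon_tot_mmol_per_g"],
            e_w=d["e_w_mmol_per_g"],
            carb_demand=d["carb_demand_mmol_per_g"],
            coverage=d["coverage_fraction"],
            level=d.get("level", "genus"),
            mode=d.get("mode", "renormalize"),
            sds=d.get("sds_mmol_per_g", {}),
            provenance=d.get("provenance", {}),
        )


def _epsilon_tot(e_w: dict[str, float]) -> float:
    # Net convention: non-acetate products floored at 0; acetate enters signed
    # (net community acetate uptake reduces the total).
    return sum(
        rate if p == "acetate" else max(rate, 0.0) for p, rate in e_w.items()
    )


def _profiles_by_taxon(
    profiles: list[StrainRateProfile], level: str
) -> dict[str, dict]:
    """Group strain profiles by taxon name at ``level``; unweighted mean
    of multiple strains mapping to the same taxon."""
    groups: dict[str, list[StrainRateProfile]] = {}
    for p in profiles:
        parsed = dict(zip(RANKS[-len(p.lineage):], p.lineage)) if p.lineage else {}
        name = parsed.get(level)
        if name is None:
            logger.debug("profile %s lacks %s-level lineage; skipped",
                         p.strain_id, level)
            continue
        groups.setdefault(name, []).append(p)
    out: dict[str, dict] = {}
    for name, plist in groups.items():
        n = len(plist)
        e_mean = {
            prod: float(np.mean([p.e.get(prod, 0.0) for p in plist]))
            for prod in PRODUCTS
        }
        sd_mean = {
            prod: float(
                np.sqrt(sum(p.sds.get(prod, 0.0) ** 2 for p in plist)) / n
            )
            for prod in PRODUCTS
        }
        out[name] = {
            "u_hexose": float(np.mean([p.u_hexose for p in plist])),
            "u_hexose_sd": float(
                np.sqrt(sum(p.sds.get("u", 0.0) ** 2 for p in plist)) / n
            ),
            "e": e_mean,
            "e_sds": sd_mean,
            "strains": [p.strain_id for p in plist],
        }
    return out


def weight_profiles(
    profiles: list[StrainRateProfile],
    abundances: pd.Series,
    level: str = "genus",
    mode: str = "renormalize",
) -> CommunityProfile:
    """Weight strain rate profiles by one sample's relative abundances.

    ``abundances`` is indexed by lineage strings or bare taxon names at
    ``level``.  Taxa without a characterized representative are dropped and
    the remaining weights renormalized to sum 1 (default), or kept as raw
    fractions so fluxes are discounted by coverage (``mode="coverage_discount"``).
    The covered fraction before renormalization is recorded as ``coverage``.
    """
    if mode not in ("renormalize", "coverage_discount"):
        raise DomainError(f"unknown weighting mode {mode!r}")
    by_taxon = _profiles_by_taxon(profiles, level)
    names = []
    for key in abundances.index:
        name = taxon_name(key, level) if "__" in str(key) else str(key)
        names.append(name)
    total = float(abundances.sum())
    if total <= 0:
        raise DomainError("abundance vector sums to 0")
    rep_mask = np.array([n in by_taxon for n in names])
    if not rep_mask.any() or float(abundances.values[rep_mask].sum()) == 0:
        raise NoRepresentationError(set(n for n in names if n is not None))
    rep_sum = float(abundances.values[rep_mask].sum())
    cov = rep_sum / total
    weights: dict[str, float] = {}
    for name, a in zip(names, abundances.values):
        if name in by_taxon and a > 0:
            weights[name] = weights.get(name, 0.0) + float(a)
    denom = rep_sum if mode == "renormalize" else total
    e_w = {prod: 0.0 for prod in PRODUCTS}
    var_w = {prod: 0.0 for prod in PRODUCTS}
    carb_demand = 0.0
    carb_var = 0.0
    for name, a in weights.items():
        w = a / denom
        entry = by_taxon[name]
        carb_demand += w * entry["u_hexose"]
        carb_var += (w * entry["u_hexose_sd"]) ** 2
        for prod in PRODUCTS:
            e_w[prod] += w * entry["e"][prod]
            var_w[prod] += (w * entry["e_sds"][prod]) ** 2
    sds = {prod: float(np.sqrt(v)) for prod, v in var_w.items()}
    sds["u_hexose"] = float(np.sqrt(carb_var))
    return CommunityProfile(
        epsilon_tot=_epsilon_tot(e_w),
        e_w=e_w,
        carb_demand=carb_demand,
        coverage=cov,
        level=level,
        mode=mode,
        sds=sds,
        provenance={
            "n_profiles": len(profiles),
            "n_taxa_represented": len(weights),
        },
    )


def reference_community_profile() -> CommunityProfile:
    """Community profile built from the measured healthy-gut constants.

    Total excretion 29 mmol/g split by the representative molar product mix,
    carbohydrate demand 13 mmol hexose equivalents/g.  This is the profile
    behind the reference-scenario point estimates; community profiles derived
    from abundance tables are used for variation analyses.
    """
    e_w = {
        p: REFERENCE_EPSILON_TOT * frac
        for p, frac in REFERENCE_PRODUCT_FRACTIONS.items()
    }
    return CommunityProfile(
        epsilon_tot=REFERENCE_EPSILON_TOT,
        e_w=e_w,
        carb_demand=REFERENCE_CARB_DEMAND,
        coverage=1.0,
        level="genus",
        mode="renormalize",
        provenance={"source": "reference healthy-gut community constants"},
    )
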