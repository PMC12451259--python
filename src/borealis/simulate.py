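"""Synthetic ITEX-like resurvey data with known ground truth.

The generator emulates the design facts of the real network — a nested
study-area > subsite > plot hierarchy (defaults: 32 areas, ~3.5 subsites
per area, ~10 plots per subsite, ≈1100 plots), two surveys 5–28 years
apart, relative covers summing to 100% per plot-year, and a 287-species
pool split into the four biogeographic classes (16 Boreal, 150
Boreal-Tundra, 14 Arctic, 107 Ubiquitous).

Dynamics between surveys are generative and fully known: each area-pool
species absent from a plot at the first survey colonises by the second
with probability ``logit⁻¹(α + β·covariates + γ·boreal-class)``; present
species go locally extinct with a fixed probability; survivors' covers
drift multiplicatively on the log scale before renormalisation (which
induces exactly the zero-sum coupling the abundance index assumes).
Morphospecies and abiotic records are injected at configurable rates so
the standardisation filters have something to remove. Every output is a
pure function of the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from borealis.composition import RECORD_COLUMNS

CLASS_POOL_SIZES = {"Boreal": 16, "BorealTundra": 150, "Arctic": 14, "Ubiquitous": 107}

#: Standardisation constants for covariates entering the colonisation
#: linear predictor (fixed generator constants, not data-derived).
_COV_SCALE = {"summer_temp_clim": (8.0, 2.0), "distance_treeline_raw": (50.0, 50.0)}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate the real network's design."""

    n_study_areas: int = 32
    mean_subsites_per_area: float = 3.5
    mean_plots_per_subsite: float = 10.0
    duration_range: tuple[int, int] = (5, 28)
    n_surveys: int = 2
    class_pool_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(CLASS_POOL_SIZES)
    )
    area_pool_size: int = 60
    baseline_richness: float = 10.0
    cover_concentration: float = 1.0
    colonisation_intercept: float = -3.6
    colonisation_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "summer_temp_clim": 0.3,
            "distance_treeline_raw": -0.3,
        }
    )
    boreal_colonisation_effect: float = 0.0  # γ: class-exchangeable by default
    extinction_probability: float = 0.12
    abundance_drift_scale: float = 0.4
    coloniser_cover_mean: float = 2.0  # raw units before renormalisation
    morphospecies_rate: float = 0.05  # per plot-year injection probability
    abiotic_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        pool = sum(self.class_pool_sizes.values())
        if self.area_pool_size > pool:
            raise ValueError("area_pool_size exceeds the global species pool")
        if self.baseline_richness > self.area_pool_size:
            raise ValueError("baseline richness exceeds the area pool size")
        if not (0 <= self.extinction_probability <= 1):
            raise ValueError("extinction probability must be in [0, 1]")
        if self.duration_range[0] < 1 or self.duration_range[0] > self.duration_range[1]:
            raise ValueError("invalid duration range")
        if self.n_surveys < 2:
            raise ValueError("need at least two surveys")


@dataclass
class GroundTruth:
    """Generating truth: species classes, per-plot turnover, coefficients."""

    species_class: dict[str, str]
    colonisers: dict[str, frozenset[str]]
    losses: dict[str, frozenset[str]]
    coefficients: dict

    def to_json(self) -> str:
        payload = {
            "species_class": self.species_class,
            "colonisers": {k: sorted(v) for k, v in self.colonisers.items()},
            "losses": {k: sorted(v) for k, v in self.losses.items()},
            "coefficients": self.coefficients,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SimulatedDataset:
    records: pd.DataFrame  # long composition table (canonical record columns)
    class_table: pd.DataFrame  # taxon, cls, source
    zone_occurrence: pd.DataFrame  # taxon + A..E + Boreal frequency categories
    covariates: pd.DataFrame  # one row per plot with subsite-level covariates
    traits: pd.DataFrame  # long (taxon, trait, value) records
    categorical_traits: pd.DataFrame  # taxon, functional_group
    truth: GroundTruth
    config: SimulationConfig

    def write_csvs(self, outdir) -> dict[str, str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("composition", self.records),
            ("class_table", self.class_table),
            ("zone_occurrence", self.zone_occurrence),
            ("covariates", self.covariates),
            ("traits", self.traits),
            ("categorical_traits", self.categorical_traits),
        ):
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False, float_format="%.10g")
            paths[name] = str(path)
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(self.truth.to_json())
        paths["ground_truth"] = str(truth_path)
        return paths


def _species_pool(config: SimulationConfig) -> dict[str, str]:
    pool = {}
    for cls, n in config.class_pool_sizes.items():
        for i in range(n):
            pool[f"{cls}_sp{i + 1:03d}"] = cls
    return pool


def _zone_occurrence_for_class(cls: str, rng: np.random.Generator) -> dict[str, str]:
    """Occurrence categories consistent with a class (for the classify stage)."""
    present = lambda: rng.choice(["frequent", "scattered"])
    absent = lambda: rng.choice(["rare", "uncertain", "absent", "absent"])
    occ = {z: absent() for z in ("A", "B", "C", "D", "E", "Boreal")}
    if cls == "Boreal":
        occ["Boreal"] = present()
    elif cls == "BorealTundra":
        occ["Boreal"] = present()
        occ[rng.choice(["D", "E"])] = present()
        if rng.random() < 0.5:
            occ["D"] = present()
            occ["E"] = present()
    elif cls == "Arctic":
        occ[rng.choice(["A", "B", "C", "D", "E"])] = present()
    elif cls == "Ubiquitous":
        occ["Boreal"] = present()
        occ[rng.choice(["D", "E"])] = present()
        occ[rng.choice(["A", "B", "C"])] = present()
    return occ


def _subsite_covariates(region: str, biome: str, rng: np.random.Generator) -> dict:
    oro = biome == "OroArctic"
    elev_site = rng.uniform(600, 1400) if oro else rng.uniform(0, 300)
    dist = abs(rng.normal(2, 1)) + 0.1 if oro else abs(rng.normal(100, 50)) + 1.0
    return {
        "region": region,
        "biome": biome,
        "latitude": rng.uniform(60, 70) if oro else rng.uniform(66, 80),
        "distance_treeline_raw": dist,
        "elevation": elev_site,
        "elevation_treeline": elev_site - rng.uniform(100, 500) if oro else np.nan,
        "barrier": rng.choice(["uninterrupted", "small_water", "mountains", "large_water"]),
        "summer_temp_clim": rng.normal(8, 2),
        "min_temp_clim": rng.normal(-20, 5),
        "precip_clim": max(rng.normal(500, 150), 100.0),
        "summer_temp_change": rng.normal(0.05, 0.02),
        "min_temp_change": rng.normal(0.06, 0.03),
        "precip_change": rng.normal(2, 1),
        "herbivory": rng.choice(["low", "medium", "high"]),
        "grazer": rng.choice(["none", "insects", "birds", "small_mammals", "large_mammals"]),
        "moisture": rng.choice(["dry", "moist", "wet", "mixed"]),
        "permafrost": rng.choice(["none", "sporadic", "discontinuous", "continuous"]),
    }


def _colonisation_probability(
    config: SimulationConfig, covariates: Mapping[str, float], is_boreal: bool
) -> float:
    lp = config.colonisation_intercept
    for var, coef in config.colonisation_coefficients.items():
        centre, scale = _COV_SCALE.get(var, (0.0, 1.0))
        lp += coef * (covariates[var] - centre) / scale
    if is_boreal:
        lp += config.boreal_colonisation_effect
    return float(1.0 / (1.0 + np.exp(-lp)))


def generate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Generate one synthetic resurvey dataset.

    ``seed`` overrides ``config.seed`` when given. All randomness flows
    from a single :class:`numpy.random.Generator`, so identical
    configuration and seed give byte-identical CSV output.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    species_class = _species_pool(config)
    all_species = sorted(species_class)
    boreal = {
        t for t, c in species_class.items() if c in ("Boreal", "BorealTundra")
    }

    zone_rows = []
    for taxon in all_species:
        occ = _zone_occurrence_for_class(species_class[taxon], rng)
        zone_rows.append({"taxon": taxon, **occ})
    zone_occurrence = pd.DataFrame(zone_rows)

    class_table = pd.DataFrame(
        {
            "taxon": all_species,
            "cls": [species_class[t] for t in all_species],
            "source": "rules",
        }
    )

    record_rows = []
    covariate_rows = []
    truth_col: dict[str, frozenset[str]] = {}
    truth_loss: dict[str, frozenset[str]] = {}

    for a in range(config.n_study_areas):
        area = f"area{a + 1:02d}"
        region = rng.choice(
            ["EasternNorthAmerica", "WesternNorthAmerica", "GreenlandIceland", "Eurasia"]
        )
        biome = rng.choice(["Arctic", "OroArctic"])
        area_pool = sorted(
            rng.choice(all_species, size=config.area_pool_size, replace=False)
        )
        n_subsites = 1 + rng.poisson(config.mean_subsites_per_area - 1)
        for s in range(n_subsites):
            subsite = f"{area}_sub{s + 1:02d}"
            cov = _subsite_covariates(region, biome, rng)
            n_plots = 1 + rng.poisson(config.mean_plots_per_subsite - 1)
            # survey campaigns are shared across a subsite's plots
            duration = int(rng.integers(config.duration_range[0],
                                        config.duration_range[1] + 1))
            start_year = int(rng.integers(1985, 2023 - duration + 1))
            years = np.linspace(start_year, start_year + duration,
                                config.n_surveys).round().astype(int)
            years = np.unique(years)
            for p in range(n_plots):
                plot = f"{subsite}_plot{p + 1:03d}"
                richness = min(
                    1 + rng.poisson(config.baseline_richness - 1), len(area_pool)
                )
                start_species = sorted(
                    rng.choice(area_pool, size=richness, replace=False)
                )
                alpha = np.full(richness, config.cover_concentration)
                start_cover = rng.dirichlet(alpha) * 100.0
                start_abund = dict(zip(start_species, start_cover))

                # end-survey dynamics
                colonisers = []
                for taxon in area_pool:
                    if taxon in start_abund:
                        continue
                    p_col = _colonisation_probability(config, cov, taxon in boreal)
                    if rng.random() < p_col:
                        colonisers.append(taxon)
                extinct = [
                    t for t in start_species
                    if rng.random() < config.extinction_probability
                ]
                end_abund = {}
                for taxon, cover in start_abund.items():
                    if taxon in extinct:
                        continue
                    drift = rng.lognormal(0.0, config.abundance_drift_scale)
                    end_abund[taxon] = cover * drift
                for taxon in colonisers:
                    end_abund[taxon] = rng.lognormal(
                        np.log(config.coloniser_cover_mean), 0.5
                    )
                if not end_abund:  # total extinction: keep one survivor
                    keep = start_species[0]
                    end_abund[keep] = start_abund[keep]
                    extinct = [t for t in extinct if t != keep]

                truth_col[plot] = frozenset(colonisers)
                truth_loss[plot] = frozenset(extinct)

                surveys = {int(years[0]): start_abund, int(years[-1]): end_abund}
                for year in years[1:-1]:
                    w = (year - years[0]) / (years[-1] - years[0])
                    mid = {}
                    for taxon in set(start_abund) | set(end_abund):
                        v = (1 - w) * start_abund.get(taxon, 0.0) + w * end_abund.get(taxon, 0.0)
                        if v > 0:
                            mid[taxon] = v
                    surveys[int(year)] = mid

                for year, abund in sorted(surveys.items()):
                    total = sum(abund.values())
                    for taxon, value in sorted(abund.items()):
                        record_rows.append(
                            (area, subsite, plot, year, taxon,
                             100.0 * value / total, "vascular", "control")
                        )
                    if rng.random() < config.morphospecies_rate:
                        share = rng.uniform(2.0, 20.0)  # percent of plot total
                        record_rows.append(
                            (area, subsite, plot, year, "Morphospecies_sp1",
                             100.0 * share / (100.0 - share), "morphospecies",
                             "control")
                        )
                    if rng.random() < config.abiotic_rate:
                        record_rows.append(
                            (area, subsite, plot, year,
                             rng.choice(["rock", "bare_soil", "litter"]),
                             rng.uniform(5, 60), "abiotic", "control")
                        )

                covariate_rows.append(
                    {
                        "study_area": area,
                        "subsite": subsite,
                        "plot": plot,
                        "plot_size": float(np.round(rng.lognormal(np.log(3.86), 0.9), 3)),
                        **cov,
                    }
                )

    records = pd.DataFrame(record_rows, columns=RECORD_COLUMNS)
    covariates = pd.DataFrame(covariate_rows)

    traits, categorical = generate_traits(all_species, rng)

    truth = GroundTruth(
        species_class=species_class,
        colonisers=truth_col,
        losses=truth_loss,
        coefficients={
            "colonisation_intercept": config.colonisation_intercept,
            "colonisation_coefficients": dict(config.colonisation_coefficients),
            "boreal_colonisation_effect": config.boreal_colonisation_effect,
            "extinction_probability": config.extinction_probability,
        },
    )
    return SimulatedDataset(
        records=records,
        class_table=class_table,
        zone_occurrence=zone_occurrence,
        covariates=covariates,
        traits=traits,
        categorical_traits=categorical,
        truth=truth,
        config=config,
    )


TRAIT_DISTRIBUTIONS = {
    # trait -> (log-mean by functional group, log-SD across species)
    "height_m": ({"shrub": np.log(0.4), "forb": np.log(0.12), "graminoid": np.log(0.25)}, 0.6),
    "sla_mm2_mg": ({"shrub": np.log(10), "forb": np.log(18), "graminoid": np.log(14)}, 0.35),
    "leaf_n_mg_g": ({"shrub": np.log(18), "forb": np.log(24), "graminoid": np.log(20)}, 0.25),
    "leaf_cn_g_g": ({"shrub": np.log(25), "forb": np.log(18), "graminoid": np.log(22)}, 0.25),
    "seed_mass_mg": ({"shrub": np.log(1.5), "forb": np.log(0.6), "graminoid": np.log(0.9)}, 0.9),
}


def generate_traits(
    species: Sequence[str],
    rng: np.random.Generator,
    mean_records: float = 8.0,
    record_noise: float = 0.25,
    n_outlier_records: int = 0,
    outlier_sd: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal trait records plus categorical traits per species.

    Record counts per species × trait vary (some below the downstream
    five-record minimum); ``n_outlier_records`` injects gross outliers at
    ``outlier_sd`` species-level SDs to exercise the outlier filter.
    Returns ``(trait_records, categorical_traits)``.
    """
    groups = rng.choice(["shrub", "forb", "graminoid"], size=len(species),
                        p=[0.3, 0.45, 0.25])
    categorical = pd.DataFrame({"taxon": list(species), "functional_group": groups})

    rows = []
    for taxon, fg in zip(species, groups):
        for trait, (log_means, log_sd) in TRAIT_DISTRIBUTIONS.items():
            species_mean = rng.lognormal(log_means[fg], log_sd)
            n_records = int(rng.integers(3, int(2 * mean_records)))
            values = species_mean * rng.lognormal(0.0, record_noise, size=n_records)
            rows.extend(
                {"taxon": taxon, "trait": trait, "value": float(v)} for v in values
            )
    traits = pd.DataFrame(rows)

    if n_outlier_records:
        stats = traits.groupby(["taxon", "trait"])["value"].agg(["mean", "std", "count"])
        eligible = stats[(stats["count"] >= 6) & (stats["std"] > 0)]
        chosen = eligible.sample(n=min(n_outlier_records, len(eligible)),
                                 random_state=int(rng.integers(2**31)))
        outliers = [
            {"taxon": taxon, "trait": trait,
             "value": float(row["mean"] + outlier_sd * row["std"])}
            for (taxon, trait), row in chosen.iterrows()
        ]
        traits = pd.concat([traits, pd.DataFrame(outliers)], ignore_index=True)
    return traits, categorical
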