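"""Synthetic species pools, taxonomies and warming surveys with ground truth.

The generator emulates a boreal-Arctic shelf fish community sampled by an
annual bottom-trawl survey:

* ~76 species whose six log-scale life-history traits are driven by a latent
  size factor, a latent slowness factor correlated with size, and an
  offspring size-number trade-off factor (fecundity and offspring size load
  on it with opposite signs);
* family- and genus-level random effects that make trait values cluster on
  the taxonomy, inducing phylogenetic signal;
* biogeographic group contrasts: boreal species are on average slower,
  larger, more fecund and produce smaller offspring than Arctic species;
* a multi-year lattice survey on a warm-SW to cold-NE bottom-temperature
  gradient that warms each year, so warm-affinity (boreal, slow) species
  expand northeast — injected "borealization" whose magnitude is known.

Every dataset carries its ground truth (latent factors, thermal optima,
injected trend) and is exactly reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fastslow.community import SurveyStation, write_survey
from fastslow.phylogeny import build_taxonomy_tree, write_newick
from fastslow.trait_io import TRAIT_NAMES, TraitTable, write_trait_table

_DIET_CLASSES = (
    "benthivorous",
    "planktivorous",
    "piscivorous",
    "bentho-piscivorous",
    "plankto-piscivorous",
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic community, with survey-realistic defaults."""

    n_species: int = 76
    # biogeography composition mirrors the study pool: 27 Arctic / 46 boreal /
    # 3 arcto-boreal out of 76
    prop_arctic: float = 27 / 76
    prop_boreal: float = 46 / 76
    prop_arcto_boreal: float = 3 / 76
    # taxonomy shape (counts of internal taxa at each rank)
    n_superclasses: int = 2
    n_classes: int = 3
    n_orders: int = 8
    n_families: int = 18
    n_genera: int = 40
    # latent-factor structure
    size_slowness_corr: float = 0.7
    size_loading: float = 0.35  # log10 units per SD of latent size
    slowness_loading: float = 0.30
    tradeoff_fecundity_loading: float = 1.2
    tradeoff_offspring_loading: float = 0.45
    family_sd: float = 1.0  # taxonomy random effects on the latent factors
    genus_sd: float = 0.5
    noise_sd: float = 0.05  # residual log10 measurement noise per trait
    # biogeographic shifts of the latent factors (size, slowness, trade-off)
    shift_boreal: tuple[float, float, float] = (0.5, 0.6, 0.7)
    shift_arctic: tuple[float, float, float] = (-0.5, -0.6, -0.7)
    shift_arcto_boreal: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_imputed_flags: int = 20
    # survey
    n_years: int = 6
    first_year: int = 2004
    stations_per_side: int = 14  # lattice, so n_stations/year = side^2
    lon_range: tuple[float, float] = (20.0, 50.0)
    lat_range: tuple[float, float] = (70.0, 76.0)
    temp_sw: float = 5.5  # degC at the warm SW corner, first year
    temp_gradient: float = 6.0  # degC drop SW -> NE
    warming_per_year: float = 0.25  # degC/yr injected trend
    temp_noise_sd: float = 0.3
    depth_range: tuple[float, float] = (50.0, 500.0)
    # thermal niches
    opt_arctic: float = -0.5
    opt_arcto_boreal: float = 1.5
    opt_boreal: float = 3.5
    opt_sd: float = 0.6
    niche_halfwidth: float = 1.5  # degC
    occupancy_steepness: float = 2.0  # 1/degC; inf = hard niche window
    occupancy_max: float = 0.5
    biogeography_family_clustering: float = 1.0  # SD of family propensity

    def __post_init__(self) -> None:
        props = self.prop_arctic + self.prop_boreal + self.prop_arcto_boreal
        if abs(props - 1.0) > 1e-9:
            raise ValueError("biogeography proportions must sum to 1")
        if self.n_species < 6:
            raise ValueError("need at least 6 species")
        for name in ("family_sd", "genus_sd", "noise_sd", "temp_noise_sd", "opt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("seed", None)  # the bundle echo records the seed alongside
        for key in ("shift_boreal", "shift_arctic", "shift_arcto_boreal",
                    "lon_range", "lat_range", "depth_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery checks."""

    latent_size: pd.Series
    latent_slowness: pd.Series
    latent_tradeoff: pd.Series
    thermal_optimum: pd.Series
    warming_per_year: float
    seed: int
    station_mean_slowness: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "latent_size": self.latent_size.to_dict(),
            "latent_slowness": self.latent_slowness.to_dict(),
            "latent_tradeoff": self.latent_tradeoff.to_dict(),
            "thermal_optimum": self.thermal_optimum.to_dict(),
            "warming_per_year": self.warming_per_year,
            "seed": self.seed,
        }
        if self.station_mean_slowness is not None:
            payload["station_mean_slowness"] = self.station_mean_slowness.to_dict(
                orient="list"
            )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _assign_nested(rng, n_children: int, parents: list[str], prefix: str) -> dict[str, str]:
    """Assign n_children labelled children across parents, each parent >= 1."""
    n_parents = len(parents)
    children = [f"{prefix}{i + 1:02d}" for i in range(n_children)]
    owner = {}
    # guarantee every parent gets one child, then fill the rest at random
    for i, parent in enumerate(parents):
        owner[children[i]] = parent
    for child in children[n_parents:]:
        owner[child] = parents[rng.integers(0, n_parents)]
    return owner


def _make_taxonomy(cfg: SimulationConfig, rng) -> pd.DataFrame:
    """Random but consistently nested 6-rank taxonomy for n_species tips."""
    supers = [f"SC{i + 1}" for i in range(cfg.n_superclasses)]
    class_of = _assign_nested(rng, cfg.n_classes, supers, "CL")
    order_of = _assign_nested(rng, cfg.n_orders, sorted(class_of), "OR")
    family_of = _assign_nested(rng, cfg.n_families, sorted(order_of), "FA")
    genus_of = _assign_nested(rng, cfg.n_genera, sorted(family_of), "GE")
    genera = sorted(genus_of)
    rows = []
    for i in range(cfg.n_species):
        sid = f"sp{i + 1:03d}"
        genus = genera[i] if i < len(genera) else genera[rng.integers(0, len(genera))]
        family = genus_of[genus]
        order = family_of[family]
        clazz = order_of[order]
        sc = class_of[clazz]
        rows.append((sid, sc, clazz, order, family, genus, sid))
    return pd.DataFrame(
        rows,
        columns=["species_id", "superclass", "class", "order", "family",
                 "genus", "species_name"],
    ).set_index("species_id")


def simulate_species_pool(
    cfg: SimulationConfig, seed: int
) -> tuple[TraitTable, GroundTruth]:
    """Generate a species pool: traits, metadata and latent ground truth."""
    rng = np.random.default_rng(seed)
    n = cfg.n_species
    taxonomy = _make_taxonomy(cfg, rng)
    species = list(taxonomy.index)

    # taxonomy random effects shared by members of a family / genus; the
    # size/slowness components are correlated like the species-level factors,
    # so relatives resemble each other coherently across traits
    rho = cfg.size_slowness_corr
    chol = np.linalg.cholesky(
        np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
    )
    families = sorted(taxonomy["family"].unique())
    genera = sorted(taxonomy["genus"].unique())
    fam_eff = {f: cfg.family_sd * (chol @ rng.normal(size=3)) for f in families}
    gen_eff = {g: cfg.genus_sd * (chol @ rng.normal(size=3)) for g in genera}
    tax_eff = np.vstack(
        [fam_eff[taxonomy.loc[s, "family"]] + gen_eff[taxonomy.loc[s, "genus"]]
         for s in species]
    )

    # biogeography: fixed composition, clustered on the taxonomy.  The warm-
    # affinity score couples to the family's slowness effect (warm, boreal
    # families are the slower ones), so group contrasts and phylogenetic
    # clustering reinforce each other as in real shelf communities
    n_arctic = round(cfg.prop_arctic * n)
    n_ab = max(round(cfg.prop_arcto_boreal * n), 0)
    fam_propensity = {
        f: rng.normal(0.0, cfg.biogeography_family_clustering)
        for f in families
    }
    fam_sd = max(cfg.family_sd, 1e-12)
    warmness = np.array(
        [fam_propensity[taxonomy.loc[s, "family"]]
         + 0.8 * fam_eff[taxonomy.loc[s, "family"]][1] / fam_sd
         for s in species]
    ) + rng.normal(0.0, 0.5, size=n)
    order_idx = np.argsort(warmness)
    groups = np.empty(n, dtype=object)
    groups[order_idx[:n_arctic]] = "Arctic"
    groups[order_idx[n_arctic:n_arctic + n_ab]] = "arcto-boreal"
    groups[order_idx[n_arctic + n_ab:]] = "boreal"
    groups = list(groups)
    shifts = {
        "boreal": np.asarray(cfg.shift_boreal),
        "Arctic": np.asarray(cfg.shift_arctic),
        "arcto-boreal": np.asarray(cfg.shift_arcto_boreal),
    }
    shift_mat = np.vstack([shifts[g] for g in groups])  # (n, 3)

    base_size = rng.normal(size=n)
    base_slow = rho * base_size + np.sqrt(1 - rho**2) * rng.normal(size=n)
    base_trade = rng.normal(size=n)
    latent = np.column_stack([base_size, base_slow, base_trade])
    latent = latent + shift_mat + tax_eff
    size, slow, trade = latent.T

    eps = rng.normal(0.0, cfg.noise_sd, size=(n, 6))
    log_max_length = 1.7 + cfg.size_loading * size + eps[:, 0]
    # maturity ratios in (0, 1) keep length_maturity <= max_length and
    # age_maturity <= longevity by construction
    mat_ratio = 1.0 / (1.0 + np.exp(-(0.5 + rng.normal(0.0, 0.3, size=n))))
    log_length_maturity = log_max_length + np.log10(np.clip(mat_ratio, 1e-3, 1 - 1e-9))
    log_longevity = 1.1 + cfg.slowness_loading * slow + eps[:, 2]
    age_ratio = 1.0 / (1.0 + np.exp(-(0.3 + rng.normal(0.0, 0.3, size=n))))
    log_age_maturity = log_longevity + np.log10(np.clip(age_ratio, 1e-3, 1 - 1e-9))
    log_fecundity = 3.5 + cfg.tradeoff_fecundity_loading * trade + eps[:, 4]
    log_offspring = 0.6 - cfg.tradeoff_offspring_loading * trade + eps[:, 5]

    traits = pd.DataFrame(
        {
            "longevity": 10.0 ** log_longevity,
            "age_maturity": 10.0 ** log_age_maturity,
            "max_length": 10.0 ** log_max_length,
            "length_maturity": 10.0 ** log_length_maturity,
            "fecundity": 10.0 ** log_fecundity,
            "offspring_size": 10.0 ** log_offspring,
        },
        index=pd.Index(species, name="species_id"),
    )

    imputed = pd.DataFrame(False, index=traits.index, columns=list(TRAIT_NAMES))
    flat = rng.choice(n * 6, size=min(cfg.n_imputed_flags, n * 6), replace=False)
    for k in flat:
        imputed.iat[k // 6, k % 6] = True

    opts = {"Arctic": cfg.opt_arctic, "boreal": cfg.opt_boreal,
            "arcto-boreal": cfg.opt_arcto_boreal}
    thermal_opt = np.array([opts[g] for g in groups]) + rng.normal(
        0.0, cfg.opt_sd, size=n
    )

    meta = taxonomy.copy()
    meta.insert(0, "biogeography", groups)
    meta.insert(1, "habitat", rng.choice(["demersal", "pelagic"], size=n, p=[0.8, 0.2]))
    meta.insert(2, "diet", rng.choice(_DIET_CLASSES, size=n))

    table = TraitTable(traits, imputed, meta)
    truth = GroundTruth(
        latent_size=pd.Series(size, index=species),
        latent_slowness=pd.Series(slow, index=species),
        latent_tradeoff=pd.Series(trade, index=species),
        thermal_optimum=pd.Series(thermal_opt, index=species),
        warming_per_year=cfg.warming_per_year,
        seed=seed,
    )
    return table, truth


def _occupancy_probability(cfg: SimulationConfig, temp: np.ndarray,
                           opt: np.ndarray) -> np.ndarray:
    """Niche window occupancy: product of two logistics, hard window as limit."""
    delta = temp[:, None] - opt[None, :]
    w, k = cfg.niche_halfwidth, cfg.occupancy_steepness
    if np.isinf(k):
        inside = np.abs(delta) < w
        return cfg.occupancy_max * inside
    lo = 1.0 / (1.0 + np.exp(-k * (delta + w)))
    hi = 1.0 / (1.0 + np.exp(-k * (w - delta)))
    return cfg.occupancy_max * lo * hi


def simulate_survey(
    cfg: SimulationConfig,
    pool: TraitTable,
    truth: GroundTruth,
    seed: int,
) -> list[SurveyStation]:
    """Simulate the multi-year lattice survey over the warming gradient."""
    rng = np.random.default_rng(seed)
    side = cfg.stations_per_side
    lons = np.linspace(*cfg.lon_range, side)
    lats = np.linspace(*cfg.lat_range, side)
    glon, glat = np.meshgrid(lons, lats)
    glon, glat = glon.ravel(), glat.ravel()
    # normalized SW->NE coordinate in [0, 1]
    u = ((glon - cfg.lon_range[0]) / (cfg.lon_range[1] - cfg.lon_range[0])
         + (glat - cfg.lat_range[0]) / (cfg.lat_range[1] - cfg.lat_range[0])) / 2.0
    # smooth depth field within the trawlable window
    dlo, dhi = cfg.depth_range
    depth = dlo + (dhi - dlo) * (0.5 + 0.45 * np.sin(2 * np.pi * glon / 25.0)
                                 * np.cos(2 * np.pi * glat / 5.0))
    depth = np.clip(depth, dlo, dhi)

    species = pool.species_ids
    opt = truth.thermal_optimum.loc[species].to_numpy()
    slow = truth.latent_slowness.loc[species].to_numpy()

    stations: list[SurveyStation] = []
    truth_rows = []
    for yi in range(cfg.n_years):
        year = cfg.first_year + yi
        temp = (cfg.temp_sw - cfg.temp_gradient * u
                + cfg.warming_per_year * yi
                + rng.normal(0.0, cfg.temp_noise_sd, size=len(u)))
        prob = _occupancy_probability(cfg, temp, opt)
        present = rng.random(prob.shape) < prob
        for i in range(len(u)):
            sp = {species[j] for j in np.flatnonzero(present[i])}
            if not sp:
                continue
            sid = f"st{i + 1:03d}"
            stations.append(
                SurveyStation(sid, year, float(glon[i]), float(glat[i]),
                              float(depth[i]), float(temp[i]), sp)
            )
            truth_rows.append(
                (sid, year, float(slow[present[i]].mean()))
            )
    truth.station_mean_slowness = pd.DataFrame(
        truth_rows, columns=["station_id", "year", "mean_latent_slowness"]
    )
    return stations


def write_fixture_bundle(cfg: SimulationConfig, out_dir, seed: int) -> dict[str, Path]:
    """Simulate a pool + survey and write the full file set the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pool, truth = simulate_species_pool(cfg, seed)
    stations = simulate_survey(cfg, pool, truth, seed + 1)
    paths = {
        "traits": out / "traits.csv",
        "metadata": out / "metadata.csv",
        "survey": out / "survey.csv",
        "taxonomy": out / "taxonomy.nwk",
        "ground_truth": out / "ground_truth.json",
        "config": out / "config.yaml",
    }
    write_trait_table(pool, paths["traits"], paths["metadata"])
    write_survey(stations, paths["survey"])
    write_newick(build_taxonomy_tree(pool.meta), paths["taxonomy"])
    truth.to_json(paths["ground_truth"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump({**cfg.to_dict(), "seed": seed}, fh, sort_keys=False)
    return paths
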