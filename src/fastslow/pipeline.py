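"""End-to-end orchestration: traits -> ordination/ranks -> indices -> maps/GLMs.

The pipeline runs five steps in order: (1) read and standardize the
life-history matrix, (2) ordinate and rank the species, (3) filter the survey
and integrate ranks with presence/absence data, (4) compute per-station
community indices, (5) krige the indices over a grid and fit the
index-versus-environment GLMs.  Every output is a pure function of
(inputs, config, seed); the run log records versions, seed and config so any
output can be reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import fastslow
from fastslow.community import filter_species, read_survey, station_indices
from fastslow.ordination import fast_slow_ranks, group_mean_ranks
from fastslow.phylogeny import build_taxonomy_tree, phylo_signal_test
from fastslow.simulate import SimulationConfig, write_fixture_bundle
from fastslow.spatial import (
    fit_index_glm,
    fit_variogram,
    make_grid,
    project_coordinates,
    universal_krige,
)
from fastslow.trait_io import read_trait_table, transform_traits, imputation_fraction

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Single-YAML configuration for the whole pipeline."""

    out_dir: str = "fastslow_out"
    seed: int = 0
    # inputs: either explicit paths or a simulation block
    traits_path: str | None = None
    metadata_path: str | None = None
    survey_path: str | None = None
    simulation: dict | None = None
    # ordination
    constraint_trait: str = "max_length"
    fs1_anchor: str = "max_length"
    fs2_anchor: str = "longevity"
    osn_anchor: str = "fecundity"
    # survey filter
    max_absent_years: int = 2
    depth_window: tuple[float, float] = (50.0, 500.0)
    pdis_scope: str = "pooled"
    # phylogeny
    n_permutations: int = 999
    # spatial
    variogram_model: str = "exponential"
    grid_spacing_km: float = 20.0
    coord_poly_degree: int = 2
    krige_indices: tuple[str, ...] = ("mean_fs1", "mean_fs2", "PDis")
    glm_responses: tuple[str, ...] = ("mean_fs1", "mean_fs2", "PDis")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("depth_window",):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        for key in ("krige_indices", "glm_responses"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.simulation is None:
            for name in ("traits_path", "metadata_path", "survey_path"):
                p = getattr(self, name)
                if p is None:
                    raise PipelineConfigError(
                        f"config must provide {name} or a simulation block"
                    )
                if not Path(p).exists():
                    raise PipelineConfigError(f"{name} does not exist: {p}")


@dataclass
class PipelineResult:
    """Paths and in-memory products of a pipeline run."""

    out_dir: Path
    ranks: object
    indices: pd.DataFrame
    signal_tests: dict[str, object]
    glms: dict[str, object]
    files: dict[str, Path] = field(default_factory=dict)


def run_rank_step(cfg: PipelineConfig, out: Path):
    """Steps 1-2: trait matrix, ordination, ranks, signal tests."""
    table = read_trait_table(cfg.traits_path, cfg.metadata_path)
    X = transform_traits(table)
    ranks = fast_slow_ranks(
        X,
        constraint=cfg.constraint_trait,
        fs1_anchor=cfg.fs1_anchor,
        fs2_anchor=cfg.fs2_anchor,
        osn_anchor=cfg.osn_anchor,
    )
    ranks.to_csv(out / "ranks.csv")
    tree = build_taxonomy_tree(table.meta)
    signal = {}
    for axis in ("fs1", "fs2", "osn"):
        signal[axis] = phylo_signal_test(
            tree, ranks.ranks(axis), n_permutations=cfg.n_permutations,
            seed=cfg.seed,
        )
    by_group = group_mean_ranks(ranks, table.meta, "biogeography")
    by_group.to_csv(out / "group_mean_ranks.csv")
    summary = {
        "n_species": len(table),
        "imputed_percent": imputation_fraction(table),
        "pca_variance_percent": [
            round(100 * v, 1) for v in ranks.pca.variance_fractions
        ],
        "rda_constrained_percent": round(100 * ranks.rda.constrained_fraction, 1),
        "rda_residual_percent": [
            round(100 * v, 1) for v in ranks.rda.variance_fractions[1:]
        ],
        "signal": {
            a: {"K": r.K, "p": r.p_value} for a, r in signal.items()
        },
    }
    with open(out / "ordination_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return table, X, ranks, tree, signal


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all five steps, writing the result bundle under cfg.out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulation is not None:
        sim_cfg = SimulationConfig(**{
            k: v for k, v in cfg.simulation.items() if k != "seed"
        })
        sim_seed = int(cfg.simulation.get("seed", cfg.seed))
        paths = write_fixture_bundle(sim_cfg, out / "simulated_input", sim_seed)
        cfg.traits_path = str(paths["traits"])
        cfg.metadata_path = str(paths["metadata"])
        cfg.survey_path = str(paths["survey"])
    cfg.validate()

    try:
        table, X, ranks, tree, signal = run_rank_step(cfg, out)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'rank' failed on {cfg.traits_path}: {exc}") from exc

    try:
        stations = read_survey(cfg.survey_path)
        stations, report = filter_species(
            stations, cfg.max_absent_years, cfg.depth_window
        )
        indices = station_indices(stations, ranks, tree, cfg.pdis_scope)
        indices.to_csv(out / "indices.csv", index=False)
        with open(out / "species_filter.json", "w") as fh:
            json.dump(
                {
                    "excluded_by_years": report.excluded_by_years,
                    "excluded_by_depth": report.excluded_by_depth,
                    "n_retained": len(report.retained),
                },
                fh, indent=1,
            )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(
            f"stage 'integrate' failed on {cfg.survey_path}: {exc}"
        ) from exc

    glms: dict[str, object] = {}
    try:
        x, y, origin = project_coordinates(indices["lon"], indices["lat"])
        pts = np.column_stack([x, y])
        grid = make_grid(pts, cfg.grid_spacing_km)
        for name in cfg.krige_indices:
            vals = indices[name].to_numpy(float)
            ok = np.isfinite(vals)
            vg = fit_variogram(pts[ok], vals[ok], model=cfg.variogram_model)
            surf = universal_krige(pts[ok], vals[ok], grid, vg)
            surf.index_name = name
            surf.origin = origin
            surf.to_frame().to_csv(out / f"kriged_{name}.csv", index=False)
        glm_lines = []
        for name in cfg.glm_responses:
            fit = fit_index_glm(indices, name, cfg.coord_poly_degree)
            glms[name] = fit
            fit.to_frame().to_csv(out / f"glm_{name}.csv")
            glm_lines.append(fit.summary_text())
        (out / "glm_summary.txt").write_text("\n\n".join(glm_lines) + "\n")
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'map' failed: {exc}") from exc

    log = {
        "fastslow_version": fastslow.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(cfg).items()},
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    files = {p.name: p for p in sorted(out.glob("*"))}
    return PipelineResult(
        out_dir=out, ranks=ranks, indices=indices,
        signal_tests=signal, glms=glms, files=files,
    )
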