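"""Survey filtering and integration of species ranks into community indices.

Surveys are presence/absence by design: abundance is deliberately ignored.
For every station-year the module computes species richness (SR), the mean
fast-slow / offspring-trade-off rank of the species present, Faith's PD over
the taxonomy tree, and phylogenetic dispersion (PDis, the residual of PD on
SR fitted across stations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fastslow.ordination import FastSlowRanks
from fastslow.phylogeny import faith_pd, phylo_dispersion

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = [
    "station_id",
    "year",
    "lon",
    "lat",
    "depth",
    "temperature",
    "species_id",
]


@dataclass
class SurveyStation:
    """One trawl station in one year with its presence set."""

    station_id: str
    year: int
    lon: float
    lat: float
    depth: float
    bottom_temperature: float
    species_present: set[str] = field(default_factory=set)

    @property
    def richness(self) -> int:
        return len(self.species_present)


@dataclass
class ExclusionReport:
    """Which species the survey filter removed, and why."""

    excluded_by_years: list[str]
    excluded_by_depth: list[str]
    retained: list[str]
    n_years: int
    depth_window: tuple[float, float]

    def summary(self) -> str:
        return (
            f"excluded {len(self.excluded_by_years)} species absent in too many "
            f"of {self.n_years} survey years, {len(self.excluded_by_depth)} "
            f"species never caught within {self.depth_window[0]:.0f}-"
            f"{self.depth_window[1]:.0f} m; retained {len(self.retained)}"
        )


def read_survey(path) -> list[SurveyStation]:
    """Read a long-format survey CSV into one SurveyStation per station-year.

    Duplicate (station, year, species) rows are collapsed with a warning;
    missing coordinates are an error.
    """
    df = pd.read_csv(path)
    if df.empty:
        return []
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey CSV missing columns: {missing}")
    if df[["lon", "lat"]].isna().any().any():
        bad = df[df[["lon", "lat"]].isna().any(axis=1)]
        raise ValueError(
            f"missing coordinates for station {bad['station_id'].iloc[0]!r}"
        )
    dupes = df.duplicated(subset=["station_id", "year", "species_id"])
    if dupes.any():
        warnings.warn(
            f"collapsed {int(dupes.sum())} duplicate (station, year, species) rows"
        )
        df = df[~dupes]
    stations = []
    for (sid, year), grp in df.groupby(["station_id", "year"], sort=True):
        stations.append(
            SurveyStation(
                station_id=str(sid),
                year=int(year),
                lon=float(grp["lon"].iloc[0]),
                lat=float(grp["lat"].iloc[0]),
                depth=float(grp["depth"].iloc[0]),
                bottom_temperature=float(grp["temperature"].iloc[0]),
                species_present=set(grp["species_id"].astype(str)),
            )
        )
    return stations


def write_survey(stations: list[SurveyStation], path) -> None:
    """Write stations back to the long CSV format :func:`read_survey` reads."""
    rows = []
    for st in stations:
        for sp in sorted(st.species_present):
            rows.append(
                (st.station_id, st.year, st.lon, st.lat, st.depth,
                 st.bottom_temperature, sp)
            )
    pd.DataFrame(rows, columns=SURVEY_COLUMNS).to_csv(path, index=False)


def filter_species(
    stations: list[SurveyStation],
    max_absent_years: int = 2,
    depth_window: tuple[float, float] = (50.0, 500.0),
) -> tuple[list[SurveyStation], ExclusionReport]:
    """Apply the survey species filter and drop out-of-window stations.

    A species is excluded when it was absent in more than ``max_absent_years``
    survey years, or when it was only ever caught at stations outside the
    trawling depth window.  Stations outside the window are dropped, species
    presence sets are reduced to the retained pool, and emptied stations are
    removed.
    """
    years = sorted({st.year for st in stations})
    if len(years) < 2:
        raise ValueError("survey must span at least 2 years to apply the filter")
    lo, hi = depth_window
    in_window = [st for st in stations if lo <= st.depth <= hi]

    years_present: dict[str, set[int]] = {}
    seen_in_window: set[str] = set()
    all_species: set[str] = set()
    for st in stations:
        for sp in st.species_present:
            all_species.add(sp)
            years_present.setdefault(sp, set()).add(st.year)
    for st in in_window:
        seen_in_window.update(st.species_present)

    excl_years = sorted(
        sp
        for sp in all_species
        if len(years) - len(years_present[sp]) > max_absent_years
    )
    excl_depth = sorted(all_species - seen_in_window - set(excl_years))
    retained = sorted(all_species - set(excl_years) - set(excl_depth))
    keep = set(retained)

    filtered = []
    for st in in_window:
        present = st.species_present & keep
        if present:
            filtered.append(
                SurveyStation(
                    st.station_id, st.year, st.lon, st.lat, st.depth,
                    st.bottom_temperature, present,
                )
            )
    report = ExclusionReport(
        excluded_by_years=excl_years,
        excluded_by_depth=excl_depth,
        retained=retained,
        n_years=len(years),
        depth_window=depth_window,
    )
    logger.info(report.summary())
    return filtered, report


def assemblage_mean_rank(
    station: SurveyStation, ranks: FastSlowRanks, axis: str
) -> float:
    """Mean axis rank (fs1 | fs2 | osn) of the ranked species present.

    Species without a rank are ignored (their count is logged); a station
    with no ranked species yields NaN.
    """
    rank_series = ranks.ranks(axis)
    present = [sp for sp in station.species_present if sp in rank_series.index]
    n_unranked = station.richness - len(present)
    if n_unranked:
        logger.debug(
            "station %s year %s: %d unranked species ignored",
            station.station_id, station.year, n_unranked,
        )
    if not present:
        logger.warning(
            "station %s year %s has no ranked species on axis %s",
            station.station_id, station.year, axis,
        )
        return float("nan")
    return float(rank_series.loc[present].mean())


def station_indices(
    stations: list[SurveyStation],
    ranks: FastSlowRanks,
    tree,
    pdis_scope: str = "pooled",
) -> pd.DataFrame:
    """Per station-year community indices: SR, mean ranks, PD, PDis.

    SR and PD count only species present in the taxonomy tree; mean ranks use
    only ranked species (counts of dropped species are logged).  PDis is the
    residual of PD on SR, fitted pooled across years (default) or per year
    (``pdis_scope='per_year'``).
    """
    if pdis_scope not in {"pooled", "per_year"}:
        raise ValueError("pdis_scope must be 'pooled' or 'per_year'")
    tree_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    rows = []
    n_dropped_tax = 0
    for st in stations:
        in_tree = st.species_present & tree_tips
        n_dropped_tax += st.richness - len(in_tree)
        sr = len(in_tree)
        pd_val = faith_pd(tree, in_tree) if in_tree else float("nan")
        rows.append(
            {
                "station_id": st.station_id,
                "year": st.year,
                "lon": st.lon,
                "lat": st.lat,
                "depth": st.depth,
                "temperature": st.bottom_temperature,
                "SR": sr,
                "mean_fs1": assemblage_mean_rank(st, ranks, "fs1"),
                "mean_fs2": assemblage_mean_rank(st, ranks, "fs2"),
                "mean_osn": assemblage_mean_rank(st, ranks, "osn"),
                "PD": pd_val,
            }
        )
    if n_dropped_tax:
        logger.info("%d presences not in taxonomy dropped from SR/PD", n_dropped_tax)
    out = pd.DataFrame(rows)
    out["PDis"] = np.nan
    ok = out["PD"].notna()
    if pdis_scope == "pooled":
        out.loc[ok, "PDis"] = phylo_dispersion(
            out.loc[ok, "PD"].to_numpy(), out.loc[ok, "SR"].to_numpy()
        )
    else:
        for _, idx in out.loc[ok].groupby("year").groups.items():
            out.loc[idx, "PDis"] = phylo_dispersion(
                out.loc[idx, "PD"].to_numpy(), out.loc[idx, "SR"].to_numpy()
            )
    return out
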