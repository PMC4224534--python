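import numpy as np
import pandas as pd
import pytest

import fastslow as fs
from fastslow.community import SURVEY_COLUMNS, SurveyStation


def station(sid="s1", year=2004, depth=200.0, temp=2.0, species=("a",),
            lon=30.0, lat=72.0):
    return SurveyStation(sid, year, lon, lat, depth, temp, set(species))


class TestReadSurvey:
    def test_rows_aggregate_into_presence_sets(self, tmp_path):
        df = pd.DataFrame(
            [["s1", 2004, 30.0, 72.0, 200.0, 2.0, sp] for sp in "abc"],
            columns=SURVEY_COLUMNS,
        )
        path = tmp_path / "survey.csv"
        df.to_csv(path, index=False)
        stations = fs.read_survey(path)
        assert len(stations) == 1
        assert stations[0].richness == 3

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "survey.csv"
        pd.DataFrame(columns=SURVEY_COLUMNS).to_csv(path, index=False)
        assert fs.read_survey(path) == []

    def test_duplicates_collapse_with_warning(self, tmp_path):
        df = pd.DataFrame(
            [["s1", 2004, 30.0, 72.0, 200.0, 2.0, "a"]] * 2,
            columns=SURVEY_COLUMNS,
        )
        path = tmp_path / "survey.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="duplicate"):
            stations = fs.read_survey(path)
        assert stations[0].richness == 1

    def test_missing_coordinates_are_an_error(self, tmp_path):
        df = pd.DataFrame(
            [["s1", 2004, None, 72.0, 200.0, 2.0, "a"]], columns=SURVEY_COLUMNS
        )
        path = tmp_path / "survey.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="coordinates"):
            fs.read_survey(path)

    def test_write_read_round_trip(self, tmp_path, default_pool):
        pool, truth = default_pool
        stations = fs.simulate_survey(fs.SimulationConfig(), pool, truth, 5)
        path = tmp_path / "survey.csv"
        fs.write_survey(stations, path)
        back = fs.read_survey(path)
        assert len(back) == len(stations)
        orig = {(s.station_id, s.year): s for s in stations}
        for st in back:
            ref = orig[(st.station_id, st.year)]
            assert st.species_present == ref.species_present
            assert st.depth == pytest.approx(ref.depth)


class TestFilterSpecies:
    def years_fixture(self):
        # 6-year survey: species 'patchy' present only in years 1-3 (absent 3 > 2),
        # 'deep' only at 600 m, 'ok' present everywhere in-window
        stations = []
        for yi in range(6):
            sp = {"ok"}
            if yi < 3:
                sp = {"ok", "patchy"}
            stations.append(station("s1", 2004 + yi, depth=200.0, species=sp))
            stations.append(
                station("s2", 2004 + yi, depth=600.0, species={"deep", "ok"})
            )
        return stations

    def test_species_absent_in_more_than_two_years_excluded(self):
        _, report = fs.filter_species(self.years_fixture())
        assert "patchy" in report.excluded_by_years

    def test_species_only_off_depth_window_excluded(self):
        _, report = fs.filter_species(self.years_fixture())
        assert report.excluded_by_depth == ["deep"]

    def test_persistent_in_window_species_retained(self):
        filtered, report = fs.filter_species(self.years_fixture())
        assert report.retained == ["ok"]
        assert all(st.species_present == {"ok"} for st in filtered)
        assert all(50 <= st.depth <= 500 for st in filtered)

    def test_single_year_survey_rejected(self):
        with pytest.raises(ValueError, match="2 years"):
            fs.filter_species([station(year=2004), station("s2", year=2004)])


class TestAssemblageMeanRank:
    def make_ranks(self, n=76):
        table = pd.DataFrame(
            {
                f"{ax}_rank": np.arange(1.0, n + 1)
                for ax in ("fs1", "fs2", "osn")
            }
            | {f"{ax}_score": np.arange(n, dtype=float) for ax in ("fs1", "fs2", "osn")},
            index=pd.Index([f"sp{i:03d}" for i in range(1, n + 1)], name="species_id"),
        )
        return fs.FastSlowRanks(table=table, pca=None, rda=None)

    def test_mean_of_present_ranks(self):
        ranks = self.make_ranks()
        st = station(species={"sp010", "sp020", "sp060"})
        assert fs.assemblage_mean_rank(st, ranks, "fs1") == pytest.approx(30.0)

    def test_single_slow_species(self):
        ranks = self.make_ranks()
        st = station(species={"sp050"})
        assert fs.assemblage_mean_rank(st, ranks, "fs1") == pytest.approx(50.0)

    def test_all_species_give_rank_sum_identity(self):
        ranks = self.make_ranks()
        st = station(species={f"sp{i:03d}" for i in range(1, 77)})
        assert fs.assemblage_mean_rank(st, ranks, "fs1") == pytest.approx(38.5)

    def test_no_ranked_species_is_missing_value(self):
        ranks = self.make_ranks()
        st = station(species={"unknown"})
        assert np.isnan(fs.assemblage_mean_rank(st, ranks, "fs1"))


class TestStationIndices:
    def test_pd_monotone_for_nested_assemblages(self, default_pool, default_ranks,
                                                default_tree):
        pool, _ = default_pool
        sp = pool.species_ids
        stations = [
            station("s1", species=set(sp[:5])),
            station("s2", species=set(sp[:15])),
            station("s3", species=set(sp[:30])),
        ]
        idx = fs.station_indices(stations, default_ranks, default_tree)
        assert idx["PD"].is_monotonic_increasing

    def test_identical_species_sets_give_identical_indices(
        self, default_pool, default_ranks, default_tree
    ):
        pool, _ = default_pool
        sp = set(pool.species_ids[:8])
        stations = [
            station("s1", species=sp),
            station("s2", temp=5.0, species=sp),
            station("s3", species=set(pool.species_ids[8:20])),
        ]
        idx = fs.station_indices(stations, default_ranks, default_tree).set_index(
            "station_id"
        )
        for col in ("SR", "mean_fs1", "mean_fs2", "mean_osn", "PD", "PDis"):
            assert idx.loc["s1", col] == pytest.approx(idx.loc["s2", col])

    def test_mean_rank_bounded_by_present_species(self, default_pool, default_ranks,
                                                  default_tree):
        pool, truth = default_pool
        stations = fs.simulate_survey(fs.SimulationConfig(n_years=2), pool, truth, 3)
        idx = fs.station_indices(stations[:200], default_ranks, default_tree)
        fs1 = default_ranks.ranks("fs1")
        for st, (_, row) in zip(stations[:200], idx.iterrows()):
            present = fs1.loc[sorted(st.species_present)]
            assert present.min() - 1e-9 <= row["mean_fs1"] <= present.max() + 1e-9

    def test_indices_invariant_to_station_order(self, default_pool, default_ranks,
                                                default_tree):
        pool, truth = default_pool
        stations = fs.simulate_survey(fs.SimulationConfig(n_years=2), pool, truth, 4)
        idx1 = fs.station_indices(stations[:60], default_ranks, default_tree)
        idx2 = fs.station_indices(stations[:60][::-1], default_ranks, default_tree)
        idx1 = idx1.sort_values(["station_id", "year"]).reset_index(drop=True)
        idx2 = idx2.sort_values(["station_id", "year"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(idx1, idx2)

    def test_warm_stations_host_slower_assemblages(self, default_pool, default_ranks,
                                                   default_tree):
        pool, truth = default_pool
        stations = fs.simulate_survey(fs.SimulationConfig(), pool, truth, 6)
        stations, _ = fs.filter_species(stations)
        idx = fs.station_indices(stations, default_ranks, default_tree)
        r = np.corrcoef(idx["temperature"], idx["mean_fs1"])[0, 1]
        assert r > 0.3
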