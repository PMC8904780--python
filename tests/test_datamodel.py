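"""Tests of the data model: rainfall series validation, seasonal sums,
taxon filtering rules, plot-year aggregation and the site-taxa matrix."""

import numpy as np
import pandas as pd
import pytest

from rainwin.datamodel import (
    DataGapError,
    RainfallSeries,
    SchemaError,
    aggregate,
    build_matrix,
    filter_taxa,
    read_taxa,
    read_traps,
    seasonal_rainfall,
)


def _series(start, days, value=1.0):
    dates = pd.date_range(start, periods=days, freq="D")
    return RainfallSeries(dates, np.full(days, value))


class TestRainfallSeries:
    def test_gap_detected(self):
        dates = pd.DatetimeIndex(["2015-01-01", "2015-01-02", "2015-01-04"])
        with pytest.raises(DataGapError, match="2015-01-02"):
            RainfallSeries(dates, np.zeros(3))

    def test_negative_amount_rejected(self):
        with pytest.raises(SchemaError):
            RainfallSeries(pd.date_range("2015-01-01", periods=3), np.array([0.0, -1.0, 0.0]))

    @pytest.mark.parametrize(
        "year,expected",
        [(2015, 59.0), (2016, 60.0)],  # non-leap vs leap February
    )
    def test_seasonal_sum_constant_series(self, year, expected):
        series = _series(f"{year}-01-01", 366, 1.0)
        assert seasonal_rainfall(series, year) == expected

    def test_seasonal_sum_zero_series(self):
        series = _series("2015-01-01", 365, 0.0)
        assert seasonal_rainfall(series, 2015) == 0.0

    def test_seasonal_sum_missing_days_named(self):
        series = _series("2015-03-01", 40, 1.0)
        with pytest.raises(DataGapError, match="2015-02-01"):
            seasonal_rainfall(series, 2015)

    def test_csv_round_trip(self, tmp_path):
        series = _series("2014-12-30", 100, 0.5)
        path = tmp_path / "rain.csv"
        series.to_csv(path)
        back = RainfallSeries.from_csv(path)
        assert back.dates.equals(series.dates)
        assert np.array_equal(back.mm, series.mm)


def _events(rows):
    return pd.DataFrame(rows, columns=["plot", "year", "round", "start_date", "taxon", "count"])


TAXA = pd.DataFrame(
    {
        "taxon": ["cicadas", "springtails", "flies"],
        "trophic_group": ["herbivore", "detritivore", "omnivore"],
        "ground_dwelling": [True, True, False],
    }
)


class TestFilterTaxa:
    def test_strict_minimum_boundary(self):
        """49 individuals over the study drops a taxon; exactly 50 keeps it."""
        events = _events(
            [("A", 2013, 1, "2013-03-01", "cicadas", 49),
             ("A", 2013, 1, "2013-03-01", "springtails", 50)]
        )
        assert filter_taxa(events, TAXA) == ["springtails"]

    def test_non_ground_dwelling_excluded_regardless_of_abundance(self):
        events = _events([("A", 2013, 1, "2013-03-01", "flies", 10000)])
        assert filter_taxa(events, TAXA) == []

    def test_empty_events(self):
        assert filter_taxa(_events([]), TAXA) == []

    def test_unknown_taxon_is_schema_error(self):
        events = _events([("A", 2013, 1, "2013-03-01", "unicorns", 3)])
        with pytest.raises(SchemaError, match="unicorns"):
            filter_taxa(events, TAXA)


@pytest.fixture()
def small_inputs():
    events = _events(
        [
            ("A", 2015, 1, "2015-03-01", "cicadas", 3),
            ("A", 2015, 2, "2015-03-20", "cicadas", 4),
            ("A", 2015, 1, "2015-03-01", "springtails", 2),
            ("B", 2015, 1, "2015-03-01", "cicadas", 1),
        ]
    )
    veg = pd.DataFrame(
        {
            "plot": ["A", "A", "B"],
            "year": [2015, 2015, 2015],
            "round": [1, 2, 1],
            "total_cover": [10.0, 24.0, 5.0],
            "herb_cover": [2.0, 3.0, 1.0],
            "grass_cover": [5.0, 2.0, 2.0],
            "n_species": [3, 5, 2],
        }
    )
    soil = pd.DataFrame(
        {
            "plot": ["A", "B"],
            "sand": [60.0, 50.0],
            "gravel": [20.0, 30.0],
            "cobble": [10.0, 10.0],
            "boulder": [7.0, 7.0],
            "large_boulder": [3.0, 3.0],
        }
    )
    rainfall = _series("2015-01-01", 120, 1.0)
    return events, veg, soil, rainfall


class TestAggregate:
    def test_sums_maxima_and_rounds(self, small_inputs):
        events, veg, soil, rainfall = small_inputs
        records = aggregate(events, veg, soil, rainfall,
                            ["cicadas", "springtails"], info=TAXA)
        a = records[records["plot"] == "A"].iloc[0]
        assert a["cicadas"] == 7  # summed over rounds
        assert a["herbivore"] == 7
        assert a["detritivore"] == 2
        assert a["total_cover"] == 24.0  # per-parameter maximum
        assert a["n_rounds"] == 2
        assert a["seasonal_rainfall"] == 59.0
        b = records[records["plot"] == "B"].iloc[0]
        assert b["n_rounds"] == 1

    def test_group_density_equals_sum_of_member_taxa(self, small_inputs):
        events, veg, soil, rainfall = small_inputs
        records = aggregate(events, veg, soil, rainfall,
                            ["cicadas", "springtails"], info=TAXA)
        assert (records["herbivore"] == records["cicadas"]).all()
        assert (records["detritivore"] == records["springtails"]).all()

    def test_missing_vegetation_kept_with_warning(self, small_inputs):
        events, veg, soil, rainfall = small_inputs
        with pytest.warns(UserWarning, match="without vegetation"):
            records = aggregate(events, veg[veg["plot"] == "A"], soil, rainfall,
                                ["cicadas"], info=TAXA)
        b = records[records["plot"] == "B"].iloc[0]
        assert np.isnan(b["total_cover"])


class TestBuildMatrix:
    def test_matrix_shape_and_zeros(self, default_study):
        records = default_study["records"]
        retained = default_study["retained"]
        matrix = default_study["matrix"]
        assert matrix.shape == (len(records), len(retained))
        assert (matrix.to_numpy() >= 0).all()

    def test_conservation_of_individuals(self, default_study):
        """The matrix total equals the retained individuals in the raw
        trap records (nothing created or lost in aggregation)."""
        traps = default_study["bundle"]["traps"]
        retained = default_study["retained"]
        raw_total = traps[traps["taxon"].isin(retained)]["count"].sum()
        assert default_study["matrix"].to_numpy().sum() == raw_total

    def test_all_zero_site_dropped_with_warning(self):
        records = pd.DataFrame(
            {
                "plot": ["A", "B", "C", "D"],
                "year": [2015] * 4,
                "cicadas": [1, 0, 2, 3],
                "springtails": [1, 0, 0, 2],
            }
        )
        with pytest.warns(UserWarning, match="B:2015"):
            M = build_matrix(records, ["cicadas", "springtails"])
        assert list(M.index) == ["A:2015", "C:2015", "D:2015"]

    def test_too_few_sites_error(self):
        records = pd.DataFrame(
            {"plot": ["A", "B"], "year": [2015, 2015], "cicadas": [1, 2], "mites": [0, 1]}
        )
        with pytest.raises(ValueError, match="ordination infeasible"):
            build_matrix(records, ["cicadas", "mites"])


class TestReaders:
    def test_traps_round_trip_and_validation(self, tmp_path, default_study):
        traps = default_study["bundle"]["traps"].copy()
        traps["start_date"] = pd.to_datetime(traps["start_date"]).dt.strftime("%Y-%m-%d")
        path = tmp_path / "traps.csv"
        traps.to_csv(path, index=False)
        back = read_traps(path)
        assert len(back) == len(traps)
        assert (back["count"].to_numpy() == traps["count"].to_numpy()).all()

    def test_bad_count_row_is_named(self, tmp_path):
        path = tmp_path / "traps.csv"
        path.write_text(
            "plot,year,round,start_date,taxon,count\nA,2015,1,2015-03-01,cicadas,2.5\n"
        )
        with pytest.raises(SchemaError, match="row 2"):
            read_traps(path)

    def test_unknown_trophic_group_rejected(self, tmp_path):
        path = tmp_path / "taxa.csv"
        path.write_text("taxon,trophic_group,ground_dwelling\ncicadas,megafauna,true\n")
        with pytest.raises(SchemaError, match="megafauna"):
            read_taxa(path)
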