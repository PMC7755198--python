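"""Breeding-season split, importance percentages, and the critical threshold."""

import datetime as dt

import pytest

from flampipe.breeding import (
    EmptySeasonError,
    breeding_table,
    classify_critical,
    flag_critical,
    half_up,
    season_of,
    yearly_breeding_series,
)
from flampipe.filters import ConfigurationError
from flampipe.records import PRESENCE_ONLY
from flampipe.regions import default_scheme


@pytest.fixture(scope="module")
def scheme():
    return default_scheme()


def breeding_record(make_record, country, year, count, month=5, locality="LB"):
    return make_record(
        country=country, subnational="", locality_id=locality,
        date=dt.date(year, month, 15), count=count,
    )


class TestSeasonOf:
    @pytest.mark.parametrize(
        "date,season",
        [
            (dt.date(2015, 4, 1), "breeding"),
            (dt.date(2015, 8, 31), "breeding"),
            (dt.date(2015, 9, 1), "nonbreeding"),
            (dt.date(2015, 12, 25), "nonbreeding"),
            (dt.date(2015, 3, 31), "nonbreeding"),
        ],
    )
    def test_boundaries(self, date, season):
        assert season_of(date) == season


class TestYearlySeries:
    def test_sums_breeding_records_per_year(self, make_record):
        recs = [
            breeding_record(make_record, "Cuba", 2012, 10),
            breeding_record(make_record, "Cuba", 2012, 5, month=7),
            breeding_record(make_record, "Cuba", 2014, 3),
            breeding_record(make_record, "Cuba", 2014, 7, month=12),  # nonbreeding
            breeding_record(make_record, "Cuba", 2008, 99),           # outside window
        ]
        assert yearly_breeding_series(recs, (2010, 2018)) == {2012: 15, 2014: 3}

    def test_presence_only_does_not_contribute(self, make_record):
        recs = [breeding_record(make_record, "Cuba", 2012, PRESENCE_ONLY)]
        assert yearly_breeding_series(recs, (2010, 2018)) == {}


class TestBreedingTable:
    def test_single_unit_takes_all(self, scheme, make_record):
        recs = [breeding_record(make_record, "Cuba", 2012, 40)]
        [row] = breeding_table(recs, scheme, (2010, 2018))
        assert half_up(row.pct_breeding, 4) == 100.0

    def test_exact_fractions_for_two_units(self, scheme, make_record):
        recs = [
            breeding_record(make_record, "Cuba", 2012, 300, locality="L1"),
            breeding_record(make_record, "Bahamas", 2012, 700, locality="L2"),
        ]
        table = {r.unit: r for r in breeding_table(recs, scheme, (2010, 2018))}
        assert half_up(table["Cuba"].pct_breeding, 4) == 30.0
        assert half_up(table["Bahamas"].pct_breeding, 4) == 70.0

    def test_percentages_sum_to_100(self, scheme, make_record):
        recs = [
            breeding_record(make_record, c, 2011 + i, 13 * (i + 1), locality=f"L{i}")
            for i, c in enumerate(["Cuba", "Bahamas", "Venezuela", "Ecuador", "Bonaire"])
        ]
        table = breeding_table(recs, scheme, (2010, 2018))
        assert sum(r.pct_breeding for r in table) == pytest.approx(100.0)

    def test_yearly_statistics(self, scheme, make_record):
        # nine yearly totals summing to 3,610 -> average 401.1 at one decimal
        totals = [57, 862, 300, 400, 500, 391, 350, 400, 350]
        assert sum(totals) == 3610
        recs = [
            breeding_record(make_record, "Ecuador", 2010 + i, n, locality=f"L{i}")
            for i, n in enumerate(totals)
        ]
        [row] = breeding_table(recs, scheme, (2010, 2018))
        assert row.n_years == 9
        assert half_up(row.avg_per_year, 1) == 401.1
        assert row.min_year_total == 57 and row.max_year_total == 862
        assert row.min_year_total <= row.avg_per_year <= row.max_year_total

    def test_single_year_unit_has_no_spread_statistics(self, scheme, make_record):
        recs = [breeding_record(make_record, "Guyana", 2013, 40)]
        [row] = breeding_table(recs, scheme, (2010, 2018))
        assert row.n_years == 1 and row.avg_per_year == 40.0
        assert row.sd_per_year is None
        assert row.min_year_total is None and row.max_year_total is None

    def test_two_year_unit_has_min_max_but_no_sd(self, scheme, make_record):
        recs = [
            breeding_record(make_record, "Cuba", 2012, 1),
            breeding_record(make_record, "Cuba", 2015, 20),
        ]
        [row] = breeding_table(recs, scheme, (2010, 2018))
        assert row.sd_per_year is None
        assert (row.min_year_total, row.max_year_total) == (1, 20)

    def test_constant_series_has_zero_sd(self, scheme, make_record):
        recs = [breeding_record(make_record, "Cuba", 2010 + i, 50) for i in range(4)]
        [row] = breeding_table(recs, scheme, (2010, 2018))
        assert row.sd_per_year == 0.0
        assert row.min_year_total == row.max_year_total == row.avg_per_year == 50

    def test_denominator_excludes_units_without_breeding_data(self, scheme, make_record):
        base = [
            breeding_record(make_record, "Cuba", 2012, 300, locality="L1"),
            breeding_record(make_record, "Bahamas", 2012, 700, locality="L2"),
        ]
        nonbreeding_only = make_record(
            country="Haiti", subnational="", locality_id="L3",
            date=dt.date(2012, 12, 1), count=500,
        )
        with_extra = breeding_table(base + [nonbreeding_only], scheme, (2010, 2018))
        without = breeding_table(base, scheme, (2010, 2018))
        assert {r.unit: r.pct_breeding for r in with_extra} == {
            r.unit: r.pct_breeding for r in without
        }

    def test_scale_invariance(self, scheme, make_record):
        def build(k):
            return [
                breeding_record(make_record, "Cuba", 2012, 3 * k, locality="L1"),
                breeding_record(make_record, "Bahamas", 2012, 7 * k, locality="L2"),
            ]

        t1 = {r.unit: r.pct_breeding for r in breeding_table(build(1), scheme, (2010, 2018))}
        t9 = {r.unit: r.pct_breeding for r in breeding_table(build(9), scheme, (2010, 2018))}
        assert t1 == pytest.approx(t9)

    def test_no_breeding_records_raises(self, scheme, make_record):
        recs = [make_record(date=dt.date(2012, 12, 1))]
        with pytest.raises(EmptySeasonError):
            breeding_table(recs, scheme, (2010, 2018))


class TestClassifyCritical:
    def _table(self, scheme, make_record, shares):
        recs = [
            breeding_record(make_record, c, 2012, n, locality=f"L{i}")
            for i, (c, n) in enumerate(shares.items())
        ]
        return breeding_table(recs, scheme, (2010, 2018))

    def test_inclusive_threshold_keeps_reference(self, scheme, make_record):
        table = self._table(scheme, make_record,
                            {"Ecuador": 10, "Venezuela": 900, "Haiti": 5})
        crit = classify_critical(table, "Ecuador")
        assert crit == ["Ecuador", "Venezuela"]

    def test_reference_at_maximum_returns_only_itself(self, scheme, make_record):
        table = self._table(scheme, make_record, {"Ecuador": 900, "Haiti": 5})
        assert classify_critical(table, "Ecuador") == ["Ecuador"]

    def test_all_equal_percentages_all_critical(self, scheme, make_record):
        table = self._table(scheme, make_record,
                            {"Ecuador": 50, "Cuba": 50, "Haiti": 50})
        assert classify_critical(table, "Ecuador") == ["Cuba", "Ecuador", "Haiti"]

    def test_missing_reference_is_configuration_error(self, scheme, make_record):
        table = self._table(scheme, make_record, {"Cuba": 50})
        with pytest.raises(ConfigurationError):
            classify_critical(table, "Ecuador")

    def test_flag_critical_marks_rows(self, scheme, make_record):
        table = self._table(scheme, make_record,
                            {"Ecuador": 10, "Venezuela": 900, "Haiti": 5})
        flagged = {r.unit: r.is_critical for r in flag_critical(table, "Ecuador")}
        assert flagged == {"Ecuador": True, "Venezuela": True, "Haiti": False}


class TestHalfUpRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(0.68265, 4, 0.6827), (13101.777, 1, 13101.8), (0.25, 1, 0.3), (2.5, 0, 3.0)],
    )
    def test_half_up(self, value, decimals, expected):
        assert half_up(value, decimals) == expected
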