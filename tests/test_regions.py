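"""Region assignment, decade windowing, summaries, effort, range classification."""

import datetime as dt
import random

import pytest
from shapely.geometry import box

from flampipe.filters import ConfigurationError
from flampipe.records import PRESENCE_ONLY
from flampipe.regions import (
    UNASSIGNED,
    WindowError,
    assign_region,
    classify_against_range,
    decade_of,
    default_recognized_range,
    default_scheme,
    default_scope_polygon,
    individuals_per_record_index,
    record_days,
    summarize_decades,
    summarize_units,
)


@pytest.fixture(scope="module")
def scheme():
    return default_scheme()


class TestAssignRegion:
    def test_yucatan_subnational_resolves(self, scheme, make_record):
        rec = make_record(country="Mexico", subnational="Yucatán")
        assert assign_region(rec, scheme) == ("North America", "Mexico", "Yucatan Peninsula")

    def test_mexico_catch_all_is_central(self, scheme, make_record):
        rec = make_record(country="Mexico", subnational="Jalisco")
        assert assign_region(rec, scheme) == ("North America", "Mexico", "Central")

    def test_bonaire_files_under_south_america(self, scheme, make_record):
        rec = make_record(country="Bonaire", subnational="")
        assert assign_region(rec, scheme) == ("South America", "Bonaire", None)

    def test_aruba_stays_caribbean(self, scheme, make_record):
        rec = make_record(country="Aruba", subnational="")
        assert assign_region(rec, scheme)[0] == "Caribbean"

    def test_unknown_country_goes_to_unassigned_bucket(self, scheme, make_record):
        rec = make_record(country="Atlantis", subnational="")
        region, country, sub = assign_region(rec, scheme)
        assert region == UNASSIGNED and country == "Atlantis" and sub is None

    def test_usa_gulf_florida_split(self, scheme, make_record):
        gulf = make_record(country="USA", subnational="Florida")
        coast = make_record(country="USA", subnational="California")
        assert assign_region(gulf, scheme)[2] == "Gulf of Mexico/Florida"
        assert assign_region(coast, scheme)[2] == "East and West Coast"


class TestDecadeOf:
    @pytest.mark.parametrize(
        "date,label",
        [
            (dt.date(1969, 12, 31), "1960s"),
            (dt.date(1970, 1, 1), "1970s"),
            (dt.date(2018, 10, 31), "2010s"),
            (dt.date(1960, 1, 1), "1960s"),
        ],
    )
    def test_labels(self, date, label):
        assert decade_of(date) == label

    @pytest.mark.parametrize("date", [dt.date(2018, 11, 1), dt.date(1959, 12, 31)])
    def test_out_of_window_rejected(self, date):
        with pytest.raises(WindowError):
            decade_of(date)


class TestSummaries:
    def test_single_record_dataset(self, scheme, make_record):
        rec = make_record(country="Cuba", subnational="", count=42)
        [summary] = summarize_units([rec], scheme, level="country")
        assert summary.unit == "Cuba" and summary.region == "Caribbean"
        assert summary.accounting.n_final == 1
        assert summary.accounting.cum_individuals == 42
        assert summary.first_record_year == rec.date.year

    def test_unit_totals_match_brute_force_sums(self, scheme, make_record):
        rng = random.Random(17)
        countries = ["Cuba", "Mexico", "Venezuela", "Bahamas"]
        recs = [
            make_record(
                country=rng.choice(countries),
                subnational="",
                locality_id=f"L{i}",
                date=dt.date(2000, 1, 1) + dt.timedelta(days=rng.randrange(5000)),
                count=rng.randrange(1, 200),
            )
            for i in range(250)
        ]
        summaries = {s.unit: s for s in summarize_units(recs, scheme, level="country")}
        for country in countries:
            mine = [r for r in recs if r.country == country]  # independent pass
            assert summaries[country].accounting.n_final == len(mine)
            assert summaries[country].accounting.cum_individuals == sum(r.count for r in mine)
            assert summaries[country].first_record_year == min(r.date.year for r in mine)

    def test_region_totals_equal_sum_of_member_countries(self, scheme, make_record):
        rng = random.Random(19)
        recs = [
            make_record(
                country=rng.choice(["Cuba", "Haiti", "Jamaica"]),
                subnational="",
                locality_id=f"L{i}",
                count=rng.randrange(1, 50),
            )
            for i in range(80)
        ]
        by_country = summarize_units(recs, scheme, level="country")
        [by_region] = summarize_units(recs, scheme, level="region")
        assert by_region.unit == "Caribbean"
        assert by_region.accounting.cum_individuals == sum(
            s.accounting.cum_individuals for s in by_country
        )
        assert by_region.accounting.n_final == sum(s.accounting.n_final for s in by_country)

    def test_decade_partition_sums_to_unit_totals(self, scheme, make_record):
        rng = random.Random(23)
        recs = [
            make_record(
                country="Cuba",
                subnational="",
                locality_id=f"L{i}",
                date=dt.date(1965, 1, 1) + dt.timedelta(days=rng.randrange(19500)),
                count=rng.randrange(1, 30),
            )
            for i in range(120)
        ]
        decades = summarize_decades(recs, scheme, level="country")
        assert sum(d.n_records for d in decades) == len(recs)
        assert sum(d.cum_individuals for d in decades) == sum(r.count for r in recs)

    def test_recent_records_only_touch_2010s(self, scheme, make_record):
        recs = [
            make_record(country="Cuba", subnational="", locality_id=f"L{i}",
                        date=dt.date(2012 + i, 3, 1))
            for i in range(5)
        ]
        decades = summarize_decades(recs, scheme, level="country")
        assert {d.decade for d in decades} == {"2010s"}


class TestEffort:
    def test_record_days_counts_distinct_dates(self, make_record):
        d1, d2 = dt.date(2015, 5, 1), dt.date(2015, 5, 2)
        recs = [make_record(date=d1), make_record(date=d1), make_record(date=d2)]
        assert record_days(recs) == 2
        assert record_days([]) == 0

    def test_record_days_bounded_by_record_count(self, make_record):
        rng = random.Random(5)
        recs = [
            make_record(date=dt.date(2015, 1, 1) + dt.timedelta(days=rng.randrange(10)))
            for _ in range(40)
        ]
        assert record_days(recs) <= len(recs)

    def test_individuals_per_record_index(self, make_record):
        recs = [make_record(locality_id=f"L{i}", count=100) for i in range(10)]
        assert individuals_per_record_index(recs) == 100.0
        ones = [make_record(locality_id=f"M{i}", count=1) for i in range(7)]
        assert individuals_per_record_index(ones) == 1.0  # lower bound
        assert individuals_per_record_index([]) is None


class TestRangeClassification:
    def test_flags_match_square_membership_oracle(self, make_record):
        rng = random.Random(41)
        square = box(-10.0, -10.0, 10.0, 10.0)
        recs = [
            make_record(latitude=rng.uniform(-20, 20), longitude=rng.uniform(-20, 20),
                        locality_id=f"L{i}")
            for i in range(1000)
        ]
        flags = classify_against_range(recs, square)
        expected = [abs(r.latitude) <= 10 and abs(r.longitude) <= 10 for r in recs]
        assert flags == expected

    def test_centroid_inside_far_point_outside(self, make_record):
        square = box(0, 0, 2, 2)
        inside = make_record(latitude=1.0, longitude=1.0)
        outside = make_record(latitude=80.0, longitude=179.0)
        assert classify_against_range([inside, outside], square) == [True, False]

    def test_default_polygons_are_valid_and_nested(self):
        scope = default_scope_polygon()
        rng = default_recognized_range()
        assert scope.is_valid and rng.is_valid
        assert scope.contains(rng)  # the recognized range lies inside the Americas scope
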