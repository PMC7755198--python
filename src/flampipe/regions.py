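"""Regional assignment and aggregation of cleaned occurrence records.

Countries are grouped into four regions — North America, Central America,
South America, and the Caribbean — following the grouping conventional in
American Flamingo assessments, which files Bonaire and Curaçao under South
America (with the continental coast their colonies belong to) and Aruba under
the Caribbean. Two countries are split into sub-country units: Mexico into
the Yucatan Peninsula and Central Mexico, and the USA into the Gulf of
Mexico/Florida coast and the East and West Coasts. The memberships are
config-editable; the defaults list the subnational units by name.

Aggregation covers per-unit accounting summaries with the year of the first
record, per-decade record/individual tallies (the study window runs
1960-01-01 to 2018-10-31, so "the 2010s" is a partial decade), two
observer-effort proxies (distinct record days; cumulative individuals per
record), and classification of each record against the recognized
distribution polygon.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .filters import ConfigurationError, FilterAccounting, run_filters
from .records import OccurrenceRecord

UNASSIGNED = "Unassigned"

#: Study window: eBird extraction covered 1960 through 31 October 2018.
WINDOW_START = _dt.date(1960, 1, 1)
WINDOW_END = _dt.date(2018, 10, 31)


class WindowError(ValueError):
    """A date falls outside the study window."""


@dataclass(frozen=True)
class SubcountryRule:
    """One sub-country unit: matched by subnational code/name, else by polygon."""

    unit: str
    subnational_names: frozenset[str] = frozenset()
    polygon: Optional[BaseGeometry] = None
    is_default: bool = False  # catch-all unit for the country

    def matches(self, record: OccurrenceRecord) -> bool:
        if record.subnational and record.subnational in self.subnational_names:
            return True
        if self.polygon is not None and self.polygon.intersects(
            Point(record.longitude, record.latitude)
        ):
            return True
        return False


@dataclass
class RegionScheme:
    """Country-to-region mapping, sub-country splits, and the recognized range."""

    country_to_region: dict[str, str]
    subcountry_rules: dict[str, list[SubcountryRule]] = field(default_factory=dict)
    recognized_range: Optional[BaseGeometry] = None

    def __post_init__(self) -> None:
        for country, rules in self.subcountry_rules.items():
            if sum(r.is_default for r in rules) != 1:
                raise ConfigurationError(
                    f"sub-country rules for {country} need exactly one catch-all unit"
                )

    def region_of(self, country: str) -> str:
        return self.country_to_region.get(country, UNASSIGNED)

    def unit_of(self, record: OccurrenceRecord) -> str:
        """Analysis unit: the sub-country unit where a split exists, else the country."""
        _, country, sub = assign_region(record, self)
        if sub is not None:
            return f"{country} - {sub}"
        return country


def assign_region(
    record: OccurrenceRecord, scheme: RegionScheme
) -> tuple[str, str, Optional[str]]:
    """Assign (region, country, sub-country unit or None).

    Unknown countries go to an explicit unassigned bucket, never silently
    dropped; sub-country resolution tries subnational codes first and any
    polygon rule second, falling back to the country's catch-all unit.
    """
    region = scheme.region_of(record.country)
    rules = scheme.subcountry_rules.get(record.country)
    if not rules:
        return region, record.country, None
    for rule in rules:
        if not rule.is_default and rule.matches(record):
            return region, record.country, rule.unit
    default = next(r for r in rules if r.is_default)
    return region, record.country, default.unit


def decade_of(date: _dt.date) -> str:
    """Decade label ("1960s" ... "2010s") within the study window."""
    if not WINDOW_START <= date <= WINDOW_END:
        raise WindowError(f"date {date} outside study window {WINDOW_START}..{WINDOW_END}")
    return f"{date.year // 10 * 10}s"


@dataclass(frozen=True)
class CountrySummary:
    unit: str
    region: str
    accounting: FilterAccounting
    first_record_year: Optional[int]


@dataclass(frozen=True)
class DecadeSummary:
    unit: str
    region: str
    decade: str
    n_records: int
    cum_individuals: int


def summarize_units(
    final_records: Sequence[OccurrenceRecord],
    scheme: RegionScheme,
    level: str = "country",
) -> list[CountrySummary]:
    """Per-unit accounting summaries over already-filtered records.

    ``level`` is ``"region"``, ``"country"`` or ``"subcountry"``. Records are
    already final, so each unit's accounting has no duplicates or qualitative
    removals — the point here is totals and the first-record year. Units with
    no records are omitted.
    """
    if level not in {"region", "country", "subcountry"}:
        raise ConfigurationError(f"unknown aggregation level {level!r}")

    def key(rec: OccurrenceRecord) -> tuple[str, str]:
        region, country, sub = assign_region(rec, scheme)
        if level == "region":
            return region, region
        if level == "country":
            return region, country
        return region, f"{country} - {sub}" if sub is not None else country

    buckets: dict[tuple[str, str], list[OccurrenceRecord]] = {}
    for rec in final_records:
        buckets.setdefault(key(rec), []).append(rec)
    out = []
    for (region, unit), recs in sorted(buckets.items()):
        _, acct = run_filters(recs, None)
        out.append(
            CountrySummary(
                unit=unit,
                region=region,
                accounting=acct,
                first_record_year=min(r.date.year for r in recs),
            )
        )
    return out


def summarize_decades(
    final_records: Sequence[OccurrenceRecord],
    scheme: RegionScheme,
    level: str = "country",
) -> list[DecadeSummary]:
    """Per-unit, per-decade record and individual tallies; empty cells absent."""
    buckets: dict[tuple[str, str, str], list[OccurrenceRecord]] = {}
    for rec in final_records:
        region, country, sub = assign_region(rec, scheme)
        if level == "region":
            unit = region
        elif level == "country":
            unit = country
        else:
            unit = f"{country} - {sub}" if sub is not None else country
        buckets.setdefault((region, unit, decade_of(rec.date)), []).append(rec)
    return [
        DecadeSummary(
            unit=unit,
            region=region,
            decade=decade,
            n_records=len(recs),
            cum_individuals=sum(r.count for r in recs),
        )
        for (region, unit, decade), recs in sorted(buckets.items())
    ]


def record_days(final_records: Iterable[OccurrenceRecord]) -> int:
    """Observer-effort proxy: number of distinct dates with at least one record."""
    return len({r.date for r in final_records})


def individuals_per_record_index(
    final_records: Sequence[OccurrenceRecord],
) -> Optional[float]:
    """Cumulative individuals per record; ``None`` (not zero) when empty.

    Applied per unit-decade this tracks how flock sizes per checklist evolve
    relative to reporting effort; it is >= 1 whenever defined because every
    final record counts at least one bird.
    """
    if not final_records:
        return None
    return sum(r.count for r in final_records) / len(final_records)


def classify_against_range(
    final_records: Sequence[OccurrenceRecord],
    recognized_range: BaseGeometry,
) -> list[bool]:
    """Flag each record inside (True) or outside the recognized distribution.

    Boundary points count as inside.
    """
    if recognized_range is None or recognized_range.is_empty or not recognized_range.is_valid:
        raise ConfigurationError("recognized range polygon is empty or invalid")
    prepared = prep(recognized_range)
    return [prepared.intersects(Point(r.longitude, r.latitude)) for r in final_records]


# ---------------------------------------------------------------------------
# GeoJSON plumbing and the default scheme
# ---------------------------------------------------------------------------

def load_polygon(path: Union[str, Path]) -> BaseGeometry:
    """Load a (multi)polygon from a GeoJSON file (geometry, feature, or collection)."""
    with Path(path).open("r", encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in obj["features"]]
        from shapely.ops import unary_union

        return unary_union(geoms)
    if obj.get("type") == "Feature":
        return shape(obj["geometry"])
    return shape(obj)


def records_to_geojson(
    records: Sequence[OccurrenceRecord], inside_flags: Sequence[bool]
) -> dict:
    """Records as a GeoJSON FeatureCollection with an ``inside_range`` property."""
    features = []
    for rec, inside in zip(records, inside_flags):
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [rec.longitude, rec.latitude]},
                "properties": {
                    "record_id": rec.record_id,
                    "country": rec.country,
                    "date": rec.date.isoformat(),
                    "count": rec.count if rec.is_quantitative else "X",
                    "inside_range": bool(inside),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def _load_packaged_polygon(name: str) -> BaseGeometry:
    with resources.files("flampipe.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return shape(json.load(fh))


def default_scope_polygon() -> BaseGeometry:
    """Generous Americas bounding polygon; excludes Europe (captive birds)."""
    return _load_packaged_polygon("americas_scope.geojson")


def default_recognized_range() -> BaseGeometry:
    """Coarse synthetic approximation of the recognized distribution.

    Boxes around the Caribbean basin, the Yucatan Peninsula, the northern
    coast of South America and the Galapagos Islands — a stand-in authored
    for this package, not a published shapefile; override with any GeoJSON
    polygon for real analyses.
    """
    return _load_packaged_polygon("recognized_range_synthetic.geojson")


_REGION_MEMBERS: dict[str, list[str]] = {
    "North America": ["Bermuda", "Canada", "USA", "Mexico"],
    "Central America": ["Belize", "Honduras"],
    # Bonaire and Curaçao sit with the continental coast their colonies
    # belong to; Aruba stays Caribbean.
    "South America": [
        "Bonaire",
        "Brazil",
        "Colombia",
        "Curaçao",
        "Ecuador",
        "Guyana",
        "Suriname",
        "Venezuela",
    ],
    "Caribbean": [
        "Anguilla",
        "Aruba",
        "Bahamas",
        "Barbados",
        "Cayman Island",
        "Cuba",
        "Dominican Republic",
        "Granada",
        "Guadalupe",
        "Haiti",
        "Jamaica",
        "Puerto Rico",
        "Saint Kitts",
        "Saint Martin",
        "Trinidad and Tobago",
        "Turks and Caicos Islands",
        "Virgin Island",
    ],
}

#: Membership lists for the two split countries; editable via config.
YUCATAN_STATES = frozenset({"Yucatán", "Yucatan", "Campeche", "Quintana Roo"})
GULF_FLORIDA_STATES = frozenset({"Florida", "Alabama", "Mississippi", "Louisiana", "Texas"})


def default_scheme(recognized_range: Optional[BaseGeometry] = None) -> RegionScheme:
    """The default four-region scheme with the Mexico and USA splits."""
    country_to_region = {
        country: region for region, members in _REGION_MEMBERS.items() for country in members
    }
    rules = {
        "Mexico": [
            SubcountryRule("Yucatan Peninsula", YUCATAN_STATES),
            SubcountryRule("Central", is_default=True),
        ],
        "USA": [
            SubcountryRule("Gulf of Mexico/Florida", GULF_FLORIDA_STATES),
            SubcountryRule("East and West Coast", is_default=True),
        ],
    }
    if recognized_range is None:
        recognized_range = default_recognized_range()
    return RegionScheme(
        country_to_region=country_to_region,
        subcountry_rules=rules,
        recognized_range=recognized_range,
    )


def scheme_from_yaml(path: Union[str, Path]) -> RegionScheme:
    """Load a scheme from a YAML file.

    Schema::

        regions:
          North America: [USA, Mexico, ...]
        subcountry:
          Mexico:
            - unit: Yucatan Peninsula
              subnational: [Yucatán, Campeche, Quintana Roo]
            - unit: Central
              default: true
        recognized_range: path/to/polygon.geojson   # optional
    """
    import yaml

    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    country_to_region = {
        country: region for region, members in cfg.get("regions", {}).items() for country in members
    }
    rules: dict[str, list[SubcountryRule]] = {}
    for country, rule_list in cfg.get("subcountry", {}).items():
        rules[country] = [
            SubcountryRule(
                unit=r["unit"],
                subnational_names=frozenset(r.get("subnational", [])),
                is_default=bool(r.get("default", False)),
            )
            for r in rule_list
        ]
    rng = None
    if cfg.get("recognized_range"):
        rng_path = Path(cfg["recognized_range"])
        if not rng_path.is_absolute():
            rng_path = path.parent / rng_path
        rng = load_polygon(rng_path)
    return RegionScheme(country_to_region, rules, rng)


def polygon_to_geojson(polygon: BaseGeometry) -> dict:
    return mapping(polygon)
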