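"""Breeding-season importance scoring with a reference-site threshold.

American Flamingos breed mostly April through August; September–March is the
non-breeding season. Over a recent window (by default the nine breeding
seasons of 2010–2018) each analysis unit's *breeding-importance percentage*
is its cumulative breeding-season individuals as a share of the total over
all units that have at least one breeding-season record in the window —
units without breeding-season data are excluded from the denominator to
avoid effort bias.

The small, isolated, confirmed-breeding Galapagos population (Ecuador) sets
the reference: any unit whose percentage is at least the reference unit's is
flagged a critical potential breeding area. The comparison is inclusive so
the reference site classifies itself.

Rounding is half-up and applied only at presentation: percentages to four
decimals, per-year averages and standard deviations to one decimal. The
yearly standard deviation is the sample (n-1) statistic and is reported only
for units with at least three years of data; min/max need at least two.
"""

from __future__ import annotations

import datetime as _dt
import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .filters import ConfigurationError
from .records import OccurrenceRecord
from .regions import RegionScheme, assign_region

BREEDING_MONTHS = frozenset({4, 5, 6, 7, 8})
DEFAULT_WINDOW = (2010, 2018)


class EmptySeasonError(ValueError):
    """No breeding-season records at all in the window."""


def season_of(date: _dt.date) -> str:
    """``"breeding"`` for April–August, ``"nonbreeding"`` for September–March."""
    return "breeding" if date.month in BREEDING_MONTHS else "nonbreeding"


def yearly_breeding_series(
    final_records: Sequence[OccurrenceRecord],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> dict[int, int]:
    """Year -> cumulative breeding-season individuals; years without data absent."""
    series: dict[int, int] = {}
    lo, hi = window
    for rec in final_records:
        if lo <= rec.date.year <= hi and season_of(rec.date) == "breeding" and rec.is_quantitative:
            series[rec.date.year] = series.get(rec.date.year, 0) + rec.count
    return dict(sorted(series.items()))


@dataclass(frozen=True)
class BreedingAssessment:
    """One unit's breeding-season statistics over the window."""

    unit: str
    region: str
    breeding_individuals: int
    pct_breeding: float  # unrounded; round only for presentation
    n_years: int
    avg_per_year: float
    sd_per_year: Optional[float]  # None unless n_years >= 3
    min_year_total: Optional[int]  # None unless n_years >= 2
    max_year_total: Optional[int]
    is_critical: bool = False


def half_up(value: float, decimals: int) -> float:
    """Half-up rounding for presentation (Python's round() is half-even)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def breeding_table(
    final_records: Sequence[OccurrenceRecord],
    scheme: RegionScheme,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[BreedingAssessment]:
    """Breeding-importance table over all units with breeding-season data.

    The denominator is the sum of breeding-season individuals over exactly
    the included units, so percentages sum to 100 and adding a unit with no
    breeding-season records changes nothing.
    """
    if window[0] > window[1]:
        raise ConfigurationError(f"empty window {window}")
    per_unit: dict[str, list[OccurrenceRecord]] = {}
    unit_region: dict[str, str] = {}
    for rec in final_records:
        region, country, sub = assign_region(rec, scheme)
        unit = f"{country} - {sub}" if sub is not None else country
        per_unit.setdefault(unit, []).append(rec)
        unit_region[unit] = region

    series_by_unit = {
        unit: yearly_breeding_series(recs, window) for unit, recs in per_unit.items()
    }
    series_by_unit = {u: s for u, s in series_by_unit.items() if s}
    if not series_by_unit:
        raise EmptySeasonError("no breeding-season records in the window")
    total = sum(sum(s.values()) for s in series_by_unit.values())

    out: list[BreedingAssessment] = []
    for unit in sorted(series_by_unit):
        series = series_by_unit[unit]
        yearly = list(series.values())
        individuals = sum(yearly)
        n_years = len(yearly)
        out.append(
            BreedingAssessment(
                unit=unit,
                region=unit_region[unit],
                breeding_individuals=individuals,
                pct_breeding=100.0 * individuals / total,
                n_years=n_years,
                avg_per_year=individuals / n_years,
                sd_per_year=statistics.stdev(yearly) if n_years >= 3 else None,
                min_year_total=min(yearly) if n_years >= 2 else None,
                max_year_total=max(yearly) if n_years >= 2 else None,
            )
        )
    return out


def classify_critical(
    table: Sequence[BreedingAssessment],
    reference_unit: str,
) -> list[str]:
    """Units at or above the reference unit's percentage, alphabetically.

    The reference unit is always included (inclusive threshold).
    """
    by_unit = {row.unit: row for row in table}
    if reference_unit not in by_unit:
        raise ConfigurationError(f"reference unit {reference_unit!r} not in table")
    threshold = by_unit[reference_unit].pct_breeding
    return sorted(u for u, row in by_unit.items() if row.pct_breeding >= threshold)


def flag_critical(
    table: Sequence[BreedingAssessment],
    reference_unit: str,
) -> list[BreedingAssessment]:
    """Return the table with ``is_critical`` set against the reference threshold."""
    critical = set(classify_critical(table, reference_unit))
    from dataclasses import replace

    return [replace(row, is_critical=row.unit in critical) for row in table]
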