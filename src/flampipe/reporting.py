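"""Tabular exports: accounting, decade, breeding, and effort tables as DataFrames.

Column names mirror the published summary layout (Record, Duplicate,
Record_clean, Record_qualitative, Record_final, Number_of_individuals) so the
CSV output can be compared cell-by-cell against reference tables. Region
subtotal rows and a TOTAL ALL row are recomputed from the member countries —
column sums hold by construction.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd
from shapely.geometry.base import BaseGeometry

from .breeding import BreedingAssessment, breeding_table, flag_critical, half_up
from .filters import accounting_by_unit, run_filters
from .records import OccurrenceRecord
from .regions import (
    RegionScheme,
    assign_region,
    decade_of,
    individuals_per_record_index,
    record_days,
    summarize_decades,
)

REGION_ORDER = ("North America", "Central America", "South America", "Caribbean", "Unassigned")

ACCOUNTING_COLUMNS = [
    "Record",
    "Duplicate",
    "Record_clean",
    "Record_qualitative",
    "Record_final",
    "Number_of_individuals",
]


def accounting_frame(
    records: Sequence[OccurrenceRecord],
    scheme: RegionScheme,
    scope_polygon: Optional[BaseGeometry] = None,
) -> pd.DataFrame:
    """Per-country accounting with region subtotals and a grand total.

    Takes *unfiltered* records: the filter chain runs per country inside.
    """
    def country_of(rec: OccurrenceRecord) -> str:
        _, country, _ = assign_region(rec, scheme)
        return country

    per_country = accounting_by_unit(records, country_of, scope_polygon)
    first_year: dict[str, Optional[int]] = {}
    scoped = records
    if scope_polygon is not None:
        from .filters import scope_filter

        scoped, _ = scope_filter(records, scope_polygon)
    final, _ = run_filters(scoped, None)
    for rec in final:
        c = country_of(rec)
        y = rec.date.year
        if c not in first_year or y < first_year[c]:
            first_year[c] = y

    rows = []
    totals = {col: 0 for col in ACCOUNTING_COLUMNS}
    for region in REGION_ORDER:
        region_countries = sorted(
            c for c in per_country if scheme.region_of(c) == region
        )
        if not region_countries:
            continue
        sub = {col: 0 for col in ACCOUNTING_COLUMNS}
        for country in region_countries:
            acct = per_country[country]
            vals = [
                acct.n_record,
                acct.n_duplicate,
                acct.n_clean,
                acct.n_qualitative,
                acct.n_final,
                acct.cum_individuals,
            ]
            rows.append(
                {"Region": region, "Country": country, "Year_of_first_record": first_year.get(country)}
                | dict(zip(ACCOUNTING_COLUMNS, vals))
            )
            for col, v in zip(ACCOUNTING_COLUMNS, vals):
                sub[col] += v
                totals[col] += v
        rows.append({"Region": region, "Country": f"Total {region}", "Year_of_first_record": None} | sub)
    rows.append({"Region": "", "Country": "TOTAL ALL", "Year_of_first_record": None} | totals)
    return pd.DataFrame(rows)


def decades_frame(
    final_records: Sequence[OccurrenceRecord],
    scheme: RegionScheme,
    level: str = "country",
) -> pd.DataFrame:
    """Per-unit per-decade records and individuals (zero cells absent)."""
    rows = [
        {
            "Region": s.region,
            "Unit": s.unit,
            "Decade": s.decade,
            "Rec": s.n_records,
            "N": s.cum_individuals,
        }
        for s in summarize_decades(final_records, scheme, level)
    ]
    return pd.DataFrame(rows, columns=["Region", "Unit", "Decade", "Rec", "N"])


def breeding_frame(table: Sequence[BreedingAssessment]) -> pd.DataFrame:
    """Breeding-importance table with presentation rounding applied."""
    rows = []
    for row in table:
        rows.append(
            {
                "Region": row.region,
                "Unit": row.unit,
                "Number_of_individuals": row.breeding_individuals,
                "Percentage_breeding": half_up(row.pct_breeding, 4),
                "Number_of_years": row.n_years,
                "Average_per_year": half_up(row.avg_per_year, 1),
                "SD": half_up(row.sd_per_year, 1) if row.sd_per_year is not None else None,
                "Min": row.min_year_total,
                "Max": row.max_year_total,
                "Critical": row.is_critical,
            }
        )
    return pd.DataFrame(rows)


def yearly_breeding_frame(
    final_records: Sequence[OccurrenceRecord],
    scheme: RegionScheme,
    window: tuple[int, int] = (2010, 2018),
) -> pd.DataFrame:
    """Unit x year matrix of breeding-season cumulative individuals."""
    from .breeding import season_of, yearly_breeding_series

    per_unit: dict[str, list[OccurrenceRecord]] = {}
    for rec in final_records:
        per_unit.setdefault(scheme.unit_of(rec), []).append(rec)
    years = list(range(window[0], window[1] + 1))
    rows = []
    for unit in sorted(per_unit):
        series = yearly_breeding_series(per_unit[unit], window)
        if not series:
            continue
        rows.append({"Unit": unit} | {str(y): series.get(y) for y in years})
    return pd.DataFrame(rows, columns=["Unit"] + [str(y) for y in years])


def effort_frame(
    final_records: Sequence[OccurrenceRecord],
    scheme: RegionScheme,
) -> pd.DataFrame:
    """Per-unit effort metrics: record days and per-decade individuals/record."""
    per_unit: dict[str, list[OccurrenceRecord]] = {}
    for rec in final_records:
        per_unit.setdefault(scheme.unit_of(rec), []).append(rec)
    rows = []
    for unit in sorted(per_unit):
        recs = per_unit[unit]
        by_decade: dict[str, list[OccurrenceRecord]] = {}
        for rec in recs:
            by_decade.setdefault(decade_of(rec.date), []).append(rec)
        for decade in sorted(by_decade):
            idx = individuals_per_record_index(by_decade[decade])
            rows.append(
                {
                    "Unit": unit,
                    "Decade": decade,
                    "Record_days": record_days(by_decade[decade]),
                    "N_records": len(by_decade[decade]),
                    "Individuals_per_record": idx,
                }
            )
        rows.append(
            {
                "Unit": unit,
                "Decade": "all",
                "Record_days": record_days(recs),
                "N_records": len(recs),
                "Individuals_per_record": individuals_per_record_index(recs),
            }
        )
    return pd.DataFrame(rows)


def full_breeding_frame(
    final_records: Sequence[OccurrenceRecord],
    scheme: RegionScheme,
    window: tuple[int, int] = (2010, 2018),
    reference_unit: str = "Ecuador",
) -> pd.DataFrame:
    table = flag_critical(breeding_table(final_records, scheme, window), reference_unit)
    return breeding_frame(table)
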