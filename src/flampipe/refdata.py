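"""Published country-level reference summaries for the American Flamingo.

These are the printed 1960–2018 eBird summary tables for *Phoenicopterus
ruber*: the per-country filter accounting (records, duplicates, qualitative
removals, cumulative individuals, first-record year, grouped into four
regions) and the 2010–2018 breeding-season importance table (cumulative
breeding-season individuals and number of years with data per unit). The raw
extract behind them is not redistributable, but the tables carry enough
arithmetic structure to serve as worked-example *inputs*: the exact-accounting
generator can manufacture a dataset that the filter chain reduces to the
accounting table, and a breeding dataset can be laid down with the printed
unit totals and year counts, after which the pipeline must recompute the
printed derived quantities (region totals, percentages, per-year averages,
critical-country set).
"""

from __future__ import annotations

import datetime as _dt
from typing import Mapping

from .filters import FilterAccounting
from .records import OccurrenceRecord

# country -> (region, n_record, n_duplicate, n_qualitative, cum_individuals, first_year)
ACCOUNTING_TABLE: dict[str, tuple[str, int, int, int, int, int]] = {
    # North America
    "Bermuda": ("North America", 51, 0, 2, 65, 1969),
    "Canada": ("North America", 2, 0, 0, 81, 1978),
    "USA": ("North America", 1269, 580, 33, 3939, 1971),
    "Mexico": ("North America", 3678, 1275, 301, 570953, 1980),
    # Central America
    "Belize": ("Central America", 1, 0, 0, 1, 2007),
    "Honduras": ("Central America", 1, 0, 0, 1, 2011),
    # South America
    "Bonaire": ("South America", 2370, 1307, 100, 109249, 1984),
    "Brazil": ("South America", 1, 0, 0, 150, 2005),
    "Colombia": ("South America", 661, 202, 54, 51519, 1979),
    "Curaçao": ("South America", 1152, 413, 20, 37459, 1992),
    "Ecuador": ("South America", 1772, 370, 387, 9771, 1973),
    "Guyana": ("South America", 7, 2, 0, 76, 2013),
    "Suriname": ("South America", 37, 13, 6, 5105, 2011),
    "Venezuela": ("South America", 714, 253, 132, 1036458, 1982),
    # Caribbean
    "Anguilla": ("Caribbean", 13, 4, 0, 13, 2015),
    "Aruba": ("Caribbean", 111, 17, 0, 152, 1986),
    "Bahamas": ("Caribbean", 406, 166, 18, 67700, 1976),
    "Barbados": ("Caribbean", 29, 10, 0, 19, 2004),
    "Cayman Island": ("Caribbean", 91, 32, 1, 291, 2009),
    "Cuba": ("Caribbean", 2439, 1109, 197, 300560, 1985),
    "Dominican Republic": ("Caribbean", 440, 102, 37, 9681, 1981),
    "Granada": ("Caribbean", 1, 0, 0, 1, 2017),
    "Guadalupe": ("Caribbean", 1, 0, 0, 1, 2013),
    "Haiti": ("Caribbean", 60, 23, 2, 1239, 1987),
    "Jamaica": ("Caribbean", 6, 1, 0, 7, 2016),
    "Puerto Rico": ("Caribbean", 912, 307, 8, 653, 1987),
    "Saint Kitts": ("Caribbean", 1, 0, 0, 1, 2002),
    "Saint Martin": ("Caribbean", 4, 0, 0, 7, 2014),
    "Trinidad and Tobago": ("Caribbean", 110, 22, 3, 2279, 2005),
    "Turks and Caicos Islands": ("Caribbean", 440, 94, 13, 29773, 1976),
    "Virgin Island": ("Caribbean", 150, 22, 9, 3176, 1979),
}

#: Records removed by geographic scoping before the accounting table
#: (European reports of captive birds).
N_OUT_OF_SCOPE = 18

# unit -> (region, country, subnational used to place records, breeding
#          individuals 2010-2018, number of years with data)
BREEDING_TABLE: dict[str, tuple[str, str, str, int, int]] = {
    "USA - East and West Coast": ("North America", "USA", "California", 21, 2),
    "USA - Gulf of Mexico/Florida": ("North America", "USA", "Florida", 1930, 9),
    "Mexico - Central": ("North America", "Mexico", "Jalisco", 10, 2),
    "Mexico - Yucatan Peninsula": ("North America", "Mexico", "Yucatán", 117916, 9),
    "Bonaire": ("South America", "Bonaire", "", 21428, 9),
    "Colombia": ("South America", "Colombia", "La Guajira", 17900, 9),
    "Curaçao": ("South America", "Curaçao", "", 11764, 8),
    "Ecuador": ("South America", "Ecuador", "Galápagos", 3610, 9),
    "Guyana": ("South America", "Guyana", "", 40, 1),
    "Suriname": ("South America", "Suriname", "Nickerie", 295, 3),
    "Venezuela": ("South America", "Venezuela", "Zulia", 243369, 9),
    "Anguilla": ("Caribbean", "Anguilla", "", 7, 1),
    "Aruba": ("Caribbean", "Aruba", "", 142, 6),
    "Bahamas": ("Caribbean", "Bahamas", "Inagua", 11463, 6),
    "Barbados": ("Caribbean", "Barbados", "", 4, 1),
    "Cayman Island": ("Caribbean", "Cayman Island", "", 9, 2),
    "Cuba": ("Caribbean", "Cuba", "Camagüey", 85007, 8),
    "Dominican Republic": ("Caribbean", "Dominican Republic", "", 553, 9),
    "Granada": ("Caribbean", "Granada", "", 1, 1),
    "Haiti": ("Caribbean", "Haiti", "", 435, 3),
    "Jamaica": ("Caribbean", "Jamaica", "", 1, 1),
    "Puerto Rico": ("Caribbean", "Puerto Rico", "", 172, 9),
    "Saint Martin": ("Caribbean", "Saint Martin", "", 4, 1),
    "Trinidad and Tobago": ("Caribbean", "Trinidad and Tobago", "", 1726, 6),
    "Turks and Caicos Islands": ("Caribbean", "Turks and Caicos Islands", "", 9688, 8),
    "Virgin Island": ("Caribbean", "Virgin Island", "", 1269, 7),
}

BREEDING_REFERENCE_UNIT = "Ecuador"
BREEDING_WINDOW = (2010, 2018)


def accounting_targets() -> dict[str, FilterAccounting]:
    """Per-country filter accounting targets from the published table."""
    return {
        country: FilterAccounting(
            n_record=rec, n_duplicate=dup, n_qualitative=qual, cum_individuals=ind
        )
        for country, (_, rec, dup, qual, ind, _) in ACCOUNTING_TABLE.items()
    }


def region_of_country() -> dict[str, str]:
    return {country: row[0] for country, row in ACCOUNTING_TABLE.items()}


def records_from_breeding_totals(
    table: Mapping[str, tuple[str, str, str, int, int]] = BREEDING_TABLE,
    window: tuple[int, int] = BREEDING_WINDOW,
) -> list[OccurrenceRecord]:
    """Lay down breeding-season records realizing the published unit totals.

    Each unit gets one quantitative record per year with data, on 15 May
    (mid breeding season), on its own locality; counts are 1 except the
    first year, which absorbs the remainder so that the yearly series sums
    to the published cumulative individuals. Per-year averages and the
    percentage column are then fully determined; the yearly spread (SD,
    min, max) is not prescribed by the published totals and is not
    reproduced.
    """
    records: list[OccurrenceRecord] = []
    serial = 0
    for ui, unit in enumerate(sorted(table)):
        _, country, subnational, individuals, n_years = table[unit]
        if individuals < n_years:
            raise ValueError(f"{unit}: fewer individuals than years with data")
        years = range(window[0], window[0] + n_years)
        counts = [1] * n_years
        counts[0] = individuals - (n_years - 1)
        for year, count in zip(years, counts):
            serial += 1
            records.append(
                OccurrenceRecord(
                    record_id=f"B{serial:06d}",
                    country=country,
                    subnational=subnational,
                    locality_id=f"LB-{ui:03d}",
                    latitude=15.0,
                    longitude=-70.0,
                    date=_dt.date(year, 5, 15),
                    count=count,
                )
            )
    return records
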