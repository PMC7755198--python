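"""Score each unit's breeding-season importance and flag critical countries.

Over the nine April–August breeding seasons of 2010–2018, each unit's share
of the global breeding-season cumulative individuals is compared against the
Galapagos (Ecuador) reference share; units at or above it are critical
potential breeding areas. Writes results/table2.csv and the unit x year
matrix results/s2_yearly.csv.
"""

from pathlib import Path

from flampipe.breeding import breeding_table, flag_critical
from flampipe.records import read_records
from flampipe.filters import run_filters
from flampipe.regions import default_scheme, default_scope_polygon
from flampipe.reporting import breeding_frame, yearly_breeding_frame

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records, _ = read_records(OUT / "synthetic_records.tsv")
    final, _ = run_filters(records, default_scope_polygon())
    scheme = default_scheme()
    table = flag_critical(breeding_table(final, scheme, (2010, 2018)), "Ecuador")
    frame = breeding_frame(table)
    frame.to_csv(OUT / "table2.csv", index=False)
    yearly_breeding_frame(final, scheme, (2010, 2018)).to_csv(
        OUT / "s2_yearly.csv", index=False
    )
    ref = frame[frame["Unit"] == "Ecuador"].iloc[0]
    critical = frame[frame["Critical"]]["Unit"].tolist()
    print(f"reference (Ecuador) share: {ref['Percentage_breeding']}%")
    print(f"{len(critical)} critical potential breeding units: {', '.join(critical)}")
    print(f"wrote {OUT / 'table2.csv'} and {OUT / 's2_yearly.csv'}")


if __name__ == "__main__":
    main()
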