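# flampipe

A citizen-science occurrence-record pipeline for the American Flamingo
(*Phoenicopterus ruber*), built for biodiversity informaticians who want the
record-cleaning, aggregation and breeding-site scoring steps of an
eBird-style distribution assessment as tested, reusable code rather than a
spreadsheet procedure.

## What it computes

Starting from an eBird-Basic-Dataset-like TSV (one row per sighting:
country, subnational unit, locality, coordinates, date, count or the
presence-only marker `X`), the pipeline applies, in order:

1. **Geographic scoping** — drop records outside the species' potential
   range polygon (e.g. European reports of captive birds);
2. **Deduplication** — keep one record per location per day. The location
   key is the eBird locality id, falling back to coordinates rounded to
   4 decimal places; within a group the record with the largest numeric
   count represents (presence-only ranks below any number; ties break on
   the smallest record id);
3. **Quantitative filtering** — drop presence-only (`X`) records.

Every input record lands in exactly one bucket — scoped-out, duplicate,
qualitative, or final — yielding the accounting columns
`Record, Duplicate, Record_clean, Record_qualitative, Record_final,
Number_of_individuals` per country, with region subtotals (North America,
Central America, South America, Caribbean) and sub-country splits for
Mexico (Yucatan Peninsula / Central) and the USA (Gulf of Mexico & Florida /
East and West Coast).

On the cleaned records it computes per-decade tallies (1960s–2010s, the
window ending 31 October 2018), two observer-effort proxies (distinct
*record days*, and cumulative individuals per record), classification of
each point against a recognized-distribution polygon, and the
**breeding-importance percentage**: for unit *i* over the nine April–August
breeding seasons of 2010–2018,

    pct_i = 100 · N_i / Σ_j N_j

where `N_i` is the unit's cumulative breeding-season individuals and the sum
runs over exactly the units with breeding-season data. The small, isolated,
confirmed-breeding Galapagos (Ecuador) population sets the reference: any
unit with `pct_i ≥ pct_Ecuador` is flagged a critical potential breeding
area (the threshold is inclusive, so the reference site flags itself).

A seeded synthetic generator emulates the structure such data actually has —
spatially fixed colonies with heavy-tailed (negative-binomial) flock sizes,
April–August abundance multipliers, decade-over-decade growth in checklist
effort, same-day same-location duplicate checklists, a fraction of `X`
counts, and a few out-of-range records — so every stage is testable without
downloading anything.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```
$ python analysis/01_simulate.py
wrote 1694 records (222 presence-only) to results/synthetic_records.tsv

$ python analysis/02_filter_records.py
extracted 1694; in scope 1676 (-18); after dedup 1325 (-351); final 1177
(-148 presence-only); 365850 cumulative individuals

$ python analysis/04_breeding_importance.py
reference (Ecuador) share: 0.5994%
6 critical potential breeding units: Bahamas, Bonaire, Cuba, Ecuador,
Mexico - Yucatan Peninsula, Venezuela

$ python analysis/05_range_classification.py
873 records inside the recognized range, 304 outside
({'USA': 158, 'Belize': 146}) — the outside records are the simulated
range-edge colonies
```

Reading the output: the 18 removed at scoping are the generator's simulated
out-of-range (European) reports; the accounting identities
`Record_clean = Record − Duplicate` and
`Record_final = Record_clean − Record_qualitative` hold at every level. The
six critical units are exactly the six colonies the generator configures
with real breeding aggregation, and the records falling outside the
recognized-range polygon are the two range-edge colonies (Florida, Belize)
placed outside it.

The same pipeline is exposed as a CLI:

```
flampipe simulate --seed 12 --out records.tsv
flampipe analyze --records records.tsv --out outdir/
flampipe check --out outdir/ --expected expected/
```

`analyze` writes `Table1.csv`, `S1_decades.csv`, `Table2.csv`,
`S2_yearly.csv`, `effort.csv`, `points.geojson` and a run manifest;
`check` compares produced tables to expected ones cell by cell and exits
nonzero with a diff report on any mismatch.

## Layout

- `src/flampipe/` — the library: `records` (TSV dialect and validation),
  `filters` (cleaning chain and accounting), `regions` (scheme, decades,
  effort, range classification), `breeding` (importance scoring),
  `synth` (generators), `refdata` (published reference tables),
  `reporting` (CSV shaping), `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and worked-example reproduction tests.
- `docs/methods.md` — model, parameters, numerical choices, limitations.
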