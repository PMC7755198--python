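# Methods

## The procedure

The pipeline operationalizes a citizen-science distribution assessment for
the American Flamingo. Its atomic unit is the *record*: one sighting by one
observer at one place on one day, carrying either a count of individuals or
a presence-only marker (`X`). Summing counts over records gives a
*cumulative number of individuals*; because flamingos move and observers
revisit sites, this cumulates repeat counts of the same birds and is an
index of observation volume, not a population estimate. All conclusions
drawn from it are comparative (between units, between decades), never
absolute abundance.

Cleaning runs in a fixed order:

1. **Scope**: records outside a potential-range polygon are removed first
   (escaped or captive birds reported far outside the range would otherwise
   contaminate every downstream table).
2. **Deduplicate**: one record per (location, day). Multiple checklists from
   one wetland on one morning are overwhelmingly the same birds.
3. **Quantitative filter**: presence-only records are removed, since every
   downstream statistic is a sum of counts.

The order matters and is part of the contract: a location-day group holding
both a numeric and an `X` record contributes nothing to the qualitative
count, because deduplication resolves the group to the numeric record first.
The accounting (`Record`, `Duplicate`, `Record_clean`, `Record_qualitative`,
`Record_final`, `Number_of_individuals`) partitions the input exactly; the
identities `clean = record − duplicate` and `final = clean − qualitative`
are enforced with a validator, and the test suite checks conservation on
random data.

### Deduplication details

The published procedure says only "one record for a given location on a
given day"; the concrete key and the choice of surviving record are this
package's decisions:

- **Location key**: the eBird locality identifier when present, else
  latitude/longitude rounded to 4 decimal places (~11 m). Localities are the
  natural sharing unit in eBird; the coordinate fallback handles personal
  locations.
- **Representative**: the record with the largest numeric count;
  presence-only ranks below any number; remaining ties break on the
  lexicographically smallest record id. Max-count keeps the most
  information, and the tie-break makes output deterministic.

No fuzzy spatial clustering of nearby localities is attempted, and no
observer-level deduplication.

## Regional scheme

Four regions — North America, Central America, South America, Caribbean —
with each country mapped to exactly one. Bonaire and Curaçao are filed under
South America (their colonies belong to the continental-coast system) while
Aruba stays Caribbean; the default scheme reproduces this convention
verbatim rather than a strict geographic rule. Two countries are split:

- Mexico → *Yucatan Peninsula* = {Yucatán, Campeche, Quintana Roo}, else
  *Central*;
- USA → *Gulf of Mexico/Florida* = {Florida, Alabama, Mississippi,
  Louisiana, Texas}, else *East and West Coast*.

The published source names these areas but not their memberships; the lists
above are this package's concretization and are editable in the YAML scheme
file. Sub-country resolution tries the subnational code first and a polygon
rule second; unknown countries route to an explicit `Unassigned` bucket and
are logged, never dropped.

Decades run 1960s–2010s with the window clipped to 1960-01-01..2018-10-31
(the extraction date); dates outside raise rather than silently binning.
Units or unit-decades with zero records are omitted from outputs (absence,
not zero).

## Breeding-importance parameter

A *breeding season of year Y* is April–August of calendar year Y; the
2010–2018 window therefore holds nine seasons. For each unit with at least
one breeding-season record in the window, the importance percentage is its
cumulative breeding-season individuals over the sum across exactly those
units. Excluding no-data units from the denominator avoids penalizing the
included ones for other countries' missing effort; its flip side — adding a
unit with data changes everyone's percentage — is inherent to a
share-of-total parameter.

The Galapagos (Ecuador) population — small, isolated, and a confirmed
breeder — sets the reference threshold. The comparison is inclusive (≥) so
the reference site classifies itself as critical. Per-year statistics: the
average is individuals divided by years-with-data; the SD is the sample
(n−1) standard deviation of the yearly totals, reported only for three or
more years; min/max need two. Rounding is half-up and applied only at
presentation (percentages to 4 decimals, averages and SDs to 1), never
inside arithmetic.

When the reference tables' per-country breeding totals are used as inputs,
the denominator is defined as the sum of that column (528,764 over
2010–2018). This reproduces the reference percentage (0.6827) exactly;
one or two printed percentages elsewhere in the table differ from the
recomputation in the 3rd–4th decimal (e.g. Venezuela 46.0260 recomputed vs
46.0269 printed), implying the original denominator differed by a handful
of individuals from its own printed column. The package reproduces column
sums, and likewise recomputes region totals from country rows where a
printed grand total disagrees with the sum of its parts by a few
individuals.

## Synthetic data

The generator emulates the structural features the analysis assumes, not
flamingo biology:

- **Colonies**: fixed sites with country/subnational/coordinates. Counts per
  checklist are `1 + NegativeBinomial(mean − 1, dispersion)` — flock sizes
  are heavy-tailed (real records reach thousands of birds), and the shift
  keeps every count ≥ 1 as the record grammar requires. During April–August
  the mean is multiplied by the colony's `breeding_multiplier`.
- **Effort**: expected checklists per colony per decade, Poisson-sampled,
  with the default rising from 1 (1960s) to 120 (2010s) to emulate the
  citizen-science reporting surge. Base checklists within a colony get
  distinct dates, so every same-location same-day collision is an
  intentional duplicate.
- **Duplicates**: with probability `duplicate_prob` a checklist is
  accompanied by a same-place same-day second checklist of strictly lower
  rank (a smaller count, or `X`), so the representative rule keeps the base
  record and configured counts survive deduplication unchanged.
- **Presence-only**: each base checklist reports `X` with probability
  `presence_only_prob`.
- **Out-of-range records**: `out_of_scope_count` records placed in Europe.

The default configuration places eight colonies across all four regions —
including a small isolated Galapagos-like colony, a large heavy-tailed
Venezuelan colony configured at ~46% of the expected breeding-season
individuals, and two range-edge colonies (Florida, Belize) lying outside
the default recognized-range polygon — with `duplicate_prob` 0.25,
`presence_only_prob` 0.12, and 18 out-of-range records. All randomness
flows from a single seeded NumPy generator; identical config and seed give
byte-identical TSV output.

What the generator does **not** emulate: movement of individual birds
between sites (so repeat-counting structure is cruder than reality),
observer heterogeneity beyond the effort curve, spatial scatter within a
colony, or misidentification. Passing tests therefore demonstrate that the
*bookkeeping* — filtering, accounting, aggregation, scoring — is correct
under realistic structure; they do not validate ecological conclusions
drawn from any particular real extract.

The exact-accounting mode (`generate_matching_accounting`) manufactures a
dataset whose filter-chain accounting equals prescribed per-country targets:
`n_final` numeric records on distinct location-day keys summing to the
target individuals, `n_qualitative` presence-only records on further keys,
and `n_duplicate` presence-only records colliding with existing keys.
Duplicates are emitted as `X` rather than as smaller numeric counts because
a prescribed-total construction legitimately produces representatives with
count 1, below which no numeric count exists; `X` ranks below any number
under the representative rule, so group representatives are unchanged — the
same stability guarantee, feasible for every published row. The filter
pipeline and this construction are mutual oracles: each validates the other
in the test suite.

## Numerical and design choices

- Counts are exact integers throughout; no floating point enters the
  accounting. Percentages and averages are floats, rounded half-up only for
  presentation.
- Point-in-polygon tests (scoping, range classification) count boundary
  points as inside, via prepared-geometry `intersects`.
- The default scope polygon is a generous Americas box; the default
  recognized-range polygon is a coarse synthetic multipolygon (Caribbean
  basin, Yucatan, northern South America coast, Galapagos) authored for
  this package because no published shapefile ships with the assessment.
  Both are plain GeoJSON and fully overridable.
- Malformed TSV rows are skipped with a line-numbered report rather than
  aborting; a missing mapped column is fatal.
- `record_days` is computed on post-filter records, alongside the analyses
  it contextualizes; computing it pre-dedup would mechanically track
  checklist volume instead.
- Statistical generator tests run at sizes where sampling error is small
  relative to the asserted band: the breeding-share recovery test saturates
  a decade's days so the checklist count is deterministic and the
  delta-method standard error of the share is ~0.35 percentage points,
  against an asserted band of ±1.5.
- Problem sizes: the worked-example reproduction manufactures 16,948
  records and the synthetic study ~1,700; both the full test suite and the
  reproduction script complete in seconds on one CPU.

## Known limitations

- Cumulative individuals recount birds; the pipeline inherits this by
  design and no correction is attempted.
- The breeding parameter is an observation-share, confounded with effort
  where effort varies across countries within a season; the effort indices
  are descriptive companions, not a correction.
- Critical-country classification depends on the reference site's own
  observation share; a reference with anomalous effort would shift the
  threshold.
- Deduplication by locality-day cannot merge records from distinct nearby
  localities covering one flock.
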