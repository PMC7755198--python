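"""Record cleaning: geographic scoping, deduplication, quantitative filtering.

The chain runs in a fixed order — scope, then one-record-per-location-per-day
deduplication, then removal of presence-only records — and traces every input
record into exactly one of four buckets: scoped-out, duplicate, qualitative,
or final. The resulting :class:`FilterAccounting` mirrors the column set of a
published country-level summary (Record, Duplicate, Record_clean,
Record_qualitative, Record_final, Number of individuals).

Deduplication keys records by eBird locality when present, falling back to
coordinates rounded to four decimal places (~11 m at the equator). Within a
duplicate group the representative is the record with the largest numeric
count — presence-only ranks below any number — with ties broken by smallest
record identifier, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .records import PRESENCE_ONLY, OccurrenceRecord

#: Decimal places used for the coordinate fallback of the deduplication key.
COORD_PRECISION = 4


class ConfigurationError(ValueError):
    """Invalid analysis configuration (degenerate polygon, bad scheme, ...)."""


@dataclass(frozen=True)
class FilterAccounting:
    """Counts tracing records through the filter chain.

    Invariants: ``n_clean == n_record - n_duplicate`` and
    ``n_final == n_clean - n_qualitative``; ``cum_individuals >= n_final``
    because every final record carries a count of at least one bird.
    ``n_scoped_out`` records fell outside the scope polygon before the chain
    proper and are not part of ``n_record``.
    """

    n_record: int
    n_duplicate: int
    n_qualitative: int
    cum_individuals: int
    n_scoped_out: int = 0

    @property
    def n_clean(self) -> int:
        return self.n_record - self.n_duplicate

    @property
    def n_final(self) -> int:
        return self.n_clean - self.n_qualitative

    def validate(self) -> None:
        if self.n_duplicate < 0 or self.n_qualitative < 0 or self.n_record < 0:
            raise ValueError("negative accounting field")
        if self.n_final < 0:
            raise ValueError("more removals than records")
        if self.n_final > 0 and self.cum_individuals < self.n_final:
            raise ValueError("cumulative individuals below final record count")
        if self.n_final == 0 and self.cum_individuals != 0:
            raise ValueError("individuals reported with no final records")


def location_key(record: OccurrenceRecord) -> tuple:
    """Deduplication location key: locality id, else rounded coordinates."""
    if record.locality_id:
        return ("loc", record.locality_id)
    return ("coord", round(record.latitude, COORD_PRECISION), round(record.longitude, COORD_PRECISION))


def _check_polygon(polygon: BaseGeometry) -> None:
    if polygon is None or polygon.is_empty or not polygon.is_valid:
        raise ConfigurationError("scope/range polygon is empty or invalid")
    if polygon.area == 0:
        raise ConfigurationError("scope/range polygon is degenerate")


def scope_filter(
    records: Sequence[OccurrenceRecord],
    scope_polygon: BaseGeometry,
) -> tuple[list[OccurrenceRecord], int]:
    """Keep records whose point lies inside or on the scope polygon.

    Returns the kept records (input order preserved) and the number removed.
    """
    _check_polygon(scope_polygon)
    prepared = prep(scope_polygon)
    kept = [r for r in records if prepared.intersects(Point(r.longitude, r.latitude))]
    return kept, len(records) - len(kept)


def _representative_rank(record: OccurrenceRecord) -> tuple:
    # Largest numeric count wins; presence-only below any number; then the
    # lexicographically smallest record_id. min() over this tuple picks it.
    if record.count is PRESENCE_ONLY:
        return (1, 0, record.record_id)
    return (0, -record.count, record.record_id)


def deduplicate(
    records: Sequence[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Keep one record per (location key, date); return (kept, removed).

    Idempotent: a second pass over the kept records removes nothing.
    """
    groups: dict[tuple, list[OccurrenceRecord]] = {}
    for rec in records:
        groups.setdefault((location_key(rec), rec.date), []).append(rec)
    kept: list[OccurrenceRecord] = []
    removed: list[OccurrenceRecord] = []
    kept_ids: set[str] = set()
    for group in groups.values():
        winner = min(group, key=_representative_rank)
        kept_ids.add(winner.record_id)
    for rec in records:  # preserve input order in both outputs
        (kept if rec.record_id in kept_ids else removed).append(rec)
    return kept, removed


def quantitative_filter(
    records: Sequence[OccurrenceRecord],
) -> tuple[list[OccurrenceRecord], int]:
    """Drop presence-only records; return (kept, number removed)."""
    kept = [r for r in records if r.is_quantitative]
    return kept, len(records) - len(kept)


def run_filters(
    records: Sequence[OccurrenceRecord],
    scope_polygon: Optional[BaseGeometry] = None,
) -> tuple[list[OccurrenceRecord], FilterAccounting]:
    """Run scope -> deduplicate -> quantitative and account for every record.

    With ``scope_polygon=None`` the scoping stage is skipped (all records are
    treated as in scope).
    """
    if scope_polygon is not None:
        scoped, n_scoped_out = scope_filter(records, scope_polygon)
    else:
        scoped, n_scoped_out = list(records), 0
    clean, removed = deduplicate(scoped)
    final, n_qual = quantitative_filter(clean)
    acct = FilterAccounting(
        n_record=len(scoped),
        n_duplicate=len(removed),
        n_qualitative=n_qual,
        cum_individuals=sum(r.count for r in final),
        n_scoped_out=n_scoped_out,
    )
    acct.validate()
    return final, acct


def accounting_by_unit(
    records: Sequence[OccurrenceRecord],
    unit_of,
    scope_polygon: Optional[BaseGeometry] = None,
) -> dict[str, FilterAccounting]:
    """Per-unit accounting, where ``unit_of(record)`` names the grouping unit.

    Filtering is global (a duplicate group never spans units in practice
    because the location key pins the country), then counts are attributed to
    each record's unit.
    """
    if scope_polygon is not None:
        scoped, _ = scope_filter(records, scope_polygon)
    else:
        scoped = list(records)
    units = sorted({unit_of(r) for r in scoped})
    out: dict[str, FilterAccounting] = {}
    for unit in units:
        subset = [r for r in scoped if unit_of(r) == unit]
        _, acct = run_filters(subset, None)
        out[unit] = acct
    return out
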