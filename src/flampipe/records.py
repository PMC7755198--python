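"""Occurrence records and their tab-separated on-disk dialect.

A *record* is one sighting of the focal species: a checklist identifier, a
place (country, subnational unit, locality, WGS84 coordinates), a calendar
date, and either a count of individuals or the presence-only marker that
citizen-science checklists write as ``X``.

Files are UTF-8 TSV with a header row. Column names are configurable through
a :class:`Dialect`; the default matches the eBird Basic Dataset headers so
that real extracts parse without configuration, while tests and the
synthetic generator use the same dialect.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union


class _PresenceOnly:
    """Singleton sentinel for a presence-only ('X') count."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "PRESENCE_ONLY"


#: Distinguished count value for records that report presence without a number.
PRESENCE_ONLY = _PresenceOnly()

Count = Union[int, _PresenceOnly]


class RecordValidationError(ValueError):
    """A field value violates the record grammar (bad count, date, coordinate)."""


class FormatError(ValueError):
    """The file itself is unusable (e.g. a mapped column is missing)."""


def parse_count(token: str) -> Count:
    """Parse a count token: ``'X'`` (any case) or a positive decimal integer.

    A sighting of zero birds is not a record, so ``'0'``, negatives and
    anything non-numeric other than ``X`` raise :class:`RecordValidationError`.
    """
    tok = token.strip()
    if not tok:
        raise RecordValidationError("empty count token")
    if tok.upper() == "X":
        return PRESENCE_ONLY
    try:
        value = int(tok)
    except ValueError:
        raise RecordValidationError(f"count {token!r} is neither 'X' nor an integer") from None
    if value < 1:
        raise RecordValidationError(f"count must be >= 1, got {value}")
    return value


def format_count(count: Count) -> str:
    """Inverse of :func:`parse_count`."""
    if count is PRESENCE_ONLY:
        return "X"
    return str(int(count))


def _parse_date(token: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(token.strip())
    except ValueError:
        raise RecordValidationError(f"unparseable date {token!r} (expected YYYY-MM-DD)") from None


@dataclass(frozen=True)
class OccurrenceRecord:
    """One sighting: where, when, how many (or presence-only), by which checklist."""

    record_id: str
    country: str
    subnational: str
    locality_id: str
    latitude: float
    longitude: float
    date: _dt.date
    count: Count

    def __post_init__(self) -> None:
        if not self.record_id:
            raise RecordValidationError("record_id must be non-empty")
        if not -90.0 <= self.latitude <= 90.0:
            raise RecordValidationError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise RecordValidationError(f"longitude {self.longitude} outside [-180, 180]")
        if self.count is not PRESENCE_ONLY:
            if not isinstance(self.count, int) or self.count < 1:
                raise RecordValidationError(f"count must be PRESENCE_ONLY or an int >= 1, got {self.count!r}")

    @property
    def is_quantitative(self) -> bool:
        return self.count is not PRESENCE_ONLY

    def with_count(self, count: Count) -> "OccurrenceRecord":
        return replace(self, count=count)


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping between record fields and TSV headers.

    Defaults follow the eBird Basic Dataset export headers.
    """

    record_id: str = "SAMPLING EVENT IDENTIFIER"
    country: str = "COUNTRY"
    subnational: str = "STATE/PROVINCE"
    locality_id: str = "LOCALITY ID"
    latitude: str = "LATITUDE"
    longitude: str = "LONGITUDE"
    date: str = "OBSERVATION DATE"
    count: str = "OBSERVATION COUNT"

    @property
    def columns(self) -> list[str]:
        return [
            self.record_id,
            self.country,
            self.subnational,
            self.locality_id,
            self.latitude,
            self.longitude,
            self.date,
            self.count,
        ]


DEFAULT_DIALECT = Dialect()


@dataclass
class ReadReport:
    """Per-row validation outcomes collected while reading a file.

    ``errors`` holds ``(line_number, reason)`` pairs for skipped rows; line
    numbers are 1-based and count the header as line 1, matching what a user
    sees in an editor.
    """

    n_read: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.errors)

    def lines(self) -> list[str]:
        return [f"{lineno}: {reason}" for lineno, reason in self.errors]


def read_records(
    path: Union[str, Path],
    dialect: Dialect = DEFAULT_DIALECT,
) -> tuple[list[OccurrenceRecord], ReadReport]:
    """Read occurrence records from a TSV file.

    Rows failing validation (bad count, date, or coordinate; duplicated
    record identifier) are skipped and reported with their line number —
    citizen-science extracts are dirty and the cleaning philosophy is to
    discard, not repair. A missing mapped column is fatal.
    """
    path = Path(path)
    report = ReadReport()
    records: list[OccurrenceRecord] = []
    seen_ids: set[str] = set()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in dialect.columns if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mapped column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = _row_to_record(row, dialect)
                if rec.record_id in seen_ids:
                    raise RecordValidationError(f"duplicate record_id {rec.record_id!r}")
            except RecordValidationError as err:
                report.errors.append((lineno, str(err)))
                continue
            seen_ids.add(rec.record_id)
            records.append(rec)
            report.n_read += 1
    return records, report


def _row_to_record(row: dict, dialect: Dialect) -> OccurrenceRecord:
    try:
        lat = float(row[dialect.latitude])
        lon = float(row[dialect.longitude])
    except (TypeError, ValueError):
        raise RecordValidationError(
            f"unparseable coordinate ({row.get(dialect.latitude)!r}, {row.get(dialect.longitude)!r})"
        ) from None
    return OccurrenceRecord(
        record_id=(row[dialect.record_id] or "").strip(),
        country=(row[dialect.country] or "").strip(),
        subnational=(row[dialect.subnational] or "").strip(),
        locality_id=(row[dialect.locality_id] or "").strip(),
        latitude=lat,
        longitude=lon,
        date=_parse_date(row[dialect.date] or ""),
        count=parse_count(row[dialect.count] or ""),
    )


def write_records(
    records: Iterable[OccurrenceRecord],
    path: Union[str, Path],
    dialect: Dialect = DEFAULT_DIALECT,
) -> None:
    """Write records as TSV in the given dialect; round-trips with :func:`read_records`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(dialect.columns)
        for rec in records:
            writer.writerow(
                [
                    rec.record_id,
                    rec.country,
                    rec.subnational,
                    rec.locality_id,
                    repr(rec.latitude),
                    repr(rec.longitude),
                    rec.date.isoformat(),
                    format_count(rec.count),
                ]
            )
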