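import datetime as dt
import itertools

import pytest

from flampipe.records import PRESENCE_ONLY, OccurrenceRecord

_serial = itertools.count(1)


@pytest.fixture
def make_record():
    """Factory for valid records with sensible defaults and unique ids."""

    def _make(
        record_id=None,
        country="Mexico",
        subnational="Yucatán",
        locality_id="L1",
        latitude=21.5,
        longitude=-88.0,
        date=dt.date(2015, 5, 10),
        count=5,
    ):
        if record_id is None:
            record_id = f"T{next(_serial):06d}"
        return OccurrenceRecord(
            record_id=record_id,
            country=country,
            subnational=subnational,
            locality_id=locality_id,
            latitude=latitude,
            longitude=longitude,
            date=date,
            count=count,
        )

    return _make


@pytest.fixture
def presence_only():
    return PRESENCE_ONLY
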