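"""Synthetic eBird-like occurrence data.

Two generators serve different purposes:

:func:`generate`
    Samples a realistic dataset from a colony/effort model: spatially fixed
    colonies with overdispersed (negative-binomial) flock sizes — flamingo
    counts are heavy-tailed, with single records of thousands of birds —
    a breeding-season (April–August) abundance multiplier, decade-by-decade
    growth in checklist effort emulating the 2010s surge of citizen-science
    reporting, same-day same-location duplicate checklists, a fraction of
    presence-only ('X') counts, and a handful of out-of-range records such
    as escaped captive birds reported in Europe.

:func:`generate_matching_accounting`
    Manufactures a dataset that the filter chain reduces to an exactly
    prescribed accounting (records, duplicates, qualitative removals, final
    records, cumulative individuals) per unit — the filter pipeline and this
    construction are mutual oracles. Duplicates are emitted as presence-only
    records colliding with existing location/date keys: 'X' ranks below any
    numeric count under the representative rule, so group representatives
    are unchanged no matter how small the prescribed counts are.

All randomness flows from one seeded NumPy generator; identical config and
seed give byte-identical output.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .filters import ConfigurationError, FilterAccounting
from .records import PRESENCE_ONLY, OccurrenceRecord

DECADES = ("1960s", "1970s", "1980s", "1990s", "2000s", "2010s")


@dataclass(frozen=True)
class Colony:
    """One breeding/foraging site emitting checklists."""

    name: str
    country: str
    subnational: str
    latitude: float
    longitude: float
    mean_count: float  # mean flock size per checklist, >= 1
    dispersion: float  # negative-binomial shape; smaller = heavier tail
    breeding_multiplier: float = 1.0  # April-August abundance factor, >= 1


@dataclass
class SyntheticConfig:
    colonies: list[Colony]
    effort: dict[str, float]  # decade label -> expected checklists per colony
    duplicate_prob: float = 0.0
    presence_only_prob: float = 0.0
    out_of_scope_count: int = 0
    date_window: tuple[_dt.date, _dt.date] = (_dt.date(1960, 1, 1), _dt.date(2018, 10, 31))
    seed: int = 0

    def validate(self) -> None:
        for p, name in ((self.duplicate_prob, "duplicate_prob"), (self.presence_only_prob, "presence_only_prob")):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        for colony in self.colonies:
            if colony.mean_count < 1:
                raise ConfigurationError(f"colony {colony.name}: mean_count must be >= 1")
            if colony.dispersion <= 0:
                raise ConfigurationError(f"colony {colony.name}: dispersion must be > 0")
            if colony.breeding_multiplier < 1:
                raise ConfigurationError(f"colony {colony.name}: breeding_multiplier must be >= 1")
        if self.out_of_scope_count < 0:
            raise ConfigurationError("out_of_scope_count must be >= 0")
        if self.date_window[0] > self.date_window[1]:
            raise ConfigurationError("empty date window")


def default_config(seed: int = 0) -> SyntheticConfig:
    """Colonies across all four regions with decade-increasing effort.

    Includes a small isolated Galapagos-like colony and a large heavy-tailed
    Venezuelan colony configured at roughly 46% of the total expected
    breeding-season individuals; nonzero duplication and presence-only rates.
    """
    colonies = [
        Colony("Quinta Playa", "Ecuador", "Galápagos", -0.96, -90.97, 15.0, 2.0, 1.5),
        Colony("Los Olivitos", "Venezuela", "Zulia", 10.9, -71.3, 830.0, 0.8, 2.0),
        Colony("Ria Lagartos", "Mexico", "Yucatán", 21.55, -88.16, 450.0, 1.0, 2.0),
        Colony("Rio Maximo", "Cuba", "Camagüey", 21.6, -77.3, 350.0, 1.0, 1.8),
        Colony("Great Inagua", "Bahamas", "Inagua", 21.08, -73.3, 120.0, 1.0, 1.8),
        Colony("Goto Meer", "Bonaire", "", 12.22, -68.28, 100.0, 1.2, 1.6),
        Colony("Florida Bay", "USA", "Florida", 25.15, -80.9, 8.0, 1.5, 1.0),
        Colony("Belize Coast", "Belize", "Belize", 17.5, -88.2, 2.0, 1.0, 1.0),
    ]
    effort = {"1960s": 1, "1970s": 2, "1980s": 5, "1990s": 10, "2000s": 25, "2010s": 120}
    return SyntheticConfig(
        colonies=colonies,
        effort=dict(effort),
        duplicate_prob=0.25,
        presence_only_prob=0.12,
        out_of_scope_count=18,
        seed=seed,
    )


def expected_breeding_share(config: SyntheticConfig, country: str) -> float:
    """Configured expectation of a country's share of breeding individuals.

    With identical per-colony effort, checklist numbers cancel and the share
    reduces to mean_count x breeding_multiplier weights.
    """
    weights = {c.name: c.mean_count * c.breeding_multiplier for c in config.colonies}
    total = sum(weights.values())
    mine = sum(w for c, w in zip(config.colonies, weights.values()) if c.country == country)
    return mine / total


def _decade_days(decade: str, window: tuple[_dt.date, _dt.date]) -> list[_dt.date]:
    start_year = int(decade[:4])
    d0 = max(_dt.date(start_year, 1, 1), window[0])
    d1 = min(_dt.date(start_year + 9, 12, 31), window[1])
    if d0 > d1:
        return []
    return [d0 + _dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]


def _sample_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # 1 + NB keeps counts >= 1 while targeting the configured mean.
    shifted = max(mean - 1.0, 0.0)
    if shifted == 0.0:
        return 1
    p = dispersion / (dispersion + shifted)
    return 1 + int(rng.negative_binomial(dispersion, p))


def generate(config: SyntheticConfig) -> list[OccurrenceRecord]:
    """Sample a dataset from the colony/effort model (see module docstring).

    Within a colony, base checklists get distinct dates (sampled without
    replacement per decade) so that every same-key-same-day collision is an
    intentional duplicate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[OccurrenceRecord] = []
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"S{serial:07d}"

    for ci, colony in enumerate(config.colonies):
        locality = f"L{ci:03d}-{colony.name.replace(' ', '_')}"
        for decade in DECADES:
            expected = config.effort.get(decade, 0.0)
            days = _decade_days(decade, config.date_window)
            if expected <= 0 or not days:
                continue
            n = int(rng.poisson(expected))
            n = min(n, len(days))
            day_idx = rng.choice(len(days), size=n, replace=False)
            for di in np.sort(day_idx):
                date = days[int(di)]
                mean = colony.mean_count
                if date.month in {4, 5, 6, 7, 8}:
                    mean *= colony.breeding_multiplier
                count = _sample_count(rng, mean, colony.dispersion)
                base_count = count if rng.random() >= config.presence_only_prob else PRESENCE_ONLY
                records.append(
                    OccurrenceRecord(
                        record_id=next_id(),
                        country=colony.country,
                        subnational=colony.subnational,
                        locality_id=locality,
                        latitude=colony.latitude,
                        longitude=colony.longitude,
                        date=date,
                        count=base_count,
                    )
                )
                if rng.random() < config.duplicate_prob:
                    # Same location and day, strictly lower rank than the base
                    # so the representative rule keeps the base record.
                    if base_count is PRESENCE_ONLY or base_count == 1:
                        dup_count = PRESENCE_ONLY
                    else:
                        dup_count = int(rng.integers(1, base_count))
                    records.append(
                        OccurrenceRecord(
                            record_id=next_id(),
                            country=colony.country,
                            subnational=colony.subnational,
                            locality_id=locality,
                            latitude=colony.latitude,
                            longitude=colony.longitude,
                            date=date,
                            count=dup_count,
                        )
                    )

    # Out-of-range reports (e.g. captive birds in Europe), removed by scoping.
    for i in range(config.out_of_scope_count):
        records.append(
            OccurrenceRecord(
                record_id=next_id(),
                country="Spain",
                subnational="",
                locality_id=f"LEU-{i:03d}",
                latitude=40.4 + 0.01 * i,
                longitude=3.7,
                date=_dt.date(2015, 6, 1) + _dt.timedelta(days=i),
                count=1,
            )
        )
    return records


def generate_matching_accounting(
    targets: Mapping[str, FilterAccounting],
    seed: int = 0,
    subnational: Optional[Mapping[str, str]] = None,
    out_of_scope_count: int = 0,
) -> list[OccurrenceRecord]:
    """Manufacture records whose filter-chain accounting equals ``targets``.

    ``targets`` maps a country name to its prescribed accounting. Per country
    the construction lays down ``n_final`` numeric records on distinct
    location/date keys whose counts sum to ``cum_individuals``, then
    ``n_qualitative`` presence-only records on further distinct keys, then
    ``n_duplicate`` presence-only records colliding round-robin with the
    existing keys. ``seed`` only perturbs coordinates; the accounting is
    deterministic by construction.
    """
    rng = np.random.default_rng(seed)
    records: list[OccurrenceRecord] = []
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"R{serial:07d}"

    base_date = _dt.date(2014, 1, 15)
    for country in sorted(targets):
        acct = targets[country]
        try:
            acct.validate()
        except ValueError as err:
            raise ConfigurationError(f"infeasible targets for {country}: {err}") from None
        if acct.n_clean == 0 and acct.n_duplicate > 0:
            raise ConfigurationError(f"infeasible targets for {country}: duplicates need a surviving key")
        sub = (subnational or {}).get(country, "")
        lat = float(rng.uniform(5, 25))
        lon = float(rng.uniform(-95, -60))
        keys: list[tuple[str, _dt.date]] = []

        counts: list[int] = []
        if acct.n_final > 0:
            counts = [1] * acct.n_final
            counts[0] = acct.cum_individuals - (acct.n_final - 1)
        for i, count in enumerate(counts):
            loc = f"L-{country}-{i:06d}"
            keys.append((loc, base_date))
            records.append(
                OccurrenceRecord(next_id(), country, sub, loc, lat, lon, base_date, count)
            )
        for i in range(acct.n_qualitative):
            loc = f"L-{country}-q{i:06d}"
            keys.append((loc, base_date))
            records.append(
                OccurrenceRecord(next_id(), country, sub, loc, lat, lon, base_date, PRESENCE_ONLY)
            )
        for i in range(acct.n_duplicate):
            loc, date = keys[i % len(keys)]
            records.append(
                OccurrenceRecord(next_id(), country, sub, loc, lat, lon, date, PRESENCE_ONLY)
            )

    for i in range(out_of_scope_count):
        records.append(
            OccurrenceRecord(
                next_id(), "Spain", "", f"LEU-{i:03d}", 40.4, 3.7,
                base_date + _dt.timedelta(days=i), 1,
            )
        )
    return records


# ---------------------------------------------------------------------------
# YAML config plumbing
# ---------------------------------------------------------------------------

def config_from_yaml(path: Union[str, Path]) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML file.

    Schema::

        seed: 42
        duplicate_prob: 0.25
        presence_only_prob: 0.12
        out_of_scope_count: 18
        date_window: [1960-01-01, 2018-10-31]   # optional
        effort: {1960s: 1, ..., 2010s: 120}
        colonies:
          - {name: ..., country: ..., subnational: "", latitude: ..,
             longitude: .., mean_count: .., dispersion: .., breeding_multiplier: ..}
    """
    import yaml

    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    colonies = [Colony(**c) for c in cfg["colonies"]]
    window = cfg.get("date_window")
    if window:
        window = tuple(
            d if isinstance(d, _dt.date) else _dt.date.fromisoformat(str(d)) for d in window
        )
    else:
        window = (_dt.date(1960, 1, 1), _dt.date(2018, 10, 31))
    out = SyntheticConfig(
        colonies=colonies,
        effort={str(k): float(v) for k, v in cfg["effort"].items()},
        duplicate_prob=float(cfg.get("duplicate_prob", 0.0)),
        presence_only_prob=float(cfg.get("presence_only_prob", 0.0)),
        out_of_scope_count=int(cfg.get("out_of_scope_count", 0)),
        date_window=window,
        seed=int(cfg.get("seed", 0)),
    )
    out.validate()
    return out


def config_to_yaml(config: SyntheticConfig, path: Union[str, Path]) -> None:
    import dataclasses

    import yaml

    payload = {
        "seed": config.seed,
        "duplicate_prob": config.duplicate_prob,
        "presence_only_prob": config.presence_only_prob,
        "out_of_scope_count": config.out_of_scope_count,
        "date_window": [d.isoformat() for d in config.date_window],
        "effort": config.effort,
        "colonies": [dataclasses.asdict(c) for c in config.colonies],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)
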