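"""Breeding phenology: assign instants to phenological periods.

The breeding season of each pair-year is split into four ordered periods
anchored on the nest record: establishment (arrival at the colony up to the
start of courtship), courtship (exactly the 21 days before laying of the
first egg), incubation (laying to hatching of the first egg) and nestling
(hatching of the first egg to fledging of the last chick).  Intervals are
start-inclusive / end-exclusive, except that fledging day itself still
belongs to the nestling period.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

COURTSHIP_DAYS = 21


class Period(enum.IntEnum):
    """Ordered breeding-season stages."""

    establishment = 0
    courtship = 1
    incubation = 2
    nestling = 3

    def __str__(self) -> str:  # plain labels in tables
        return self.name


@dataclass
class BreedingRecord:
    """Phenology anchors for one pair-year.

    ``brood_size_by_date`` maps dates to chick counts (long-format CSV input);
    missing dates fall back to the most recent earlier entry.
    """

    pair_id: str
    arrival_date: pd.Timestamp
    laying_date: pd.Timestamp
    hatching_date: pd.Timestamp
    fledging_date: pd.Timestamp
    brood_size_by_date: dict = field(default_factory=dict)

    def __post_init__(self):
        self.arrival_date = pd.Timestamp(self.arrival_date)
        self.laying_date = pd.Timestamp(self.laying_date)
        self.hatching_date = pd.Timestamp(self.hatching_date)
        self.fledging_date = pd.Timestamp(self.fledging_date)
        courtship_start = self.laying_date - pd.Timedelta(days=COURTSHIP_DAYS)
        if not (
            self.arrival_date <= courtship_start
            < self.laying_date
            < self.hatching_date
            < self.fledging_date
        ):
            raise ValueError(
                "breeding record must satisfy "
                "arrival <= laying - 21 d < laying < hatching < fledging"
            )
        if any(v < 0 for v in self.brood_size_by_date.values()):
            raise ValueError("brood sizes must be non-negative")

    @property
    def courtship_start(self) -> pd.Timestamp:
        return self.laying_date - pd.Timedelta(days=COURTSHIP_DAYS)

    def brood_size(self, date) -> int | None:
        """Brood size on a date: most recent recorded count at or before it."""
        date = pd.Timestamp(date).normalize()
        known = sorted(pd.Timestamp(d).normalize() for d in self.brood_size_by_date)
        prior = [d for d in known if d <= date]
        if not prior:
            return None
        return int(self.brood_size_by_date[max(prior)])


def assign_period(instant, record: BreedingRecord) -> Period:
    """Phenological period of an instant within one pair-year.

    Courtship starts at laying - 21 days (inclusive); incubation at laying;
    nestling at hatching.  Instants outside [arrival, fledging] raise
    ``ValueError`` — the caller must drop them.
    """
    t = pd.Timestamp(instant)
    if t.tzinfo is not None:
        t = t.tz_localize(None)
    day = t.normalize()
    end = record.fledging_date + pd.Timedelta(days=1)  # fledging day is nestling
    if not (record.arrival_date <= day < end):
        raise ValueError(f"{instant} outside breeding window of pair {record.pair_id}")
    if day < record.courtship_start:
        return Period.establishment
    if day < record.laying_date:
        return Period.courtship
    if day < record.hatching_date:
        return Period.incubation
    return Period.nestling


def eldest_chick_age(date, record: BreedingRecord) -> int:
    """Age of the eldest chick in whole days; hatch day is age 0."""
    day = pd.Timestamp(date).normalize()
    if day < record.hatching_date:
        raise ValueError("date precedes hatching: no chicks yet")
    return int((day - record.hatching_date).days)


def read_breeding_records(path, brood_path=None) -> dict[str, BreedingRecord]:
    """Breeding-record CSV ``pair_id,arrival,laying,hatching,fledging`` plus an
    optional long-format brood table ``pair_id,date,brood_size``."""
    df = pd.read_csv(path)
    broods: dict[str, dict] = {}
    if brood_path is not None:
        b = pd.read_csv(brood_path)
        for _, r in b.iterrows():
            broods.setdefault(str(r["pair_id"]), {})[pd.Timestamp(r["date"])] = int(
                r["brood_size"]
            )
    out = {}
    for _, r in df.iterrows():
        pid = str(r["pair_id"])
        out[pid] = BreedingRecord(
            pair_id=pid,
            arrival_date=r["arrival"],
            laying_date=r["laying"],
            hatching_date=r["hatching"],
            fledging_date=r["fledging"],
            brood_size_by_date=broods.get(pid, {}),
        )
    return out
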