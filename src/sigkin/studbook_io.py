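"""Studbook parsing, cleaning and monthly residency reconstruction.

Zoological studbooks record one row per animal (identity, sex, parentage,
birth/death dates, natal institution) plus a longitudinal table of transfer
events between institutions.  This module turns a CSV pair of that shape into
a cleaned, month-resolution data model:

* dates are converted to integer month indices relative to a configurable
  epoch, rounding day-resolved dates to the nearest month;
* rows or events with uncertain dates (``"1988"``, ``"~Mar 1988"``) are
  excluded and the exclusion is counted, never silently dropped;
* non-zoo institutions (suppliers, private owners, unlisted addresses) are
  recoded to the ``WILD`` sentinel, arrivals from ``WILD`` become immigrant
  founders with no recorded parents, and animals released to ``WILD`` or lost
  to follow-up are excluded from analysis;
* a piecewise-constant residency table (institution per animal per month) is
  derived from natal institution plus transfer events, with the transfer
  month credited to the destination.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

log = logging.getLogger(__name__)

WILD = "WILD"

FEMALE = "F"
MALE = "M"
UNKNOWN = "U"

#: canonical record CSV header
RECORD_FIELDS = [
    "id", "sex", "dam", "sire", "birth_date", "death_date",
    "birth_institution", "origin", "disposition",
]
#: canonical transfer CSV header
TRANSFER_FIELDS = ["id", "date", "from", "to"]

_MONTHS = {m.lower(): i + 1 for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"])}

_ISO_FULL = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")
_ISO_MONTH = re.compile(r"^(\d{4})-(\d{2})$")
_MON_YEAR = re.compile(r"^([A-Za-z]{3})\s+(\d{4})$")


class UncertainDate(ValueError):
    """Raised for a date recorded below month resolution or flagged uncertain."""


@dataclass
class IOConfig:
    """Dialect and cleaning configuration.

    epoch: (year, month) that maps to month index 0.
    nonzoo_institutions: institution names recoded to WILD during cleaning
        (animal suppliers, private owners, institutions with no address).
    drop_lost_to_followup / drop_released: exclusion toggles.
    """

    epoch: tuple[int, int] = (1970, 1)
    nonzoo_institutions: frozenset[str] = frozenset()
    drop_lost_to_followup: bool = True
    drop_released: bool = True


@dataclass
class StudbookRecord:
    individual_id: str
    sex: str = UNKNOWN                      # F / M / U
    dam_id: Optional[str] = None
    sire_id: Optional[str] = None
    birth_month: Optional[int] = None
    death_month: Optional[int] = None
    birth_institution: str = WILD
    origin: str = "zoo_bred"                # zoo_bred / immigrant
    disposition: str = "alive"              # alive / dead / lost_to_followup / released

    def alive_at(self, month: int, data_end: Optional[int] = None) -> bool:
        if self.birth_month is None or month < self.birth_month:
            return False
        if self.death_month is not None and month > self.death_month:
            return False
        if data_end is not None and month > data_end:
            return False
        return True

    def age_at(self, month: int) -> Optional[int]:
        return None if self.birth_month is None else month - self.birth_month


@dataclass
class TransferEvent:
    individual_id: str
    event_month: int
    from_institution: str
    to_institution: str


@dataclass
class StudbookTable:
    """Cleaned individual-level records plus transfers and exclusion accounting.

    ``records`` holds analyzable individuals; ``ghosts`` holds excluded
    individuals retained only because they are referenced as parents.
    """

    records: dict[str, StudbookRecord] = field(default_factory=dict)
    transfers: list[TransferEvent] = field(default_factory=list)
    exclusion_report: Counter = field(default_factory=Counter)
    ghosts: dict[str, StudbookRecord] = field(default_factory=dict)
    data_end: Optional[int] = None
    config: IOConfig = field(default_factory=IOConfig)

    def __post_init__(self) -> None:
        if self.data_end is None:
            months = [m for r in self.records.values()
                      for m in (r.birth_month, r.death_month) if m is not None]
            months += [t.event_month for t in self.transfers]
            self.data_end = max(months) if months else 0

    def record_or_ghost(self, individual_id: str) -> Optional[StudbookRecord]:
        return self.records.get(individual_id) or self.ghosts.get(individual_id)


def parse_month(text: str, epoch: tuple[int, int]) -> Optional[int]:
    """Parse a date string to an integer month index (months since epoch).

    Accepts ISO ``YYYY-MM-DD`` (day <= 15 rounds to that month, day > 15 to the
    next), ``YYYY-MM`` and ``Mon YYYY``.  Empty strings mean missing (None).
    Bare years, a leading ``~`` or any other form raise :class:`UncertainDate`.
    """
    text = (text or "").strip()
    if not text:
        return None
    if text.startswith("~"):
        raise UncertainDate(text)
    if m := _ISO_FULL.match(text):
        year, month, day = int(m[1]), int(m[2]), int(m[3])
        if not (1 <= month <= 12 and 1 <= day <= 31):
            raise UncertainDate(text)
        idx = (year - epoch[0]) * 12 + (month - epoch[1])
        return idx + 1 if day > 15 else idx
    if m := _ISO_MONTH.match(text):
        year, month = int(m[1]), int(m[2])
        if not 1 <= month <= 12:
            raise UncertainDate(text)
        return (year - epoch[0]) * 12 + (month - epoch[1])
    if m := _MON_YEAR.match(text):
        mon = _MONTHS.get(m[1].lower())
        if mon is None:
            raise UncertainDate(text)
        return (int(m[2]) - epoch[0]) * 12 + (mon - epoch[1])
    raise UncertainDate(text)


def month_to_date(index: int, epoch: tuple[int, int]) -> str:
    year, month = divmod(epoch[1] - 1 + index, 12)
    return f"{epoch[0] + year:04d}-{month + 1:02d}"


def parse_studbook(records_path: str | Path,
                   transfers_path: Optional[str | Path] = None,
                   config: Optional[IOConfig] = None) -> StudbookTable:
    """Parse a records CSV (and optional transfers CSV) into a StudbookTable.

    Rows that cannot be interpreted are logged to the exclusion report under a
    rule tag; a malformed header is fatal.
    """
    config = config or IOConfig()
    report: Counter = Counter()
    records: dict[str, StudbookRecord] = {}

    with open(records_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != RECORD_FIELDS:
            raise ValueError(
                f"malformed records header {reader.fieldnames!r}; expected {RECORD_FIELDS}")
        for row in reader:
            rid = (row["id"] or "").strip()
            if not rid:
                report["bad_row"] += 1
                log.warning("row with empty id skipped")
                continue
            if rid in records:
                report["duplicate_id"] += 1
                log.warning("duplicate id %s skipped", rid)
                continue
            try:
                birth = parse_month(row["birth_date"], config.epoch)
            except UncertainDate:
                report["uncertain_date"] += 1
                log.warning("individual %s excluded: uncertain birth date %r",
                            rid, row["birth_date"])
                continue
            try:
                death = parse_month(row["death_date"], config.epoch)
            except UncertainDate:
                # only the death event is uncertain; keep the individual
                report["uncertain_death_event"] += 1
                death = None
            if birth is not None and death is not None and birth > death:
                report["date_order"] += 1
                log.warning("individual %s excluded: death precedes birth", rid)
                continue
            sex = (row["sex"] or "U").strip().upper()[:1]
            if sex not in (FEMALE, MALE):
                sex = UNKNOWN
            dam = (row["dam"] or "").strip() or None
            sire = (row["sire"] or "").strip() or None
            if dam == rid or sire == rid:
                report["self_parent"] += 1
                log.warning("individual %s excluded: listed as own parent", rid)
                continue
            records[rid] = StudbookRecord(
                individual_id=rid, sex=sex, dam_id=dam, sire_id=sire,
                birth_month=birth, death_month=death,
                birth_institution=(row["birth_institution"] or WILD).strip() or WILD,
                origin=(row["origin"] or "zoo_bred").strip() or "zoo_bred",
                disposition=(row["disposition"] or "alive").strip() or "alive",
            )

    transfers: list[TransferEvent] = []
    if transfers_path is not None:
        with open(transfers_path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != TRANSFER_FIELDS:
                raise ValueError(
                    f"malformed transfers header {reader.fieldnames!r}; expected {TRANSFER_FIELDS}")
            for row in reader:
                rid = (row["id"] or "").strip()
                try:
                    month = parse_month(row["date"], config.epoch)
                except UncertainDate:
                    report["uncertain_event_date"] += 1
                    continue
                if not rid or month is None:
                    report["bad_event"] += 1
                    continue
                transfers.append(TransferEvent(
                    rid, month,
                    (row["from"] or WILD).strip() or WILD,
                    (row["to"] or WILD).strip() or WILD))

    return StudbookTable(records=records, transfers=transfers,
                         exclusion_report=report, config=config)


def clean_records(table: StudbookTable, config: Optional[IOConfig] = None) -> StudbookTable:
    """Apply institution recoding and exclusion rules.

    Non-zoo institutions are recoded to WILD; arrivals from WILD make an
    individual an immigrant founder (parents cleared); transfers to WILD mark
    the individual released.  Released and lost-to-follow-up individuals are
    excluded.  An excluded individual referenced as a parent is retained as a
    parent-only ghost node.
    """
    config = config or table.config
    nonzoo = set(config.nonzoo_institutions)
    recode = lambda inst: WILD if inst in nonzoo else inst

    transfers = [replace(t,
                         from_institution=recode(t.from_institution),
                         to_institution=recode(t.to_institution))
                 for t in table.transfers]

    records: dict[str, StudbookRecord] = {}
    report = Counter(table.exclusion_report)
    by_id: dict[str, list[TransferEvent]] = {}
    for t in transfers:
        by_id.setdefault(t.individual_id, []).append(t)

    for rid, rec in table.records.items():
        rec = replace(rec, birth_institution=recode(rec.birth_institution))
        events = by_id.get(rid, [])
        if rec.birth_institution == WILD or any(
                t.from_institution == WILD for t in events):
            rec = replace(rec, origin="immigrant", dam_id=None, sire_id=None)
        if any(t.to_institution == WILD for t in events) and rec.disposition == "alive":
            rec = replace(rec, disposition="released")
        records[rid] = rec

    kept: dict[str, StudbookRecord] = {}
    ghosts: dict[str, StudbookRecord] = dict(table.ghosts)
    excluded: dict[str, StudbookRecord] = {}
    for rid, rec in records.items():
        if config.drop_lost_to_followup and rec.disposition == "lost_to_followup":
            report["lost_to_followup"] += 1
            excluded[rid] = rec
        elif config.drop_released and rec.disposition == "released":
            report["released"] += 1
            excluded[rid] = rec
        else:
            kept[rid] = rec

    referenced = {p for r in kept.values() for p in (r.dam_id, r.sire_id) if p}
    for rid, rec in excluded.items():
        if rid in referenced:
            log.warning("excluded individual %s kept as parent-only ghost", rid)
            ghosts[rid] = rec

    transfers = [t for t in transfers if t.individual_id in kept]
    return StudbookTable(records=kept, transfers=transfers,
                         exclusion_report=report, ghosts=ghosts,
                         data_end=table.data_end, config=config)


class ResidencyTable:
    """Institution per (individual, month), piecewise constant between transfers."""

    def __init__(self, segments: dict[str, list[tuple[int, str]]],
                 ends: dict[str, int]):
        self._segments = segments      # id -> sorted [(start_month, institution)]
        self._ends = ends              # id -> last resident month (inclusive)
        self._by_month: Optional[dict[int, dict[str, list[str]]]] = None

    def at(self, individual_id: str, month: int) -> Optional[str]:
        segs = self._segments.get(individual_id)
        if not segs or month < segs[0][0] or month > self._ends[individual_id]:
            return None
        inst = None
        for start, where in segs:
            if start > month:
                break
            inst = where
        return inst

    def individuals(self) -> Iterable[str]:
        return self._segments.keys()

    def _index(self) -> dict[int, dict[str, list[str]]]:
        if self._by_month is None:
            idx: dict[int, dict[str, list[str]]] = {}
            for rid, segs in self._segments.items():
                end = self._ends[rid]
                for i, (start, inst) in enumerate(segs):
                    stop = segs[i + 1][0] - 1 if i + 1 < len(segs) else end
                    for m in range(start, stop + 1):
                        idx.setdefault(m, {}).setdefault(inst, []).append(rid)
            self._by_month = idx
        return self._by_month

    def occupants(self, institution: str, month: int) -> list[str]:
        return self._index().get(month, {}).get(institution, [])

    def location_index(self, month: int) -> dict[str, str]:
        """individual -> institution for one month (cached)."""
        if not hasattr(self, "_loc_cache"):
            self._loc_cache: dict[int, dict[str, str]] = {}
        cached = self._loc_cache.get(month)
        if cached is None:
            cached = {rid: inst
                      for inst, rids in self._index().get(month, {}).items()
                      for rid in rids}
            self._loc_cache[month] = cached
        return cached

    def occupancy(self, institution: str, month: int) -> int:
        return len(self.occupants(institution, month))

    def institutions(self) -> set[str]:
        return {inst for segs in self._segments.values() for _, inst in segs}

    def months(self) -> tuple[int, int]:
        starts = [s[0][0] for s in self._segments.values() if s]
        ends = list(self._ends.values())
        return (min(starts), max(ends)) if starts else (0, 0)


def monthly_residency(table: StudbookTable) -> ResidencyTable:
    """Derive the month-by-month residency of every analyzable individual.

    The transfer month belongs to the destination; two transfers in the same
    month resolve to the last one (a warning is logged).  A transfer outside
    the individual's lifespan is an error.
    """
    by_id: dict[str, list[TransferEvent]] = {}
    for t in table.transfers:
        by_id.setdefault(t.individual_id, []).append(t)

    segments: dict[str, list[tuple[int, str]]] = {}
    ends: dict[str, int] = {}
    for rid, rec in table.records.items():
        events = sorted(by_id.get(rid, []), key=lambda t: t.event_month)
        if rec.birth_month is None:
            continue
        for t in events:
            if t.event_month < rec.birth_month or (
                    rec.death_month is not None and t.event_month > rec.death_month):
                raise ValueError(
                    f"transfer of {rid} at month {t.event_month} outside lifespan "
                    f"[{rec.birth_month}, {rec.death_month}]")
        segs: list[tuple[int, str]] = []
        if rec.birth_institution != WILD:
            segs.append((rec.birth_month, rec.birth_institution))
        for t in events:
            if segs and segs[-1][0] == t.event_month:
                log.warning("same-month transfers for %s at month %d; last wins",
                            rid, t.event_month)
                segs[-1] = (t.event_month, t.to_institution)
            else:
                segs.append((t.event_month, t.to_institution))
        segs = [(m, inst) for m, inst in segs if inst != WILD]
        if not segs:
            continue
        end = rec.death_month if rec.death_month is not None else table.data_end
        segments[rid] = segs
        ends[rid] = end
    return ResidencyTable(segments, ends)


def write_studbook(table: StudbookTable, out_dir: str | Path,
                   epoch: Optional[tuple[int, int]] = None) -> None:
    """Write the canonical CSV pair plus a JSON exclusion report."""
    epoch = epoch or table.config.epoch
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = lambda m: "" if m is None else month_to_date(m, epoch)
    with open(out / "records.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RECORD_FIELDS)
        for rec in table.records.values():
            w.writerow([rec.individual_id, rec.sex, rec.dam_id or "",
                        rec.sire_id or "", fmt(rec.birth_month),
                        fmt(rec.death_month), rec.birth_institution,
                        rec.origin, rec.disposition])
    with open(out / "transfers.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRANSFER_FIELDS)
        for t in table.transfers:
            w.writerow([t.individual_id, fmt(t.event_month),
                        t.from_institution, t.to_institution])
    with open(out / "exclusions.json", "w", encoding="utf-8") as fh:
        json.dump(dict(table.exclusion_report), fh, indent=2, sort_keys=True)
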