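"""Reading, validation and writing of correction-event and roster tables.

A therapeutic-community (TC) unit keeps two flat records: a corrections
table (one row per written peer correction: date, sender, receiver) and a
resident roster (entry/exit dates, graduation outcome, age, race indicator
and LSI-R risk score).  Both are headered CSV with ISO-8601 dates; column
names are remappable through a ``dialect`` mapping so exports from other
record systems can be ingested unchanged.

Validation is two-staged: per-file parsing (:func:`read_corrections`,
:func:`read_roster`) drops or rejects malformed rows, and
:func:`cross_validate` reconciles events against the roster, dropping
events whose participants are unknown or whose date falls outside either
participant's tenure.  Nothing is dropped silently: every drop is counted
under a named reason in a :class:`ValidationReport`.
"""

from __future__ import annotations

import datetime
import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: canonical column names of the corrections CSV
EVENT_COLUMNS = ("date", "sender_id", "receiver_id")
#: canonical column names of the roster CSV
ROSTER_COLUMNS = (
    "resident_id",
    "entry_date",
    "exit_date",
    "graduated",
    "age",
    "race_minority",
    "lsi_r",
)


@dataclass(frozen=True)
class CorrectionEvent:
    """One dated, directed peer correction — the network edge atom."""

    date: datetime.date
    sender_id: str
    receiver_id: str

    def __post_init__(self) -> None:
        if self.sender_id == self.receiver_id:
            raise ValueError(
                f"self-correction not allowed: {self.sender_id!r}"
            )


@dataclass
class ResidentRecord:
    """One roster row: tenure window, outcome and covariates.

    ``age``, ``race_minority`` and ``lsi_r`` may be ``None`` when the
    archival record is incomplete; such residents are retained through the
    network stages but excluded from the regression stage.
    """

    resident_id: str
    entry_date: datetime.date
    exit_date: datetime.date
    graduated: int
    age: float | None
    race_minority: int | None
    lsi_r: float | None

    def __post_init__(self) -> None:
        if self.exit_date < self.entry_date:
            raise ValueError(
                f"resident {self.resident_id!r}: exit_date precedes entry_date"
            )
        if self.graduated not in (0, 1):
            raise ValueError(
                f"resident {self.resident_id!r}: graduated must be 0 or 1"
            )

    @property
    def days_in_program(self) -> int:
        return (self.exit_date - self.entry_date).days

    @property
    def complete(self) -> bool:
        """True when all regression covariates are present."""
        return (
            self.age is not None
            and self.race_minority is not None
            and self.lsi_r is not None
        )


@dataclass
class ValidationReport:
    """Accounting of rows read and dropped across both validation stages."""

    n_events_read: int
    n_events_dropped: int
    drop_reasons: list[tuple[str, int]]
    n_residents: int

    def to_dict(self) -> dict:
        return {
            "n_events_read": self.n_events_read,
            "n_events_dropped": self.n_events_dropped,
            "drop_reasons": [list(r) for r in self.drop_reasons],
            "n_residents": self.n_residents,
        }

    def to_log(self) -> str:
        lines = [
            f"events read:      {self.n_events_read}",
            f"events dropped:   {self.n_events_dropped}",
            f"residents:        {self.n_residents}",
        ]
        for reason, count in self.drop_reasons:
            lines.append(f"  dropped ({reason}): {count}")
        return "\n".join(lines) + "\n"


def _remap(df: pd.DataFrame, required: Sequence[str],
           dialect: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename dialect columns to canonical names; fail on missing columns."""
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    return df


def _parse_date(raw: str) -> datetime.date:
    return datetime.date.fromisoformat(raw.strip())


def _int_like(raw) -> int:
    """Parse an integer, tolerating integral float renderings ("1.0")."""
    value = float(str(raw).strip())
    if value != int(value):
        raise ValueError(f"not an integer: {raw!r}")
    return int(value)


def read_corrections(
    path, dialect: Mapping[str, str] | None = None
) -> tuple[list[CorrectionEvent], dict[str, int]]:
    """Read a corrections CSV.

    Parameters
    ----------
    path : path-like
        Headered CSV with (at least) the columns of :data:`EVENT_COLUMNS`,
        possibly under other names remapped by ``dialect``.
    dialect : mapping, optional
        ``{canonical_name: file_column_name}``.

    Returns
    -------
    events : list of CorrectionEvent
        One event per parseable row, in file order.
    drops : dict
        Counts of rows dropped, keyed by reason (``"self_loop"``,
        ``"bad_date"``, ``"missing_field"``).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _remap(df, EVENT_COLUMNS, dialect)
    events: list[CorrectionEvent] = []
    drops: Counter[str] = Counter()
    for row in df.itertuples(index=False):
        sender = str(getattr(row, "sender_id")).strip()
        receiver = str(getattr(row, "receiver_id")).strip()
        if not sender or not receiver or not str(row.date).strip():
            drops["missing_field"] += 1
            continue
        try:
            date = _parse_date(row.date)
        except ValueError:
            drops["bad_date"] += 1
            continue
        if sender == receiver:
            drops["self_loop"] += 1
            continue
        events.append(CorrectionEvent(date, sender, receiver))
    return events, dict(drops)


def read_roster(
    path, dialect: Mapping[str, str] | None = None
) -> list[ResidentRecord]:
    """Read a resident roster CSV.

    Duplicate resident ids, reversed tenure windows and malformed
    outcomes are fatal (``ValueError`` naming the offender).  Blank
    covariate cells flag the record as incomplete instead.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _remap(df, ROSTER_COLUMNS, dialect)
    records: list[ResidentRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        rid = str(row.resident_id).strip()
        if not rid:
            raise ValueError(f"row {i}: blank resident_id")
        if rid in seen:
            raise ValueError(f"duplicate resident_id {rid!r}")
        seen.add(rid)
        try:
            entry = _parse_date(row.entry_date)
            exit_ = _parse_date(row.exit_date)
        except ValueError as exc:
            raise ValueError(f"row {i} (resident {rid!r}): bad date") from exc
        if exit_ < entry:
            raise ValueError(
                f"row {i} (resident {rid!r}): exit_date precedes entry_date"
            )
        try:
            graduated = _int_like(row.graduated)
        except ValueError as exc:
            raise ValueError(
                f"row {i} (resident {rid!r}): graduated not 0/1"
            ) from exc

        def _opt_float(raw: str) -> float | None:
            raw = str(raw).strip()
            return float(raw) if raw else None

        age = _opt_float(row.age)
        race_raw = str(row.race_minority).strip()
        race = _int_like(race_raw) if race_raw else None
        lsi = _opt_float(row.lsi_r)
        records.append(
            ResidentRecord(rid, entry, exit_, graduated, age, race, lsi)
        )
    return records


def cross_validate(
    events: Iterable[CorrectionEvent],
    roster: Sequence[ResidentRecord],
    read_drops: Mapping[str, int] | None = None,
) -> tuple[list[CorrectionEvent], ValidationReport]:
    """Reconcile events against the roster.

    Drops (with per-reason counts) events referencing residents absent
    from the roster (``"unknown_resident"``) and events dated outside the
    tenure window of either participant (``"out_of_tenure"``).  The
    operation is idempotent: the surviving events all pass a second pass
    unchanged.
    """
    events = list(events)
    tenure = {r.resident_id: (r.entry_date, r.exit_date) for r in roster}
    drops: Counter[str] = Counter(read_drops or {})
    kept: list[CorrectionEvent] = []
    for ev in events:
        if ev.sender_id not in tenure or ev.receiver_id not in tenure:
            drops["unknown_resident"] += 1
            continue
        s0, s1 = tenure[ev.sender_id]
        r0, r1 = tenure[ev.receiver_id]
        if not (s0 <= ev.date <= s1 and r0 <= ev.date <= r1):
            drops["out_of_tenure"] += 1
            continue
        kept.append(ev)
    n_read = len(events) + sum((read_drops or {}).values())
    report = ValidationReport(
        n_events_read=n_read,
        n_events_dropped=n_read - len(kept),
        drop_reasons=sorted(drops.items()),
        n_residents=len(roster),
    )
    return kept, report


def write_corrections(events: Iterable[CorrectionEvent], path) -> None:
    df = pd.DataFrame(
        [(e.date.isoformat(), e.sender_id, e.receiver_id) for e in events],
        columns=list(EVENT_COLUMNS),
    )
    df.to_csv(path, index=False)


def write_roster(records: Iterable[ResidentRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            (
                r.resident_id,
                r.entry_date.isoformat(),
                r.exit_date.isoformat(),
                r.graduated,
                "" if r.age is None else r.age,
                "" if r.race_minority is None else r.race_minority,
                "" if r.lsi_r is None else r.lsi_r,
            )
        )
    pd.DataFrame(rows, columns=list(ROSTER_COLUMNS)).to_csv(path, index=False)


def write_validation_report(report: ValidationReport, json_path, log_path) -> None:
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(log_path, "w") as fh:
        fh.write(report.to_log())


def events_to_frame(events: Iterable[CorrectionEvent]) -> pd.DataFrame:
    """Dataclass list -> analysis frame (datetime64 dates)."""
    events = list(events)
    return pd.DataFrame(
        {
            "date": pd.to_datetime([e.date for e in events]),
            "sender_id": [e.sender_id for e in events],
            "receiver_id": [e.receiver_id for e in events],
        }
    )


def roster_to_frame(records: Iterable[ResidentRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "resident_id": [r.resident_id for r in records],
            "entry_date": pd.to_datetime([r.entry_date for r in records]),
            "exit_date": pd.to_datetime([r.exit_date for r in records]),
            "graduated": [r.graduated for r in records],
            "age": [float("nan") if r.age is None else r.age for r in records],
            "race_minority": [
                float("nan") if r.race_minority is None else r.race_minority
                for r in records
            ],
            "lsi_r": [
                float("nan") if r.lsi_r is None else r.lsi_r for r in records
            ],
            "days_in_program": [r.days_in_program for r in records],
            "complete": [r.complete for r in records],
        }
    )


def frame_to_roster(df: pd.DataFrame) -> list[ResidentRecord]:
    """Analysis frame -> dataclass list (inverse of :func:`roster_to_frame`)."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ResidentRecord(
                str(row.resident_id),
                pd.Timestamp(row.entry_date).date(),
                pd.Timestamp(row.exit_date).date(),
                int(row.graduated),
                None if pd.isna(row.age) else float(row.age),
                None if pd.isna(row.race_minority) else int(row.race_minority),
                None if pd.isna(row.lsi_r) else float(row.lsi_r),
            )
        )
    return records
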