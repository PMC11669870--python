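"""Data model and CSV readers/writers for minute-level wearable sensor data.

The study data consist of four per-patient streams, each exchanged as a
plain CSV file:

* ``hr.csv`` / ``steps.csv`` — one row per *worn* minute
  (``patient_id, timestamp, value``).  Absent minutes mean the device was
  not worn; they are never zero-filled for heart rate.
* ``events.csv`` — smart-inhaler actuations
  (``patient_id, timestamp, inhaler_type``), one of SABA / LABA / ICS /
  ICS_LABA.
* ``medstatus.csv`` — weekly-questionnaire analogue: inclusive date
  intervals flagging whether the patient was on LABA maintenance therapy
  (``patient_id, start_date, end_date, laba``).

All timestamps are naive local clock time and are floored to the minute on
ingestion (seconds are discarded); daylight-saving irregularities are
treated as ordinary missing/duplicate data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StoreError",
    "ParseError",
    "IntegrityError",
    "DomainError",
    "HEART_RATE",
    "STEPS",
    "INHALER_TYPES",
    "MinuteSeries",
    "EventLog",
    "MedStatusTimeline",
    "PatientData",
    "CohortBundle",
    "read_minute_csv",
    "read_event_csv",
    "read_medstatus_csv",
    "read_bundle",
    "write_bundle",
]


class StoreError(ValueError):
    """Base class for data-store errors."""


class ParseError(StoreError):
    """A field could not be parsed (names the offending line)."""


class IntegrityError(StoreError):
    """A structural invariant is violated (duplicates, overlaps)."""


class DomainError(StoreError):
    """A value is outside its physiological/enumerated domain."""


HEART_RATE = "heart_rate_bpm"
STEPS = "steps_per_minute"
_KINDS = (HEART_RATE, STEPS)

# Physiological plausibility bounds for stored heart rate.
HR_MIN, HR_MAX = 20.0, 250.0

INHALER_TYPES = ("SABA", "LABA", "ICS", "ICS_LABA")

MINUTES_PER_DAY = 1440


def _check_minute_aligned(index: pd.DatetimeIndex) -> None:
    if len(index) and not (index == index.floor("min")).all():
        raise IntegrityError("timestamps must be minute-aligned (seconds == 0)")


@dataclass
class MinuteSeries:
    """One patient's minute-resolution measurement stream.

    ``data`` is a float Series indexed by minute-aligned, strictly
    increasing, unique timestamps.  A missing index entry means the device
    was not worn that minute.
    """

    patient_id: str
    kind: str
    data: pd.Series

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise DomainError(f"unknown series kind {self.kind!r}; expected one of {_KINDS}")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise IntegrityError("MinuteSeries requires a DatetimeIndex")
        idx = self.data.index
        _check_minute_aligned(idx)
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise IntegrityError("timestamps must be sorted increasing")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise IntegrityError(
                f"duplicate minute {dup} for patient {self.patient_id}"
            )
        values = self.data.to_numpy(dtype=float)
        if self.kind == HEART_RATE:
            if len(values) and ((values < HR_MIN) | (values > HR_MAX)).any():
                bad = values[(values < HR_MIN) | (values > HR_MAX)][0]
                raise DomainError(
                    f"heart rate {bad} bpm outside [{HR_MIN}, {HR_MAX}] "
                    f"for patient {self.patient_id}"
                )
        else:
            if len(values) and ((values < 0) | (values != np.floor(values))).any():
                raise DomainError(
                    f"steps must be non-negative integers (patient {self.patient_id})"
                )
        self.data = self.data.astype(float)
        self.data.name = self.kind

    @property
    def n_minutes(self) -> int:
        return len(self.data)

    def dates(self) -> pd.DatetimeIndex:
        """Distinct calendar dates (normalized timestamps) with data."""
        return pd.DatetimeIndex(self.data.index.normalize().unique())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MinuteSeries):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.kind == other.kind
            and self.data.index.equals(other.data.index)
            and np.array_equal(self.data.to_numpy(), other.data.to_numpy())
        )


@dataclass
class EventLog:
    """Timestamped inhaler actuations for one patient.

    Events are minute-aligned, sorted by time; identical
    (timestamp, inhaler_type) pairs collapse to a single actuation.
    """

    patient_id: str
    events: pd.DataFrame  # columns: timestamp, inhaler_type

    def __post_init__(self) -> None:
        ev = self.events.copy()
        if not {"timestamp", "inhaler_type"}.issubset(ev.columns):
            raise IntegrityError("EventLog needs columns timestamp, inhaler_type")
        bad = set(ev["inhaler_type"]) - set(INHALER_TYPES)
        if bad:
            raise DomainError(
                f"unknown inhaler_type {sorted(bad)}; allowed: {list(INHALER_TYPES)}"
            )
        ev["timestamp"] = pd.DatetimeIndex(ev["timestamp"]).floor("min")
        ev = (
            ev.drop_duplicates(["timestamp", "inhaler_type"])
            .sort_values(["timestamp", "inhaler_type"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.events = ev[["timestamp", "inhaler_type"]]

    def of_type(self, *types: str) -> pd.DataFrame:
        unknown = set(types) - set(INHALER_TYPES)
        if unknown:
            raise DomainError(f"unknown inhaler_type {sorted(unknown)}")
        return self.events[self.events["inhaler_type"].isin(types)]

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return self.patient_id == other.patient_id and self.events.equals(other.events)


@dataclass
class MedStatusTimeline:
    """Per-patient inclusive date intervals of known LABA status.

    Intervals are sorted and non-overlapping; dates outside every interval
    have *unknown* status and are excluded from the group comparison.
    """

    patient_id: str
    intervals: pd.DataFrame  # columns: start_date, end_date, laba (bool)

    def __post_init__(self) -> None:
        iv = self.intervals.copy()
        if not {"start_date", "end_date", "laba"}.issubset(iv.columns):
            raise IntegrityError("MedStatusTimeline needs start_date, end_date, laba")
        iv["start_date"] = pd.DatetimeIndex(iv["start_date"]).normalize()
        iv["end_date"] = pd.DatetimeIndex(iv["end_date"]).normalize()
        iv["laba"] = iv["laba"].astype(bool)
        if (iv["start_date"] > iv["end_date"]).any():
            row = iv[iv["start_date"] > iv["end_date"]].iloc[0]
            raise IntegrityError(
                f"interval start {row.start_date.date()} after end "
                f"{row.end_date.date()} for patient {self.patient_id}"
            )
        iv = iv.sort_values("start_date", kind="mergesort").reset_index(drop=True)
        overlap = iv["start_date"].iloc[1:].to_numpy() <= iv["end_date"].iloc[:-1].to_numpy()
        if overlap.any():
            raise IntegrityError(
                f"overlapping medication-status intervals for patient {self.patient_id}"
            )
        self.intervals = iv[["start_date", "end_date", "laba"]]

    def status_for_dates(self, dates: pd.DatetimeIndex) -> pd.array:
        """LABA status per date: True/False, or pd.NA where unknown."""
        out = pd.array([pd.NA] * len(dates), dtype="boolean")
        dates = pd.DatetimeIndex(dates).normalize()
        for _, row in self.intervals.iterrows():
            mask = (dates >= row.start_date) & (dates <= row.end_date)
            out[np.asarray(mask)] = bool(row.laba)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MedStatusTimeline):
            return NotImplemented
        return self.patient_id == other.patient_id and self.intervals.equals(
            other.intervals
        )


@dataclass
class PatientData:
    """All streams for a single patient (any of them may be empty)."""

    patient_id: str
    hr: MinuteSeries
    steps: MinuteSeries
    events: EventLog
    medstatus: MedStatusTimeline

    def __post_init__(self) -> None:
        for comp in (self.hr, self.steps, self.events, self.medstatus):
            if comp.patient_id != self.patient_id:
                raise IntegrityError(
                    f"component patient_id {comp.patient_id!r} != {self.patient_id!r}"
                )


def empty_patient(patient_id: str) -> PatientData:
    return PatientData(
        patient_id,
        MinuteSeries(patient_id, HEART_RATE, pd.Series(dtype=float, index=pd.DatetimeIndex([]))),
        MinuteSeries(patient_id, STEPS, pd.Series(dtype=float, index=pd.DatetimeIndex([]))),
        EventLog(patient_id, pd.DataFrame(columns=["timestamp", "inhaler_type"])),
        MedStatusTimeline(
            patient_id, pd.DataFrame(columns=["start_date", "end_date", "laba"])
        ),
    )


@dataclass
class CohortBundle:
    """The full cohort: a mapping patient_id -> PatientData."""

    patients: dict[str, PatientData] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def __getitem__(self, patient_id: str) -> PatientData:
        return self.patients[patient_id]

    def __iter__(self):
        return (self.patients[pid] for pid in self.patient_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortBundle):
            return NotImplemented
        if self.patient_ids != other.patient_ids:
            return False
        for pid in self.patient_ids:
            a, b = self[pid], other[pid]
            if not (
                a.hr == b.hr
                and a.steps == b.steps
                and a.events == b.events
                and a.medstatus == b.medstatus
            ):
                return False
        return True


# ---------------------------------------------------------------------------
# CSV ingestion


def _parse_timestamps(raw: pd.Series, path: Path) -> pd.DatetimeIndex:
    ts = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if ts.isna().any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 2
        raise ParseError(f"{path}: malformed timestamp on line {line}: {raw.iloc[line - 2]!r}")
    return pd.DatetimeIndex(ts).floor("min")


def read_minute_csv(path, kind: str) -> dict[str, MinuteSeries]:
    """Read a per-minute value CSV into one MinuteSeries per patient.

    Timestamps are floored to the minute; a duplicated patient+minute row is
    an integrity error, a negative value a domain error.
    """
    path = Path(path)
    # round_trip float parsing keeps write->read the exact identity
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = {"patient_id", "timestamp", "value"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df.assign(timestamp=_parse_timestamps(df["timestamp"], path))
    if (df["value"].astype(float) < 0).any():
        raise DomainError(f"{path}: negative sensor value")
    out: dict[str, MinuteSeries] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        if grp["timestamp"].duplicated().any():
            dup = grp.loc[grp["timestamp"].duplicated(), "timestamp"].iloc[0]
            raise IntegrityError(f"{path}: duplicate minute {dup} for patient {pid}")
        grp = grp.sort_values("timestamp", kind="mergesort")
        series = pd.Series(
            grp["value"].to_numpy(dtype=float),
            index=pd.DatetimeIndex(grp["timestamp"]),
        )
        out[str(pid)] = MinuteSeries(str(pid), kind, series)
    return out


def read_event_csv(path) -> dict[str, EventLog]:
    """Read smart-inhaler actuations; unknown inhaler types are rejected."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "inhaler_type": str})
    missing = {"patient_id", "timestamp", "inhaler_type"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["inhaler_type"]) - set(INHALER_TYPES)
    if bad:
        raise DomainError(
            f"{path}: unknown inhaler_type {sorted(bad)}; allowed: {list(INHALER_TYPES)}"
        )
    df = df.assign(timestamp=_parse_timestamps(df["timestamp"], path))
    return {
        str(pid): EventLog(str(pid), grp[["timestamp", "inhaler_type"]])
        for pid, grp in df.groupby("patient_id", sort=True)
    }


def read_medstatus_csv(path) -> dict[str, MedStatusTimeline]:
    """Read LABA-status date intervals; overlapping intervals are rejected."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = {"patient_id", "start_date", "end_date", "laba"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["laba"] = df["laba"].astype(int).astype(bool)
    return {
        str(pid): MedStatusTimeline(str(pid), grp[["start_date", "end_date", "laba"]])
        for pid, grp in df.groupby("patient_id", sort=True)
    }


# ---------------------------------------------------------------------------
# Bundle round-trip

_FILES = {
    "hr": "hr.csv",
    "steps": "steps.csv",
    "events": "events.csv",
    "medstatus": "medstatus.csv",
}


def write_bundle(bundle: CohortBundle, directory) -> dict[str, Path]:
    """Write a cohort as the four interface CSVs; gaps stay absent rows.

    Round-trips exactly: ``read_bundle(write_bundle(b)) == b``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in _FILES.items()}

    def minute_frames(attr):
        frames = []
        for patient in bundle:
            series: MinuteSeries = getattr(patient, attr)
            if series.n_minutes:
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": patient.patient_id,
                            "timestamp": series.data.index.strftime("%Y-%m-%dT%H:%M:%S"),
                            "value": series.data.to_numpy(),
                        }
                    )
                )
        cols = ["patient_id", "timestamp", "value"]
        return pd.concat(frames)[cols] if frames else pd.DataFrame(columns=cols)

    minute_frames("hr").to_csv(paths["hr"], index=False)
    minute_frames("steps").to_csv(paths["steps"], index=False)

    ev_frames = []
    for patient in bundle:
        ev = patient.events.events
        if len(ev):
            ev_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient.patient_id,
                        "timestamp": pd.DatetimeIndex(ev["timestamp"]).strftime(
                            "%Y-%m-%dT%H:%M:%S"
                        ),
                        "inhaler_type": ev["inhaler_type"].to_numpy(),
                    }
                )
            )
    ev_cols = ["patient_id", "timestamp", "inhaler_type"]
    (pd.concat(ev_frames)[ev_cols] if ev_frames else pd.DataFrame(columns=ev_cols)).to_csv(
        paths["events"], index=False
    )

    ms_frames = []
    for patient in bundle:
        iv = patient.medstatus.intervals
        if len(iv):
            ms_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient.patient_id,
                        "start_date": pd.DatetimeIndex(iv["start_date"]).strftime("%Y-%m-%d"),
                        "end_date": pd.DatetimeIndex(iv["end_date"]).strftime("%Y-%m-%d"),
                        "laba": iv["laba"].astype(int).to_numpy(),
                    }
                )
            )
    ms_cols = ["patient_id", "start_date", "end_date", "laba"]
    (pd.concat(ms_frames)[ms_cols] if ms_frames else pd.DataFrame(columns=ms_cols)).to_csv(
        paths["medstatus"], index=False
    )
    return paths


def read_bundle(directory) -> CohortBundle:
    """Read the four interface CSVs back into a CohortBundle."""
    directory = Path(directory)
    hr = read_minute_csv(directory / _FILES["hr"], HEART_RATE)
    steps = read_minute_csv(directory / _FILES["steps"], STEPS)
    events = read_event_csv(directory / _FILES["events"])
    medstatus = read_medstatus_csv(directory / _FILES["medstatus"])
    bundle = CohortBundle()
    for pid in sorted(set(hr) | set(steps) | set(events) | set(medstatus)):
        blank = empty_patient(pid)
        bundle.patients[pid] = PatientData(
            pid,
            hr.get(pid, blank.hr),
            steps.get(pid, blank.steps),
            events.get(pid, blank.events),
            medstatus.get(pid, blank.medstatus),
        )
    return bundle
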