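"""Core record types for medical time-series data and lossless readers/writers.

A patient record splits each hospital visit into two modalities:

* **static event data** ``m = (c, y, E)`` — demographic covariates ``c``, a set
  of outcome labels ``y`` and a timestamp-ordered sequence of discrete clinical
  events ``E`` (diagnoses, procedures);
* **temporal data** ``t`` — timestamped continuous measurements such as vital
  signs and laboratory values.

Both carry a ``qa_status`` flag distinguishing freshly generated output
(``raw``) from output that has passed its quality gate (``constrained``).
Times are integer hours since visit admission; visit timestamps are ISO-8601
strings.  The canonical on-disk form is JSON-lines, one patient per line,
preceded by a header object carrying ``format_version`` and the dataset
schema.  A long-format CSV dialect is provided for tabular tooling.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"

QA_RAW = "raw"
QA_CONSTRAINED = "constrained"


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset violates the documented schema."""


@dataclass
class ClinicalEvent:
    """One discrete clinical event (diagnosis, surgery, ...) at an hour offset."""

    code: str
    timestamp: int
    event_type: str = "diagnosis"

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("ClinicalEvent.code must be non-empty")
        if self.timestamp < 0:
            raise ValueError(f"ClinicalEvent.timestamp must be >= 0, got {self.timestamp}")


@dataclass
class TemporalPoint:
    """Measurements observed at one time point (hours from admission)."""

    time: int
    measurements: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("TemporalPoint needs at least one measurement")
        names = [n for n, _ in self.measurements]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate measurement names at time {self.time}: {sorted(names)}")
        for name, value in self.measurements:
            if not math.isfinite(value):
                raise ValueError(f"non-finite value for variable '{name}' at time {self.time}")


@dataclass
class StaticEventData:
    """Discrete portion of one visit: covariates, outcomes, ordered events."""

    covariates: dict[str, object] = field(default_factory=dict)
    outcomes: set[str] = field(default_factory=set)
    events: list[ClinicalEvent] = field(default_factory=list)
    qa_status: str = QA_RAW


@dataclass
class TemporalSeries:
    """Continuous portion of one visit: strictly time-increasing points."""

    points: list[TemporalPoint] = field(default_factory=list)
    qa_status: str = QA_RAW

    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.points:
            for name, _ in p.measurements:
                seen.setdefault(name)
        return list(seen)


@dataclass
class Visit:
    visit_time: str  # ISO-8601
    static: StaticEventData = field(default_factory=StaticEventData)
    temporal: TemporalSeries = field(default_factory=TemporalSeries)


@dataclass
class PatientRecord:
    patient_id: str
    visits: list[Visit] = field(default_factory=list)


@dataclass
class Dataset:
    patients: list[PatientRecord] = field(default_factory=list)
    schema: dict[str, list[str]] = field(default_factory=lambda: {"variables": [], "labels": []})

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# validation

def validate_record(p: PatientRecord) -> list[str]:
    """Return human-readable invariant violations; empty list iff the record is valid.

    Pure function — never mutates its argument.
    """
    violations: list[str] = []
    if not p.patient_id:
        violations.append("patient_id is empty")
    times = [v.visit_time for v in p.visits]
    if times != sorted(times):
        violations.append(f"visits out of order by visit_time: {times}")
    for vi, visit in enumerate(p.visits):
        ev = visit.static.events
        for a, b in zip(ev, ev[1:]):
            if a.timestamp > b.timestamp:
                violations.append(
                    f"visit {vi}: events out of timestamp order: "
                    f"'{a.code}'@{a.timestamp} before '{b.code}'@{b.timestamp}"
                )
        for e in ev:
            if e.timestamp < 0:
                violations.append(f"visit {vi}: event '{e.code}' has negative timestamp")
            if not e.code:
                violations.append(f"visit {vi}: event with empty code")
        pts = visit.temporal.points
        for a_p, b_p in zip(pts, pts[1:]):
            if a_p.time >= b_p.time:
                violations.append(
                    f"visit {vi}: temporal points not strictly increasing "
                    f"({a_p.time} then {b_p.time})"
                )
        for pt in pts:
            names = [n for n, _ in pt.measurements]
            dupes = {n for n in names if names.count(n) > 1}
            if dupes:
                violations.append(
                    f"visit {vi}: duplicate variable name(s) {sorted(dupes)} at time {pt.time}"
                )
            for name, value in pt.measurements:
                if not math.isfinite(value):
                    violations.append(
                        f"visit {vi}: non-finite value for '{name}' at time {pt.time}"
                    )
    return violations


def is_fully_constrained(p: PatientRecord) -> bool:
    """True iff every visit carries qa_status=constrained on both modalities."""
    return all(
        v.static.qa_status == QA_CONSTRAINED and v.temporal.qa_status == QA_CONSTRAINED
        for v in p.visits
    )


# ---------------------------------------------------------------------------
# JSON-lines serialization (canonical)

def _event_to_json(e: ClinicalEvent) -> dict:
    return {"code": e.code, "timestamp": e.timestamp, "event_type": e.event_type}


def _visit_to_json(v: Visit) -> dict:
    return {
        "visit_time": v.visit_time,
        "static": {
            "covariates": dict(sorted(v.static.covariates.items())),
            "outcomes": sorted(v.static.outcomes),
            "events": [_event_to_json(e) for e in v.static.events],
            "qa_status": v.static.qa_status,
        },
        "temporal": {
            "points": [
                {"time": p.time, "measurements": [[n, x] for n, x in p.measurements]}
                for p in v.temporal.points
            ],
            "qa_status": v.temporal.qa_status,
        },
    }


def _patient_to_json(p: PatientRecord) -> dict:
    return {"patient_id": p.patient_id, "visits": [_visit_to_json(v) for v in p.visits]}


def _patient_from_json(obj: dict, line_no: int) -> PatientRecord:
    try:
        pid = obj["patient_id"]
        visits = []
        for v in obj.get("visits", []):
            st = v["static"]
            events = []
            for e in st.get("events", []):
                events.append(
                    ClinicalEvent(e["code"], int(e["timestamp"]), e.get("event_type", "diagnosis"))
                )
            if any(a.timestamp > b.timestamp for a, b in zip(events, events[1:])):
                logger.warning(
                    "patient %s: events out of order on input; re-sorting by timestamp", pid
                )
                events.sort(key=lambda e: (e.timestamp, e.code))
            tp = v["temporal"]
            points = []
            for pt in tp.get("points", []):
                meas = []
                for name, value in pt["measurements"]:
                    fv = float(value)
                    if not math.isfinite(fv):
                        raise DatasetFormatError(
                            f"line {line_no}: non-finite value for variable '{name}' "
                            f"of patient '{pid}'"
                        )
                    meas.append((name, fv))
                points.append(TemporalPoint(int(pt["time"]), meas))
            visits.append(
                Visit(
                    visit_time=v["visit_time"],
                    static=StaticEventData(
                        covariates=dict(st.get("covariates", {})),
                        outcomes=set(st.get("outcomes", [])),
                        events=events,
                        qa_status=st.get("qa_status", QA_RAW),
                    ),
                    temporal=TemporalSeries(points=points, qa_status=tp.get("qa_status", QA_RAW)),
                )
            )
        return PatientRecord(patient_id=pid, visits=visits)
    except DatasetFormatError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise DatasetFormatError(f"line {line_no}: malformed patient record: {exc}") from exc


def _dumps(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def write_dataset(d: Dataset, path: str | Path, format: str = "jsonl") -> None:
    """Write ``d`` canonically: patients sorted by id, visits by time."""
    path = Path(path)
    if format == "jsonl":
        lines = [_dumps({"format_version": FORMAT_VERSION, "schema": d.schema})]
        for p in sorted(d.patients, key=lambda p: p.patient_id):
            rec = PatientRecord(p.patient_id, sorted(p.visits, key=lambda v: v.visit_time))
            lines.append(_dumps(_patient_to_json(rec)))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "long_csv":
        _write_long_csv(d, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_dataset(path: str | Path, format: str = "jsonl") -> Dataset:
    """Read a dataset file; see module docstring for the two dialects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "long_csv":
        return _read_long_csv(path)
    raise ValueError(f"unknown format: {format!r}")


def _read_jsonl(path: Path) -> Dataset:
    patients: list[PatientRecord] = []
    schema: dict = {"variables": [], "labels": []}
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise DatasetFormatError(f"line {i}: invalid JSON: {exc}") from exc
            if i == 1 and "format_version" in obj:
                schema = obj.get("schema", schema)
                continue
            patients.append(_patient_from_json(obj, i))
    return Dataset(patients=patients, schema=schema)


# ---------------------------------------------------------------------------
# long CSV dialect
#
# columns: patient_id, visit_idx, kind, time, name, value
#   kind=visit      time="", name="visit_time",   value=ISO timestamp
#   kind=qa         time="", name=static|temporal value=raw|constrained
#   kind=covariate  time="", name=field,          value=field value
#   kind=outcome    time="", name=label,          value=""
#   kind=event      time=ts, name=code,           value=event_type
#   kind=temporal   time=t,  name=variable,       value=measurement

_CSV_COLUMNS = ["patient_id", "visit_idx", "kind", "time", "name", "value"]


def _write_long_csv(d: Dataset, path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["#format_version", FORMAT_VERSION, _dumps(d.schema), "", "", ""])
        w.writerow(_CSV_COLUMNS)
        for p in sorted(d.patients, key=lambda p: p.patient_id):
            for vi, v in enumerate(sorted(p.visits, key=lambda v: v.visit_time)):
                w.writerow([p.patient_id, vi, "visit", "", "visit_time", v.visit_time])
                w.writerow([p.patient_id, vi, "qa", "", "static", v.static.qa_status])
                w.writerow([p.patient_id, vi, "qa", "", "temporal", v.temporal.qa_status])
                for name, value in sorted(v.static.covariates.items()):
                    w.writerow([p.patient_id, vi, "covariate", "", name, value])
                for label in sorted(v.static.outcomes):
                    w.writerow([p.patient_id, vi, "outcome", "", label, ""])
                for e in v.static.events:
                    w.writerow([p.patient_id, vi, "event", e.timestamp, e.code, e.event_type])
                for pt in v.temporal.points:
                    for name, value in pt.measurements:
                        w.writerow([p.patient_id, vi, "temporal", pt.time, name, repr(value)])


def _read_long_csv(path: Path) -> Dataset:
    schema: dict = {"variables": [], "labels": []}
    builders: dict[str, dict[int, dict]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        rows = csv.reader(fh)
        for i, row in enumerate(rows, start=1):
            if not row:
                continue
            if row[0] == "#format_version":
                schema = json.loads(row[2]) if row[2] else schema
                continue
            if row[0] == "patient_id":  # header
                continue
            if len(row) != len(_CSV_COLUMNS):
                raise DatasetFormatError(f"line {i}: expected {len(_CSV_COLUMNS)} columns")
            pid, vi_s, kind, time_s, name, value = row
            try:
                vi = int(vi_s)
            except ValueError as exc:
                raise DatasetFormatError(f"line {i}: bad visit index {vi_s!r}") from exc
            visit = builders.setdefault(pid, {}).setdefault(
                vi,
                {"visit_time": "", "qa": {}, "covariates": {}, "outcomes": set(),
                 "events": [], "temporal": {}},
            )
            if kind == "visit":
                visit["visit_time"] = value
            elif kind == "qa":
                visit["qa"][name] = value
            elif kind == "covariate":
                # CSV is untyped: recover numeric covariates (ints preferred)
                try:
                    visit["covariates"][name] = int(value)
                except ValueError:
                    try:
                        visit["covariates"][name] = float(value)
                    except ValueError:
                        visit["covariates"][name] = value
            elif kind == "outcome":
                visit["outcomes"].add(name)
            elif kind == "event":
                visit["events"].append(ClinicalEvent(name, int(time_s), value or "diagnosis"))
            elif kind == "temporal":
                fv = float(value)
                if not math.isfinite(fv):
                    raise DatasetFormatError(
                        f"line {i}: non-finite value for variable '{name}' of patient '{pid}'"
                    )
                visit["temporal"].setdefault(int(time_s), []).append((name, fv))
            else:
                raise DatasetFormatError(f"line {i}: unknown row kind {kind!r}")
    patients = []
    for pid in sorted(builders):
        visits = []
        for vi in sorted(builders[pid]):
            b = builders[pid][vi]
            events = sorted(b["events"], key=lambda e: e.timestamp)
            points = [TemporalPoint(t, b["temporal"][t]) for t in sorted(b["temporal"])]
            visits.append(
                Visit(
                    visit_time=b["visit_time"],
                    static=StaticEventData(
                        covariates=b["covariates"], outcomes=b["outcomes"], events=events,
                        qa_status=b["qa"].get("static", QA_RAW),
                    ),
                    temporal=TemporalSeries(points=points, qa_status=b["qa"].get("temporal", QA_RAW)),
                )
            )
        patients.append(PatientRecord(pid, visits))
    return Dataset(patients=patients, schema=schema)


def iter_events(d: Dataset) -> Iterable[tuple[str, int, ClinicalEvent]]:
    """Yield (patient_id, visit_idx, event) across the dataset in canonical order."""
    for p in d.patients:
        for vi, v in enumerate(p.visits):
            for e in v.static.events:
                yield p.patient_id, vi, e
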