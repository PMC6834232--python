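"""File formats and in-memory containers for oximetry signals and scored events.

Two formats are handled here:

* the app-dialect oximetry CSV — one row per sample at a fixed rate, with
  columns ``timestamp,spo2_pct,pulse_bpm,pi_pct`` (ISO-8601 timestamps,
  empty SpO2 field = missing sample).  This dialect is a documented
  stand-in for the vendor export, whose exact layout is not public; a
  converter from a real export only needs to produce these four columns.
* a JSON document of scored respiratory events (apnea/hypopnea with a
  central/obstructive mechanism label), standing in for the event list a
  scored home-sleep-test (polygraph) would produce.

Missing samples are carried as an explicit validity mask rather than a
sentinel value, because 0 is a plausible corrupt oximeter reading.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

APP_CSV_HEADER = ["timestamp", "spo2_pct", "pulse_bpm", "pi_pct"]

SPO2_MIN = 50
SPO2_MAX = 100

EVENT_TYPES = frozenset({"apnea", "hypopnea"})
MECHANISMS = frozenset({"central", "obstructive"})


@dataclass
class SpO2Trace:
    """A uniformly sampled SpO2 series with device metadata.

    Sample ``i`` covers the half-open interval ``[i/fs, (i+1)/fs)`` seconds
    from ``start_time``.  ``values`` holds integer percent saturation;
    entries where ``valid_mask`` is False are meaningless (dropouts,
    sensor-off segments) and must be ignored by every consumer.
    """

    device: str  # "app" or "polygraph"
    fs: float  # sampling rate, Hz
    start_time: datetime
    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape or self.values.ndim != 1:
            raise ValueError("values and valid_mask must be equal-length 1-D arrays")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.device not in ("app", "polygraph"):
            raise ValueError(f"unknown device {self.device!r}")
        v = self.values[self.valid_mask]
        if v.size and (v.min() < SPO2_MIN or v.max() > SPO2_MAX):
            raise ValueError(
                f"valid SpO2 values must lie in [{SPO2_MIN}, {SPO2_MAX}]"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        """Recording span in seconds (sample count over sampling rate)."""
        return self.values.size / self.fs

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass(frozen=True)
class RespiratoryEvent:
    """One scored apnea or hypopnea with its mechanism label."""

    onset_s: float
    duration_s: float
    type: str  # "apnea" | "hypopnea"
    mechanism: str  # "central" | "obstructive"

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration_s}")
        if self.type not in EVENT_TYPES:
            raise ValueError(
                f"event type {self.type!r} not in {sorted(EVENT_TYPES)}"
            )
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"mechanism {self.mechanism!r} not in {sorted(MECHANISMS)}; "
                "mixed or other labels must be resolved before loading"
            )

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


def validate_events(events: Sequence[RespiratoryEvent]) -> list[RespiratoryEvent]:
    """Sort events by onset and reject overlapping pairs."""
    ordered = sorted(events, key=lambda e: e.onset_s)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.onset_s < prev.end_s:
            raise ValueError(
                f"overlapping events: [{prev.onset_s}, {prev.end_s}) and "
                f"[{cur.onset_s}, {cur.end_s})"
            )
    return ordered


# ---------------------------------------------------------------------------
# App-dialect CSV
# ---------------------------------------------------------------------------

def write_app_csv(trace: SpO2Trace, path: str | Path) -> Path:
    """Write a trace in the app CSV dialect (one row per sample).

    Invalid samples are written with an empty SpO2 field; pulse and
    perfusion-index columns are left empty (they are not modelled).
    Round-trips bit-exactly through :func:`read_app_csv` for 1 Hz traces.
    """
    path = Path(path)
    step = timedelta(seconds=1.0 / trace.fs)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(APP_CSV_HEADER)
        t = trace.start_time
        for value, ok in zip(trace.values, trace.valid_mask):
            spo2 = f"{int(round(value))}" if ok else ""
            writer.writerow([t.isoformat(), spo2, "", ""])
            t = t + step
    return path


def read_app_csv(path: str | Path) -> SpO2Trace:
    """Read an app-dialect oximetry CSV into a 1 Hz trace.

    Every row becomes exactly one sample: blank, non-numeric, or zero SpO2
    fields are kept as invalid samples, never dropped, so the sample count
    always equals the row count.  Timestamps must be strictly increasing.
    """
    path = Path(path)
    values: list[float] = []
    mask: list[bool] = []
    start: datetime | None = None
    prev_ts: datetime | None = None
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != APP_CSV_HEADER:
            raise ValueError(
                f"{path}: malformed header {header!r}; expected columns "
                f"{','.join(APP_CSV_HEADER)}"
            )
        for i, row in enumerate(reader):
            if not row:
                continue
            ts = datetime.fromisoformat(row[0])
            if prev_ts is not None and ts <= prev_ts:
                raise ValueError(
                    f"{path}: non-monotonic timestamp at data row {i} ({row[0]})"
                )
            prev_ts = ts
            if start is None:
                start = ts
            raw = row[1].strip() if len(row) > 1 else ""
            try:
                spo2 = float(raw)
            except ValueError:
                spo2 = 0.0
            if raw == "" or spo2 == 0.0:
                values.append(np.nan)
                mask.append(False)
            else:
                values.append(spo2)
                mask.append(True)
    if start is None:
        start = datetime(2000, 1, 1)
    return SpO2Trace(
        device="app",
        fs=1,
        start_time=start,
        values=np.array(values, dtype=float),
        valid_mask=np.array(mask, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Respiratory-event JSON
# ---------------------------------------------------------------------------

def events_to_dicts(events: Iterable[RespiratoryEvent]) -> list[dict]:
    return [
        {
            "onset_s": e.onset_s,
            "duration_s": e.duration_s,
            "type": e.type,
            "mechanism": e.mechanism,
        }
        for e in events
    ]


def write_events(
    events: Sequence[RespiratoryEvent],
    path: str | Path,
    *,
    patient_id: str | None = None,
    extra: dict | None = None,
) -> Path:
    """Write scored events as a JSON document (sorted by onset)."""
    path = Path(path)
    doc: dict = {"events": events_to_dicts(validate_events(events))}
    if patient_id is not None:
        doc["patient_id"] = patient_id
    if extra:
        doc.update(extra)
    path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    return path


def read_events(path: str | Path) -> list[RespiratoryEvent]:
    """Read a scored-event JSON document.

    Accepts either a bare JSON array of event objects or a document with an
    ``events`` key.  Events are returned sorted by onset; overlapping events
    and unknown mechanism strings are rejected.
    """
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    raw = doc if isinstance(doc, list) else doc.get("events")
    if raw is None:
        raise ValueError(f"{path}: no 'events' array found")
    events = [
        RespiratoryEvent(
            onset_s=float(item["onset_s"]),
            duration_s=float(item["duration_s"]),
            type=str(item["type"]),
            mechanism=str(item["mechanism"]),
        )
        for item in raw
    ]
    return validate_events(events)
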