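"""Time-stamped process data historian.

Append-only in-memory store of sensor records with per-channel ordering
checks, half-open window queries, cycle segmentation from the event log,
spectral pre-processing and bit-exact CSV persistence.  Internally time is
seconds from campaign start; at the CSV boundary timestamps are ISO-8601 UTC
at 1 s resolution anchored at a configurable campaign epoch.
"""

from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "SensorRecord",
    "CycleRecord",
    "Spectrum",
    "Historian",
    "OrderingError",
    "HistorianLoadError",
    "DegenerateSpectrumError",
    "segment_cycles",
    "preprocess_spectrum",
    "export_events",
    "load_events",
    "export_spectra",
    "load_spectra",
]

EPOCH = datetime(2024, 1, 1, tzinfo=timezone.utc)


class OrderingError(ValueError):
    """A record's timestamp precedes the channel's last stored timestamp."""


class HistorianLoadError(ValueError):
    """A CSV row could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, msg: str):
        super().__init__(f"line {line}: {msg}")
        self.line = line


class DegenerateSpectrumError(ValueError):
    """SNV is undefined on a flat spectrum (sd = 0)."""


@dataclass(frozen=True)
class SensorRecord:
    t: float  # seconds from campaign start
    unit_id: str
    sensor_id: str
    value: float
    cycle_id: int | None = None


@dataclass
class CycleRecord:
    """All traces of one unit belonging to one cycle window [start, end)."""

    cycle_id: int
    unit_id: str
    start: float
    end: float
    traces: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    phase_boundaries: dict[str, float] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Spectrum:
    axis: np.ndarray
    intensity: np.ndarray
    t: float = 0.0
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape:
            raise ValueError("axis and intensity lengths differ")
        if len(self.axis) > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")


class _Channel:
    """Column store for one (unit, sensor) stream."""

    __slots__ = ("t", "value", "cycle")

    def __init__(self) -> None:
        self.t: list[float] = []
        self.value: list[float] = []
        self.cycle: list[int | None] = []


class Historian:
    """Append-only historian keyed by (unit_id, sensor_id) channels."""

    def __init__(self) -> None:
        self._channels: dict[tuple[str, str], _Channel] = {}
        self._count = 0

    def __len__(self) -> int:
        return self._count

    @property
    def channels(self) -> list[tuple[str, str]]:
        return sorted(self._channels)

    def append(self, record: SensorRecord) -> None:
        """Append one record; rejects out-of-order timestamps per channel."""
        ch = self._channels.setdefault((record.unit_id, record.sensor_id), _Channel())
        if ch.t and record.t < ch.t[-1]:
            raise OrderingError(
                f"channel ({record.unit_id}, {record.sensor_id}): "
                f"t={record.t} precedes last stored t={ch.t[-1]}"
            )
        if not np.isfinite(record.value):
            raise ValueError("sensor value must be finite")
        ch.t.append(float(record.t))
        ch.value.append(float(record.value))
        ch.cycle.append(record.cycle_id)
        self._count += 1

    def extend(self, unit_id: str, sensor_id: str, t: np.ndarray, values: np.ndarray) -> None:
        """Bulk append one channel's samples (vectorised ordering check)."""
        t = np.asarray(t, dtype=float)
        values = np.asarray(values, dtype=float)
        if t.shape != values.shape:
            raise ValueError("t and values lengths differ")
        if t.size == 0:
            return
        if np.any(np.diff(t) < 0):
            raise OrderingError(f"channel ({unit_id}, {sensor_id}): times not non-decreasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("sensor values must be finite")
        ch = self._channels.setdefault((unit_id, sensor_id), _Channel())
        if ch.t and t[0] < ch.t[-1]:
            raise OrderingError(
                f"channel ({unit_id}, {sensor_id}): t={t[0]} precedes last stored t={ch.t[-1]}"
            )
        ch.t.extend(t.tolist())
        ch.value.extend(values.tolist())
        ch.cycle.extend([None] * t.size)
        self._count += t.size

    def query(
        self,
        t0: float,
        t1: float,
        unit_id: str | None = None,
        sensor_id: str | None = None,
    ) -> list[SensorRecord]:
        """Records with t in the half-open window [t0, t1), time-ordered."""
        out: list[SensorRecord] = []
        for (uid, sid), ch in sorted(self._channels.items()):
            if unit_id is not None and uid != unit_id:
                continue
            if sensor_id is not None and sid != sensor_id:
                continue
            lo = bisect.bisect_left(ch.t, t0)
            hi = bisect.bisect_left(ch.t, t1)
            out.extend(
                SensorRecord(ch.t[i], uid, sid, ch.value[i], ch.cycle[i]) for i in range(lo, hi)
            )
        out.sort(key=lambda r: (r.t, r.unit_id, r.sensor_id))
        return out

    def channel_arrays(self, unit_id: str, sensor_id: str) -> tuple[np.ndarray, np.ndarray]:
        ch = self._channels.get((unit_id, sensor_id))
        if ch is None:
            return np.empty(0), np.empty(0)
        return np.asarray(ch.t), np.asarray(ch.value)

    def assign_cycle(self, unit_id: str, t0: float, t1: float, cycle_id: int) -> None:
        """Tag every record of ``unit_id`` in [t0, t1) with ``cycle_id``."""
        for (uid, _), ch in self._channels.items():
            if uid != unit_id:
                continue
            lo = bisect.bisect_left(ch.t, t0)
            hi = bisect.bisect_left(ch.t, t1)
            for i in range(lo, hi):
                ch.cycle[i] = cycle_id

    # -- persistence ------------------------------------------------------

    def export(self, path) -> None:
        """Write all records as CSV: timestamp, unit_id, sensor_id, value, cycle_id.

        Values are written with 17 significant digits so that load() is a
        bit-exact inverse; timestamps are ISO-8601 UTC at 1 s resolution with
        sub-second remainders carried in a fractional-seconds column.
        """
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["timestamp", "frac_s", "unit_id", "sensor_id", "value", "cycle_id"])
            for (uid, sid), ch in sorted(self._channels.items()):
                for t, v, c in zip(ch.t, ch.value, ch.cycle):
                    whole = int(t // 1)
                    frac = t - whole
                    ts = (EPOCH + timedelta(seconds=whole)).strftime("%Y-%m-%dT%H:%M:%SZ")
                    w.writerow([ts, repr(frac), uid, sid, repr(v), "" if c is None else c])

    @classmethod
    def load(cls, path) -> "Historian":
        store = cls()
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or header[:1] != ["timestamp"]:
                raise HistorianLoadError(1, "missing or malformed header")
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                try:
                    ts, frac, uid, sid, val, cyc = row
                    dt = datetime.strptime(ts, "%Y-%m-%dT%H:%M:%SZ").replace(tzinfo=timezone.utc)
                    t = (dt - EPOCH).total_seconds() + float(frac)
                    record = SensorRecord(t, uid, sid, float(val), int(cyc) if cyc else None)
                except (ValueError, TypeError) as exc:
                    raise HistorianLoadError(lineno, str(exc)) from exc
                store.append(record)
        return store

    def equals(self, other: "Historian") -> bool:
        if self.channels != other.channels:
            return False
        for key in self._channels:
            a, b = self._channels[key], other._channels[key]
            if a.t != b.t or a.value != b.value or a.cycle != b.cycle:
                return False
        return True


def export_spectra(spectra, path) -> None:
    """Write spectra as wide CSV: first column timestamp (s), remaining
    columns one per axis point.  All spectra must share one axis."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to export")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if not np.array_equal(s.axis, axis):
            raise ValueError("all spectra must share the same axis")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_s"] + [repr(float(a)) for a in axis])
        for s in spectra:
            w.writerow([repr(float(s.t))] + [repr(float(v)) for v in s.intensity])


def load_spectra(path) -> list[Spectrum]:
    """Inverse of :func:`export_spectra`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[:1] != ["t_s"]:
            raise HistorianLoadError(1, "missing or malformed header")
        axis = np.array([float(x) for x in header[1:]])
        out = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                out.append(Spectrum(axis=axis.copy(),
                                    intensity=np.array([float(x) for x in row[1:]]),
                                    t=float(row[0])))
            except (ValueError, TypeError) as exc:
                raise HistorianLoadError(lineno, str(exc)) from exc
    return out


def export_events(events, path) -> None:
    """Write an event log as CSV: timestamp, frac_s, source, trigger_id, action."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "frac_s", "source", "trigger_id", "action"])
        for e in events:
            whole = int(e.t // 1)
            ts = (EPOCH + timedelta(seconds=whole)).strftime("%Y-%m-%dT%H:%M:%SZ")
            w.writerow([ts, repr(e.t - whole), e.source, e.trigger_id, e.action])


def load_events(path) -> list:
    """Inverse of :func:`export_events`."""
    from .topology import Event

    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[:1] != ["timestamp"]:
            raise HistorianLoadError(1, "missing or malformed header")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                ts, frac, source, trig, action = row
                dt = datetime.strptime(ts, "%Y-%m-%dT%H:%M:%SZ").replace(tzinfo=timezone.utc)
                out.append(Event((dt - EPOCH).total_seconds() + float(frac), source, trig, action))
            except (ValueError, TypeError) as exc:
                raise HistorianLoadError(lineno, str(exc)) from exc
    return out


def segment_cycles(
    events,
    store: Historian,
    unit_id: str,
    sensors: list[str] | None = None,
    kind: str = "chromatography",
) -> tuple[list[CycleRecord], list[str]]:
    """Cut a unit's sensor streams into cycles from the event log.

    Chromatography cycles run from one ``load_start`` event to the next; the
    trailing window after the last ``load_start`` is incomplete and excluded
    (reported in the warnings list).  Filtration cycles run from a
    ``feed_start`` to the next ``feed_pause``.  Cycle ids are 1-based and
    campaign-global per unit; records in each window are tagged in the store.
    """
    warnings: list[str] = []
    ev = [e for e in events if e.source == unit_id]
    if kind == "chromatography":
        starts = sorted(e.t for e in ev if e.action == "load_start")
        if not starts:
            warnings.append(f"{unit_id}: no load_start events; no cycles segmented")
            return [], warnings
        windows = list(zip(starts[:-1], starts[1:]))
        if len(starts) >= 1:
            warnings.append(f"{unit_id}: trailing incomplete cycle after t={starts[-1]} excluded")
    elif kind == "filtration":
        starts = sorted(e.t for e in ev if e.action == "feed_start")
        pauses = sorted(e.t for e in ev if e.action == "feed_pause")
        windows = []
        for s in starts:
            nxt = [p for p in pauses if p > s]
            if nxt:
                windows.append((s, nxt[0]))
            else:
                warnings.append(f"{unit_id}: feed_start at t={s} has no matching pause; excluded")
    else:
        raise ValueError(f"unknown cycle kind {kind!r}")

    if sensors is None:
        sensors = sorted(sid for (uid, sid) in store.channels if uid == unit_id)
    cycles: list[CycleRecord] = []
    for i, (t0, t1) in enumerate(windows, start=1):
        rec = CycleRecord(cycle_id=i, unit_id=unit_id, start=t0, end=t1)
        for sid in sensors:
            tt, vv = store.channel_arrays(unit_id, sid)
            lo = np.searchsorted(tt, t0, side="left")
            hi = np.searchsorted(tt, t1, side="left")
            rec.traces[sid] = (tt[lo:hi], vv[lo:hi])
        store.assign_cycle(unit_id, t0, t1, i)
        cycles.append(rec)
    return cycles, warnings


def preprocess_spectrum(
    s: Spectrum,
    smooth: bool = True,
    window: int = 11,
    polyorder: int = 2,
    snv: bool = True,
    derivative: bool = False,
) -> Spectrum:
    """Standard spectral pre-processing pipeline.

    Ordered: Savitzky–Golay smoothing (default window 11, order 2) →
    standard normal variate (per-spectrum mean 0, sd 1) → optional first
    derivative along the axis.  Provenance flags record exactly which steps
    ran.
    """
    y = s.intensity.copy()
    steps: list[str] = []
    if smooth:
        if len(y) < window:
            raise ValueError(f"spectrum shorter than smoothing window {window}")
        y = savgol_filter(y, window_length=window, polyorder=polyorder)
        steps.append(f"savgol(w={window},p={polyorder})")
    if snv:
        sd = y.std(ddof=0)
        if sd < 1e-12 * max(1.0, abs(float(y.mean()))):
            raise DegenerateSpectrumError("flat spectrum: SNV undefined (sd = 0)")
        y = (y - y.mean()) / sd
        steps.append("snv")
    if derivative:
        y = np.gradient(y, s.axis)
        steps.append("d1")
    return Spectrum(axis=s.axis.copy(), intensity=y, t=s.t, provenance=s.provenance + tuple(steps))
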