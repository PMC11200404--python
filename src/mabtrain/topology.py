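"""Train topology, periodic counter-current scheduling and the trigger state machine.

The continuous train is a single chain of unit operations (clarification
through UF-DF) linked by surge tanks.  The programmable-logic layer of the
physical plant is replaced by a deterministic software state machine: named
triggers fire against the train state and every firing is appended to an
event log.  Hardware I/O protocols are carried as descriptive metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "UnitOp",
    "SurgeTankSpec",
    "TrainTopology",
    "ScheduleTrigger",
    "Event",
    "TopologyError",
    "ValidationError",
    "SchedulingError",
    "UNIT_KINDS",
    "UNIT_STATES",
    "PCC_PHASES",
    "build_topology",
    "default_config",
    "pcc_schedule",
    "fire_trigger",
]

UNIT_KINDS = (
    "clarification",
    "depth_filtration",
    "protein_a",
    "viral_inactivation",
    "sterile_filtration",
    "cex",
    "ufdf",
)
UNIT_STATES = ("running", "paused", "faulted", "idle")
CHROMATOGRAPHY_KINDS = ("protein_a", "cex")

#: canonical chromatography phase order for a PCC cycle
PCC_PHASES = ("load", "wash", "elute", "clean", "equilibrate")


class TopologyError(ValueError):
    """The unit/tank chain is not a single connected train."""


class ValidationError(ValueError):
    """A field value violates a type invariant."""


class SchedulingError(ValueError):
    """A PCC phase table cannot give gap-free continuous loading."""


@dataclass
class UnitOp:
    """One unit operation in the train.

    ``protocol`` is descriptive metadata (e.g. "Modbus 485") standing in for
    the physical I/O channel; it is never interpreted.
    """

    id: str
    kind: str
    state: str = "running"
    inlet_tank: str | None = None
    outlet_tank: str | None = None
    n_columns: int = 0
    standby_available: bool = False
    protocol: str = ""

    def __post_init__(self) -> None:
        if self.kind not in UNIT_KINDS:
            raise ValidationError(f"unknown unit kind {self.kind!r} for unit {self.id!r}")
        if self.state not in UNIT_STATES:
            raise ValidationError(f"unknown unit state {self.state!r}")
        if self.kind in CHROMATOGRAPHY_KINDS and self.n_columns < 1:
            raise ValidationError(
                f"chromatography unit {self.id!r} needs n_columns >= 1, got {self.n_columns}"
            )

    @property
    def is_chromatography(self) -> bool:
        return self.kind in CHROMATOGRAPHY_KINDS


@dataclass
class SurgeTankSpec:
    """Surge-tank set points.  All weights in grams of solution.

    Invariant: 0 <= w_min < w_restart_lo <= w_restart_hi < w_max <= capacity.
    """

    id: str
    capacity: float
    w_max: float
    w_min: float
    w_restart_lo: float
    w_restart_hi: float
    upstream_unit: str | None = None
    downstream_unit: str | None = None

    def __post_init__(self) -> None:
        ok = (
            0.0 <= self.w_min
            < self.w_restart_lo
            <= self.w_restart_hi
            < self.w_max
            <= self.capacity
        )
        if not ok:
            raise ValidationError(
                f"tank {self.id!r}: threshold ordering violated "
                f"(need 0 <= w_min < w_restart_lo <= w_restart_hi < w_max <= capacity; got "
                f"w_min={self.w_min}, w_restart_lo={self.w_restart_lo}, "
                f"w_restart_hi={self.w_restart_hi}, w_max={self.w_max}, capacity={self.capacity})"
            )


@dataclass
class TrainTopology:
    """An ordered chain of units with a surge tank between each pair."""

    units: list[UnitOp]
    tanks: list[SurgeTankSpec]
    campaign_duration_h: float = 60.0
    startup_duration_h: float = 7.0
    chrom_cycle_duration_min: float = 68.0
    ufdf_cycle_duration_h: float = 12.0

    def unit(self, unit_id: str) -> UnitOp:
        for u in self.units:
            if u.id == unit_id:
                return u
        raise KeyError(unit_id)

    def tank(self, tank_id: str) -> SurgeTankSpec:
        for t in self.tanks:
            if t.id == tank_id:
                return t
        raise KeyError(tank_id)

    def upstream_of(self, unit_id: str) -> UnitOp | None:
        idx = [u.id for u in self.units].index(unit_id)
        return self.units[idx - 1] if idx > 0 else None

    def downstream_of(self, unit_id: str) -> UnitOp | None:
        ids = [u.id for u in self.units]
        idx = ids.index(unit_id)
        return self.units[idx + 1] if idx + 1 < len(self.units) else None

    @property
    def n_chrom_cycles(self) -> int:
        """Whole chromatography cycles in the campaign (partial final cycle included
        as a full cycle when it covers >= half the cycle duration)."""
        return round(self.campaign_duration_h * 60.0 / self.chrom_cycle_duration_min)

    @property
    def n_ufdf_cycles(self) -> int:
        return round(self.campaign_duration_h / self.ufdf_cycle_duration_h)


@dataclass
class Event:
    """One event-log entry: seconds from campaign start, source id, trigger id, action."""

    t: float
    source: str
    trigger_id: str
    action: str


@dataclass
class ScheduleTrigger:
    """A linked trigger: when ``condition`` holds on the train state, apply ``action``.

    ``condition`` receives the mutable train-state mapping and returns bool.
    ``action`` is one of pause_unit / resume_unit / fault_unit / idle_unit /
    advance_phase / end_cycle, applied to ``target`` (defaults to ``source``).
    """

    id: str
    source: str
    condition: Callable[[Mapping], bool]
    action: str
    target: str | None = None


# legal state transitions per action
_TRANSITIONS = {
    "pause_unit": {"running": "paused"},
    "resume_unit": {"paused": "running", "idle": "running"},
    "fault_unit": {"running": "faulted", "paused": "faulted"},
    "idle_unit": {"running": "idle", "paused": "idle"},
    # phase bookkeeping actions do not change unit state
    "advance_phase": {s: s for s in UNIT_STATES},
    "end_cycle": {s: s for s in UNIT_STATES},
}


def fire_trigger(state: Mapping, trigger: ScheduleTrigger, t: float, log: list[Event]) -> bool:
    """Evaluate one trigger against the train state; apply its transition if true.

    ``state`` maps unit ids to :class:`UnitOp` under key ``"units"`` (plus any
    tank/weight entries the condition inspects).  Returns True when the trigger
    fired.  An illegal transition is rejected: the state is left untouched and
    a fault event is logged instead.
    """
    if not trigger.condition(state):
        return False
    target_id = trigger.target or trigger.source
    unit: UnitOp = state["units"][target_id]
    legal = _TRANSITIONS.get(trigger.action)
    if legal is None:
        raise ValidationError(f"unknown trigger action {trigger.action!r}")
    new_state = legal.get(unit.state)
    if new_state is None:
        log.append(Event(t, target_id, trigger.id, f"rejected:{trigger.action}"))
        return False
    unit.state = new_state
    log.append(Event(t, target_id, trigger.id, trigger.action))
    return True


def evaluate_triggers(
    state: Mapping, triggers: Iterable[ScheduleTrigger], t: float, log: list[Event]
) -> int:
    """Fire all triggers whose condition holds, in (id, source) order. Returns count fired."""
    fired = 0
    for trig in sorted(triggers, key=lambda tr: (tr.id, tr.source)):
        fired += fire_trigger(state, trig, t, log)
    return fired


def pcc_schedule(
    n_columns: int,
    phase_durations: Sequence[tuple[str, float]],
    t: float,
) -> dict[int, str]:
    """Per-column phase assignment of a periodic counter-current method at time ``t``.

    Columns rotate through the phase table; column ``k``'s schedule is column
    ``k-1``'s shifted by one load duration, so that at any instant exactly one
    column is loading.  That requires ``load_duration * n_columns == total
    cycle duration`` — otherwise continuous loading is impossible and a
    :class:`SchedulingError` is raised.
    """
    if n_columns < 1:
        raise ValidationError("n_columns must be >= 1")
    phases = [p for p, _ in phase_durations]
    durs = [float(d) for _, d in phase_durations]
    if any(d <= 0 for d in durs):
        raise ValidationError("phase durations must be positive")
    if "load" not in phases:
        raise SchedulingError("phase table has no load phase")
    order = {p: i for i, p in enumerate(PCC_PHASES)}
    if sorted(phases, key=lambda p: order.get(p, 99)) != phases:
        raise ValidationError(f"phases must follow the order {PCC_PHASES}")
    total = sum(durs)
    load = durs[phases.index("load")]
    if abs(load * n_columns - total) > 1e-9 * total:
        raise SchedulingError(
            f"continuous loading impossible: load duration {load} x {n_columns} columns "
            f"!= cycle duration {total}"
        )
    edges = []
    acc = 0.0
    for p, d in zip(phases, durs):
        edges.append((acc, acc + d, p))
        acc += d

    def phase_at(tau: float) -> str:
        tau = tau % total
        for lo, hi, p in edges:
            if lo <= tau < hi:
                return p
        return edges[-1][2]

    return {j: phase_at(t + j * load) for j in range(n_columns)}


DEFAULT_UNIT_CHAIN: tuple[tuple[str, str, dict], ...] = (
    ("clar", "clarification", {"protocol": "TCP/IP"}),
    ("depth", "depth_filtration", {"protocol": "Modbus 485"}),
    ("proa", "protein_a", {"n_columns": 3, "standby_available": True, "protocol": "TCP/IP"}),
    ("vi", "viral_inactivation", {"protocol": "RS-232"}),
    ("sterile", "sterile_filtration", {"protocol": "Modbus 485"}),
    ("cex", "cex", {"n_columns": 3, "standby_available": True, "protocol": "TCP/IP"}),
    ("ufdf", "ufdf", {"protocol": "Profibus"}),
)

DEFAULT_TANK_THRESHOLDS = dict(
    capacity=1000.0, w_max=800.0, w_min=150.0, w_restart_lo=300.0, w_restart_hi=600.0
)


def default_config() -> dict:
    """Structured config for the full default train (7 units, 6 tanks)."""
    units = []
    for uid, kind, extra in DEFAULT_UNIT_CHAIN:
        units.append({"id": uid, "kind": kind, **extra})
    tanks = []
    for a, b in zip(DEFAULT_UNIT_CHAIN[:-1], DEFAULT_UNIT_CHAIN[1:]):
        tanks.append(
            {
                "id": f"tank_{a[0]}_{b[0]}",
                "upstream_unit": a[0],
                "downstream_unit": b[0],
                **DEFAULT_TANK_THRESHOLDS,
            }
        )
    return {
        "units": units,
        "tanks": tanks,
        "campaign_duration_h": 60.0,
        "startup_duration_h": 7.0,
        "chrom_cycle_duration_min": 68.0,
        "ufdf_cycle_duration_h": 12.0,
        "proa_column_volume_ml": 16.7,
    }


def build_topology(config: Mapping | None = None) -> TrainTopology:
    """Build and validate a :class:`TrainTopology` from a structured config.

    With ``config=None`` the default full train is built: clarification,
    depth filtration, Protein A (3 columns, 16.7 mL each, standby available),
    viral inactivation, sterile filtration, CEX, UF-DF; six surge tanks; a
    60 h campaign with 7 h start-up and 68 min chromatography cycles.
    """
    if config is None:
        config = default_config()
    unit_cfgs = config.get("units")
    if not unit_cfgs:
        raise TopologyError("config lists no units")
    units = [
        UnitOp(
            id=u["id"],
            kind=u["kind"],
            n_columns=int(u.get("n_columns", 0)),
            standby_available=bool(u.get("standby_available", False)),
            protocol=u.get("protocol", ""),
        )
        for u in unit_cfgs
    ]
    tanks = [
        SurgeTankSpec(
            id=t["id"],
            capacity=float(t["capacity"]),
            w_max=float(t["w_max"]),
            w_min=float(t["w_min"]),
            w_restart_lo=float(t["w_restart_lo"]),
            w_restart_hi=float(t["w_restart_hi"]),
            upstream_unit=t.get("upstream_unit"),
            downstream_unit=t.get("downstream_unit"),
        )
        for t in config.get("tanks", [])
    ]
    # chain check: tank i must link unit i -> unit i+1
    if len(tanks) != len(units) - 1:
        raise TopologyError(
            f"{len(units)} units need {len(units) - 1} surge tanks, config has {len(tanks)}"
        )
    by_pair = {(t.upstream_unit, t.downstream_unit): t for t in tanks}
    for a, b in zip(units[:-1], units[1:]):
        tank = by_pair.get((a.id, b.id))
        if tank is None:
            raise TopologyError(f"missing surge tank between units {a.id!r} and {b.id!r}")
        a.outlet_tank = tank.id
        b.inlet_tank = tank.id
    return TrainTopology(
        units=units,
        tanks=tanks,
        campaign_duration_h=float(config.get("campaign_duration_h", 60.0)),
        startup_duration_h=float(config.get("startup_duration_h", 7.0)),
        chrom_cycle_duration_min=float(config.get("chrom_cycle_duration_min", 68.0)),
        ufdf_cycle_duration_h=float(config.get("ufdf_cycle_duration_h", 12.0)),
    )
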