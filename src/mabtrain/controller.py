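"""Rule-based supervisory control: alarms, diversion, standby switchover,
surge-tank cascade pause/restart and the closed monitoring-control loop.

Rules are data, not code: each maps a predicate over the latest cycle
assessment (status, which sensor dominates the residual, which unit) to an
ordered action list.  Operator interaction is scripted — every alarm is
acknowledged after a configurable delay — so closed-loop campaigns are
fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .historian import CycleRecord
from .monitor import (
    CHROM_SENSORS,
    UFDF_SENSORS,
    CycleAssessment,
    Monitor,
    merge_cycle_records,
)
from .simulator import CampaignResult, DeviationSpec, ProcessConfig, run_campaign
from .topology import TrainTopology

__all__ = [
    "ControlRule",
    "ControlAction",
    "AlarmRecord",
    "AlarmLog",
    "PendingAlarmError",
    "DEFAULT_RULES",
    "load_rules",
    "evaluate_rules",
    "cascade_pause",
    "cascade_restart",
    "ClosedLoopResult",
    "closed_loop",
]

ACTION_KINDS = (
    "raise_alarm",
    "divert_to_waste",
    "switch_standby_column",
    "pause_unit",
    "hold_schedule",
    "resume_unit",
    "request_operator_check",
)


@dataclass(frozen=True)
class ControlAction:
    kind: str
    target: str | None = None
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ACTION_KINDS:
            raise ValueError(f"unknown action kind {self.kind!r}")


@dataclass(frozen=True)
class ControlRule:
    """when: {group, dominant (sensor name), unit (optional)} -> actions.

    ``resolves`` names the deviation types this corrective action clears
    once the operator acknowledges the alarm.
    """

    id: str
    priority: int
    when: Mapping[str, str]
    actions: tuple[str, ...]
    target: str | None = None
    resolves: tuple[str, ...] = ()

    def matches(self, group: str, dominant_unit: str, dominant_sensor: str,
                status: str) -> bool:
        if status != self.when.get("status", "out_of_control"):
            return False
        if self.when.get("group", group) != group:
            return False
        want = self.when.get("dominant")
        if want is not None and want != dominant_sensor:
            return False
        want_unit = self.when.get("unit")
        if want_unit is not None and want_unit != dominant_unit:
            return False
        return True


# default rule store: reconstructed from the deviation-handling narratives —
# pressure/UV faults on a column get a standby switch and waste diversion,
# post-VI pH faults pause the neutralisation feed for an operator check,
# a conductivity-gradient fault diverts pools and holds the next elution.
DEFAULT_RULES: tuple[ControlRule, ...] = (
    ControlRule(
        id="chrom_pressure", priority=1,
        when={"group": "chrom", "status": "out_of_control", "dominant": "press"},
        actions=("raise_alarm", "switch_standby_column", "divert_to_waste"),
        resolves=("column_pressure_buildup",),
    ),
    ControlRule(
        id="chrom_uv", priority=2,
        when={"group": "chrom", "status": "out_of_control", "dominant": "uv"},
        actions=("raise_alarm", "switch_standby_column", "divert_to_waste"),
        resolves=("column_pressure_buildup", "valve_manifold_error"),
    ),
    ControlRule(
        id="chrom_post_vi_ph", priority=3,
        when={"group": "chrom", "status": "out_of_control", "dominant": "ph_load"},
        actions=("raise_alarm", "pause_unit", "request_operator_check"),
        target="vi",
        resolves=("neutralization_pump_error",),
    ),
    ControlRule(
        id="chrom_cond", priority=4,
        when={"group": "chrom", "status": "out_of_control", "dominant": "cond"},
        actions=("raise_alarm", "divert_to_waste", "hold_schedule"),
        resolves=("buffer_tank_empty",),
    ),
    ControlRule(
        id="chrom_pre_vi_ph", priority=5,
        when={"group": "chrom", "status": "out_of_control", "dominant": "ph",
              "unit": "proa"},
        actions=("raise_alarm", "divert_to_waste", "switch_standby_column"),
        resolves=("valve_manifold_error",),
    ),
    ControlRule(
        id="chrom_ph_other", priority=6,
        when={"group": "chrom", "status": "out_of_control", "dominant": "ph"},
        actions=("raise_alarm", "divert_to_waste", "request_operator_check"),
        resolves=("valve_manifold_error", "buffer_tank_empty"),
    ),
    ControlRule(
        id="ufdf_pressure", priority=7,
        when={"group": "ufdf", "status": "out_of_control"},
        actions=("raise_alarm", "request_operator_check"),
        resolves=("upstream_propagation",),
    ),
)


def load_rules(path) -> tuple[ControlRule, ...]:
    """Load a rule store from a YAML file (same schema as the packaged one)."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules = []
    for r in doc.get("rules", []):
        rules.append(
            ControlRule(
                id=r["id"], priority=int(r["priority"]), when=dict(r.get("when", {})),
                actions=tuple(r["actions"]), target=r.get("target"),
                resolves=tuple(r.get("resolves", ())),
            )
        )
    return tuple(rules)


def evaluate_rules(
    assessment: CycleAssessment,
    context: Mapping,
    rules: Sequence[ControlRule] = DEFAULT_RULES,
) -> list[ControlAction]:
    """Deterministic action list for one assessment.

    ``context`` needs ``group`` ("chrom" | "ufdf") and, for out-of-control
    assessments, ``dominant`` — the "unit:sensor" channel that dominates the
    residual contributions.  An in-control assessment yields no actions; the
    first matching rule (priority, then id order) supplies the action list.
    """
    if assessment.status != "out_of_control":
        return []
    dominant = context.get("dominant", "")
    d_unit, _, d_sensor = dominant.partition(":")
    group = context.get("group", "chrom")
    for rule in sorted(rules, key=lambda r: (r.priority, r.id)):
        if rule.matches(group, d_unit, d_sensor, assessment.status):
            target = rule.target or d_unit
            return [
                ControlAction(kind=a, target=target, params={"rule_id": rule.id})
                for a in rule.actions
            ]
    return []


# ------------------------------------------------------------- cascades


def cascade_pause(
    topo: TrainTopology,
    tank_weights: Mapping[str, float],
    unit_rates_g_min: Mapping[str, float],
    failed_unit: str,
    paused_units: Sequence[str] = (),
) -> list[tuple[str, float]]:
    """Reverse-order pause plan after a unit failure.

    The failed unit pauses immediately; each upstream unit keeps producing
    into its outlet tank and pauses when that tank reaches w_max — computed
    from the tank's headspace and the unit's output rate, propagating
    strictly upstream.  Returns (unit_id, pause_time_s) pairs with
    non-decreasing times along the upstream direction.  Downstream units are
    not part of the plan: they finish their current cycle and starve out.
    """
    if failed_unit in paused_units:
        return []
    ids = [u.id for u in topo.units]
    idx = ids.index(failed_unit)
    plan = [(failed_unit, 0.0)]
    t_down = 0.0
    for u in reversed(topo.units[:idx]):
        tank = topo.tank(u.outlet_tank)
        w = float(tank_weights.get(tank.id, 0.0))
        rate = float(unit_rates_g_min.get(u.id, 0.0))
        if rate <= 0:
            t_up = t_down  # no production: pauses with its consumer
        else:
            headspace = max(tank.w_max - w, 0.0)
            t_up = t_down + headspace / rate * 60.0
        plan.append((u.id, t_up))
        t_down = t_up
    return plan


class PendingAlarmError(RuntimeError):
    """Restart refused while an alarm is unacknowledged."""


def cascade_restart(
    topo: TrainTopology,
    tank_weights: Mapping[str, float],
    unit_rates_g_min: Mapping[str, float],
    repaired_unit: str,
    alarm_log: "AlarmLog | None" = None,
    one_cycle_mass_g: float = 0.0,
) -> list[tuple[str, float]]:
    """Downstream-propagating automatic restart plan.

    The repaired unit resumes at t=0; each downstream unit resumes once its
    inlet tank holds an acceptable weight — at least the restart floor and
    one cycle's worth of load — waiting for refill at the upstream unit's
    output rate where needed.  A tank already above the restart ceiling is
    restart-eligible immediately (resuming is what drains it).  Refuses to
    plan while any alarm is unacknowledged.
    """
    if alarm_log is not None and alarm_log.pending():
        raise PendingAlarmError(
            f"{len(alarm_log.pending())} unacknowledged alarm(s); restart refused"
        )
    ids = [u.id for u in topo.units]
    idx = ids.index(repaired_unit)
    plan = [(repaired_unit, 0.0)]
    t_up = 0.0
    upstream = topo.units[idx]
    for u in topo.units[idx + 1:]:
        tank = topo.tank(u.inlet_tank)
        w = float(tank_weights.get(tank.id, 0.0))
        needed = max(tank.w_restart_lo, one_cycle_mass_g)
        rate = float(unit_rates_g_min.get(upstream.id, 0.0))
        if w >= needed:
            t_d = t_up
        elif rate > 0:
            t_d = t_up + (needed - w) / rate * 60.0
        else:
            t_d = float("inf")  # cannot refill: deferred indefinitely
        plan.append((u.id, t_d))
        t_up = t_d
        upstream = u
    return plan


# ------------------------------------------------------------- alarms


@dataclass
class AlarmRecord:
    alarm_id: int
    t_raised: float
    description: str
    affected_cycles: tuple[int, ...]
    statistic: str  # e.g. "T2", "DModX", "univariate"
    acknowledged: bool = False
    operator_entry: str = ""
    t_signed: float | None = None


class AlarmLog:
    """Append-only alarm log with time-stamped operator signatures."""

    def __init__(self) -> None:
        self.records: list[AlarmRecord] = []

    def raise_alarm(self, t: float, description: str, affected_cycles, statistic: str
                    ) -> AlarmRecord:
        rec = AlarmRecord(
            alarm_id=len(self.records) + 1, t_raised=float(t),
            description=description, affected_cycles=tuple(affected_cycles),
            statistic=statistic,
        )
        self.records.append(rec)
        return rec

    def acknowledge(self, alarm_id: int, operator_entry: str, t: float) -> AlarmRecord:
        rec = next((r for r in self.records if r.alarm_id == alarm_id), None)
        if rec is None:
            raise KeyError(f"unknown alarm id {alarm_id}")
        if rec.acknowledged:
            raise ValueError(f"alarm {alarm_id} already acknowledged")
        if t < rec.t_raised:
            raise ValueError("acknowledgement cannot precede the alarm")
        rec.acknowledged = True
        rec.operator_entry = operator_entry
        rec.t_signed = float(t)
        return rec

    def pending(self) -> list[AlarmRecord]:
        return [r for r in self.records if not r.acknowledged]


# ------------------------------------------------------------- closed loop


@dataclass
class ClosedLoopResult:
    campaign: CampaignResult
    actions: list[tuple[float, str, ControlAction]]
    alarms: AlarmLog
    chrom_monitor: Monitor | None
    ufdf_monitor: Monitor | None

    @property
    def flagged_chrom_cycles(self) -> list[int]:
        if self.chrom_monitor is None:
            return []
        return sorted(a.cycle_id for a in self.chrom_monitor.assessments if a.out_of_control)


def closed_loop(
    topology: TrainTopology | None = None,
    schedule: Sequence[DeviationSpec] = (),
    seed: int = 0,
    cfg: ProcessConfig = ProcessConfig(),
    rules: Sequence[ControlRule] = DEFAULT_RULES,
    L: int | None = None,
    k: int | float = 3,
    alpha: float = 0.05,
    chrom_ref: tuple[int, int] = (7, 42),
    ufdf_ref: tuple[int, int] = (1, 4),
    ack_delay_min: float = 5.0,
    noise: bool = True,
) -> ClosedLoopResult:
    """Run the full loop: simulator → historian → monitor → rules → simulator.

    The chromatography reference model freezes after the reference window;
    every later cycle is assessed as soon as it completes and any matching
    rule's actions are executed — diversion applies to the flagged cycle's
    own elution pool, a standby switch clears column-bound faults, a post-VI
    pause is held for the scripted operator-acknowledgement delay (default
    5 min, within the surge tank's tolerance), after which the deviation is
    considered repaired.
    """
    if L is None:
        from .monitor import DEFAULT_LANDMARKS as L  # noqa: N806
    chrom_mon = Monitor(CHROM_SENSORS, L=L, k=k, alpha=alpha)
    ufdf_mon: Monitor | None = None
    alarms = AlarmLog()
    actions_log: list[tuple[float, str, ControlAction]] = []
    state = {"fitted": False, "ufdf_seen": 0}

    def hook(C, c: int):
        directives: dict = {}
        t_now = c * C.topo.chrom_cycle_duration_min * 60.0
        if c == chrom_ref[1]:
            merged = merge_cycle_records([C.proa_cycles, C.cex_cycles])
            chrom_mon.fit([r for r in merged if chrom_ref[0] <= r.cycle_id <= chrom_ref[1]])
            state["fitted"] = True
        elif state["fitted"] and c > chrom_ref[1]:
            merged = merge_cycle_records([C.proa_cycles[-1:], C.cex_cycles[-1:]])
            a = chrom_mon.refresh(merged[0])
            if a.out_of_control:
                dominant = chrom_mon.dominant_sensor(a)
                acts = evaluate_rules(a, {"group": "chrom", "dominant": dominant}, rules)
                directives.update(
                    _execute(acts, a, dominant, t_now, C, alarms, actions_log,
                             ack_delay_min, rules)
                )
        # UF-DF monitor: fit once the reference window's cycles are complete
        n_u = len(C.ufdf_cycles)
        nonlocal ufdf_mon
        if ufdf_mon is None and n_u >= ufdf_ref[1]:
            k_u = min(int(k) if not isinstance(k, float) else 3, ufdf_ref[1] - ufdf_ref[0] - 1)
            ufdf_mon = Monitor(UFDF_SENSORS, L=L, k=max(k_u, 1), alpha=alpha)
            ufdf_mon.fit([r for r in merge_cycle_records([C.ufdf_cycles])
                          if ufdf_ref[0] <= r.cycle_id <= ufdf_ref[1]])
            state["ufdf_seen"] = ufdf_ref[1]
        if ufdf_mon is not None and n_u > state["ufdf_seen"]:
            for rec in merge_cycle_records([C.ufdf_cycles[state["ufdf_seen"]:]]):
                a = ufdf_mon.refresh(rec)
                if a.out_of_control:
                    dominant = ufdf_mon.dominant_sensor(a)
                    acts = evaluate_rules(a, {"group": "ufdf", "dominant": dominant}, rules)
                    directives.update(
                        _execute(acts, a, dominant, t_now, C, alarms, actions_log,
                                 ack_delay_min, rules)
                    )
            state["ufdf_seen"] = n_u
        return directives

    campaign = run_campaign(
        topology=topology, schedule=schedule, seed=seed, cfg=cfg, noise=noise,
        cycle_hook=hook,
    )
    return ClosedLoopResult(
        campaign=campaign, actions=actions_log, alarms=alarms,
        chrom_monitor=chrom_mon if state["fitted"] else None, ufdf_monitor=ufdf_mon,
    )


def _execute(acts: list[ControlAction], a: CycleAssessment, dominant: str,
             t_now: float, C, alarms: AlarmLog, actions_log, ack_delay_min: float,
             rules) -> dict:
    """Apply one rule's actions; returns the simulator directives."""
    directives: dict = {}
    rule_id = acts[0].params.get("rule_id", "") if acts else ""
    rule = next((r for r in rules if r.id == rule_id), None)
    d_unit = dominant.partition(":")[0]
    stat = "T2" if a.t2 > a.dmodx else "DModX"
    # the scripted operator inspects the implicated equipment: corrective
    # actions are executed only when a matching fault is actually present;
    # an echo of residual process disturbance gets an alarm entry only
    fault_found = [
        d.scenario for d in C.schedule
        if rule is not None and d.type in rule.resolves
        and d.scenario not in C.resolved and d.active(a.cycle_id)
    ]
    for act in acts:
        if act.kind != "raise_alarm" and not fault_found:
            continue
        actions_log.append((t_now, rule_id, act))
        if act.kind == "raise_alarm":
            rec = alarms.raise_alarm(
                t_now,
                f"cycle {a.cycle_id}: out-of-control ({dominant} dominates residual)",
                [a.cycle_id], stat,
            )
            # acknowledged after the configured delay with the operator's entry
            entry = (f"checked {d_unit}; corrective action per rule {rule_id}"
                     if fault_found else
                     f"checked {d_unit}; no equipment fault found (residual disturbance)")
            alarms.acknowledge(rec.alarm_id, entry, t_now + ack_delay_min * 60.0)
            if fault_found:
                directives.setdefault("resolve_scenarios", []).extend(fault_found)
        elif act.kind == "divert_to_waste":
            if d_unit == "proa":
                directives["divert_proa"] = True
            else:
                directives["divert_cex"] = True
        elif act.kind == "switch_standby_column":
            if d_unit == "proa":
                directives["switch_standby"] = True
        elif act.kind == "pause_unit" and act.target == "vi":
            directives["pause_vi_min"] = ack_delay_min
        # hold_schedule / request_operator_check / resume_unit are log-only
    return directives
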