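"""Synthetic plant: multi-rate sensor data, surge-tank mass balances, deviations.

This module is the software stand-in for the physical continuous train.  It
generates per-cycle chromatography traces (UV, pH, conductivity, pressure)
for Protein A and CEX, the post-viral-inactivation neutralisation pH, UF-DF
feed/retentate/permeate pressures, clarification turbidity/cell density and
surge-tank weights, integrates a double-entry mAb mass balance, and injects
scheduled deviation scenarios (pressure build-up, neutralisation pump error,
buffer-tank emptying, valve-manifold error, upstream propagation into UF-DF).

Steady-state cycle-to-cycle variation is modelled as three independent
two-level common-cause factors with disjoint sensor footprints — harvest
lot (UV response), buffer lot (conductivity and pressure baselines) and pH
probe recalibration (pH offsets), each alternating between two levels on
its own fixed schedule — plus small per-sensor noise (iid Gaussian for
pH/conductivity/UV, AR(1) for pressures).  In-line sensors sample every
10 s; tank weights and UF-DF pressures every 60 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .historian import CycleRecord, Historian
from .topology import Event, SurgeTankSpec, TrainTopology, build_topology

__all__ = [
    "SensorTrace",
    "SurgeTankState",
    "DeviationSpec",
    "CampaignResult",
    "ProcessConfig",
    "DEVIATION_TYPES",
    "simulate_clarification",
    "simulate_chrom_cycle",
    "simulate_vi",
    "simulate_ufdf_cycle",
    "simulate_cqa_series",
    "simulate_atline_spectrum",
    "step_surge_tank",
    "inject_deviation",
    "run_campaign",
    "default_phase_durations",
]

# ------------------------------------------------------------------ types

DEVIATION_TYPES = (
    "column_pressure_buildup",
    "neutralization_pump_error",
    "buffer_tank_empty",
    "valve_manifold_error",
    "upstream_propagation",
)

_KNOWN_UNITS = {"clar", "depth", "proa", "vi", "sterile", "cex", "ufdf"}


@dataclass(frozen=True)
class SensorTrace:
    """One sensor's time series: strictly increasing times (s), finite values."""

    sensor_id: str
    unit_id: str
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")
        if self.sensor_id == "ph" and v.size and (v.min() < 0 or v.max() > 14):
            raise ValueError("pH out of [0, 14]")


@dataclass
class SurgeTankState:
    """Mutable state of one surge tank (well-mixed)."""

    spec: SurgeTankSpec
    weight: float  # g solution
    mab_mass: float = 0.0  # g mAb held
    inflow_rate: float = 0.0  # g/min solution
    outflow_rate: float = 0.0  # g/min solution
    inflow_conc: float = 0.0  # g mAb per g solution
    paused_upstream: bool = False
    paused_downstream: bool = False

    @property
    def concentration(self) -> float:
        """g mAb per g solution (≈ g/L at unit density)."""
        return self.mab_mass / self.weight if self.weight > 0 else 0.0


@dataclass(frozen=True)
class DeviationSpec:
    """One injected fault scenario.

    ``params`` carries the magnitude knobs of each type, e.g.
    ``ramp_bar_per_min`` and ``peak_area_factor`` for a column pressure
    build-up, ``ph_offset`` for a neutralisation pump error,
    ``plateau_fraction`` for an emptied elution-buffer tank, ``ph_spike`` /
    ``spike_minutes`` / ``yield_factor`` for a valve-manifold error, and
    ``load_factor`` / ``concentration_factor`` for upstream propagation into
    the UF-DF feed tank.  Cycle indices are chromatography cycles for the
    first four types and UF-DF cycles for ``upstream_propagation``.
    """

    scenario: int
    type: str
    unit: str
    onset_cycle: int
    end_cycle: int
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.type not in DEVIATION_TYPES:
            raise ValueError(f"unknown deviation type {self.type!r}")
        if self.onset_cycle > self.end_cycle:
            raise ValueError(
                f"scenario {self.scenario}: onset cycle {self.onset_cycle} "
                f"> end cycle {self.end_cycle}"
            )

    def active(self, cycle: int) -> bool:
        return self.onset_cycle <= cycle <= self.end_cycle


def inject_deviation(schedule: Sequence[DeviationSpec], spec: DeviationSpec) -> list[DeviationSpec]:
    """Return the schedule extended by ``spec``; overlapping specs compose."""
    if spec.unit not in _KNOWN_UNITS:
        raise ValueError(f"unknown target unit {spec.unit!r}")
    return list(schedule) + [spec]


@dataclass
class CampaignResult:
    historian: Historian
    events: list[Event]
    mass_audit: dict[str, float]
    seed: int
    chrom_cycles: dict[str, list[CycleRecord]] = field(default_factory=dict)
    ufdf_cycles: list[CycleRecord] = field(default_factory=list)
    ufdf_summaries: list[dict] = field(default_factory=list)
    pool_ledger: list[dict] = field(default_factory=list)

    @property
    def mass_balance_error(self) -> float:
        """Relative |in - (product + waste + holdup)| / in."""
        a = self.mass_audit
        total_in = a["total_in"]
        if total_in == 0:
            return 0.0
        out = a["to_product"] + a["to_waste"] + a["holdup"]
        return abs(total_in - out) / total_in


# ------------------------------------------------------------------ config


@dataclass(frozen=True)
class ProcessConfig:
    """Process-scale numbers.  Titer and Protein A column size follow the
    lab train (5.5 g/L, 3 x 16.7 mL columns); flow rates, pool sizes and
    tank thresholds are fixture defaults recorded here."""

    feed_solution_rate_g_h: float = 300.0
    feed_titer_g_per_kg: float = 0.0055  # 5.5 g/L at unit density
    proa_yield: float = 0.92
    proa_pool_mass_g: float = 100.0
    cex_yield: float = 0.95
    cex_pool_mass_g: float = 80.0
    ufdf_yield: float = 0.99
    ufdf_min_weight_g: float = 250.0
    vi_set_point_ph: float = 7.0
    binding_penalty_factor: float = 0.6
    binding_ph_tolerance: float = 0.5
    uv_response_au_s_per_g: float = 50.0
    uv_load_au_per_g: float = 0.1
    tank_initial_weight_g: float = 400.0
    ufdf_tank_initial_weight_g: float = 500.0
    # start-up (cycles within the start-up window): column-conditioning
    # signature on the traces — smaller, broader elution peaks and an
    # elevated pressure baseline, decaying cycle by cycle
    startup_area_penalty: float = 0.4
    startup_width_factor: float = 0.6
    startup_press_offset_bar: float = 0.15
    startup_decay_cycles: float = 2.0
    clar_chambers: int = 4
    clar_chamber_efficiency: float = 1.0 - 0.10**0.25  # (1-e)^4 = 0.10
    inlet_cell_density_e6_per_ml: float = 20.0
    # noise (stationary sd); pressures are AR(1) with the given coefficient
    noise_uv_au: float = 0.003
    noise_ph: float = 0.01
    noise_cond_ms_cm: float = 0.08
    noise_press_bar: float = 0.015
    noise_weight_g: float = 0.5
    noise_turbidity_frac: float = 0.02
    ar1_coeff: float = 0.8
    # smooth systematic steady-state drift (fixed phases: process property)
    drift_titer_amp: float = 0.05
    drift_titer_period_h: float = 24.0
    # three independent two-level common-cause factors with disjoint
    # sensor footprints: harvest lot (UV), buffer lot (conductivity and
    # pressure baselines), pH probe recalibration (pH); each alternates
    # between two levels on its own schedule
    drift_cond_amp_ms_cm: float = 0.3
    drift_press_amp_bar: float = 0.07
    drift_ph_amp: float = 0.03
    lot_titer_period_h: float = 17.0
    lot_titer_offset_h: float = 3.0
    lot_buffer_period_h: float = 11.0
    lot_buffer_offset_h: float = 5.0
    lot_ph_period_h: float = 26.0
    lot_ph_offset_h: float = 8.0
    # UF-DF transmembrane-pressure model
    tmp_per_g_l: float = 0.04
    tmp_progress_gain: float = 0.3


def _square(t_h: float, period_h: float, offset_h: float) -> float:
    """Two-level alternation (+1/-1) with the given period and phase offset."""
    return 1.0 if int(math.floor((t_h - offset_h) / period_h)) % 2 == 0 else -1.0


def _drift_titer(cfg: ProcessConfig, t_h: float) -> float:
    return 1.0 + cfg.drift_titer_amp * _square(t_h, cfg.lot_titer_period_h,
                                               cfg.lot_titer_offset_h)


def _buffer_lot(cfg: ProcessConfig, t_h: float) -> float:
    return _square(t_h, cfg.lot_buffer_period_h, cfg.lot_buffer_offset_h)


def _drift_ph(cfg: ProcessConfig, t_h: float) -> float:
    return cfg.drift_ph_amp * _square(t_h, cfg.lot_ph_period_h, cfg.lot_ph_offset_h)


def _drift_cond(cfg: ProcessConfig, t_h: float) -> float:
    return cfg.drift_cond_amp_ms_cm * _buffer_lot(cfg, t_h)


def _drift_press(cfg: ProcessConfig, t_h: float) -> float:
    return cfg.drift_press_amp_bar * _buffer_lot(cfg, t_h)


def default_phase_durations(cycle_s: float = 4080.0, n_columns: int = 3):
    """PCC phase table (seconds) with load = cycle/n so loading is continuous."""
    load = cycle_s / n_columns
    rest = cycle_s - load
    return [
        ("load", load),
        ("wash", rest * 0.25),
        ("elute", rest * 0.375),
        ("clean", rest * 0.22),
        ("equilibrate", rest * 0.155),
    ]


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * math.sqrt(1 - rho * rho), n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return x


# ------------------------------------------------------------------ unit ops


def simulate_clarification(
    per_chamber_efficiency: float,
    n_chambers: int,
    inlet_cell_density: float,
    duration_s: float,
    rng: np.random.Generator,
    dt_s: float = 10.0,
    noise_frac: float = 0.02,
) -> tuple[list[SensorTrace], float]:
    """Acoustic-wave clarification: serial chambers, each removing a fixed
    fraction of cells.  Total reduction = 1 - (1 - e)^n; the outlet turbidity
    trace scales with the surviving cell density."""
    if not 0.0 <= per_chamber_efficiency < 1.0:
        raise ValueError("per-chamber efficiency must be in [0, 1)")
    if n_chambers < 1:
        raise ValueError("n_chambers must be >= 1")
    reduction = 1.0 - (1.0 - per_chamber_efficiency) ** n_chambers
    t = np.arange(0.0, duration_s, dt_s)
    out_density = inlet_cell_density * (1.0 - reduction)
    turb_in = 100.0  # NTU at inlet, proportional to cell density
    turb_out = turb_in * (1.0 - reduction)
    mult1 = rng.normal(1.0, noise_frac, t.size) if noise_frac else np.ones(t.size)
    mult2 = rng.normal(1.0, noise_frac, t.size) if noise_frac else np.ones(t.size)
    traces = [
        SensorTrace("turbidity_out", "clar", t, np.clip(turb_out * mult1, 0, None)),
        SensorTrace("cell_density_out", "clar", t, np.clip(out_density * mult2, 0, None)),
    ]
    return traces, reduction


def simulate_vi(
    inlet_ph: np.ndarray | float | None,
    pump_ok: bool,
    pump_error_magnitude: float,
    rng: np.random.Generator,
    set_point: float = 7.0,
    noise_sd: float = 0.02,
    n: int | None = None,
) -> np.ndarray:
    """Post-viral-inactivation neutralisation pH.

    With a healthy Tris pump the output sits at the set point (default 7.0)
    plus sensor noise; a pump error shifts the whole trace by
    ``pump_error_magnitude`` pH units.
    """
    if n is None:
        n = int(np.size(inlet_ph)) if inlet_ph is not None else 1
    base = np.full(n, set_point, dtype=float)
    if not pump_ok:
        base += pump_error_magnitude
    if noise_sd:
        base = base + rng.normal(0.0, noise_sd, n)
    return np.clip(base, 0.0, 14.0)


def _phase_edges(phases: Sequence[tuple[str, float]]):
    edges, acc = {}, 0.0
    for p, d in phases:
        edges[p] = (acc, acc + d)
        acc += d
    return edges, acc


def _gauss_peak(t: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_chrom_cycle(
    unit: str,
    cycle_index: int,
    phases: Sequence[tuple[str, float]],
    load_mass_g: float,
    deviations: Sequence[DeviationSpec],
    rng: np.random.Generator,
    *,
    cfg: ProcessConfig = ProcessConfig(),
    t0_s: float = 0.0,
    post_vi_ph: float | None = None,
    dt_s: float = 10.0,
    noise: bool = True,
    startup_scale: float = 0.0,
) -> tuple[CycleRecord, dict]:
    """One chromatography cycle for ``unit`` in {"protein_a", "cex"}.

    Returns the cycle's traces plus a summary dict with the recovered mAb
    mass, pool solution mass and the multiplicative factors any active
    deviations applied.  The UV elution peak is Gaussian with area
    proportional to recovered mass; CEX elution carries a linear conductivity
    gradient (which plateaus early if the buffer tank empties); Protein A
    elution is a low-pH step followed by a caustic clean; pressures are
    baseline + AR(1) noise (plus a linear ramp under a column pressure
    build-up).
    """
    if unit not in ("protein_a", "cex"):
        raise ValueError(f"unknown chromatography unit {unit!r}")
    if load_mass_g < 0:
        raise ValueError("load mass must be >= 0")
    for d in deviations:
        if d.type not in DEVIATION_TYPES:
            raise ValueError(f"unknown deviation type {d.type!r}")

    edges, total = _phase_edges(phases)
    t = np.arange(0.0, total, dt_s)
    el0, el1 = edges["elute"]
    el_dur = el1 - el0
    active = [d for d in deviations if d.active(cycle_index)]

    def has(kind, target):
        return next((d for d in active if d.type == kind and d.unit == target), None)

    yield_factor = 1.0
    area_factor = 1.0
    uid = "proa" if unit == "protein_a" else "cex"

    def sd(s):
        return s if noise else 0.0

    rec = CycleRecord(cycle_id=cycle_index, unit_id=uid, start=t0_s, end=t0_s + total)
    rec.phase_boundaries = {p: t0_s + lo for p, (lo, _hi) in edges.items()}

    t_mid_h = (t0_s + total / 2) / 3600.0
    # the slow systematic drifts count as part of the stochastic environment:
    # the noise-free limit is the ideal, perfectly repeatable plant
    cond_drift = _drift_cond(cfg, t_mid_h) if noise else 0.0
    press_drift = _drift_press(cfg, t_mid_h) if noise else 0.0
    titer_f = _drift_titer(cfg, t_mid_h) if noise else 1.0
    ph_drift = _drift_ph(cfg, t_mid_h) if noise else 0.0
    # column conditioning during start-up: smaller, broader peaks and a
    # slightly elevated pressure baseline (trace-level signature only)
    su_area = 1.0 - cfg.startup_area_penalty * startup_scale
    su_width = 1.0 + cfg.startup_width_factor * startup_scale
    su_press = cfg.startup_press_offset_bar * startup_scale

    if unit == "protein_a":
        dev_p = has("column_pressure_buildup", "proa")
        dev_v = has("valve_manifold_error", "proa")
        if dev_p is not None:
            area_factor *= float(dev_p.params.get("peak_area_factor", 0.8))
        if dev_v is not None:
            yield_factor *= float(dev_v.params.get("yield_factor", 0.7))
        recovered = load_mass_g * cfg.proa_yield * area_factor * yield_factor
        # UV: baseline + elution peak, area proportional to recovered mass
        uv = np.full(t.size, 0.2)
        l0, l1 = edges["load"]
        uv[(t >= l0) & (t < l1)] += cfg.uv_load_au_per_g * load_mass_g
        uv += _gauss_peak(t, el0 + 0.5 * el_dur, el_dur / 8.0 * su_width,
                          recovered * cfg.uv_response_au_s_per_g * su_area)
        uv = uv * titer_f + rng.normal(0.0, sd(cfg.noise_uv_au), t.size)
        # pH: neutral load/wash, acidic elution, caustic clean
        ph = np.full(t.size, 7.4)
        ph[(t >= el0) & (t < el1)] = 3.6
        c0, c1 = edges["clean"]
        ph[(t >= c0) & (t < c1)] = 12.5
        if dev_v is not None:
            spike = float(dev_v.params.get("ph_spike", 2.0))
            sp0 = el0 + 0.3 * el_dur
            sp1 = sp0 + 60.0 * float(dev_v.params.get("spike_minutes", 3.0))
            ph[(t >= sp0) & (t < sp1)] += spike
        ph += ph_drift + rng.normal(0.0, sd(cfg.noise_ph), t.size)
        # conductivity: step profile + slow buffer drift
        cond = np.full(t.size, 5.0)
        cond[(t >= el0) & (t < el1)] = 15.0
        cond[(t >= c0) & (t < c1)] = 40.0
        cond += cond_drift + rng.normal(0.0, sd(cfg.noise_cond_ms_cm), t.size)
        # pressure: baseline + drift + AR(1); linear ramp under build-up
        press = np.full(t.size, 2.0) + press_drift + su_press
        press += _ar1(rng, t.size, sd(cfg.noise_press_bar), cfg.ar1_coeff)
        if dev_p is not None:
            press += float(dev_p.params.get("ramp_bar_per_min", 0.05)) * t / 60.0
        rec.traces = {
            "uv": (t0_s + t, uv),
            "ph": (t0_s + t, np.clip(ph, 0, 14)),
            "cond": (t0_s + t, cond),
            "press": (t0_s + t, press),
        }
        pool_mass = cfg.proa_pool_mass_g * yield_factor
    else:  # cex
        dev_b = has("buffer_tank_empty", "cex")
        load_ph = cfg.vi_set_point_ph if post_vi_ph is None else post_vi_ph
        binding = 1.0
        if abs(load_ph - cfg.vi_set_point_ph) > cfg.binding_ph_tolerance:
            binding = cfg.binding_penalty_factor
        if dev_b is not None:
            # a truncated gradient elutes only part of the bound product
            binding *= 0.5 + 0.5 * float(dev_b.params.get("plateau_fraction", 0.6))
        recovered = load_mass_g * cfg.cex_yield * binding
        uv = np.full(t.size, 0.2)
        l0, l1 = edges["load"]
        uv[(t >= l0) & (t < l1)] += cfg.uv_load_au_per_g * load_mass_g
        uv += _gauss_peak(t, el0 + 0.5 * el_dur, el_dur / 8.0 * su_width,
                          recovered * cfg.uv_response_au_s_per_g * su_area)
        uv = uv * titer_f + rng.normal(0.0, sd(cfg.noise_uv_au), t.size)
        # load-line pH = post-VI neutralisation pH, held across the cycle
        ph_load = np.full(t.size, load_ph) + ph_drift \
            + rng.normal(0.0, sd(cfg.noise_ph), t.size)
        # elution pH gradient 5 -> 8.5
        ph = np.full(t.size, 6.0)
        m = (t >= el0) & (t < el1)
        ph[m] = 5.0 + 3.5 * (t[m] - el0) / el_dur
        ph += ph_drift + rng.normal(0.0, sd(cfg.noise_ph), t.size)
        # conductivity: linear gradient 5 -> 25 mS/cm during elution;
        # an emptied buffer tank plateaus the ramp where it stopped
        cond = np.full(t.size, 5.0)
        ramp = 5.0 + 20.0 * (t[m] - el0) / el_dur
        if dev_b is not None:
            frac = float(dev_b.params.get("plateau_fraction", 0.6))
            ramp = np.minimum(ramp, 5.0 + 20.0 * frac)
        cond[m] = ramp
        cond += cond_drift + rng.normal(0.0, sd(cfg.noise_cond_ms_cm), t.size)
        press = np.full(t.size, 1.5) + press_drift + su_press
        press += _ar1(rng, t.size, sd(cfg.noise_press_bar), cfg.ar1_coeff)
        rec.traces = {
            "uv": (t0_s + t, uv),
            "ph_load": (t0_s + t, np.clip(ph_load, 0, 14)),
            "ph": (t0_s + t, np.clip(ph, 0, 14)),
            "cond": (t0_s + t, cond),
            "press": (t0_s + t, press),
        }
        pool_mass = cfg.cex_pool_mass_g
        yield_factor = binding

    info = {
        "recovered_mass_g": recovered,
        "waste_mass_g": load_mass_g - recovered,
        "pool_solution_g": pool_mass,
        "yield_factor": yield_factor,
        "area_factor": area_factor,
    }
    return rec, info


def simulate_ufdf_cycle(
    load_weight_g: float,
    load_concentration_g_l: float,
    min_weight_setpoint_g: float,
    rng: np.random.Generator,
    *,
    draw_rate_g_min: float = 80.0 / 68.0,
    dt_s: float = 60.0,
    t0_s: float = 0.0,
    noise_sd_bar: float = 0.02,
    ar1: float = 0.8,
    tmp_per_g_l: float = 0.04,
    tmp_progress_gain: float = 0.3,
) -> tuple[CycleRecord, dict]:
    """One batch UF-DF draw-down cycle.

    The feed pump draws the load at a fixed rate; the cycle ends exactly when
    the remaining weight falls below the minimum set point, i.e. after
    ``(load - setpoint) / rate`` minutes.  Transmembrane pressure (feed -
    permeate) is proportional to the instantaneous feed concentration and
    rises with the processed fraction, so a more dilute load gives lower TMP
    throughout.
    """
    if load_weight_g <= min_weight_setpoint_g:
        raise ValueError("load weight must exceed the minimum set point (empty cycle)")
    end_min = (load_weight_g - min_weight_setpoint_g) / draw_rate_g_min
    t = np.arange(0.0, end_min * 60.0, dt_s)
    progress = np.clip(t / (end_min * 60.0), 0.0, 1.0)
    conc = load_concentration_g_l * (1.0 + tmp_progress_gain * progress)
    tmp = tmp_per_g_l * conc
    permeate = 0.2 + _ar1(rng, t.size, noise_sd_bar, ar1)
    feed = permeate + tmp + _ar1(rng, t.size, noise_sd_bar, ar1)
    retentate = feed - 0.25 + _ar1(rng, t.size, noise_sd_bar / 2, ar1)
    rec = CycleRecord(cycle_id=0, unit_id="ufdf", start=t0_s, end=t0_s + end_min * 60.0)
    rec.traces = {
        "press_feed": (t0_s + t, feed),
        "press_retentate": (t0_s + t, retentate),
        "press_permeate": (t0_s + t, permeate),
    }
    drawn = load_weight_g - min_weight_setpoint_g
    info = {
        "end_time_min": end_min,
        "drawn_solution_g": drawn,
        "drawn_mab_g": load_concentration_g_l / 1000.0 * drawn,
    }
    return rec, info


def simulate_cqa_series(
    duration_h: float,
    rng: np.random.Generator,
    means: Mapping[str, float] | None = None,
    rel_sd: float = 0.02,
) -> dict[str, SensorTrace]:
    """Hourly at-line quality-attribute draws (HPLC-style discrete data).

    Each attribute is an independent noisy series around its mean — no
    chemistry model; meant for univariate mean ± k·SD charting.
    """
    if means is None:
        means = {"titer_g_l": 5.5, "monomer_pct": 98.5, "main_charge_pct": 65.0}
    t = np.arange(0.0, duration_h * 3600.0, 3600.0)
    out = {}
    for name, mu in means.items():
        vals = mu * (1.0 + rng.normal(0.0, rel_sd, t.size))
        out[name] = SensorTrace(name, "atline", t, vals)
    return out


def simulate_atline_spectrum(
    t_s: float,
    rng: np.random.Generator,
    n_points: int = 256,
    noise_sd: float = 0.01,
):
    """One synthetic at-line spectrum: a few Gaussian bands on a sloped
    baseline (shape only; no chemometric calibration model)."""
    from .historian import Spectrum

    axis = np.linspace(400.0, 1800.0, n_points)
    y = 0.2 + 1e-4 * (axis - 400.0)
    for center, width, height in ((1004.0, 12.0, 0.8), (1250.0, 40.0, 0.5),
                                  (1450.0, 25.0, 0.6), (1660.0, 18.0, 1.0)):
        y = y + height * np.exp(-0.5 * ((axis - center) / width) ** 2)
    y = y + rng.normal(0.0, noise_sd, n_points)
    return Spectrum(axis=axis, intensity=y, t=t_s)


def step_surge_tank(state: SurgeTankState, dt_s: float) -> tuple[SurgeTankState, list[str]]:
    """Advance one tank by ``dt_s`` seconds; returns (new state, events).

    Rates are g/min and honour the pause flags (paused upstream ⇒ inflow 0,
    paused downstream ⇒ outflow 0).  Emits ``pause_upstream_request`` on an
    upward crossing of w_max, ``pause_downstream_request`` on a downward
    crossing of w_min, ``restart_eligible`` on entering the restart range and
    an ``overflow_fault`` (weight clamped at capacity) on overflow.
    """
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    spec = state.spec
    inflow = 0.0 if state.paused_upstream else state.inflow_rate
    outflow = 0.0 if state.paused_downstream else state.outflow_rate
    dm_in = inflow * dt_s / 60.0
    dm_out = min(outflow * dt_s / 60.0, state.weight + dm_in)  # cannot overdraw
    w0 = state.weight
    w1 = w0 + dm_in - dm_out
    conc0 = state.mab_mass / w0 if w0 > 0 else state.inflow_conc
    mab_out = dm_out * conc0
    new = replace(
        state,
        weight=w1,
        mab_mass=state.mab_mass + dm_in * state.inflow_conc - mab_out,
    )
    events: list[str] = []
    if w1 > spec.capacity:
        events.append("overflow_fault")
        new.weight = spec.capacity
    if w0 <= spec.w_max < w1:
        events.append("pause_upstream_request")
    if w0 >= spec.w_min > w1:
        events.append("pause_downstream_request")
    in_range = spec.w_restart_lo <= new.weight <= spec.w_restart_hi
    was_in_range = spec.w_restart_lo <= w0 <= spec.w_restart_hi
    if in_range and not was_in_range:
        events.append("restart_eligible")
    return new, events


# ------------------------------------------------------------------ campaign


class _Campaign:
    """Internal mutable state of one campaign run."""

    def __init__(self, topo: TrainTopology, schedule, seed: int, dt_s: float,
                 cfg: ProcessConfig, noise: bool):
        self.topo = topo
        self.schedule = list(schedule)
        self.seed = int(seed)
        self.dt_s = dt_s
        self.cfg = cfg
        self.noise = noise
        self.store = Historian()
        self.events: list[Event] = []
        self.ledger = {"total_in": 0.0, "to_product": 0.0, "to_waste": 0.0}
        self.resolved: set[int] = set()
        self.standby_switched = False
        self.divert = {"proa": False, "cex": False}
        self.pause_log: list[dict] = []

        cyc_h = topo.chrom_cycle_duration_min / 60.0
        steady_load = cfg.feed_solution_rate_g_h * cyc_h * cfg.feed_titer_g_per_kg
        conc_mid = steady_load * cfg.proa_yield / cfg.proa_pool_mass_g
        cex_draw = cfg.proa_pool_mass_g  # g solution drawn by CEX per cycle
        conc_ufdf = cex_draw * conc_mid * cfg.cex_yield / cfg.cex_pool_mass_g
        prime = {
            "tank_clar_depth": cfg.feed_titer_g_per_kg,
            "tank_depth_proa": cfg.feed_titer_g_per_kg,
            "tank_proa_vi": conc_mid,
            "tank_vi_sterile": conc_mid,
            "tank_sterile_cex": conc_mid,
            "tank_cex_ufdf": conc_ufdf,
        }
        self.tanks: dict[str, SurgeTankState] = {}
        for t in topo.tanks:
            w0 = (cfg.ufdf_tank_initial_weight_g if t.id == "tank_cex_ufdf"
                  else cfg.tank_initial_weight_g)
            self.tanks[t.id] = SurgeTankState(
                spec=t, weight=w0, mab_mass=w0 * prime.get(t.id, 0.0)
            )
        self.initial_inventory = sum(st.mab_mass for st in self.tanks.values())
        self.ledger["total_in"] += self.initial_inventory
        self.weight_traces: dict[str, tuple[list, list]] = {
            tid: ([], []) for tid in self.tanks
        }
        self.tank_index = {t.id: i for i, t in enumerate(topo.tanks)}
        # cycle records accumulate here so a closed-loop hook can see them
        self.proa_cycles: list[CycleRecord] = []
        self.cex_cycles: list[CycleRecord] = []
        self.ufdf_cycles: list[CycleRecord] = []
        self.ufdf_summaries: list[dict] = []

    def active_devs(self, cycle: int) -> list[DeviationSpec]:
        out = []
        for d in self.schedule:
            if d.scenario in self.resolved or d.type == "upstream_propagation":
                continue
            # a standby switch clears column-bound faults only; a valve
            # manifold error is a system-level fault and persists
            if self.standby_switched and d.type == "column_pressure_buildup":
                continue
            if d.active(cycle):
                out.append(d)
        return out

    def prop_dev(self, ufdf_idx: int) -> DeviationSpec | None:
        for d in self.schedule:
            if (d.type == "upstream_propagation" and d.scenario not in self.resolved
                    and d.active(ufdf_idx)):
                return d
        return None

    def tank_step(self, tid: str, t_now: float, step_s: float, inflow_g_min: float,
                  outflow_g_min: float, inflow_conc: float) -> tuple[float, float]:
        """Step one tank, log its weight sample; returns (solution_out, mab_out) in g."""
        st = self.tanks[tid]
        st.inflow_rate, st.outflow_rate, st.inflow_conc = inflow_g_min, outflow_g_min, inflow_conc
        w0, m0 = st.weight, st.mab_mass
        new, evs = step_surge_tank(st, step_s)
        dm_in = (0.0 if st.paused_upstream else inflow_g_min) * step_s / 60.0
        dm_out = min((0.0 if st.paused_downstream else outflow_g_min) * step_s / 60.0,
                     w0 + dm_in)
        mab_out = m0 + dm_in * inflow_conc - new.mab_mass
        self.tanks[tid] = new
        for ev in evs:
            self.events.append(Event(t_now, tid, f"tank_{tid}", ev))
        self.weight_traces[tid][0].append(t_now)
        self.weight_traces[tid][1].append(new.weight)
        return dm_out, mab_out


def run_campaign(
    topology: TrainTopology | None = None,
    schedule: Sequence[DeviationSpec] = (),
    seed: int = 0,
    dt_s: float = 10.0,
    cfg: ProcessConfig = ProcessConfig(),
    noise: bool = True,
    cycle_hook=None,
) -> CampaignResult:
    """Simulate a full campaign, writing every sensor record and event to a
    historian and keeping a double-entry mAb mass ledger.

    The chromatography units run on a synchronised cadence (default 68 min).
    Clarified, depth-filtered harvest feeds the Protein A surge tank; the
    Protein A pool transits the viral-inactivation and sterile-filtration
    tanks (well-mixed) into the CEX feed; CEX pools accumulate in the UF-DF
    feed tank, which the UF-DF skid draws within each 12-h filtration window
    until its weight falls below the minimum set point.  Identical
    (topology, schedule, seed, dt) give an identical result.

    ``cycle_hook(state, cycle_index)`` is called after each completed
    chromatography cycle and may return control directives
    ({"divert_proa", "divert_cex", "switch_standby", "resolve_scenarios",
    "pause_vi_min"}) — the closed-loop controller's entry point.  The mass
    audit counts the primed tank inventory as part of ``total_in``.
    """
    topo = topology if topology is not None else build_topology()
    for d in schedule:
        inject_deviation([], d)  # validates type/unit/ordering

    C = _Campaign(topo, schedule, seed, dt_s, cfg, noise)
    n_cycles = topo.n_chrom_cycles
    cyc_s = topo.chrom_cycle_duration_min * 60.0
    cyc_min = cyc_s / 60.0
    campaign_s = n_cycles * cyc_s
    n_steps = int(round(cyc_min))
    phases = default_phase_durations(cyc_s, max(topo.unit("proa").n_columns, 1))
    n_startup = int(round(topo.startup_duration_h * 3600.0 / cyc_s))
    window_s = topo.ufdf_cycle_duration_h * 3600.0
    n_ufdf = topo.n_ufdf_cycles

    # clarification runs continuously; generated once for the whole campaign
    clar_rng = np.random.default_rng([C.seed, 10])
    clar_traces, clar_reduction = simulate_clarification(
        cfg.clar_chamber_efficiency, cfg.clar_chambers, cfg.inlet_cell_density_e6_per_ml,
        campaign_s, clar_rng, dt_s=dt_s,
        noise_frac=cfg.noise_turbidity_frac if noise else 0.0,
    )
    for tr in clar_traces:
        C.store.extend(tr.unit_id, tr.sensor_id, tr.t, tr.values)

    proa_cycles = C.proa_cycles
    cex_cycles = C.cex_cycles
    pool_ledger: list[dict] = []
    ufdf_cycles = C.ufdf_cycles
    ufdf_summaries = C.ufdf_summaries
    # elution pools sit in a collection vessel for one cycle before release,
    # so the controller can divert a flagged cycle's pool before it reaches
    # the downstream surge tank: (solution g, mAb g)
    staged_proa = (0.0, 0.0)
    staged_cex = (0.0, 0.0)
    # UF-DF feed state machine: one filtration cycle per 12-h window, ending
    # early if the feed-tank weight falls below the minimum set point
    ufdf = {"open": None, "done_window": 0}
    ufdf_tid = topo.unit("ufdf").inlet_tank
    draw_rate = cfg.cex_pool_mass_g / cyc_min  # g/min, matches nominal inflow

    def close_ufdf(tn: float):
        cur = ufdf["open"]
        if cur is None:
            return
        rec, summary = _materialise_ufdf(cur, cfg, C.seed, noise, tn)
        for sid, (tt, vv) in rec.traces.items():
            C.store.extend("ufdf", sid, tt, vv)
        C.events.append(Event(tn, "ufdf", "ufdf_feed", "feed_pause"))
        ufdf_cycles.append(rec)
        ufdf_summaries.append(summary)
        C.ledger["to_product"] += cur["drawn_mab"] * cfg.ufdf_yield
        C.ledger["to_waste"] += cur["drawn_mab"] * (1 - cfg.ufdf_yield)
        ufdf["done_window"] = cur["idx"]
        ufdf["open"] = None

    for c in range(1, n_cycles + 1):
        t0 = (c - 1) * cyc_s
        t_mid_h = (t0 + cyc_s / 2) / 3600.0
        feed_conc = cfg.feed_titer_g_per_kg
        feed_sol = cfg.feed_solution_rate_g_h * cyc_s / 3600.0  # g solution this cycle
        feed_mab = feed_sol * feed_conc
        C.ledger["total_in"] += feed_mab

        C.events.append(Event(t0, "proa", "pcc_load", "load_start"))
        C.events.append(Event(t0, "cex", "pcc_load", "load_start"))

        # harvest -> clarification -> depth filtration -> ProA feed tank
        # (flow-through for mAb: removed cells/debris carry no product)
        rate = feed_sol / cyc_min
        sol, mab = feed_sol, feed_mab
        for tid in ("tank_clar_depth", "tank_depth_proa"):
            conc_in = mab / sol if sol > 0 else 0.0
            out_s = out_m = 0.0
            for i in range(n_steps):
                s, m = C.tank_step(tid, t0 + i * 60.0, 60.0, rate, rate, conc_in)
                out_s += s
                out_m += m
            sol, mab = out_s, out_m
        proa_load_mab = mab

        # --- Protein A cycle
        devs = C.active_devs(c)
        su = math.exp(-(c - 1) / cfg.startup_decay_cycles) if c <= n_startup else 0.0
        rng_pa = np.random.default_rng([C.seed, 11, c])
        rec_pa, info_pa = simulate_chrom_cycle(
            "protein_a", c, phases, proa_load_mab, devs, rng_pa,
            cfg=cfg, t0_s=t0, dt_s=dt_s, noise=noise, startup_scale=su,
        )
        proa_cycles.append(rec_pa)
        for sid, (tt, vv) in rec_pa.traces.items():
            C.store.extend("proa", sid, tt, vv)
        C.ledger["to_waste"] += info_pa["waste_mass_g"]

        # --- viral inactivation / neutralisation pH (in-line sensor at VI exit)
        vi_devs = [d for d in devs if d.unit == "vi"]
        pump_ok = not any(d.type == "neutralization_pump_error" for d in vi_devs)
        offset = next(
            (float(d.params.get("ph_offset", -1.5)) for d in vi_devs
             if d.type == "neutralization_pump_error"), 0.0,
        )
        rng_vi = np.random.default_rng([C.seed, 12, c])
        n_vi = int(cyc_s // dt_s)
        vi_ph = simulate_vi(None, pump_ok, offset, rng_vi, set_point=cfg.vi_set_point_ph,
                            noise_sd=cfg.noise_ph if noise else 0.0, n=n_vi)
        C.store.extend("vi", "ph", t0 + np.arange(n_vi) * dt_s, vi_ph)
        post_vi_ph = cfg.vi_set_point_ph + (0.0 if pump_ok else offset)

        # last cycle's released ProA pool transits the VI and sterile tanks
        sol, mab = staged_proa
        mid_rate = cfg.proa_pool_mass_g / cyc_min
        for tid in ("tank_proa_vi", "tank_vi_sterile", "tank_sterile_cex"):
            conc_in = mab / sol if sol > 0 else 0.0
            in_rate = sol / cyc_min
            out_s = out_m = 0.0
            for i in range(n_steps):
                s, m = C.tank_step(tid, t0 + i * 60.0, 60.0, in_rate, mid_rate, conc_in)
                out_s += s
                out_m += m
            sol, mab = out_s, out_m
        cex_load_mab = mab

        # --- CEX cycle
        rng_cx = np.random.default_rng([C.seed, 13, c])
        rec_cx, info_cx = simulate_chrom_cycle(
            "cex", c, phases, cex_load_mab, devs, rng_cx,
            cfg=cfg, t0_s=t0, post_vi_ph=post_vi_ph, dt_s=dt_s, noise=noise,
            startup_scale=su,
        )
        cex_cycles.append(rec_cx)
        for sid, (tt, vv) in rec_cx.traces.items():
            C.store.extend("cex", sid, tt, vv)
        C.ledger["to_waste"] += info_cx["waste_mass_g"]
        cex_pool_mab = info_cx["recovered_mass_g"]
        cex_pool_sol = cfg.cex_pool_mass_g if cex_load_mab > 0 else 0.0

        # --- UF-DF feed tank: last cycle's released CEX pool flows in while
        # the skid draws down within its filtration window
        base_in_rate = staged_cex[0] / cyc_min
        base_in_conc = staged_cex[1] / staged_cex[0] if staged_cex[0] > 0 else 0.0
        for i in range(n_steps):
            tn = t0 + i * 60.0
            w_idx = int(tn // window_s) + 1
            cur = ufdf["open"]
            if cur is not None and tn >= cur["idx"] * window_s:
                close_ufdf(cur["idx"] * window_s)
                cur = None
            prop = C.prop_dev(w_idx) if w_idx <= n_ufdf else None
            in_rate, in_conc = base_in_rate, base_in_conc
            if prop is not None:
                lf = float(prop.params.get("load_factor", 0.6))
                cf = float(prop.params.get("concentration_factor", 0.8))
                lost = in_rate * in_conc * (1.0 - lf * cf)
                C.ledger["to_waste"] += lost  # g/min * 1 min steps
                in_rate, in_conc = in_rate * lf, in_conc * cf
            if cur is None and w_idx <= n_ufdf and ufdf["done_window"] < w_idx \
                    and C.tanks[ufdf_tid].weight > cfg.ufdf_min_weight_g:
                ufdf["open"] = cur = {"idx": w_idx, "t": [], "conc": [],
                                      "drawn_mab": 0.0, "drawn_sol": 0.0}
                C.events.append(Event(tn, "ufdf", "ufdf_feed", "feed_start"))
            drawing = cur is not None and C.tanks[ufdf_tid].weight > cfg.ufdf_min_weight_g
            s_out, m_out = C.tank_step(ufdf_tid, tn, 60.0, in_rate,
                                       draw_rate if drawing else 0.0, in_conc)
            if cur is not None:
                if drawing:
                    cur["t"].append(tn)
                    cur["conc"].append(1000.0 * m_out / s_out if s_out > 0 else 0.0)
                    cur["drawn_mab"] += m_out
                    cur["drawn_sol"] += s_out
                elif cur["t"]:
                    close_ufdf(tn)  # weight fell below the minimum set point

        # assessment hook runs before this cycle's pools are released, so a
        # flagged cycle's material can be diverted before the downstream tank
        if cycle_hook is not None:
            directives = cycle_hook(C, c) or {}
            C.divert["proa"] = bool(directives.get("divert_proa", False))
            C.divert["cex"] = bool(directives.get("divert_cex", False))
            if directives.get("switch_standby") and not C.standby_switched:
                C.standby_switched = True
                C.events.append(Event(t0 + cyc_s, "proa", "standby", "switch_standby_column"))
            for sc in directives.get("resolve_scenarios", []):
                C.resolved.add(int(sc))
            if directives.get("pause_vi_min"):
                C.pause_log.append(
                    {"t": t0 + cyc_s, "unit": "vi", "minutes": float(directives["pause_vi_min"])}
                )
                C.events.append(Event(t0 + cyc_s, "vi", "controller", "pause_unit"))
                C.events.append(
                    Event(t0 + cyc_s + float(directives["pause_vi_min"]) * 60.0,
                          "vi", "controller", "resume_unit")
                )

        # route this cycle's pools: release to the next stage or divert
        pool_mab, pool_sol = info_pa["recovered_mass_g"], info_pa["pool_solution_g"]
        if C.divert["proa"]:
            C.ledger["to_waste"] += pool_mab
            C.events.append(Event(t0 + cyc_s, "proa", "divert", "pool_to_waste"))
            pool_mab = pool_sol = 0.0
        staged_proa = (pool_sol, pool_mab)
        if C.divert["cex"]:
            C.ledger["to_waste"] += cex_pool_mab
            C.events.append(Event(t0 + cyc_s, "cex", "divert", "pool_to_waste"))
            cex_pool_mab = cex_pool_sol = 0.0
        staged_cex = (cex_pool_sol, cex_pool_mab)
        pool_ledger.append(
            {"cycle": c, "proa_load_g": proa_load_mab, "proa_pool_g": pool_mab,
             "cex_load_g": cex_load_mab, "cex_pool_g": cex_pool_mab}
        )

    close_ufdf(campaign_s)
    if n_cycles >= 1:
        # closing load_start marks the end of the last complete cycle
        C.events.append(Event(campaign_s, "proa", "pcc_load", "load_start"))
        C.events.append(Event(campaign_s, "cex", "pcc_load", "load_start"))

    # tank weight sensor records (60 s cadence), with measurement noise
    for tid, (tt, vv) in C.weight_traces.items():
        if not tt:
            continue
        rng_w = np.random.default_rng([C.seed, 14, C.tank_index[tid]])
        v = np.asarray(vv) + rng_w.normal(0.0, cfg.noise_weight_g if noise else 0.0, len(vv))
        C.store.extend(tid, "weight", np.asarray(tt), v)

    holdup = sum(st.mab_mass for st in C.tanks.values()) + staged_proa[1] + staged_cex[1]
    audit = {
        "total_in": C.ledger["total_in"],
        "initial_inventory": C.initial_inventory,
        "to_product": C.ledger["to_product"],
        "to_waste": C.ledger["to_waste"],
        "holdup": holdup,
        "clarification_reduction": clar_reduction,
    }
    C.events.sort(key=lambda e: (e.t, e.source, e.trigger_id, e.action))
    return CampaignResult(
        historian=C.store,
        events=C.events,
        mass_audit=audit,
        seed=C.seed,
        chrom_cycles={"proa": proa_cycles, "cex": cex_cycles},
        ufdf_cycles=ufdf_cycles,
        ufdf_summaries=ufdf_summaries,
        pool_ledger=pool_ledger,
    )


def _materialise_ufdf(state: dict, cfg: ProcessConfig, seed: int, noise: bool,
                      t_end: float) -> tuple[CycleRecord, dict]:
    """Build one UF-DF filtration cycle's pressure traces from the feed
    concentration profile accumulated while the pump was drawing."""
    t = np.asarray(state["t"], dtype=float)
    conc = np.asarray(state["conc"], dtype=float)
    idx = state["idx"]
    dur = (t[-1] + 60.0 - t[0]) if t.size else 0.0
    progress = (t - t[0]) / dur if dur > 0 else np.zeros_like(t)
    tmp = cfg.tmp_per_g_l * conc * (1.0 + cfg.tmp_progress_gain * progress)
    rng = np.random.default_rng([int(seed), 15, idx])
    sd = cfg.noise_press_bar if noise else 0.0
    permeate = 0.2 + _ar1(rng, t.size, sd, cfg.ar1_coeff)
    feed = permeate + tmp + _ar1(rng, t.size, sd, cfg.ar1_coeff)
    retentate = feed - 0.25 + _ar1(rng, t.size, sd / 2, cfg.ar1_coeff)
    rec = CycleRecord(
        cycle_id=idx, unit_id="ufdf",
        start=float(t[0]) if t.size else t_end, end=float(t_end),
    )
    rec.traces = {
        "press_feed": (t, feed),
        "press_retentate": (t, retentate),
        "press_permeate": (t, permeate),
    }
    summary = {
        "cycle": idx,
        "duration_h": dur / 3600.0,
        "drawn_mab_g": state["drawn_mab"],
        "drawn_solution_g": state["drawn_sol"],
        "mean_conc_g_l": float(conc.mean()) if conc.size else 0.0,
    }
    return rec, summary
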