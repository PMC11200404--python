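# Methods

## The simulated train

The default topology is a single chain of seven unit operations —
clarification (acoustic wave separator), depth filtration, Protein A
capture, viral inactivation (VI) with in-line Tris neutralisation, sterile
filtration, cation-exchange (CEX) polishing and single-pass UF-DF — with a
surge tank between every adjacent pair. The campaign runs 60 h: 53
chromatography cycles of 68 min (cycles 1–6 are the ≈7 h start-up) and five
12 h UF-DF filtration windows. Process-scale anchors follow the lab-scale
train the package emulates: harvest titer 5.5 g/L, three 16.7 mL Protein A
columns on a periodic counter-current schedule, four clarification chambers
in series sized for a 90% total cell-density reduction
((1−e)⁴ = 0.10 ⇒ e ≈ 0.438 per chamber). Flow rates, pool masses (100 g
Protein A pool, 80 g CEX pool per cycle), tank set points
(w_min 150 g < restart 300–600 g < w_max 800 g ≤ capacity 1000 g) and the
UF-DF minimum-weight set point (250 g) are fixture defaults recorded in
`ProcessConfig` and the packaged YAML config; they are chosen for a
self-consistent desk-scale balance, not measured values.

Mass is tracked as grams of antibody in a double-entry ledger: feed +
primed tank inventory = product + waste + holdup, exact to float precision
on every campaign (the audit is asserted at 10⁻⁶ relative). Tanks are
well-mixed; transfers integrate at 60 s steps. Elution pools sit in a
collection vessel for one cycle before release so the controller can divert
a flagged cycle's own material — this is what makes the "no flagged
material in the product ledger" guarantee exact rather than approximate.

The simulator starts from a primed train (tanks at steady concentration)
and keeps mass flows steady from t = 0; the start-up window appears as a
column-conditioning signature on the traces (smaller, broader elution
peaks, elevated pressure baseline, decaying over cycles 1–6). This choice
keeps the reference window free of slow tank-chain transients; a cold-start
mass transient would otherwise smear through five well-mixed tanks with a
multi-hour time constant and leak into the monitoring reference.

## Steady-state variability model

Cycle-to-cycle common-cause variation is modelled as three independent
**two-level factors with disjoint sensor footprints**, plus per-sensor
noise:

| factor | footprint | magnitude | alternation |
|---|---|---|---|
| harvest lot | all UV landmarks (multiplicative) | ±5% | every 17 h |
| buffer lot | conductivity ±0.3 mS/cm, pressure ±0.07 bar | — | every 11 h |
| pH recalibration | all pH channels | ±0.03 pH | every 26 h |

Noise: UV 3 mAU, pH 0.01, conductivity 0.08 mS/cm iid Gaussian; pressures
AR(1) (coefficient 0.8, stationary sd 0.015 bar); tank weights 0.5 g. The
UV detector baseline is 0.2 AU so that every UV landmark carries the lot
factor — noise shares are deliberately even (≈0.05–0.2 of column variance)
across all features.

This structure is a deliberate design, for two reasons. First, two-level
lot/shift changes (feed bags, buffer batches, probe recalibrations) are the
dominant real steady-state disturbances at lab scale. Second, they make the
monitoring statistics well-calibrated at a 36-cycle reference: binary
scores give every cycle nearly the same leverage (T² ≈ 3), so the
PC-estimation leak into residuals is constant and absorbed into s0, and new
in-control cycles stay below the DModX limit. Smooth drifts with extremes
(e.g. sinusoids) instead concentrate leverage in a few cycles and push
their prediction residuals past the F-limit — a general small-n property
of SIMCA-style DModX, not a feature of this plant. `noise=False` disables
both the noise and the lot factors, giving a perfectly repeatable ideal
plant (used by the trace-level invariance tests).

The harvest-lot factor is applied to the UV *traces* (detector response)
while the mass ledger uses the nominal feed rate; propagating ±5% titer
through the tank chain would add lagged copies of the factor and raise the
systematic rank above the model's k = 3. This is the one place the sensor
layer and the ledger are intentionally decoupled.

## Deviation scenarios

The packaged schedule injects five faults, all gross equipment failures
(tens of reference SDs, as real column leaks and stopped pumps are):
pressure ramp 0.05 bar/min with a 0.8 peak-area factor (chromatography
cycles 43–45); VI neutralisation offset −1.5 pH with a 0.6 CEX
binding-efficiency factor when the load pH is off by > 0.5 (43–45);
CEX conductivity gradient plateau at 60% of the programmed ramp with a
proportional recovery loss (45–47); elution pH spike +2.0 for 3 min with a
0.7 yield factor (50–51); and UF-DF feed starvation in filtration cycle 5
(inflow ×0.6, concentration ×0.8), which composes with the mechanical
propagation of the upstream yield losses. Scenario magnitudes are physical
fixture choices; effects compose additively where physical. The UF-DF cycle
ends exactly when its feed-tank weight crosses the minimum set point, so
the starved cycle 5 is both shorter and runs at visibly lower
transmembrane pressure (TMP = 0.04 bar·L/g × feed concentration, rising
30% over the processed fraction).

## Monitoring conventions

* Landmarks: each trace is linearly interpolated onto **L = 15** equispaced
  points over its own cycle window; features concatenated sensor-major
  (chromatography: 9 channels over Protein A + CEX, p = 135; UF-DF: 3
  pressure channels, p = 45). L is a parameter; 15 is the default because
  at n_ref = 36 the DModX F-limit's headroom must exceed the irreducible
  prediction-leverage inflation ((k+1)/n ≈ 0.11): at p = 135 the headroom
  is ≈ 0.20, while at p ≈ 450 it shrinks to ≈ 0.11 and about half of all
  in-control monitored cycles would flag spuriously. Detection is
  insensitive to L at these fault magnitudes.
* Autoscaling uses the reference window only; zero-variance columns are
  scaled by 1 and flagged.
* PCA is SVD-based, k = 3 components by default (a cumulative
  variance-fraction rule is available); loadings signed so each vector's
  largest-magnitude element is positive.
* Limits at α = 0.05: T² and DModX as in the README. The chromatography
  reference is cycles 7–42, frozen thereafter; the UF-DF reference is
  cycles 1–4 with k capped at n_ref − 2.
* Phase I / Phase II semantics: reference cycles are re-assessed for the
  charts and a calibration check (at most ⌈α·n⌉+1 may exceed their own
  limits), but monitoring proper starts after the reference freezes — the
  "first out-of-control cycle" of a campaign is the first flagged
  *monitored* cycle. This is the standard batch-MSPC reading; the training
  window cannot be under surveillance against limits it defined.
* Root-cause attribution: squared residual contributions summed per
  sensor; ties broken by sensor id order.

## Controller

Rules are data (`config/rules.yaml`): a predicate over (status, dominant
sensor, unit) mapping to an ordered action list — pressure/UV-dominated
faults get `raise_alarm, switch_standby_column, divert_to_waste`; a post-VI
pH fault pauses the neutralisation feed for an operator check (the pause,
one acknowledgement delay of 5 min by default, stays far inside the surge
tank's buffer); a conductivity-gradient fault diverts pools and holds the
next elution. Operator interaction is scripted for reproducibility: every
alarm is acknowledged after the configured delay, and corrective actions
execute only when the inspection finds a matching active fault — an echo
flag from still-equilibrating material gets an alarm entry only. A standby
switch clears column-bound faults but not system-level valve faults. The
cascade planners are pure arithmetic on tank states: pause times propagate
upstream as headspace/rate, restart times downstream as refill-to-floor
time, where the floor is max(w_restart_lo, one cycle's load mass). A tank
above the restart ceiling is treated as restart-eligible, since resuming
the consumer is the only way it can drain.

## What the generator does and does not emulate

It emulates the multi-rate, multi-channel, cycle-structured character of
train data, realistic fault signatures, lot-level common-cause variation
and the mass-routing consequences of control actions. It does not emulate
mechanistic chromatography (no general rate model: elution peaks are
Gaussians with area ∝ recovered mass), filter fouling, biochemical CQAs, or
spectral chemistry (the pre-processing pipeline is implemented; the spectra
themselves are synthetic shapes). Passing tests therefore demonstrate the
correctness and calibration of the data path, statistics and control
logic — not predictive fidelity to any particular physical column.

## Known limitations

* The UF-DF monitor's reference holds only 4 cycles; with n = 4 the DModX
  F-limit is unavoidably anti-conservative for prediction (inflation
  ≈ 1+(k+1)/n), so on a fault-free campaign the fifth filtration cycle can
  be weakly flagged (≈1.3–1.5× vs the limit) from prediction-variance alone.
  Under the packaged schedule the genuine deviation sits at ≈10× the limit,
  an order of magnitude away from this floor. False-alarm calibration is
  therefore assessed on the chromatography monitor.
* With 68-min cycles and start-up ≈ cycles 1–6, the first fault at cycle 43
  begins 47.6 h into the campaign; the alarm-free operating span is
  reported from campaign start (47.6 h ≈ 48 h at print precision).
* Trigger evaluation, tank integration (60 s) and pool routing are
  cycle-granular; sub-minute control dynamics are out of scope.
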