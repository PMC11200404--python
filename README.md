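# mabtrain

Closed-loop simulation, monitoring and supervisory control of a continuous
monoclonal-antibody (mAb) production train.

Continuous bioprocessing chains perfusion harvest, clarification, Protein A
capture on a periodic counter-current (PCC) column schedule, low-pH viral
inactivation, cation-exchange (CEX) polishing and single-pass
ultrafiltration/diafiltration (UF-DF) into one always-running line, with
surge tanks buffering each pair of steps. Operating such a train requires
three software layers that this package implements end to end, with a
synthetic plant standing in for the physical equipment:

* **Plant simulator** (`mabtrain.simulator`) — multi-rate sensor traces (UV,
  pH, conductivity, pressure, tank weights, turbidity), surge-tank mass
  balances with a double-entry product ledger, and an injectable fault
  schedule (column pressure build-up, neutralisation pump error, emptied
  elution-buffer tank, valve-manifold error, starved UF-DF feed).
* **Historian** (`mabtrain.historian`) — an append-only, time-stamped store
  with half-open window queries, cycle segmentation from the event log
  (chromatography: load-start to next load-start; filtration: feed-pump
  start to pause), spectral pre-processing (Savitzky–Golay → SNV) and
  bit-exact CSV persistence.
* **Monitor + controller** (`mabtrain.monitor`, `mabtrain.controller`) —
  cycle-wise multivariate statistical process control and a rule store that
  maps flagged cycles to corrective actions (alarms, standby-column
  switchover, divert-to-waste, schedule holds, reverse-order cascade pause
  and automatic restart), closing the loop back into the simulator.

The package is intended for process-analytics and automation developers who
want a reproducible, fully synthetic testbed for cycle-based MSPC and
surge-tank control logic.

## Monitoring model

Each completed cycle is resampled onto L landmarks per sensor and stacked
into a vector x ∈ ℝᵖ (p = n_sensors × L), autoscaled with the reference
window's column means and standard deviations. A PCA model with k
components (loadings P, score standard deviations s_a, residual scale s0)
is fitted once on the steady-state reference cycles and frozen. For every
cycle,

* scores t = Pᵀx and Hotelling **T² = Σ_a (t_a/s_a)²**, with limit
  k(n²−1)/(n(n−k)) · F₁₋α(k, n−k);
* **DModX = √(RSS/(p−k)) / s0**, with s0² = RSS_ref/((n−k−1)(p−k)) and
  limit √F₁₋α(p−k, (n−k−1)(p−k)) (SIMCA convention);

a cycle is out of control when either statistic exceeds its limit; squared
per-feature residuals (contribution plots) attribute the deviation to a
sensor, which selects the control rule. Univariate mean ± k·SD charts are
provided for discrete at-line series.

## Worked example

`examples/monitor_deviations.py` runs the packaged 60 h campaign (53
chromatography cycles of 68 min, start-up cycles 1–6, five UF-DF windows of
12 h) with the five-scenario fault schedule and monitors it against a
reference model fitted on cycles 7–42:

```
first out-of-control chromatography cycle : 43
all flagged chromatography cycles         : [43, 44, 45, 46, 47, 48, 49, 50, 51, 52, 53]
flagged UF-DF cycles                      : [5]
alarm-free span before first flag         : 47.6 h
  cycle 42: T2=    2.3  DModX=  0.92  in_control
  cycle 43: T2=  388.2  DModX= 69.01  out_of_control
```

Cycle 43 is the onset of the pressure build-up and neutralisation-pump
scenarios: T² and DModX jump two orders of magnitude above their 95%
limits, while every reference cycle sits far below them. The UF-DF chart
flags only the final filtration cycle, whose feed tank was starved and
diluted by the upstream losses — it ends early on the minimum-weight
trigger with visibly lower transmembrane pressure. The other examples
demonstrate the mass-balance audit, the PCC rotation table, historian round
trips, the surge-tank cascade planners and the full closed loop with
scripted operator acknowledgements.

A thin CLI wraps the same functions:

```
mabtrain simulate --seed 1 --out run1        # historian + event CSVs
mabtrain monitor run1 --out mon1             # assessments CSV + charts
mabtrain closed-loop --seed 1 --out loop1    # + action and alarm logs
```

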