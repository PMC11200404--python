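# Five-scenario deviation schedule for the 60 h campaign.  Cycle indices are
# chromatography cycles for scenarios 1-4 and UF-DF filtration cycles for
# scenario 5.  Magnitudes are fixture choices sized to gross equipment
# faults (a leaking column, a stopped neutralisation pump, an empty elution
# buffer tank, stuck manifold valves, and the resulting starved UF-DF feed).
deviations:
  - scenario: 1
    type: column_pressure_buildup
    unit: proa
    onset_cycle: 43
    end_cycle: 45
    params: {ramp_bar_per_min: 0.05, peak_area_factor: 0.8}
  - scenario: 2
    type: neutralization_pump_error
    unit: vi
    onset_cycle: 43
    end_cycle: 45
    params: {ph_offset: -1.5}
  - scenario: 3
    type: buffer_tank_empty
    unit: cex
    onset_cycle: 45
    end_cycle: 47
    params: {plateau_fraction: 0.6}
  - scenario: 4
    type: valve_manifold_error
    unit: proa
    onset_cycle: 50
    end_cycle: 51
    params: {ph_spike: 2.0, spike_minutes: 3, yield_factor: 0.7}
  - scenario: 5
    type: upstream_propagation
    unit: ufdf
    onset_cycle: 5
    end_cycle: 5
    params: {load_factor: 0.6, concentration_factor: 0.8}
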