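# Default rule store for the supervisory controller.  Rules are evaluated in
# (priority, id) order; the first match supplies the ordered action list.
# "dominant" names the sensor whose features dominate the residual
# contributions of the flagged cycle; "unit" optionally restricts the match.
rules:
  - id: chrom_pressure
    priority: 1
    when: {group: chrom, status: out_of_control, dominant: press}
    actions: [raise_alarm, switch_standby_column, divert_to_waste]
    resolves: [column_pressure_buildup]
  - id: chrom_uv
    priority: 2
    when: {group: chrom, status: out_of_control, dominant: uv}
    actions: [raise_alarm, switch_standby_column, divert_to_waste]
    resolves: [column_pressure_buildup, valve_manifold_error]
  - id: chrom_post_vi_ph
    priority: 3
    when: {group: chrom, status: out_of_control, dominant: ph_load}
    actions: [raise_alarm, pause_unit, request_operator_check]
    target: vi
    resolves: [neutralization_pump_error]
  - id: chrom_cond
    priority: 4
    when: {group: chrom, status: out_of_control, dominant: cond}
    actions: [raise_alarm, divert_to_waste, hold_schedule]
    resolves: [buffer_tank_empty]
  - id: chrom_pre_vi_ph
    priority: 5
    when: {group: chrom, status: out_of_control, dominant: ph, unit: proa}
    actions: [raise_alarm, divert_to_waste, switch_standby_column]
    resolves: [valve_manifold_error]
  - id: chrom_ph_other
    priority: 6
    when: {group: chrom, status: out_of_control, dominant: ph}
    actions: [raise_alarm, divert_to_waste, request_operator_check]
    resolves: [valve_manifold_error, buffer_tank_empty]
  - id: ufdf_pressure
    priority: 7
    when: {group: ufdf, status: out_of_control}
    actions: [raise_alarm, request_operator_check]
    resolves: [upstream_propagation]
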