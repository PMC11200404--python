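# Default continuous mAb train: 7 unit operations linked by 6 surge tanks.
# Weights in grams of solution; durations as named.  The hardware protocol
# strings are descriptive metadata only.
units:
  - {id: clar,    kind: clarification,       protocol: "TCP/IP"}
  - {id: depth,   kind: depth_filtration,    protocol: "Modbus 485"}
  - {id: proa,    kind: protein_a,           n_columns: 3, standby_available: true, protocol: "TCP/IP"}
  - {id: vi,      kind: viral_inactivation,  protocol: "RS-232"}
  - {id: sterile, kind: sterile_filtration,  protocol: "Modbus 485"}
  - {id: cex,     kind: cex,                 n_columns: 3, standby_available: true, protocol: "TCP/IP"}
  - {id: ufdf,    kind: ufdf,                protocol: "Profibus"}
tanks:
  - {id: tank_clar_depth,  upstream_unit: clar,    downstream_unit: depth,
     capacity: 1000.0, w_max: 800.0, w_min: 150.0, w_restart_lo: 300.0, w_restart_hi: 600.0}
  - {id: tank_depth_proa,  upstream_unit: depth,   downstream_unit: proa,
     capacity: 1000.0, w_max: 800.0, w_min: 150.0, w_restart_lo: 300.0, w_restart_hi: 600.0}
  - {id: tank_proa_vi,     upstream_unit: proa,    downstream_unit: vi,
     capacity: 1000.0, w_max: 800.0, w_min: 150.0, w_restart_lo: 300.0, w_restart_hi: 600.0}
  - {id: tank_vi_sterile,  upstream_unit: vi,      downstream_unit: sterile,
     capacity: 1000.0, w_max: 800.0, w_min: 150.0, w_restart_lo: 300.0, w_restart_hi: 600.0}
  - {id: tank_sterile_cex, upstream_unit: sterile, downstream_unit: cex,
     capacity: 1000.0, w_max: 800.0, w_min: 150.0, w_restart_lo: 300.0, w_restart_hi: 600.0}
  - {id: tank_cex_ufdf,    upstream_unit: cex,     downstream_unit: ufdf,
     capacity: 1000.0, w_max: 800.0, w_min: 150.0, w_restart_lo: 300.0, w_restart_hi: 600.0}
campaign_duration_h: 60.0
startup_duration_h: 7.0
chrom_cycle_duration_min: 68.0
ufdf_cycle_duration_h: 12.0
proa_column_volume_ml: 16.7
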