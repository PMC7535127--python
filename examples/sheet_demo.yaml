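# Fast 2-D demo: one slow-conducting patch on a 60 x 60 mm sheet.
seed: 1
geometry:
  sheet:
    width_mm: 60.0
    height_mm: 60.0
    dx: 0.6
    patches:
      - center_mm: [38.0, 30.0]
        radius_mm: 7.5
        iir: 1.16
n_sites: 2
sim_duration_ms: 2000.0
dt_ms: 0.1
record_interval_ms: 2.0
calibrate: true
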