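# Crop presets: light-response constants and photoperiod discretization.
# a: ETR asymptote (umol m-2 s-1); k: initial-slope coefficient;
# dpi_target: minimum daily photochemical integral (mol m-2 d-1).
green_towers_lettuce:
  a: 121.0
  k: 0.00277
  dpi_target: 3.0
  photoperiod_hours: 16
  step_seconds: 900
  start_hour: 4.5
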