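# Demo pipeline configuration: a small dense synthetic scene.
seed: 7
output_dir: tmf_demo_output
scene:
  rows: 30
  cols: 30
  event_rates:
    degradation: 0.10
    deforestation: 0.08
    deforestation_after_degradation: 0.05
    regrowth_after_deforestation: 0.05
  archive:
    preset: dense
    obs_per_year: 12
    invalid_fraction: 0.1
    first_year: 1990
  noise_sd: 0.0
thresholds: {}
validation:
  n_plots: 120
projection:
  horizon: 2050
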