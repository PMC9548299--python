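# Study conditions for the analysis run: a desk-scale synthetic ICU cohort
# (150 admissions, ~50 emergent intubations after a 12 h deterioration ramp,
# 5% DNI), default epoch rules (16 h split gap, 1 h isolated epochs),
# 30-min/15-min feature windows, three risk models, 200-replicate
# admission-level bootstrap.  All values here are the package defaults made
# explicit; edit and re-run scripts 01-06 to explore other conditions.
seed: 20210927
cohort:
  n_admissions: 150
  event_fraction: 0.3333333333333333
  dni_fraction: 0.05
  stay_median_hours: 48.0
  ramp_hours: 12.0
  rr_variability_shrink: 0.4
evaluation:
  n_bootstrap: 200
models: [politano, moss_micu, moss_sicu]
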