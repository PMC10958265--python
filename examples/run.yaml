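# Full-pipeline configuration for `needsmsm report --config examples/run.yaml`.
# Generate the input first, e.g.:
#   needsmsm simulate --n 500 --seed 0 --out panel.csv
panel: panel.csv
out_dir: needsmsm_out

# model
h_lik: 1.0                  # likelihood band width, years
death_convention: exact     # dated deaths contribute a density; `interval` treats them as interval-censored
impute_missing_death_dates: true
maxiter: 150
include_unadjusted_hr: false  # true adds single-covariate refits (slower)

# predictions
prob_horizon: 2.0           # years, for the transition-probability table

# life expectancy
le_ages: [60.0, 70.0]
le_h: 0.5                   # occupancy grid step, years
max_age: 115.0
B: 1000                     # parameter draws for simulation CIs
seed: 0
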