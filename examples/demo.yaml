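# Demo pipeline configuration: a four-year synthetic world, apportioned,
# modelled, and projected to its no-controls counterfactual.
outdir: aq_demo_run
seeds:
  default: 1
simulate:
  n_days: 1461          # 2005-2008, daily
apportion:
  n_factors: 4
  n_random_starts: 5
  max_iterations: 2000
fit:
  k: 8
  cv: true
  n_folds: 10
  importance: true
  n_shuffles: 5
scenario:
  name: all_controls_removed
  choices:
    EGU: counterfactual
    mobile_gasoline: counterfactual
    mobile_diesel: counterfactual
uncertainty:
  n_draws: 200
  specs:
    "EGU:SO2": {dist: lognormal, sd: 0.2}
    "EGU:NOx": {dist: lognormal, sd: 0.2}
    "mobile_gasoline:PM25": {dist: lognormal, sd: 0.2}
    "mobile_diesel:PM25": {dist: lognormal, sd: 0.2}
report:
  year: 2008
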