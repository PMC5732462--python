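# Synthetic illustrative scenario: a three-state disease model
# (healthy -> progressed -> death, with progression and death competing from
# healthy) comparing a control strategy against an intervention that extends
# survival in the progressed state at a higher monthly treatment cost.
# All numeric values are invented for this fixture; they are chosen to be of
# realistic magnitude (times in months, costs in currency units, utilities
# as QALY weights per year) but do not describe any trial.
model:
  structure:
    healthy: {progression: progressed, death: death}
    progressed: {death: death}
  initial_state: healthy
  families:
    healthy.progression: weibull
    healthy.death: weibull
    progressed.death: weibull
  min_events: 2
  discount_rate: 0.03
  horizon: 240
  wtp_reference: 134000
  lambda_grid: {start: 0, stop: 200000, num: 41}
  use_crn: false
  econ_params:
    u_healthy: {dist: beta, mean: 0.85, se: 0.03}
    u_progressed: {dist: beta, mean: 0.65, se: 0.04}
    c_healthy: {dist: gamma, mean: 300, se: 30}
    c_prog_control: {dist: gamma, mean: 1200, se: 120}
    c_prog_intervention: {dist: gamma, mean: 2000, se: 200}
    c_event_progression: {dist: gamma, mean: 5000, se: 500}
  strategies:
    - name: control
      group: control
      mechanism: event_probability
      utilities: {healthy: u_healthy, progressed: u_progressed}
      cost_rates: {healthy: c_healthy, progressed: c_prog_control}
      event_costs: {progression: c_event_progression}
    - name: intervention
      group: intervention
      mechanism: event_probability
      utilities: {healthy: u_healthy, progressed: u_progressed}
      cost_rates: {healthy: c_healthy, progressed: c_prog_intervention}
      event_costs: {progression: c_event_progression}
population:
  initial_state: healthy
  frailty_sd: 0.0
  censor_time: null
  groups:
    control:
      healthy:
        progression: {family: weibull, shape: 1.4, scale: 18}
        death: {family: weibull, shape: 1.2, scale: 40}
      progressed:
        death: {family: weibull, shape: 1.3, scale: 12}
    intervention:
      healthy:
        progression: {family: weibull, shape: 1.4, scale: 18}
        death: {family: weibull, shape: 1.2, scale: 40}
      progressed:
        death: {family: weibull, shape: 1.3, scale: 18}
study:
  sample_sizes: [500, 100, 50, 25]
  n_trials: 20
  r: 200
  n_patients: 1000
  approaches: [fixed, bootstrap, mvnorm]
  seed: 0
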