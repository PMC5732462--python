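# Minimal smoke-test study configuration: same synthetic scenario as
# scenario_default.yaml but with tiny dimensions so a full nested study
# (trials x approaches x PSA runs x patients) completes in seconds.
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
  lambda_grid: {start: 0, stop: 200000, num: 21}
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
  sample_sizes: [60]
  n_trials: 2
  r: 10
  n_patients: 100
  approaches: [fixed]
  seed: 0
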