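# Symmetric anti-Hebbian LTD, scenario 3: pathway A Hebbian (enduring LTP,
# not inactivated), dominated by pathway B's LTD.
calcium:
  c_pre: 7
  c_post: 15
  tau_ca: 17 ms
  delay: 10 ms
pathways:
  - name: A
    gamma_p: 420
    gamma_d: 360
    theta0_p: 11
    theta0_d: 10
    mu_p: .inf
    mu_d: .inf
  - name: B
    gamma_p: 0
    gamma_d: 550
    theta0_p: .inf
    theta0_d: 14
    mu_p: .inf
    mu_d: 25
dynamics:
  tau: 280
  rho_star: 0.5
  sigma: 1
readout:
  ltp_star: 4
  ltd_star: 0.5
  slope: 0.5
thresholds:
  model: piecewise
  epsilon: 1.0
settings:
  n_synapses: 1000
  n_iter: 204000
  t_start: -1
  t_end: 101
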