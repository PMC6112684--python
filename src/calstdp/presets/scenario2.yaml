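# Symmetric anti-Hebbian LTD, scenario 2: pathway A with an early,
# inactivating LTP plus LTD; pathway B LTD-only.
calcium:
  c_pre: 7
  c_post: 15
  tau_ca: 17 ms
  delay: 10 ms
pathways:
  - name: A
    gamma_p: 430
    gamma_d: 220
    theta0_p: 6
    theta0_d: 10
    mu_p: 8
    mu_d: 29
  - name: B
    gamma_p: 0
    gamma_d: 100
    theta0_p: .inf
    theta0_d: 5.8
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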