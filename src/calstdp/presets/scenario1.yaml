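# Symmetric anti-Hebbian LTD, scenario 1: a single LTD-only pathway.
calcium:
  c_pre: 7
  c_post: 7
  tau_ca: 17 ms
  delay: 0
pathways:
  - name: A
    gamma_p: 0
    gamma_d: 190
    theta0_p: .inf
    theta0_d: 6
    mu_p: .inf
    mu_d: .inf
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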