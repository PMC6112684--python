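# Cortico-striatal synapse: eCB (LTP+LTD) and NMDAR (LTP only) pathways.
calcium:
  c_pre: 7
  c_post: 17.1
  tau_ca: 18 ms
  delay: 10 ms
pathways:
  - name: eCB
    gamma_p: 290
    gamma_d: 250
    theta0_p: 6
    theta0_d: 13.5
    mu_p: 6
    mu_d: .inf
  - name: NMDAR
    gamma_p: 50
    gamma_d: 0
    theta0_p: 5.8
    theta0_d: .inf
    mu_p: 32
    mu_d: .inf
dynamics:
  tau: 165
  rho_star: 0.5
  sigma: 1
readout:
  ltp_star: 3.475
  ltd_star: 0.55
  slope: 0.7
thresholds:
  model: piecewise
  epsilon: 1.0
settings:
  n_synapses: 1000
  n_iter: 102000
  t_start: -1
  t_end: 101
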