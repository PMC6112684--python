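# Classical symmetric Hebbian STDP: single calcium pathway, no pre/post delay.
calcium:
  c_pre: 2
  c_post: 2
  tau_ca: 20 ms
  delay: 0
pathways:
  - name: ca
    gamma_p: 257.447
    gamma_d: 160
    theta0_p: 1.3
    theta0_d: 1
    mu_p: .inf
    mu_d: .inf
dynamics:
  tau: 150
  rho_star: 0.5
  sigma: 2.8284
readout:
  ltp_star: 4
  ltd_star: 0.5
  slope: 0.5
thresholds:
  model: piecewise
  epsilon: 1.0
settings:
  n_synapses: 1000
  n_iter: 102000
  t_start: -1
  t_end: 101
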