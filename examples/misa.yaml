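# Mutual-inhibition/self-activation motif, baseline repressor kinetics
model:
  motif: misa
  preset: baseline        # g0=2, g1=14, k=1, h_a=0.1, f_a=1, h_r=1e-4, f_r=1e-2
  n_max: 30
analysis:
  tau: 5.0
  n_macrostates: 4
  n_eigenvalues: 8
  tpt: {source: 1, target: 2}
simulation:
  seed: 1
  t_end: 20000.0
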