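# Non-adiabatic regime: all 16 promoter configurations are metastable
model:
  motif: misa
  preset: slow            # h_a=1e-3, f_a=1e-2, h_r=1e-6, f_r=1e-4
  n_max: 30
analysis:
  tau: 1.0
  n_macrostates: 16
  n_eigenvalues: 20
simulation:
  seed: 1
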