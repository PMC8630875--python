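# Demonstration pipeline: synthetic survey of 5,000 children over a 6x6
# lattice of regions, short MCMC chains.  Rerunning with the same seed
# reproduces every artifact byte-for-byte.
seed: 7
paths:
  outdir: demo_output
simulate:
  n_children: 5000
  n_side: 6
screen_alpha: 0.20
models:
  forms: [M0, M3]
  spatial: tensor
  n_segments: 10
  spatial_segments: 4
mcmc:
  n_iter: 800
  n_burnin: 300
  thin: 1
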