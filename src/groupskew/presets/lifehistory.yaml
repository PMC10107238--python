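# Shared scaffolding for the three life-history presets.  The production
# curve is calibrated at load time: n0 solves optimal_n = target_n_star at
# steepness q, and A is scaled so a reference group of n*+1 members produces
# `margin` times its subsistence at the production optimum.  The margin is
# set high enough that the solitary ancestral state (N=1, p=1, x=0.3, hence
# n = 0.5 producer-equivalents) already clears subsistence: trajectories
# must be able to begin there.
t: 0.2
s: 100.0
target_n_star: 21.47
q: 1.3
margin: 25.0
start:
  N: 1.0
  p: 1.0
  x: 0.3
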