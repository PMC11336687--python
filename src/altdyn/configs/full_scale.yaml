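# Full-scale conditions (cluster scale; hours per replicate).
# Evolutionary probabilities mu=5e-7, q=1e-5 and beta=50 as in the
# full-scale study; the (phi, d, K) anchor is configurable -- the
# non-dimensional adsorption ratio is what matters.
r: 1.0
d: 0.1
phi: 1.0e-7
q: 1.0e-5
mu: 5.0e-7
beta: 50
g: 15
K: 100000
w: 0.0
t_max: 2000.0
sample_dt: 1.0
seed: 0
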