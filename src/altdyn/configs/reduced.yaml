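# Reduced-scale conditions exhibiting alternating dynamics (CI scale).
# phi is set so the naive-host reproductive ratio beta*phi*K/(d+phi*K) = 5.
r: 1.0
d: 0.1
phi: 5.5555555555555556e-06
q: 1.0e-3
mu: 5.0e-5
beta: 50
g: 15
K: 2000
w: 0.0
t_max: 500.0
sample_dt: 1.0
seed: 0
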