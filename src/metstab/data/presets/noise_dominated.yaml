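# No real interaction: everything in the GE stratum is plot noise.
g: 10
e: 10
r: 3
mu: 3.0
sigma2_g: 0.05
sigma2_e: 0.5
lambdas: []
sigma2_block: 0.01
sigma2_res: 0.4
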