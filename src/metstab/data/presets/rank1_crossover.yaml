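# One strong crossover axis; interaction rivals the genotype main effect.
g: 8
e: 10
r: 3
mu: 3.0
sigma2_g: 0.02
sigma2_e: 0.4
lambdas: [4.0]
sigma2_block: 0.01
sigma2_res: 0.05
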