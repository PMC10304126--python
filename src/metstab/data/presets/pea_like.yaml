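# Palouse-pea-like MET: environment-dominated variation; interaction ~60% signal,
# two strong axes carrying ~2/3 of the signal over a diffuse background, which
# reproduces the ~86-87% cumulative share of the first six axes seen in such trials.
g: 12
e: 28
r: 3
mu: 2.7          # t/ha grand mean
sigma2_g: 0.03   # genotype main-effect variance (t/ha)^2
sigma2_e: 0.88   # environment main-effect variance
lambdas: [2.45, 1.71]  # planted multiplicative axes (cell-mean scale)
sigma2_ge: 0.015       # diffuse iid interaction background
sigma2_block: 0.01
sigma2_res: 0.09       # plot error; trial CV ~ 11% at mu=2.7
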