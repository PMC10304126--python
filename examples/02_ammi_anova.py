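"""Joint ANOVA and AMMI decomposition of a synthetic pea-like MET.

Generates a balanced 12 x 28 x 3 trial series, partitions the variation,
splits the interaction into signal and noise, and tests each
multiplicative axis (Gollob F-test against the pooled residual).
"""

from metstab import (fit_ammi_from_dataset, ge_signal_noise,
                     generate_from_preset, ipca_tests, joint_anova)

data, truth = generate_from_preset("pea-like", seed=0)
print(data, "\n")

an = joint_anova(data)
print(an.table.round(3), "\n")
print("shares of G+E+GE:",
      {k: round(v, 3) for k, v in an.shares.items()})

part = ge_signal_noise(an)
print(f"GE partition: signal {part.signal:.1f}, noise {part.noise:.1f} "
      f"-> {100 * part.signal_fraction:.0f}% signal\n")

fit = fit_ammi_from_dataset(data)
print(ipca_tests(fit).round(4).head(5))
print("\nThe first two axes are the planted interaction structure; the")
print("environment share dominates, as it does in real trial series.")
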