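"""Sample size for detecting a swallowing-sound-index difference.

Solves the smallest total n (two equal groups) so a two-sided two-sample
t-test at the given alpha reaches the target power for the stated minimum
difference and standard deviation, using noncentral-t power evaluated at
t critical values.
"""

import swallowsound as ss

spec = ss.PowerSpec(min_difference=0.08, sd=0.06, alpha=0.05, power=0.80)
n_total = ss.sample_size(spec)
print(f"minimum difference {spec.min_difference}, SD {spec.sd}, "
      f"alpha {spec.alpha}, power {spec.power}")
print(f"required participants in total: {n_total} ({n_total // 2} per group)")
print(f"achieved power at that n: {ss.power_at(n_total // 2, spec):.4f}")

# Doubling the detectable difference shrinks the requirement sharply:
for delta in (0.08, 0.12, 0.16):
    n = ss.sample_size(ss.PowerSpec(min_difference=delta, sd=0.06))
    print(f"  difference {delta:.2f} -> total n = {n}")
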