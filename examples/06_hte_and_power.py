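"""Heterogeneity of treatment effects and repeated-measures power.

The HTE decomposition asks whether active-arm change scores are more
variable than control-arm ones — the excess SD (SD_IR) estimates how much
individual responses to treatment truly differ. The power calculation
reproduces the two published design analyses (d=0.48 at N=48, d=0.47 at
N=72, both at 95% power).
"""

from cogmech import (
    PowerSpec,
    required_sample_size,
    rm_interaction_power,
    sd_individual_response,
)

# worked arithmetic example: standardized change-score SDs of 0.5 (active)
# and 0.3 (control), 100 subjects per arm
r = sd_individual_response(0.5, 0.3, 99, 99)
print("HTE decomposition:")
print(f"  SD_IR = {r.SD_IR:.3f} (SE {r.SD_IRse:.4f})")
print(f"  95% CI [{r.CI95[0]:.3f}, {r.CI95[1]:.3f}]  ->  "
      f"{r.effect_class} individual-response effect")

print("\nRepeated-measures interaction power:")
for d, n, rho in ((0.48, 48, 0.6), (0.47, 72, 0.43)):
    p = rm_interaction_power(PowerSpec(d=d, N=n, m=2, rho=rho, alpha=0.05))
    print(f"  d={d}, N={n}, rho={rho}: power = {p:.3f}")

n95 = required_sample_size(0.48, target_power=0.95, rho=0.6)
print(f"\nsmallest N reaching 95% power at d=0.48, rho=0.6: {n95}")
print(
    "\nSD_IR in (0.3, 0.6) is a moderate heterogeneity signal: individual"
    "\nresponses to the active intervention differ enough to justify looking"
    "\nfor moderators."
)
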