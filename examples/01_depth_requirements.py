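"""How much sequencing depth separates heterozygous triploid from tetraploid loci?

Simulates binomial allele-ratio envelopes for the simplex-tetraploid state
(ABBB, alt fraction 0.25) and the heterozygous-triploid state (ABB, 1/3),
then finds the depth at which their one-sided 95% envelopes stop
overlapping, and compares it with the closed-form normal approximation.
"""
import numpy as np

from tetradose import (discrimination_depth_normal_approx,
                       find_discrimination_depth, simulate_ratio_envelope)

env = simulate_ratio_envelope(p=0.25, depths=[10, 50, 320, 1000],
                              n_loci=2500, seed=7)
print("ABBB (p=0.25) allele-ratio envelope by depth:")
print(env.round(3))

crossing = find_discrimination_depth(p_tetra=0.25, p_tri=1 / 3,
                                     confidence=0.95,
                                     depths=range(3, 1001),
                                     n_loci=2500, seed=7)
analytic = discrimination_depth_normal_approx(0.25, 1 / 3, 0.95)
print(f"\nsimulated crossing depth : {crossing}x")
print(f"normal approximation     : {analytic:.0f}x")
print("\nBelow the crossing depth the 95th percentile of the 0.25-state")
print("overlaps the 5th percentile of the 1/3-state, so a single locus'")
print("ploidy state cannot be called with 95% confidence - depth in the")
print("hundreds is needed, far beyond routine genotyping-by-sequencing.")
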