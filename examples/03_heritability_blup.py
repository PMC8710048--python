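"""Aggregate a replicated angle table, estimate broad-sense
heritability with the divisor-2 estimator H2 = s2G / (s2G + s2e/2),
and screen genotypes whose BLUP lies more than 5 SD from the mean."""

import numpy as np

import leafangle3d as la
from leafangle3d import genetics as gen

# balanced simulation: 100 genotypes x 4 replicate plants,
# genetic variance 1, residual variance 2 -> true H2 = 1/(1 + 2/2) = 0.5
table = gen.simulate_replicated_phenotypes(
    n_genotypes=100, reps=4, sigma2_G=1.0, sigma2_e=2.0, seed=7
)

h2, vc = la.heritability(table)
print(f"variance components ({vc.method}): "
      f"s2G = {vc.sigma2_G:.3f}, s2e = {vc.sigma2_e:.3f}")
print(f"broad-sense heritability H2 = {h2:.3f}  (true value 0.5)")

# plant an extreme genotype and watch the 5-SD BLUP screen remove it
table.loc[table["genotype_id"] == "g0", "angle_deg"] += 60.0
screen = la.blup_outlier_screen(table)
print(f"\nBLUP outlier screen: removed {screen.removed} "
      f"(of {len(screen.blups)} genotypes)")
print(f"largest |BLUP|: {screen.blups.abs().max():.1f} deg; "
      f"5-SD cut-off: {5 * screen.blups.std():.1f} deg")
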