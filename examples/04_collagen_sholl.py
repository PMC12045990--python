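"""Sholl profiling of ring-like vs scattered collagen deposition.

Generates control-like images (collagen puncta confined to a peripheral
ring at 0.8 of the organoid radius) and mutant-like images (the same
amount of signal scattered uniformly), counts signal intersections on 50
concentric circles, and compares the radial distributions with a
Mann-Whitney U test.
"""

import numpy as np

from organoid_mech.sholl import compare_profiles, sholl_counts
from organoid_mech.synth import gen_collagen_image

profiles = {"ring": [], "scattered": []}
for mode in profiles:
    for seed in (0, 1, 2):
        img = gen_collagen_image(mode=mode, seed=seed)
        profiles[mode].append(sholl_counts(img))

for mode, profs in profiles.items():
    counts = np.mean([p.counts for p in profs], axis=0)
    peak = profs[0].radii[int(np.argmax(counts))]
    frac_peripheral = counts[profs[0].radii > 0.7].sum() / counts.sum()
    print(f"{mode:9s}: peak at r = {peak:.2f}, "
          f"{100 * frac_peripheral:.0f}% of intersections beyond r = 0.7")

res = compare_profiles(profiles["ring"], profiles["scattered"])
print(f"\nMann-Whitney U = {res.statistic:.0f}, two-sided p = {res.p_value:.2e} "
      f"(n = {res.n[0]} vs {res.n[1]} pooled intersections)")
print()
print("The ring phenotype concentrates intersections near the periphery;")
print("the scattered phenotype spreads them across radii - the rank-sum")
print("test separates the two organization patterns decisively.")
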