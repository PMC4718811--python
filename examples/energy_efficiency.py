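"""Per-region energy efficiency and its maturation.

Efficiency = connectivity strength (sum of positive incident correlations)
divided by normalized regional uptake: connections obtained per unit
metabolic cost.  Compares 5 vs 15 weeks with a Bonferroni-corrected
permutation test.
"""

from metconn import (
    SyntheticConfig, extract_voi_means, gaussian_smooth, generate_cohort,
    global_normalize, group_efficiency, permutation_efficiency_test,
)

cfg = SyntheticConfig(grid_shape=(20, 24, 8), voxel_spacing_mm=(7.75, 7.75, 15.5),
                      seed=7)
scansets, truth = generate_cohort(cfg)
mask = truth.brain_mask

vms = {}
for g, s in scansets.items():
    pre = s.map(lambda v: global_normalize(gaussian_smooth(v, 12.0), mask))
    vms[g] = extract_voi_means(pre, truth.voi_masks)

for g in ("5wk", "15wk"):
    print(f"\nefficiency at {g}:")
    print(group_efficiency(vms[g]).to_frame().round(3).to_string(index=False))

t = permutation_efficiency_test(vms["5wk"], vms["15wk"], n_perm=10000, seed=0)
print("\n5wk -> 15wk comparison (Bonferroni over 8 VOIs at family alpha 0.05):")
print(t.round(4).to_string(index=False))
# A significant "increase" at MedF / Rsp means the midline default-mode hubs
# gain connectivity per unit glucose cost as the brain matures — the planted
# maturation effect.
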