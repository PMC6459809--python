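"""Per-region moderated-t differential expression on planted effects.

Generates a dataset with a log2 effect of 1.0 planted in four modules
(one region each) and runs the empirical-Bayes moderated t per region,
the excess-DEG chi-square test and BH correction.
"""

import braincoex as bc

ds, truth = bc.generate_dataset(bc.de_power_config(seed=1))
results = bc.de_all_regions(ds)

print(f"{'region':>6} {'DEGs':>5} {'chi2':>9} {'prior df':>9} "
      f"{'power on planted':>17}")
for region, res in results.items():
    degs = res.deg_set(alpha=0.05)
    n_det = int(res.table["p"].notna().sum())
    stat, p = bc.degs_vs_chance(len(degs), n_det, alpha=0.05)
    planted = truth.true_deg_set(region)
    power = (len(degs & planted) / len(planted)) if planted else float("nan")
    print(f"{region:>6} {len(degs):>5} {stat:>9.1f} {res.prior_df:>9.1f} "
          f"{power:>17.2f}")
# Regions with a planted effect show DEG counts far above the 5% chance
# level (large chi-square) and near-complete recovery of affected genes;
# regions without effects sit at the chance level (chi2 ~ 0, p ~ 1).
# The prior df quantifies how much variance information is shared across
# genes by the empirical-Bayes shrinkage.

tmat = bc.t_value_matrix(results)
labels, centers = bc.cluster_t_values(tmat, results=results, k=4, seed=0)
print(f"\nK-means on t-value profiles of {len(labels)} top genes "
      f"(p < 0.001 somewhere): cluster sizes "
      f"{labels.value_counts().sort_index().tolist()}")
# Genes regulated in the same region cluster together, mirroring the
# region-specific structure of the planted effects.
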