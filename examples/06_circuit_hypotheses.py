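"""From gene modules to neural-circuit hypotheses.

Characterizes the benchmark's detected modules, derives per-region
regulation calls for each module, and intersects co-regulated region
pairs with the shipped anatomical connectivity table for the seven study
regions (PFC, AcbC, AcbSh, BNST, BLA, CeA, VTA).
"""

import pandas as pd

import braincoex as bc

ds, truth = bc.generate_dataset(bc.benchmark_config(seed=1))
net = bc.build_network(ds.values, beta=12)
labels = net.labels

results = bc.de_all_regions(ds)
markers = bc.generate_marker_and_geneset_collections(
    truth, contamination=0.2, n_decoy_sets=0, seed=1)
eig, _ = bc.module_eigengene(ds.values, labels)
char = bc.characterize_modules(labels, results, markers,
                               universe=set(labels.index),
                               eigengenes=eig, metadata=ds.metadata)

deg_union = set()
for res in results.values():
    deg_union |= res.deg_set(alpha=0.05)
_, hubs = bc.intramodular_connectivity_and_hubs(net.adjacency, labels)
profiles = bc.module_region_profiles(char.deg_enrichment, eig, ds.metadata,
                                     hub_genes=hubs, deg_union=deg_union)

neuron_flags = char.cell_types["cell_types"].str.contains("neuron")
table = bc.ConnectivityTable.default()
hyps, upstream = bc.candidate_connections(
    profiles, table, neuron_flags=neuron_flags,
    selection_flags=char.selection_responsive)

print("circuit hypotheses (neuron-specific, selection-responsive modules, "
      "co-regulated region pairs with a known anatomical connection):")
for h in hyps:
    print(f"  {h.module}: {h.source} -> {h.target} "
          f"({h.source_call}/{h.target_call}, score {h.score:.1f}, "
          f"{h.annotation})")
print("common-upstream candidates (co-regulated but not directly "
      "connected):")
for h in upstream:
    print(f"  {h.module}: {h.source} -- {h.target} (score {h.score:.1f})")
# The planted neuron module is up-regulated in BLA, CeA and AcbSh; the
# table contains BLA->CeA and BLA->AcbSh projections, so those become
# ranked hypotheses (the score sums the -log10 enrichment q of the two
# endpoint regions), while the unconnected CeA/AcbSh pair is flagged as
# sharing a putative upstream driver.
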