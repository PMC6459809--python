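"""Flag selection-responsive modules, assign cell types, test region
dependence.

Uses the planted module labels directly (any labeling works) so the
characterization machinery is visible in isolation: DEG
over-representation per (region, direction), marker-set enrichment with
20% contaminated markers, and the eigengene region ANOVA.
"""

import pandas as pd

import braincoex as bc

ds, truth = bc.generate_dataset(bc.benchmark_config(seed=1))
labels = pd.Series(truth.gene_module)
labels[labels == "background"] = "grey"

results = bc.de_all_regions(ds)
markers = bc.generate_marker_and_geneset_collections(
    truth, contamination=0.2, n_decoy_sets=0, seed=1)
eig, _ = bc.module_eigengene(ds.values, labels)

char = bc.characterize_modules(labels, results, markers,
                               universe=set(labels.index),
                               eigengenes=eig, metadata=ds.metadata)
print(char.flags_table().to_string())
# selection_responsive: the module is over-represented with DEGs from at
# least one (region, direction) list at q < 0.05 — exactly the modules
# carrying planted genotype effects.  cell_types: marker sets assigned at
# FDR < 5% despite 20% marker contamination.  region_dependent: one-way
# ANOVA of the eigengene across the seven regions — modules with planted
# region baselines; the flat housekeeping-like module is the exception.
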