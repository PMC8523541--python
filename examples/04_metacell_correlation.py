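"""Compare gene-gene co-expression networks between groups via metacells.

Plants a positive RBPJ-NOTCH1-ITGAE co-regulation into WT cells only
(a shared log-normal latent factor), pools each group's cells into
metacells (Leiden communities on a kNN graph, minimum 15 cells each),
summarizes them by the regularized geometric mean, and compares Spearman
correlations: delta = rho_WT - rho_MT exposes the group-specific network.
Raw single-cell counts are too zero-inflated for this — pooling is what
makes the planted correlation measurable.
"""

import numpy as np

from sclandscape import (
    CompositionScenario,
    compare_networks,
    gen_composition,
    gen_expression,
    lognormalize,
    metacell_profiles,
    partition_metacells,
)
from sclandscape.io import AnnotatedCounts

scenario = CompositionScenario.with_fold_changes(1, {"WT": 500, "MT": 500}, {})
labels = gen_composition(scenario, seed=8)
names = ["RBPJ", "NOTCH1", "ITGAE"] + [f"G{i:05d}" for i in range(37)]
counts = gen_expression(
    labels, 40, {}, seed=8, gene_names=names, base_mean_median=1.0,
    coexpression_plan=[{"genes": ["RBPJ", "NOTCH1", "ITGAE"],
                        "subset": "C0", "group": "WT", "sd": 1.0}],
)
norm = lognormalize(counts)

profiles = {}
for grp in ("WT", "MT"):
    mask = (labels["group"] == grp).to_numpy()
    idx = np.flatnonzero(mask)
    sub = AnnotatedCounts(counts.counts[:, idx], counts.gene_ids,
                          [counts.cell_ids[i] for i in idx],
                          counts.cell_meta.iloc[idx])
    part = partition_metacells(norm.values[:, idx].toarray().T,
                               k_graph=30, min_size=15, seed=9)
    profiles[grp] = metacell_profiles(sub, part)
    print(f"{grp}: {part.n_metacells} metacells "
          f"(sizes {part.sizes().min()}-{part.sizes().max()})")

comparison = compare_networks(profiles["WT"], profiles["MT"],
                              anchor_genes=["RBPJ"],
                              target_genes=["NOTCH1", "ITGAE"])
print("\nanchor-target Spearman correlations:")
print(comparison.round(3).to_string(index=False))
print("\nPositive delta for both planted targets: the co-regulation exists "
      "in WT metacells and is absent in MT, mirroring a lost regulatory "
      "network in one group.")
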