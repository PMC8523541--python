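"""Score directed ligand-receptor interactions with a permutation null.

Plants a CXCL13 -> CXCR5 axis (sender C1, receiver C2) in WT cells only and
silences both genes in MT.  The interaction statistic is the average of the
ligand's mean expression in the sender and the receptor's mean in the
receiver, reported only when both are expressed in >= 10% of their subset;
significance comes from shuffling cluster labels (add-one estimator, so the
smallest attainable p with 1,000 permutations is 1/1001).
"""

import numpy as np

from sclandscape import (
    CompositionScenario,
    gen_composition,
    gen_expression,
    interaction_mean,
    lognormalize,
    permutation_test,
)
from sclandscape.interactions import LrPair

scenario = CompositionScenario.with_fold_changes(3, {"WT": 400, "MT": 400}, {})
labels = gen_composition(scenario, seed=9)
names = ["CXCL13", "CXCR5"] + [f"G{i:05d}" for i in range(38)]
silenced_in_mt = [(f"C{j}", 0.05, "MT") for j in range(3)]
counts = gen_expression(
    labels, 40,
    {"CXCL13": [("C1", 12.0, "WT")] + silenced_in_mt,
     "CXCR5": [("C2", 12.0, "WT")] + silenced_in_mt},
    seed=9, gene_names=names, base_mean_median=0.4,
)
norm = lognormalize(counts)
pair = LrPair("CXCL13", "CXCR5")

for grp in ("WT", "MT"):
    mask = (labels["group"] == grp).to_numpy()
    sub = norm.subset_cells(mask)
    clusters = labels["cluster"].to_numpy()[mask]
    scored = interaction_mean(sub, clusters, pair, sender="C1", receiver="C2")
    if scored is None:
        print(f"{grp}: CXCL13->CXCR5 not expressed (gated at 10%)")
        continue
    mean_stat, pct_l, pct_r = scored
    p = permutation_test(sub, clusters, pair, "C1", "C2", n_perm=1000, seed=10)
    print(f"{grp}: mean stat = {mean_stat:.3f} "
          f"(ligand in {pct_l:.0%} of senders, receptor in {pct_r:.0%} of "
          f"receivers), permutation p = {p:.4g}")

print("\nThe axis is detected at the minimum attainable p in WT and is "
      "gated out (or insignificant) in MT - the planted group contrast.")
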