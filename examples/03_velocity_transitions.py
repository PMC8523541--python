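"""Estimate cell-state persistence from spliced/unspliced kinetics.

Simulates two subsets under the transcription-splicing-degradation model
(du/dt = a - b*u, ds/dt = b*u - g*s) with 40% of C0 cells in transit toward
C1's state.  The steady-state slope gamma is fitted per gene from extreme
quantiles of spliced expression, velocity v = u - gamma*s points along each
cell's future, and the transition kernel turns velocity-displacement
correlations into a subset-level transition matrix whose diagonal is the
persistence of each state.
"""

import numpy as np
import pandas as pd

from sclandscape import (
    KineticsSpec,
    compute_velocity,
    fit_gamma,
    gen_kinetics,
    subset_transitions,
    transition_kernel,
)

labels = pd.DataFrame(
    {"patient": "P1", "group": "WT", "cluster": ["C0"] * 250 + ["C1"] * 250},
    index=[f"c{i}" for i in range(500)],
)
spec = KineticsSpec(
    alpha=np.full(12, 6.0), gamma=np.full(12, 0.6),
    subset_alpha_scale={"C1": np.full(12, 2.0)},
    transit={"C0": ("C1", 0.4)},          # 40% of C0 en route to C1
    transit_time_range=(0.5, 3.0),
)
spliced, unspliced, truth = gen_kinetics(labels, spec, seed=2)

fit = fit_gamma(spliced, unspliced, smoothing_k=30, q=0.1)
vel = compute_velocity(fit, spliced, unspliced, smoothing_k=10)
keep = [int(g[1:]) for g in vel.gene_ids]
model = transition_kernel(vel, spliced.toarray()[keep], k=150, sigma=0.05)
model = subset_transitions(model, labels["cluster"].to_numpy())

print("fitted degradation rates (true gamma = 0.6):")
print(fit.gamma.round(3).head(5).to_string())
print("\nsubset transition matrix (rows sum to 1):")
print(model.M.round(3).to_string())
print(f"\nC0 persistence = {model.persistence['C0']:.3f}: with 40% of C0 "
      "transiting, a large share of its transition mass points at C1 — on "
      "unperturbed data this diagonal stays near 1.")
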