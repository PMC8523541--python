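"""Estimate subset fractions in bulk samples and stratify treatment response.

Builds a gene x subset signature matrix, simulates a 40-sample bulk cohort
as noisy mixtures with responder labels coupled to the C1 fraction
(logistic model), deconvolves each sample by non-negative least squares,
and tests the association: one-tailed Mann-Whitney U (responders greater),
rank-based AUROC, and a waterfall of score minus the cohort median.
"""

import numpy as np
import pandas as pd

from sclandscape import BulkCohortSpec, assess_response, estimate_fractions, gen_bulk_cohort
from sclandscape.deconvolution import SignatureMatrix

rng = np.random.default_rng(0)
S = pd.DataFrame(rng.uniform(0.2, 5.0, size=(120, 4)),
                 index=[f"g{i}" for i in range(120)],
                 columns=["C0", "C1", "C2", "C3"])
sig = SignatureMatrix(S=S)

spec = BulkCohortSpec(n_samples=40, designated_subset="C1", noise_sd=0.05,
                      slope=25.0, intercept=-5.0, seed=4)
bulk, responders, truth = gen_bulk_cohort(S, spec)

est = estimate_fractions(bulk, sig)
err = np.abs(est.f.to_numpy() - truth["fractions"].to_numpy()).max()
print(f"max fraction-recovery error at 5% noise: {err:.4f}")

assessment = assess_response(est.f["C1"], responders)
print(f"one-tailed Mann-Whitney U = {assessment.u_stat:.0f}, "
      f"p = {assessment.p_one_tailed:.4g}")
print(f"AUROC for retrieving responders = {assessment.auroc:.3f}")
print("\nwaterfall (top 5 deviations from the cohort median):")
print(assessment.waterfall.head(5).round(4).to_string())
print("\nA significant p and AUROC well above 0.5 recover the planted "
      "coupling between the C1 fraction and response; fractions themselves "
      "are recovered to a few percent despite the measurement noise.")
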