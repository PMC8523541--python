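# sclandscape

Comparative single-cell immune-landscape analysis between two sample groups
— built for the question "how does the tumor-infiltrating immune compartment
of one molecular subtype (e.g. EGFR-mutant lung cancer) differ from
another?" given an annotated scRNA-seq atlas. For computational biologists
who have cluster labels and group labels in hand and want the downstream
comparative statistics as a tested, scriptable library rather than a chain
of one-off notebooks.

## What it computes

Given gene × cell UMI counts with per-cell (patient, group, cluster)
annotations, and optionally spliced/unspliced layers and a bulk cohort:

1. **Composition shifts** — for groups i and subsets j, expected counts
   `E_ij = (T_i/T_tot)·T_j` and Pearson residuals
   `r_ij = (O_ij − E_ij)/√E_ij`; χ² goodness of fit `Σ r²`;
   augmented/depleted calls at `|r| > 3.5` (two-sided tail 4.7e-4, inside
   the Bonferroni-adjusted level 0.01/18 = 0.00056 for an 18-subset atlas);
   mosaic-plot geometry and SVG export.
2. **Differential expression** — subset-vs-rest and WT-vs-MT contrasts:
   Wilcoxon rank-sum (exact for n ≤ 12, tie-corrected normal with seeded
   permutation refinement of tail p-values otherwise), natural-log fold
   change of linear means, BH adjustment; calls at q < 0.05 and
   |avgLogFC| > 0.25.
3. **RNA-velocity transitions** — steady-state degradation rates
   `γ̂ = Σus/Σs²` on extreme spliced quantiles of k-NN-pooled layers,
   velocity `v = u − γ̂s`, a softmax transition kernel over velocity-
   displacement correlations, and the subset × subset mean transition
   matrix whose diagonal is each state's *persistence*.
4. **Metacell correlation networks** — Leiden pooling into ≥ 20-cell
   metacells, regularized geometric-mean profiles, Spearman networks and
   per-pair `Δρ = ρ_WT − ρ_MT`.
5. **Deconvolution + response** — gene × subset signature from the atlas,
   non-negative least squares fractions for bulk samples, one-tailed
   Mann–Whitney test / AUROC / median-baseline waterfall against responder
   labels.
6. **Ligand–receptor scoring** — directed interaction means with an
   expression gate and a label-permutation null (add-one p estimator).

A first-class synthetic-data module (`sclandscape.simulate`,
`sclandscape.scenario`) generates inputs with known planted structure for
every stage — clustered negative-binomial counts, kinetic spliced/unspliced
pairs, pseudo-bulk responder cohorts — so the whole pipeline runs and is
tested without any external download. See `docs/methods.md` for models,
parameter defaults and caveats.

## Worked example

`examples/01_composition_shift.py` implants a 2-fold depletion of subset C2
in the MT group (10,000 cells per group, six subsets) and runs the
composition test:

```
MT-row Pearson residuals (negative = depleted in MT):
subset
C0    1.42
C1    1.83
C2   -9.24
C3    2.13
C4    2.04
C5    0.49

calls at |r| > 3.5:
C2     depleted      (all others unchanged)

goodness of fit: chi2 = 199.3, dof = 5, p = 4e-41
```

Only the implanted subset clears the conservative threshold: C2's residual
−9.24 means its observed MT count sits 9.2 "standard deviations" below the
count expected if both groups shared one composition, while the other
subsets' residuals stay inside the null band. The χ² p-value summarizes the
table-wide departure from proportionality.

The other scripts in `examples/` walk through each capability the same way
(DEG calling, persistence of a transiting subset, WT-only co-regulation
recovery, responder stratification with AUROC 0.97 on a planted cohort, and
a group-specific CXCL13→CXCR5 axis); `examples/07_full_pipeline.py` runs
everything end to end from one simulated study via `RunConfig` /
`run_pipeline`.

A thin CLI mirrors the library for shell use:

```bash
sclandscape simulate --seed 1 --out data/
sclandscape composition --meta data/cell_meta.tsv --out comp.json
sclandscape run --config pipeline.yaml
```

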