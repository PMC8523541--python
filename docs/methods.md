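# Methods

`sclandscape` compares the immune landscape of two sample groups (labelled
WT and MT throughout, after the wild-type/mutant contrast the design
targets) across annotated cell subsets. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Composition testing by Pearson residuals

For a groups × subsets table of cell counts `O` with group totals `T_i`,
subset totals `T_j` and grand total `T_tot`, the expected count under
proportional composition is `E_ij = (T_i / T_tot) · T_j` and the Pearson
residual `r_ij = (O_ij − E_ij) / √E_ij`. The overall goodness of fit is
`χ² = Σ r_ij²` with `(rows−1)(columns−1)` degrees of freedom, upper tail.

Calls are made from the MT row: `r > threshold` augmented, `r < −threshold`
depleted, otherwise unchanged. The default family level 0.01 is Bonferroni-
divided by the number of subsets; for an 18-subset atlas this gives
5.6e-4, and the default working threshold 3.5 (two-sided normal tail
4.65e-4) clears it. Mosaic-export color bands follow |r| > 2 (p < 0.05) and
|r| > 4 (p < 0.0001).

Two caveats are deliberate properties, not bugs:

* **Scale equivariance.** Multiplying all counts by `k` scales every
  residual by `√k`; on tables with tens of thousands of cells even small
  proportional shifts produce large residuals, which is why a conservative
  cutoff is appropriate.
* **Conservatism under the null.** With both margins estimated from the
  data, `Var(r_ij) = (1 − T_i/T_tot)(1 − T_j/T_tot)` (the adjusted-residual
  factor), not 1. Raw residuals are therefore *under*-dispersed: on a
  two-equal-group, ten-subset null table the empirical rate of |r| > 2 is
  ≈ 0.3%, not the nominal 4.6%. The tests assert both the conservative
  bound and the exact adjusted-normal prediction. Treating r as standard
  normal (as the threshold derivation does) only makes calls more
  conservative.

Cells are treated as independent draws; patient-level pseudo-replication is
not modelled. A warning is emitted whenever one patient contributes more
than half of a cluster, which is the situation in which subsets should be
excluded from interpretation.

Empty subset columns get `r = 0` with a warning and are excluded from the
GOF degrees of freedom (avoids 0/0). All-zero tables and degenerate
single-row/column tables are rejected.

## Differential expression

Subset-DEG contrasts one subset against the rest of its major type;
group-DEG contrasts WT vs MT within a subset (WT is the foreground, so
positive fold changes mean higher in WT). Per gene: a two-sided Wilcoxon
rank-sum test and `avgLogFC = ln(mean(expm1 x) + 1) − ln(mean(expm1 y) + 1)`
on log-normalized values — **natural log**, the Seurat-v3 convention; add
×1.443 to convert to log2. Genes are tested only if expressed in ≥ 10% of
one side (`min_pct`); BH adjustment runs across tested genes; calls need
q < 0.05 and |avgLogFC| > 0.25.

The rank-sum p-value is exact (full enumeration, correct under ties) for
n₁+n₂ ≤ 12 and otherwise a tie-corrected, continuity-corrected normal
approximation. On heavily tied (zero-inflated) data that approximation is
anti-conservative deep in the tail (empirically ≈ 1.8× the nominal rate at
p = 1e-4), exactly where multiple-testing decisions are made. `call_degs`
therefore refines asymptotic p-values below 0.02 with a seeded Monte-Carlo
permutation estimate (9,999 label shuffles shared across genes; add-one
estimator, so the floor is 1e-4). Set `refine_below=0` for the plain
asymptotic pipeline.

Under the full null, BH's familywise rejection probability equals the q
threshold, so ~5% of marker-free datasets will contain at least one call
even with perfectly calibrated p-values; the per-gene false-call rate is
what stays far below 5%. The under-specified "high expression but low
nonzero ratio" exclusion is implemented as a *flag* (top expression decile
with foreground nonzero fraction < 0.25), reported but never auto-dropped.

## RNA velocity and subset transitions

The kinetic model is `du/dt = α − βu`, `ds/dt = βu − γs` with β fixed to 1
(time-unit normalization), so γ is identified as the slope of u against s
at steady state. `fit_gamma` regresses through the origin,
`γ̂ = Σ u·s / Σ s²`, over cells in the union of the top-`q` and bottom-`q`
quantiles of spliced expression (default q = 0.05); genes with fewer than
10 usable extreme cells are marked unfit and excluded downstream. The fit
runs on k-NN-pooled layers (default k = 30, `smoothing_k=1` for raw
counts): pooling is essential because Poisson noise in s otherwise
attenuates the slope by a factor ≈ 1/(1 + γ/α) (errors-in-variables), 10–40%
for shallow genes. The recovery benchmark (2,400 cells in three
steady-state subsets spanning a 4-fold expression range, q = 0.1, k = 50)
recovers γ within 5% for every gene with mean spliced count ≥ 5; a
homogeneous single-state population is the estimator's worst case and
recovery there is a few per cent (median) with occasional ~6% outliers.

Velocity is `v = u_smooth − γ̂ s_smooth`. The transition kernel scores each
of a cell's k nearest candidates (Euclidean in spliced space over fitted
genes, default k = 150) by the Pearson correlation ρ between the cell's
velocity vector and the spliced-space displacement to the candidate, then
row-normalizes `exp(ρ/σ)` (default σ = 0.05; σ→0 concentrates on the
best-aligned neighbor, zero-variance velocity degrades to a uniform kernel
with a warning). Self-transitions are excluded, so the reported
"persistence" (diagonal of the subset-averaged matrix
`M_AB = mean_{c∈A} Σ_{c'∈B} P_{cc'}`) is the probability mass a subset's
cells place on *other cells of the same subset*. WT and MT are processed
separately. Numerical identity with external velocity tools is not a goal
(their defaults are version-dependent); the contract is directional and
ordering behaviour — e.g. persistence decreases monotonically as the
planted transiting fraction grows, and a group whose cells are en route to
another state shows visibly lower persistence than its counterpart.

2-D arrow export is `arrow_c = Σ_{c'} P_{cc'}(e_{c'} − e_c)` on a supplied
embedding; embeddings are inputs, never computed here.

## Metacell correlation networks

Cells are partitioned by seeded Leiden community detection on a symmetrized
k-NN graph in expression space (default K = 100 neighbors), raising the
resolution until communities are metacell-sized and then merging any
community under `min_size` (default 20) into its most-connected neighbor.
This is a deliberate single-pass simplification of bootstrapped
co-clustering pipelines; pooling quality, not procedural fidelity, is the
contract, and partition purity on separated synthetic subsets is tested.
Down-sampling before pooling is replaced by library-size scaling (to the
median library by default).

Each metacell is summarized by the regularized geometric mean of scaled
counts x: `profile(m,g) = exp(mean_{c∈m} ln(1 + x_cg)) − 1` (pseudo-count
fixed at 1, exposed as a parameter). Gene–gene association uses Spearman's
rank correlation with average-rank ties; constant genes give NaN. Group
comparison reports `delta = rho_WT − rho_MT` per anchor–target pair, sorted
by |delta|. The default anchors are RBPJ and NOTCH1 and the default target
panel is RGS2, NOTCH1, RGS1, PDCD1, CRTAM, CXCR6, TIA1, HIF1A, NAB1, ITGAE —
genes tied to tissue-resident-memory T-cell differentiation and
maintenance. Pooling provably reduces the zero fraction and, on planted
latent correlations, recovers the association with far less attenuation
than cell-level correlation — the module's reason to exist, verified by
simulation.

## Deconvolution and responder stratification

The signature matrix `S(g,k)` is the mean linear-scale normalized
expression of gene g over cells of subset k, over a selected gene set
(HVGs by default; subsets under 10 cells are excluded with a warning).
Bulk samples are decomposed by active-set non-negative least squares,
`min_f ||b − S f||₂ s.t. f ≥ 0`, then renormalized to the simplex (raw
coefficients are retained in the output; renormalized fractions are the
default score). NNLS replaces the support-vector-regression deconvolution
used by the tool this emulates — transparent and dependency-free; published
cohort p-values from that tool are reference points, not test targets.
Estimates are scale-invariant per sample and exact on noiseless mixtures;
at 5% Gaussian noise the fraction RMSE stays below 0.05.

Response association: one-tailed Mann–Whitney U (responders stochastically
greater; exact enumeration for n ≤ 12, tie-corrected normal otherwise),
rank-based AUROC = U/(n₁n₀) with ties counted ½, and a waterfall of score
minus cohort median (even-n median is the midpoint, so no sample need sit
at zero).

## Ligand–receptor interaction scoring

For a directed (sender, receiver) pair and single-gene ligand/receptor, the
statistic is `m = (mean ligand in sender + mean receptor in receiver)/2`
on log-normalized values, reported only when both expressing fractions are
≥ 10%. Significance: cluster labels shuffled across cells (default 1,000
permutations), `p = (1 + #{m_perm ≥ m_obs})/(n_perm + 1)` — the add-one
estimator, floor 1/(n_perm+1). The permuted statistic ignores the
expression gate (the gate is a reporting rule on observed data, not part of
the null). Multi-subunit complexes are rejected explicitly. The bundled
pair panel (CXCL13–CXCR5 and other canonical immune axes) is a small
hand-picked stand-in, editable TSV, not a vendored database. WT and MT are
scored separately.

## Normalization and HVG selection

`lognormalize`: `value = ln(1 + count · scale_factor / libsize)` with
scale factor 10,000; zero-library cells are a hard error naming the
barcode. HVG score: variance of normalized expression z-scored within 20
equal-frequency bins of mean expression (bins by stable sort, so the
procedure is exactly reproducible); zero-variance genes are never
selectable; ties break lexicographically on gene id. Typical calls use
2,000 HVGs for neighborhood construction and 7,431 for signatures, matching
common atlas practice.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (spec, seed); per-stage child seeds
come from hashing stage names, so stages are mutually isolated. The
negative binomial is parameterized by mean and dispersion
(variance = μ + μ²/θ), θ = 2 by default — typical UMI overdispersion; gene
baseline means are log-normal (median 0.25 UMI, log-sd 1.2) and per-cell
library factors log-normal (log-sd 0.35). Kinetics layers are Poisson
around the analytic ODE solutions, with per-cell log-normal depth factors
(log-sd 0.35) that cancel in the u/s ratio. Bulk cohorts are `S·f + noise`
clipped at zero, with `noise_sd` expressed as a fraction of the cohort-mean
signal, and responder labels Bernoulli with
logit = intercept + slope · (designated subset's fraction).

The default study scenario (`default_scenario`) uses 2,000 cells per group
over ten subsets, with C2 (the T_RM-like role), C9 (T_FH-like) and C8
(B-cell-like) depleted 2.5-fold in MT, C1 augmented, a WT-only
RBPJ–NOTCH1–ITGAE co-regulation in C2, a CXCL13→CXCR5 axis, and 10% (WT)
vs 45% (MT) of C2 cells in transit toward C0 with transit times uniform on
(0.1, 1.5) and between-subset kinetic scales log-normal (sd 0.25).

Not emulated: real gene–gene covariance structure, doublets, ambient RNA,
batch effects, patient-level variance components, multi-subunit receptor
complexes. Passing tests therefore demonstrate correct arithmetic,
calibration under the stated sampling models, and recovery of planted
structure — not robustness to the full messiness of real tumor data.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run on
one CPU in well under the stated budgets: calibration loops use 200–1,000
seeds of small tables, DEG calibration 200 seeds of 60-gene/400-cell
datasets, velocity recovery 2,400 cells/40 genes, deconvolution cohorts of
24–100 samples over 120 genes, interaction nulls 200 pairs at 99
permutations. Every stochastic step takes an explicit seed; pipeline reruns
with the same config reproduce deterministic outputs byte-identically.

## Known limitations

* Composition inference is a fixed-table χ² decomposition; no
  Dirichlet-multinomial or mixed-effects alternative is provided.
* The velocity estimator is the steady-state one; dynamical/latent-time
  models are out of scope, and absolute persistence values depend on kernel
  parameters (k, σ) — only comparisons across groups or conditions at fixed
  parameters are meaningful.
* Deconvolution assumes the bulk mixture lives in the signature's span;
  platform shifts between the single-cell reference and bulk data are not
  corrected.
* The interaction score treats subsets as well-mixed bags of cells; no
  spatial structure.
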