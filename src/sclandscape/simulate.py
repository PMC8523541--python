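"""Synthetic data with the statistical structure each analysis stage assumes.

Real tumor data are never required: these generators emulate

* two-group (WT/MT) clustered cell populations with implanted subset
  proportion shifts (for composition testing),
* clustered negative-binomial UMI counts with marker-gene structure
  (for DEG calling, signatures, metacells, interactions),
* spliced/unspliced layer pairs obeying the linear transcription-splicing-
  degradation kinetics du/dt = a - b*u, ds/dt = b*u - g*s (for velocity),
* pseudo-bulk mixtures with known subset fractions and responder labels
  coupled to one subset's fraction (for deconvolution).

All generators are pure functions of (spec, seed): identical seeds reproduce
bit-identical outputs.  Per-stage child seeds are derived by stable hashing
of stage names, so adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AnnotatedCounts, ValidationError


def child_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# composition scenarios
# ---------------------------------------------------------------------------

@dataclass
class CompositionScenario:
    """Two-group multinomial composition with implanted shifts.

    ``proportions`` maps each group to a probability vector over subsets;
    ``perturbed_subsets`` records which subsets were deliberately shifted and
    in which direction (ground truth for recovery tests).
    """

    n_subsets: int
    group_totals: dict  # {"WT": int, "MT": int}
    proportions: dict  # {"WT": vec, "MT": vec}
    perturbed_subsets: list = field(default_factory=list)  # [(subset, "augmented"/"depleted")]

    def __post_init__(self):
        for grp, vec in self.proportions.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.n_subsets,):
                raise ValidationError(f"{grp} proportions must have length {self.n_subsets}")
            if abs(vec.sum() - 1.0) > 1e-12:
                raise ValidationError(f"{grp} proportions sum to {vec.sum()}, not 1")
            if (vec < 0).any():
                raise ValidationError("proportions must be non-negative")
            self.proportions[grp] = vec
        for grp, tot in self.group_totals.items():
            if tot < 1:
                raise ValidationError("group totals must be >= 1")

    @property
    def subsets(self) -> list:
        return [f"C{j}" for j in range(self.n_subsets)]

    @classmethod
    def with_fold_changes(
        cls,
        n_subsets: int,
        group_totals: dict,
        mt_folds: dict | None = None,
        base_proportions=None,
    ) -> "CompositionScenario":
        """Uniform (or given) WT proportions; MT proportions multiply the
        subsets named in ``mt_folds`` by their fold and renormalize."""
        base = (
            np.full(n_subsets, 1.0 / n_subsets)
            if base_proportions is None
            else np.asarray(base_proportions, dtype=float)
        )
        base = base / base.sum()
        mt = base.copy()
        perturbed = []
        for subset, fold in (mt_folds or {}).items():
            j = int(str(subset).lstrip("C"))
            if fold <= 0:
                raise ValidationError("fold must be positive")
            mt[j] *= fold
            perturbed.append((f"C{j}", "augmented" if fold > 1 else "depleted"))
        mt = mt / mt.sum()
        return cls(n_subsets, dict(group_totals), {"WT": base, "MT": mt}, perturbed)


def gen_composition(
    scn: CompositionScenario, seed: int, patients_per_group: int = 5
) -> pd.DataFrame:
    """Draw per-cell (patient, group, cluster) labels, multinomially per group.

    Returns a DataFrame indexed by synthetic barcode with columns
    ``patient``, ``group``, ``cluster``.
    """
    rng = np.random.default_rng(child_seed(seed, "composition"))
    rows = []
    pid = 0
    for grp in ("WT", "MT"):
        total = scn.group_totals[grp]
        clusters = rng.choice(scn.n_subsets, size=total, p=scn.proportions[grp])
        patients = [f"P{pid + 1 + (i % patients_per_group)}" for i in range(total)]
        for i, (cl, pat) in enumerate(zip(clusters, patients)):
            rows.append((f"{grp}-{i:06d}", pat, grp, f"C{cl}"))
        pid += patients_per_group
    df = pd.DataFrame(rows, columns=["barcode", "patient", "group", "cluster"])
    return df.set_index("barcode")


# ---------------------------------------------------------------------------
# negative-binomial expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with variance mu + mu**2/theta (gamma-Poisson)."""
    if np.isinf(theta):
        return rng.poisson(mu)
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-300) / theta)
    return rng.poisson(lam)


def gen_expression(
    labels: pd.DataFrame,
    n_genes: int,
    marker_plan: dict | None = None,
    seed: int = 0,
    theta: float = 2.0,
    base_mean_median: float = 0.25,
    base_mean_log_sd: float = 1.2,
    libsize_log_sd: float = 0.35,
    gene_names: list | None = None,
    coexpression_plan: list | None = None,
) -> AnnotatedCounts:
    """Clustered negative-binomial UMI counts with planted marker genes.

    ``marker_plan`` maps a gene name to ``(subset, fold_change)`` or
    ``(subset, fold_change, group)``: the gene's mean is multiplied by
    ``fold_change`` in cells of that subset (optionally only within one
    group, for planting group-contrasted patterns).  ``coexpression_plan``
    entries are dicts ``{"genes": [...], "subset": ..., "group": None or
    "WT"/"MT", "sd": float}``: the listed genes share a log-normal latent
    factor in the matching cells, planting a positive gene-gene correlation.
    Baseline gene means are log-normal across genes (median
    ``base_mean_median`` UMI, typical for 10x data where most genes are
    shallow); per-cell library-size factors are log-normal; overdispersion
    theta=2 gives variance mu+mu^2/2, typical UMI overdispersion.
    """
    rng = np.random.default_rng(child_seed(seed, "expression"))
    if gene_names is None:
        gene_names = [f"G{i:05d}" for i in range(n_genes)]
    if len(gene_names) != n_genes:
        raise ValidationError("gene_names length must equal n_genes")
    base = np.exp(rng.normal(np.log(base_mean_median), base_mean_log_sd, size=n_genes))
    libfac = np.exp(rng.normal(0.0, libsize_log_sd, size=len(labels)))
    clusters = labels["cluster"].to_numpy()
    groups = labels["group"].to_numpy()
    mu = np.outer(base, libfac)  # genes x cells
    gene_index = {g: i for i, g in enumerate(gene_names)}
    for gene, plan in (marker_plan or {}).items():
        plans = plan if isinstance(plan[0], (list, tuple)) else [plan]
        for p in plans:
            subset, fold = p[0], p[1]
            grp = p[2] if len(p) > 2 else None
            if fold <= 0:
                raise ValidationError(f"fold-change for {gene} must be positive")
            mask = clusters == subset
            if grp is not None:
                mask &= groups == grp
            mu[gene_index[gene], mask] *= fold
    for entry in coexpression_plan or []:
        mask = clusters == entry["subset"]
        if entry.get("group") is not None:
            mask &= groups == entry["group"]
        factor = np.exp(rng.normal(0.0, entry.get("sd", 0.8), size=int(mask.sum())))
        for gene in entry["genes"]:
            mu[gene_index[gene], mask] *= factor
    counts = _nb_draw(rng, mu, theta)
    return AnnotatedCounts(
        sp.csc_matrix(counts),
        gene_names,
        list(labels.index),
        labels.copy(),
    )


# ---------------------------------------------------------------------------
# splicing kinetics
# ---------------------------------------------------------------------------

@dataclass
class KineticsSpec:
    """Transcription-splicing-degradation rates and subset occupancies.

    Each subset k has per-gene transcription rates alpha * subset_scale[k];
    a cell of subset k is either at the steady state (u* = a/b, s* = a/g) or
    in transit from its own steady state toward a target subset's rates,
    sampled at a time drawn from ``transit_time_range`` along the analytic
    relaxation of the linear ODE system.  beta is fixed to 1 by default
    (time-unit normalization) so gamma is identified as the u/s slope.

    ``cell_size_log_sd`` adds per-cell log-normal depth factors multiplying
    both layers' means, emulating UMI capture variation; the factor cancels
    in the u/s ratio, so gamma is unchanged, but it gives the spliced axis
    the cell-to-cell dynamic range that steady-state slope fitting relies on.
    """

    alpha: np.ndarray  # per-gene baseline transcription rates
    gamma: np.ndarray  # per-gene degradation rates
    beta: float = 1.0
    subset_alpha_scale: dict = field(default_factory=dict)  # subset -> per-gene multiplier
    transit: dict = field(default_factory=dict)  # subset -> (target subset, fraction in transit)
    transit_time_range: tuple = (0.05, 0.5)
    cell_size_log_sd: float = 0.35

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if (self.alpha <= 0).any() or (self.gamma <= 0).any() or self.beta <= 0:
            raise ValidationError("all kinetic rates must be positive")
        for subset, (target, frac) in self.transit.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("transit occupancies must be in [0, 1]")

    def subset_alpha(self, subset: str) -> np.ndarray:
        scale = self.subset_alpha_scale.get(subset)
        return self.alpha if scale is None else self.alpha * np.asarray(scale, float)


def _relaxation(alpha_from, alpha_to, beta, gamma, t):
    """u(t), s(t) relaxing from the ``alpha_from`` steady state toward
    ``alpha_to`` rates under du/dt = a - b u, ds/dt = b u - g s."""
    delta = alpha_from - alpha_to
    u = alpha_to / beta + (delta / beta) * np.exp(-beta * t)
    # avoid the b == g removable singularity
    g = np.where(np.abs(gamma - beta) < 1e-9, gamma + 1e-6, gamma)
    s = (
        alpha_to / g
        + (delta / (g - beta)) * np.exp(-beta * t)
        - (delta * beta / (g * (g - beta))) * np.exp(-g * t)
    )
    return u, s


def gen_kinetics(labels: pd.DataFrame, spec: KineticsSpec, seed: int = 0):
    """Spliced/unspliced layers from the kinetic model.

    Returns ``(spliced, unspliced, truth)`` where truth records per-gene
    gamma/beta, the per-cell transit mask and sampled times.
    """
    rng = np.random.default_rng(child_seed(seed, "kinetics"))
    clusters = labels["cluster"].to_numpy()
    n_genes, n_cells = spec.alpha.size, len(labels)
    u_mean = np.empty((n_genes, n_cells))
    s_mean = np.empty((n_genes, n_cells))
    transiting = np.zeros(n_cells, dtype=bool)
    times = np.zeros(n_cells)
    lo, hi = spec.transit_time_range
    for subset in np.unique(clusters):
        idx = np.flatnonzero(clusters == subset)
        a_own = spec.subset_alpha(subset)
        target, frac = spec.transit.get(subset, (None, 0.0))
        n_tr = int(round(frac * idx.size))
        tr_idx = rng.choice(idx, size=n_tr, replace=False) if n_tr else np.array([], int)
        ss_idx = np.setdiff1d(idx, tr_idx)
        u_mean[:, ss_idx] = (a_own / spec.beta)[:, None]
        s_mean[:, ss_idx] = (a_own / spec.gamma)[:, None]
        if n_tr:
            a_tgt = spec.subset_alpha(target)
            t = rng.uniform(lo, hi, size=n_tr)
            u_t, s_t = _relaxation(
                a_own[:, None], a_tgt[:, None], spec.beta, spec.gamma[:, None], t[None, :]
            )
            u_mean[:, tr_idx] = u_t
            s_mean[:, tr_idx] = s_t
            transiting[tr_idx] = True
            times[tr_idx] = t
    size = np.exp(rng.normal(0.0, spec.cell_size_log_sd, size=n_cells))
    unspliced = rng.poisson(np.maximum(u_mean, 0.0) * size)
    spliced = rng.poisson(np.maximum(s_mean, 0.0) * size)
    truth = {
        "gamma": spec.gamma.copy(),
        "beta": spec.beta,
        "transiting": transiting,
        "times": times,
    }
    return sp.csc_matrix(spliced), sp.csc_matrix(unspliced), truth


# ---------------------------------------------------------------------------
# bulk cohorts
# ---------------------------------------------------------------------------

@dataclass
class BulkCohortSpec:
    """Pseudo-bulk mixtures with known fractions and coupled responder labels.

    ``noise_sd`` is the Gaussian noise standard deviation expressed as a
    fraction of the cohort-mean signal.  Responder labels are Bernoulli with
    logit = intercept + slope * (designated subset's fraction); the slope's
    sign encodes the planted direction of association.
    """

    n_samples: int
    designated_subset: str
    noise_sd: float = 0.05
    slope: float = 40.0
    intercept: float = -8.0
    true_fractions: np.ndarray | None = None
    dirichlet_alpha: float = 2.0
    seed: int = 0

    def fractions(self, n_subsets: int, rng: np.random.Generator) -> np.ndarray:
        if self.true_fractions is not None:
            f = np.asarray(self.true_fractions, dtype=float)
            if f.shape != (self.n_samples, n_subsets):
                raise ValidationError("true_fractions must be samples x subsets")
            if np.abs(f.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValidationError("fraction rows must sum to 1")
            return f
        return rng.dirichlet(np.full(n_subsets, self.dirichlet_alpha), size=self.n_samples)


def gen_bulk_cohort(signature: pd.DataFrame, spec: BulkCohortSpec):
    """Bulk = S @ f + noise, clipped at zero, with responder labels.

    ``signature`` is a genes x subsets DataFrame.  Returns
    ``(bulk_df samples x genes, labels Series of 0/1, truth dict)``.
    """
    rng = np.random.default_rng(child_seed(spec.seed, "bulk"))
    subsets = list(signature.columns)
    if spec.designated_subset not in subsets:
        raise ValidationError(f"{spec.designated_subset} not a signature column")
    f = spec.fractions(len(subsets), rng)
    clean = f @ signature.to_numpy(float).T  # samples x genes
    scale = clean.mean() if clean.mean() > 0 else 1.0
    bulk = clean + rng.normal(0.0, spec.noise_sd * scale, size=clean.shape)
    bulk = np.clip(bulk, 0.0, None)
    score = f[:, subsets.index(spec.designated_subset)]
    from scipy.special import expit

    logit = spec.intercept + spec.slope * score
    labels = rng.random(spec.n_samples) < expit(logit)
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    bulk_df = pd.DataFrame(bulk, index=samples, columns=signature.index)
    truth = {"fractions": pd.DataFrame(f, index=samples, columns=subsets)}
    return bulk_df, pd.Series(labels.astype(int), index=samples, name="responder"), truth
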