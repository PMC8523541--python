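"""Steady-state RNA velocity and subset transition/persistence matrices.

Under the kinetic model du/dt = a - b*u, ds/dt = b*u - g*s, cells at steady
state satisfy u = (g/b) * s, so the degradation/splicing slope gamma is
identified (with b fixed to 1 by time-unit normalization) by a regression
through the origin on cells in the extreme quantiles of spliced expression,

    gamma_g = sum(u*s) / sum(s^2)   over extreme-quantile cells.

Velocity is the residual from the steady-state line on k-NN-smoothed layers,
v = u_smooth - gamma * s_smooth: positive for genes being induced, negative
for repressed.  A cell's transition kernel scores each k-NN candidate c' by
the Pearson correlation rho between the cell's velocity vector and the
spliced-space displacement s(c') - s(c) across fitted genes, then softmaxes,
P(c -> c') proportional to exp(rho / sigma), self excluded, row-normalized.

The subset transition matrix averages the kernel over cluster labels,
M[A, B] = mean over cells c in A of sum over c' in B of P(c, c'); its
diagonal is the persistence of each subset.  Because self-transitions are
excluded from P, persistence measures mass on *other* cells of the same
subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io import ValidationError

DEFAULT_EXTREME_Q = 0.05
DEFAULT_SMOOTHING_K = 30
DEFAULT_KERNEL_K = 150
DEFAULT_SIGMA = 0.05
MIN_FIT_CELLS = 10


@dataclass
class GammaFit:
    gamma: pd.Series  # per fitted gene
    extreme_quantile: float
    fit_cells: dict = field(default_factory=dict)  # gene -> index array

    @property
    def fitted_genes(self) -> list:
        return list(self.gamma.index)


@dataclass
class VelocityField:
    v: np.ndarray  # fitted genes x cells
    gene_ids: list
    cell_ids: list
    smoothing_k: int


@dataclass
class TransitionModel:
    P: sp.csr_matrix  # cell x cell, row-stochastic over candidate sets
    sigma: float
    cell_ids: list
    M: pd.DataFrame | None = None  # subset x subset mean transition
    persistence: pd.Series | None = None


def _to_dense(mat) -> np.ndarray:
    return mat.toarray() if sp.issparse(mat) else np.asarray(mat, float)


def fit_gamma(
    spliced,
    unspliced,
    gene_ids=None,
    q: float = DEFAULT_EXTREME_Q,
    smoothing_k: int = DEFAULT_SMOOTHING_K,
    min_cells: int = MIN_FIT_CELLS,
) -> GammaFit:
    """Per-gene steady-state slope on extreme-quantile cells.

    For each gene, cells in the union of the top-q and bottom-q quantiles of
    spliced expression anchor a regression through the origin; genes with
    fewer than ``min_cells`` usable cells (nonzero u+s among the extremes) or
    no spliced signal are marked unfit and excluded downstream.

    The slope is fitted on k-NN-pooled layers (``smoothing_k=1`` fits raw
    counts): pooling is essential because Poisson noise in the spliced
    counts otherwise attenuates the regression-through-origin slope
    (errors-in-variables bias of order 1/mean(s)).
    """
    s = _to_dense(spliced)
    u = _to_dense(unspliced)
    if s.shape != u.shape:
        raise ValidationError("spliced and unspliced layers must share axes")
    if smoothing_k > 1:
        space = np.log1p(s.T)
        s = _knn_average(s, space, smoothing_k)
        u = _knn_average(u, space, smoothing_k)
    n_genes, n_cells = s.shape
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    gammas, fit_cells = {}, {}
    for g in range(n_genes):
        sg, ug = s[g], u[g]
        lo, hi = np.quantile(sg, [q, 1 - q])
        extreme = np.flatnonzero((sg <= lo) | (sg >= hi))
        usable = extreme[(sg[extreme] + ug[extreme]) > 0]
        denom = float((sg[usable] ** 2).sum())
        if usable.size < min_cells or denom == 0.0:
            continue
        gammas[gene_ids[g]] = float((ug[usable] * sg[usable]).sum() / denom)
        fit_cells[gene_ids[g]] = usable
    return GammaFit(
        gamma=pd.Series(gammas, name="gamma", dtype=float),
        extreme_quantile=q,
        fit_cells=fit_cells,
    )


def _knn_average(X: np.ndarray, space: np.ndarray, k: int) -> np.ndarray:
    """Average columns of X (features x cells) over each cell's k nearest
    neighbors (including self) in ``space`` (cells x dims); k=1 is identity."""
    if k <= 1:
        return X.copy()
    k = min(k, space.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(space)
    _, idx = nn.kneighbors(space)
    return X[:, idx].mean(axis=2)


def compute_velocity(
    fit: GammaFit,
    spliced,
    unspliced,
    gene_ids=None,
    cell_ids=None,
    nn_space: np.ndarray | None = None,
    smoothing_k: int = DEFAULT_SMOOTHING_K,
) -> VelocityField:
    """v = u_smooth - gamma * s_smooth on fitted genes.

    ``nn_space`` (cells x dims, e.g. normalized HVG expression) defines the
    smoothing neighborhoods; by default the spliced layer of fitted genes is
    used.  ``smoothing_k=1`` returns raw residuals.
    """
    s = _to_dense(spliced)
    u = _to_dense(unspliced)
    n_genes, n_cells = s.shape
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    keep = [i for i, g in enumerate(gene_ids) if g in fit.gamma.index]
    if not keep:
        raise ValidationError("no fitted genes in the provided layers")
    s, u = s[keep], u[keep]
    kept_ids = [gene_ids[i] for i in keep]
    if nn_space is None:
        nn_space = np.log1p(s.T)
    s_sm = _knn_average(s, nn_space, smoothing_k)
    u_sm = _knn_average(u, nn_space, smoothing_k)
    g = fit.gamma.loc[kept_ids].to_numpy()[:, None]
    return VelocityField(
        v=u_sm - g * s_sm, gene_ids=kept_ids, cell_ids=list(cell_ids),
        smoothing_k=smoothing_k,
    )


def transition_kernel(
    vel: VelocityField,
    spliced,
    gene_ids=None,
    k: int = DEFAULT_KERNEL_K,
    sigma: float = DEFAULT_SIGMA,
) -> TransitionModel:
    """Row-stochastic cell transition kernel over k-NN candidate sets.

    ``spliced`` provides the displacement space (genes x cells, restricted
    internally to the fitted genes).  A zero-variance velocity vector yields
    rho = 0 for all candidates (uniform kernel) with a warning.
    """
    s = _to_dense(spliced)
    if gene_ids is not None:
        keep = [i for i, g in enumerate(gene_ids) if g in set(vel.gene_ids)]
        s = s[keep]
    if s.shape[0] != len(vel.gene_ids):
        raise ValidationError("spliced matrix must cover the fitted genes")
    n_cells = s.shape[1]
    if k >= n_cells:
        k = n_cells - 1
    coords = s.T  # cells x fitted genes
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows, cols, vals = [], [], []
    warned = False
    v = vel.v
    for c in range(n_cells):
        cand = idx[c][idx[c] != c][:k]
        delta = coords[cand] - coords[c]  # cand x genes
        vc = v[:, c]
        vc_c = vc - vc.mean()
        denom_v = np.sqrt((vc_c**2).sum())
        d_c = delta - delta.mean(axis=1, keepdims=True)
        denom_d = np.sqrt((d_c**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (d_c @ vc_c) / (denom_d * denom_v)
        rho = np.where(np.isfinite(rho), rho, 0.0)
        if denom_v == 0 and not warned:
            warnings.warn("zero-variance velocity vector: uniform kernel used")
            warned = True
        w = np.exp((rho - rho.max()) / sigma)
        w /= w.sum()
        rows.extend([c] * cand.size)
        cols.extend(cand.tolist())
        vals.extend(w.tolist())
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n_cells, n_cells))
    return TransitionModel(P=P, sigma=sigma, cell_ids=list(vel.cell_ids))


def subset_transitions(model: TransitionModel, cluster_labels) -> TransitionModel:
    """Subset x subset mean transition matrix and its diagonal (persistence).

    M[A, B] = (1/|A|) * sum over c in A of sum over c' in B of P[c, c'].
    """
    labels = np.asarray(cluster_labels)
    if labels.size != model.P.shape[0]:
        raise ValidationError("labels must cover all cells in P")
    subsets = sorted(np.unique(labels), key=lambda c: (len(str(c)), str(c)))
    onehot = np.stack([(labels == s).astype(float) for s in subsets], axis=1)
    mass = model.P @ onehot  # cells x subsets
    M = np.stack([mass[labels == s].mean(axis=0) for s in subsets])
    model.M = pd.DataFrame(M, index=subsets, columns=subsets)
    model.persistence = pd.Series(np.diag(M), index=subsets, name="persistence")
    return model


def embed_arrows(model: TransitionModel, embedding: np.ndarray) -> pd.DataFrame:
    """Expected 2-D displacement per cell: arrow_c = sum P[c,c'] (e_c' - e_c)."""
    emb = np.asarray(embedding, float)
    if emb.shape != (model.P.shape[0], 2):
        raise ValidationError("embedding must be cells x 2")
    expected = model.P @ emb
    arrows = expected - emb  # rows of P sum to 1
    return pd.DataFrame(
        {"x": emb[:, 0], "y": emb[:, 1], "dx": arrows[:, 0], "dy": arrows[:, 1]},
        index=model.cell_ids,
    )
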