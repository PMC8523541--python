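"""Log-normalization and highly-variable-gene selection.

Normalization follows the standard single-cell recipe: each cell's counts are
scaled to a common library size (default 10,000) and natural-log transformed,
value(g, c) = ln(1 + count(g, c) * scale_factor / libsize(c)).

HVG selection ranks genes by a binned dispersion score: the variance of
normalized expression, z-scored within 20 equal-frequency bins of mean
expression.  Binning removes the mean-variance trend so that lowly and highly
expressed genes compete on even terms.  Ties break lexicographically on
gene id for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AnnotatedCounts, ValidationError

DEFAULT_SCALE_FACTOR = 10_000.0


@dataclass
class NormalizedMatrix:
    values: sp.csc_matrix  # genes x cells, ln(1 + scaled counts)
    scale_factor: float
    gene_ids: list
    cell_ids: list

    @property
    def shape(self):
        return self.values.shape

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def subset_cells(self, mask) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            self.values[:, idx],
            self.scale_factor,
            self.gene_ids,
            [self.cell_ids[i] for i in idx],
        )


@dataclass
class HvgSet:
    gene_ids: list  # top-n, in rank order
    n_requested: int
    dispersion_scores: pd.Series  # score for every scored gene


def lognormalize(
    counts: AnnotatedCounts, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """Library-size normalize and natural-log transform raw counts.

    Raises :class:`ValidationError` naming the barcode if a cell has zero
    total counts (its proportions are undefined).
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    libsize = np.asarray(counts.counts.sum(axis=0)).ravel()
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValidationError(
            f"zero-library cell(s): {[counts.cell_ids[i] for i in zero[:5]]}"
        )
    mat = sp.csc_matrix(counts.counts, dtype=float)
    # scale each column, then log1p on the sparse data vector
    mat = mat @ sp.diags(scale_factor / libsize)
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        sp.csc_matrix(mat), float(scale_factor), counts.gene_ids, counts.cell_ids
    )


def _row_mean_var(values: sp.csc_matrix):
    n = values.shape[1]
    mean = np.asarray(values.mean(axis=1)).ravel()
    sq = values.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def hvg_scores(norm: NormalizedMatrix, n_bins: int = 20) -> pd.Series:
    """Binned dispersion score per gene (z-scored variance within mean bins).

    Genes with zero variance receive no score (they can never be variable).
    """
    mean, var = _row_mean_var(norm.values)
    scored = pd.DataFrame(
        {"mean": mean, "var": var}, index=pd.Index(norm.gene_ids, name="gene")
    )
    scored = scored[scored["var"] > 0]
    if scored.empty:
        return pd.Series(dtype=float, name="dispersion")
    # equal-frequency bins: sort genes by (mean, gene id) and chunk into
    # n_bins nearly equal groups; z-score the variance within each bin
    order = scored.sort_values(["mean"], kind="stable").index
    z = pd.Series(np.nan, index=scored.index, name="dispersion")
    for chunk in np.array_split(np.asarray(order), min(n_bins, len(scored))):
        v = scored.loc[chunk, "var"]
        sd = v.std(ddof=1)
        z.loc[chunk] = 0.0 if (len(v) < 2 or sd == 0) else (v - v.mean()) / sd
    return z


def select_hvg(norm: NormalizedMatrix, n: int, n_bins: int = 20) -> HvgSet:
    """Top-``n`` genes by binned dispersion, in rank order.

    If ``n`` exceeds the number of genes with nonzero variance, all scored
    genes are returned with a warning.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    scores = hvg_scores(norm, n_bins=n_bins)
    if n > len(scores):
        warnings.warn(
            f"requested {n} HVGs but only {len(scores)} genes have nonzero variance"
        )
    order = scores.reset_index().sort_values(
        ["dispersion", "gene"], ascending=[False, True]
    )["gene"]
    top = order.head(n).tolist()
    return HvgSet(gene_ids=top, n_requested=n, dispersion_scores=scores)
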