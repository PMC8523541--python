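"""Signature-matrix deconvolution of bulk expression and response stratification.

A signature matrix S (genes x subsets) holds each subset's mean linear-scale
normalized expression over a selected gene set (highly variable genes by
default).  A bulk sample b is decomposed by non-negative least squares,

    min_f || b - S f ||_2  subject to  f >= 0,

and the coefficient vector is renormalized to the simplex so entries read as
subset fractions.  The fraction of a designated subset (e.g. the
tissue-resident memory T-cell subset) is then the per-sample score used for
response stratification: a one-tailed Mann-Whitney U test of responders vs
non-responders, the rank-based AUROC, and a waterfall of score minus cohort
median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from ._stats import auroc, rank_sum_test
from .io import ValidationError
from .preprocess import NormalizedMatrix

__all__ = [
    "SignatureMatrix", "FractionEstimate", "ResponseAssessment",
    "build_signature", "estimate_fractions", "mann_whitney_one_tailed",
    "auroc", "waterfall", "assess_response",
]

MIN_SUBSET_CELLS = 10


@dataclass
class SignatureMatrix:
    S: pd.DataFrame  # genes x subsets, non-negative
    gene_set_id: str = "hvg"

    def __post_init__(self):
        if (self.S.to_numpy() < 0).any():
            raise ValidationError("signature entries must be non-negative")
        dead = self.S.columns[(self.S.to_numpy() == 0).all(axis=0)]
        if len(dead):
            raise ValidationError(f"all-zero signature column(s): {list(dead)}")

    @property
    def subset_order(self) -> list:
        return list(self.S.columns)


@dataclass
class FractionEstimate:
    f: pd.DataFrame  # samples x subsets, simplex rows
    raw: pd.DataFrame  # pre-renormalization NNLS coefficients
    residual_norm: pd.Series


@dataclass
class ResponseAssessment:
    scores: pd.Series
    labels: pd.Series
    u_stat: float
    p_one_tailed: float
    auroc: float
    waterfall: pd.Series


def build_signature(
    norm: NormalizedMatrix,
    cluster_labels,
    gene_set=None,
    min_cells: int = MIN_SUBSET_CELLS,
    gene_set_id: str = "hvg",
) -> SignatureMatrix:
    """S(g, k) = mean linear-scale normalized expression of g in subset k.

    Subsets with fewer than ``min_cells`` cells are excluded with a warning
    (their means would be too noisy to anchor deconvolution).
    """
    labels = np.asarray(cluster_labels)
    if gene_set is None:
        gene_set = list(norm.gene_ids)
    gene_idx = [norm.gene_ids.index(g) for g in gene_set]
    lin = norm.values[gene_idx, :].copy()
    lin.data = np.expm1(lin.data)
    cols = {}
    for subset in sorted(np.unique(labels), key=lambda c: (len(str(c)), str(c))):
        mask = labels == subset
        if mask.sum() < min_cells:
            warnings.warn(f"subset {subset} has {int(mask.sum())} cells (< {min_cells}): excluded")
            continue
        cols[subset] = np.asarray(lin[:, np.flatnonzero(mask)].mean(axis=1)).ravel()
    if not cols:
        raise ValidationError("no subset met the cell floor")
    return SignatureMatrix(
        S=pd.DataFrame(cols, index=list(gene_set)), gene_set_id=gene_set_id
    )


def estimate_fractions(bulk: pd.DataFrame, sig: SignatureMatrix) -> FractionEstimate:
    """Active-set NNLS per bulk sample, then simplex renormalization.

    ``bulk`` is samples x genes on a linear scale; genes are intersected with
    the signature's gene set (error if the intersection is empty or smaller
    than 2x the number of subsets).
    """
    shared = [g for g in sig.S.index if g in bulk.columns]
    if not shared:
        raise ValidationError("no genes shared between bulk data and signature")
    if len(shared) < 2 * sig.S.shape[1]:
        raise ValidationError(
            f"only {len(shared)} shared genes for {sig.S.shape[1]} subsets; "
            "need >= 2x more genes than subsets"
        )
    S = sig.S.loc[shared].to_numpy(float)
    B = bulk[shared].to_numpy(float)
    raw = np.empty((B.shape[0], S.shape[1]))
    resid = np.empty(B.shape[0])
    for i in range(B.shape[0]):
        raw[i], resid[i] = nnls(S, B[i])
    totals = raw.sum(axis=1)
    f = np.divide(raw, totals[:, None], out=np.zeros_like(raw), where=totals[:, None] > 0)
    return FractionEstimate(
        f=pd.DataFrame(f, index=bulk.index, columns=sig.S.columns),
        raw=pd.DataFrame(raw, index=bulk.index, columns=sig.S.columns),
        residual_norm=pd.Series(resid, index=bulk.index, name="residual_norm"),
    )


def mann_whitney_one_tailed(scores_pos, scores_neg):
    """One-tailed Mann-Whitney U: positives stochastically greater.

    Exact enumeration for n1 + n2 <= 12, tie-corrected normal approximation
    otherwise.  Returns (u_stat, p).
    """
    return rank_sum_test(scores_pos, scores_neg, alternative="greater")


def waterfall(scores: pd.Series) -> pd.Series:
    """Per-sample deviation from the cohort median, sorted descending.

    The zero baseline is the cohort median (even-n median is the midpoint of
    the two central values, so no sample need sit exactly at zero).
    """
    scores = pd.Series(scores, dtype=float)
    if scores.empty:
        raise ValidationError("waterfall needs at least one sample")
    dev = scores - scores.median()
    return dev.sort_values(ascending=False)


def assess_response(scores: pd.Series, labels: pd.Series) -> ResponseAssessment:
    """Full responder stratification of a per-sample score."""
    scores = pd.Series(scores, dtype=float)
    labels = pd.Series(labels).astype(int).loc[scores.index]
    pos = scores[labels == 1].to_numpy()
    neg = scores[labels == 0].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both responders and non-responders required")
    u, p = mann_whitney_one_tailed(pos, neg)
    return ResponseAssessment(
        scores=scores,
        labels=labels,
        u_stat=u,
        p_one_tailed=p,
        auroc=auroc(scores.to_numpy(), labels.to_numpy()),
        waterfall=waterfall(scores),
    )
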