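"""Ligand-receptor interaction scoring with a label-permutation null.

For a ligand-receptor pair and a (sender subset, receiver subset) direction,
the interaction statistic is the average of the ligand's mean log-normalized
expression in the sender and the receptor's mean in the receiver,

    m = (mean ligand in sender + mean receptor in receiver) / 2,

reported only when both genes are expressed in at least ``min_pct`` of their
respective subsets.  Significance comes from shuffling cluster labels across
cells: p = (1 + #{m_perm >= m_obs}) / (n_perm + 1), the add-one estimator,
so p is never zero and its floor is 1/(n_perm + 1).

Only single-gene ligands and receptors are supported; multi-subunit
complexes are rejected with a clear message.  A small curated pair panel
(CXCL13-CXCR5 and other canonical immune axes) ships with the package as an
editable TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ValidationError
from .preprocess import NormalizedMatrix

DEFAULT_MIN_PCT = 0.1
DEFAULT_N_PERM = 1000


@dataclass(frozen=True)
class LrPair:
    ligand: str
    receptor: str

    @property
    def pair_id(self) -> str:
        return f"{self.ligand}->{self.receptor}"


def load_pairs(path=None) -> list:
    """Load ligand-receptor pairs from a TSV (columns ligand, receptor).

    Defaults to the small panel shipped with the package — a hand-picked
    stand-in of canonical immune axes, not a vendored database.  Entries with
    complex subunits (gene names containing '+' or ',') are rejected.
    """
    if path is None:
        with resources.files("sclandscape.data").joinpath("lr_pairs.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(Path(path), sep="\t")
    pairs = []
    for _, row in df.iterrows():
        lig, rec = str(row["ligand"]), str(row["receptor"])
        if any(ch in lig + rec for ch in "+,"):
            raise ValidationError(
                f"multi-subunit complex not supported: {lig}-{rec}"
            )
        pairs.append(LrPair(lig, rec))
    return pairs


def _mean_and_pct(values, gene_row: int, cell_idx: np.ndarray):
    sub = values[gene_row, :][:, cell_idx]
    mean = float(sub.sum() / cell_idx.size)
    pct = float(sub.getnnz() / cell_idx.size)
    return mean, pct


def interaction_mean(
    norm: NormalizedMatrix,
    cluster_labels,
    pair: LrPair,
    sender: str,
    receiver: str,
    min_pct: float = DEFAULT_MIN_PCT,
):
    """Interaction mean and expressing fractions, or None if gated.

    Returns ``(mean_stat, pct_ligand, pct_receptor)``; ``None`` when either
    expressing fraction falls below ``min_pct`` (pair not expressed for this
    directed subset pair).
    """
    labels = np.asarray(cluster_labels)
    send_idx = np.flatnonzero(labels == sender)
    recv_idx = np.flatnonzero(labels == receiver)
    if send_idx.size == 0 or recv_idx.size == 0:
        raise ValidationError(f"empty subset in {sender}->{receiver}")
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    for gene in (pair.ligand, pair.receptor):
        if gene not in gene_pos:
            raise ValidationError(f"gene {gene} absent from expression matrix")
    m_lig, pct_lig = _mean_and_pct(norm.values, gene_pos[pair.ligand], send_idx)
    m_rec, pct_rec = _mean_and_pct(norm.values, gene_pos[pair.receptor], recv_idx)
    if pct_lig < min_pct or pct_rec < min_pct:
        return None
    return ( (m_lig + m_rec) / 2.0, pct_lig, pct_rec )


def permutation_test(
    norm: NormalizedMatrix,
    cluster_labels,
    pair: LrPair,
    sender: str,
    receiver: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_pct: float = DEFAULT_MIN_PCT,
) -> float:
    """Label-permutation p-value for one directed pair.

    Cluster labels are shuffled across cells n_perm times; the permuted
    statistic ignores the expression gate (the gate is an observed-data
    reporting rule, not part of the null).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = np.asarray(cluster_labels)
    if np.unique(labels).size < 2:
        raise ValidationError("permutation test needs >= 2 clusters")
    obs = interaction_mean(norm, labels, pair, sender, receiver, min_pct=0.0)
    m_obs = obs[0]
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    lig = np.asarray(norm.values[gene_pos[pair.ligand], :].todense()).ravel()
    rec = np.asarray(norm.values[gene_pos[pair.receptor], :].todense()).ravel()
    n_send = int((labels == sender).sum())
    n_recv = int((labels == receiver).sum())
    rng = np.random.default_rng(seed)
    n = labels.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        send_idx = perm[:n_send]
        recv_idx = perm[n_send : n_send + n_recv]
        m = (lig[send_idx].mean() + rec[recv_idx].mean()) / 2.0
        if m >= m_obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def score_interactions(
    norm: NormalizedMatrix,
    cluster_labels,
    pairs: list,
    subset_pairs: list,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_pct: float = DEFAULT_MIN_PCT,
    group: str = "",
) -> pd.DataFrame:
    """Score every (ligand-receptor pair) x (sender, receiver) combination.

    Returns one record per combination with mean_stat, expressing fractions
    and permutation p (gated combinations carry NaN statistics and
    ``expressed = False``).
    """
    rows = []
    for pair in pairs:
        for sender, receiver in subset_pairs:
            got = interaction_mean(norm, cluster_labels, pair, sender, receiver, min_pct)
            if got is None:
                rows.append(
                    dict(pair_id=pair.pair_id, sender=sender, receiver=receiver,
                         group=group, mean_stat=np.nan, pct_ligand=np.nan,
                         pct_receptor=np.nan, p_perm=np.nan, expressed=False)
                )
                continue
            m, pct_l, pct_r = got
            p = permutation_test(
                norm, cluster_labels, pair, sender, receiver,
                n_perm=n_perm, seed=seed, min_pct=min_pct,
            )
            rows.append(
                dict(pair_id=pair.pair_id, sender=sender, receiver=receiver,
                     group=group, mean_stat=m, pct_ligand=pct_l,
                     pct_receptor=pct_r, p_perm=p, expressed=True)
            )
    return pd.DataFrame(rows)


def dotplot_export(records: pd.DataFrame) -> pd.DataFrame:
    """Long-format dot-plot table: one row per expressed record per group.

    Columns: pair, direction, group, mean_stat, neg_log10_p (dot size is
    significance, color is the interaction mean).
    """
    cols = ["pair", "direction", "group", "mean_stat", "neg_log10_p"]
    if records.empty:
        return pd.DataFrame(columns=cols)
    kept = records[records["expressed"]].copy()
    out = pd.DataFrame(
        {
            "pair": kept["pair_id"],
            "direction": kept["sender"] + "->" + kept["receiver"],
            "group": kept["group"],
            "mean_stat": kept["mean_stat"],
            "neg_log10_p": -np.log10(kept["p_perm"]),
        }
    )
    return out.reset_index(drop=True)[cols]
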