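"""Group-wise cell-subset composition testing by Pearson residuals.

For a groups x subsets contingency table of cell counts O with group totals
T_i, subset totals T_j and grand total T_tot, the expected count under
proportional composition is E_ij = (T_i / T_tot) * T_j and the Pearson
residual is

    r_ij = (O_ij - E_ij) / sqrt(E_ij).

Residuals are approximately standard normal under the null, so |r| > 2
corresponds to p < 0.05 and |r| > 4 to p < 0.0001.  For a conservative
familywise test, the significance level (default 0.01) is Bonferroni-divided
by the number of subsets; with 18 subsets this gives p = 0.00056, and the
residual cutoff 3.5 (two-sided tail 4.65e-4) is the adopted working
threshold: subsets with r > 3.5 in the test group are called augmented,
r < -3.5 depleted, otherwise unchanged.  The overall goodness of fit is the
chi-square statistic sum(r_ij^2) with (rows-1)(cols-1) degrees of freedom,
upper tail.

Note the residual scales with sqrt of the total cell count: multiplying all
counts by k scales r by sqrt(k).  This is why a conservative cutoff is used
on tables with tens of thousands of cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

DEFAULT_THRESHOLD = 3.5
DEFAULT_ALPHA_FAMILY = 0.01


@dataclass
class ContingencyTable:
    O: pd.DataFrame  # groups x subsets, integer counts

    def __post_init__(self):
        self.O = self.O.astype(np.int64)
        if (self.O.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def row_totals(self) -> pd.Series:
        return self.O.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.O.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.O.to_numpy().sum())


@dataclass
class ResidualResult:
    table: ContingencyTable
    E: pd.DataFrame
    r: pd.DataFrame
    chi2: float | None = None
    dof: int | None = None
    p_gof: float | None = None
    calls: pd.Series | None = None
    threshold: float | None = None
    alpha_family: float | None = None
    alpha_adjusted: float | None = None


def build_contingency(
    cell_labels: pd.DataFrame,
    subset_order: list | None = None,
    group_order: tuple = ("WT", "MT"),
) -> ContingencyTable:
    """Count cells per (group, cluster); empty clusters kept as zero columns.

    ``cell_labels`` needs ``group`` and ``cluster`` columns (extra columns
    such as ``patient`` are ignored here).
    """
    if subset_order is not None:
        unknown = set(cell_labels["cluster"]) - set(subset_order)
        if unknown:
            raise ValidationError(f"unknown cluster ids: {sorted(unknown)}")
    tab = pd.crosstab(cell_labels["group"], cell_labels["cluster"])
    tab = tab.reindex(index=list(group_order), fill_value=0)
    if subset_order is not None:
        tab = tab.reindex(columns=list(subset_order), fill_value=0)
    tab.index.name, tab.columns.name = "group", "subset"
    return ContingencyTable(tab.fillna(0))


def pearson_residuals(tab: ContingencyTable) -> ResidualResult:
    """Expected counts E_ij = (T_i/T_tot) T_j and residuals (O-E)/sqrt(E).

    An empty subset column has E = 0; its residual is defined as 0 with a
    warning and the column is excluded from the GOF degrees of freedom.
    """
    if tab.grand_total == 0:
        raise ValidationError("all-zero contingency table")
    T_i = tab.row_totals.to_numpy(float)
    T_j = tab.col_totals.to_numpy(float)
    E = np.outer(T_i / tab.grand_total, T_j)
    O = tab.O.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (O - E) / np.sqrt(E)
    empty = E == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.any(axis=0).sum())} empty subset column(s): residual set to 0"
        )
        r[empty] = 0.0
    idx, cols = tab.O.index, tab.O.columns
    return ResidualResult(
        table=tab,
        E=pd.DataFrame(E, index=idx, columns=cols),
        r=pd.DataFrame(r, index=idx, columns=cols),
    )


def gof_test(tab: ContingencyTable):
    """One-sided chi-square goodness of fit: chi2 = sum r^2, upper tail.

    dof = (rows with positive total - 1) * (non-empty columns - 1).
    """
    res = pearson_residuals(tab)
    rows = int((tab.row_totals > 0).sum())
    cols = int((tab.col_totals > 0).sum())
    dof = (rows - 1) * (cols - 1)
    if dof == 0:
        raise ValidationError("table needs >= 2 groups and >= 2 subsets with cells")
    chi2 = float((res.r.to_numpy() ** 2).sum())
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p


def bonferroni_alpha(alpha_family: float, n_subsets: int):
    """Bonferroni-adjusted level and the matching two-sided residual cutoff.

    The cutoff is the standard-normal quantile with two-sided tail equal to
    the adjusted level: 2*(1 - Phi(cutoff)) = alpha_family / n_subsets.
    """
    if not 0 < alpha_family < 1:
        raise ValidationError("alpha_family must be in (0, 1)")
    if n_subsets < 1:
        raise ValidationError("n_subsets must be >= 1")
    alpha_adjusted = alpha_family / n_subsets
    cutoff = float(stats.norm.isf(alpha_adjusted / 2))
    return alpha_adjusted, cutoff


def classify_subsets(
    res: ResidualResult, threshold: float = DEFAULT_THRESHOLD, test_group: str = "MT"
) -> pd.Series:
    """Per-subset call from the test group's residual row.

    augmented if r > threshold, depleted if r < -threshold, else unchanged.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if test_group not in res.r.index:
        raise ValidationError(f"{test_group!r} is not a row of the table")
    row = res.r.loc[test_group]
    calls = pd.Series("unchanged", index=row.index, name="call")
    calls[row > threshold] = "augmented"
    calls[row < -threshold] = "depleted"
    return calls


def analyze_composition(
    cell_labels: pd.DataFrame,
    subset_order: list | None = None,
    alpha_family: float = DEFAULT_ALPHA_FAMILY,
    threshold: float = DEFAULT_THRESHOLD,
    test_group: str = "MT",
) -> ResidualResult:
    """Full composition analysis: table, residuals, GOF, calls, thresholds."""
    tab = build_contingency(cell_labels, subset_order=subset_order)
    res = pearson_residuals(tab)
    res.chi2, res.dof, res.p_gof = gof_test(tab)
    n_subsets = tab.O.shape[1]
    res.alpha_family = alpha_family
    res.alpha_adjusted, _ = bonferroni_alpha(alpha_family, n_subsets)
    res.threshold = threshold
    res.calls = classify_subsets(res, threshold=threshold, test_group=test_group)
    return res


def residuals_from_counts_tsv(path, test_group: str = "MT", **kwargs) -> ResidualResult:
    """Composition analysis from an on-disk groups x subsets count table.

    The TSV has groups on rows (index column ``group``) and subset ids as
    column headers — the format of a published cluster-count table, so that
    reported residuals can be recomputed directly from counts.
    """
    O = pd.read_csv(path, sep="\t", index_col=0)
    tab = ContingencyTable(O)
    res = pearson_residuals(tab)
    res.chi2, res.dof, res.p_gof = gof_test(tab)
    res.alpha_family = kwargs.get("alpha_family", DEFAULT_ALPHA_FAMILY)
    res.alpha_adjusted, _ = bonferroni_alpha(res.alpha_family, O.shape[1])
    res.threshold = kwargs.get("threshold", DEFAULT_THRESHOLD)
    res.calls = classify_subsets(res, threshold=res.threshold, test_group=test_group)
    return res


# ---------------------------------------------------------------------------
# mosaic export
# ---------------------------------------------------------------------------

def mosaic_export(
    tab: ContingencyTable, res: ResidualResult, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Mosaic-plot tile geometry: one row per (group, subset) tile.

    Tile width is the subset's share of all cells; within a column, tile
    height is the group's share of that subset.  The color class encodes the
    residual band: |r| > 4 strong (p < 0.0001), |r| > 2 weak (p < 0.05),
    else neutral, signed by direction; ``call`` applies the working
    threshold.
    """
    widths = tab.col_totals / max(tab.grand_total, 1)
    rows = []
    x = 0.0
    for subset in tab.O.columns:
        col = tab.O[subset]
        col_tot = col.sum()
        y = 0.0
        for group in tab.O.index:
            h = (col[group] / col_tot) if col_tot > 0 else 1.0 / len(tab.O.index)
            r = float(res.r.loc[group, subset])
            if abs(r) > 4:
                band = "strong"
            elif abs(r) > 2:
                band = "weak"
            else:
                band = "neutral"
            color = "neutral" if band == "neutral" else (
                f"{band}_{'augmented' if r > 0 else 'depleted'}"
            )
            call = (
                "augmented" if r > threshold else "depleted" if r < -threshold else "unchanged"
            )
            rows.append(
                dict(
                    group=group, subset=subset, x=x, width=float(widths[subset]),
                    y=y, height=float(h), residual=r, color_class=color, call=call,
                )
            )
            y += h
        x += float(widths[subset])
    return pd.DataFrame(rows)


def mosaic_svg(geometry: pd.DataFrame, path, size: int = 640) -> str:
    """Render mosaic geometry as a standalone SVG (blue augmented, red
    depleted, gray neutral, saturation by band)."""
    palette = {
        "neutral": "#c8c8c8",
        "weak_augmented": "#9ecae1",
        "strong_augmented": "#2171b5",
        "weak_depleted": "#fc9272",
        "strong_depleted": "#cb181d",
    }
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{size}" height="{size // 2}" '
        f'viewBox="0 0 1 1" preserveAspectRatio="none">'
    ]
    for _, t in geometry.iterrows():
        parts.append(
            f'<rect x="{t.x:.6f}" y="{t.y:.6f}" width="{t.width:.6f}" '
            f'height="{t.height:.6f}" fill="{palette[t.color_class]}" '
            f'stroke="white" stroke-width="0.003"/>'
        )
    parts.append("</svg>")
    svg = "\n".join(parts)
    from pathlib import Path

    Path(path).write_text(svg)
    return svg
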