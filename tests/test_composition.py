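import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sclandscape.composition import (
    ContingencyTable,
    analyze_composition,
    bonferroni_alpha,
    build_contingency,
    classify_subsets,
    gof_test,
    mosaic_export,
    pearson_residuals,
)
from sclandscape.io import ValidationError


def table(rows, groups=("WT", "MT"), subsets=None):
    rows = np.asarray(rows)
    subsets = subsets or [f"C{j}" for j in range(rows.shape[1])]
    return ContingencyTable(pd.DataFrame(rows, index=list(groups), columns=subsets))


def labels_df(pairs):
    return pd.DataFrame(
        {"group": [g for g, _ in pairs], "cluster": [c for _, c in pairs],
         "patient": "P1"},
        index=[f"b{i}" for i in range(len(pairs))],
    )


def test_contingency_counts_and_order_invariance():
    pairs = [("WT", "C0"), ("WT", "C0"), ("MT", "C0"), ("MT", "C1")]
    tab = build_contingency(labels_df(pairs))
    assert tab.O.values.tolist() == [[2, 0], [1, 1]]
    shuffled = build_contingency(labels_df(pairs[::-1]))
    assert (tab.O == shuffled.O).all().all()
    with pytest.raises(ValidationError, match="unknown"):
        build_contingency(labels_df(pairs), subset_order=["C0"])


def test_residuals_on_worked_table():
    res = pearson_residuals(table([[30, 10], [10, 30]]))
    assert (res.E.to_numpy() == 20.0).all()
    np.testing.assert_allclose(
        res.r.to_numpy(), [[10 / np.sqrt(20), -10 / np.sqrt(20)],
                           [-10 / np.sqrt(20), 10 / np.sqrt(20)]], atol=1e-12
    )
    chi2, dof, p = gof_test(table([[30, 10], [10, 30]]))
    assert chi2 == pytest.approx(20.0, abs=1e-9)
    assert dof == 1
    assert p == pytest.approx(stats.chi2.sf(20, 1), rel=1e-12)
    assert p == pytest.approx(7.744e-6, rel=1e-3)


def test_proportional_table_gives_zero_residuals_and_p_one():
    res = pearson_residuals(table([[20, 40], [10, 20]]))
    np.testing.assert_allclose(res.r.to_numpy(), 0.0, atol=1e-12)
    chi2, _, p = gof_test(table([[20, 40], [10, 20]]))
    assert chi2 == pytest.approx(0.0, abs=1e-12) and p == 1.0


def test_chi2_equals_classical_statistic_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = rng.integers(2, 8)
        O = rng.integers(1, 60, size=(2, k))
        tab = table(O)
        chi2, dof, _ = gof_test(tab)
        # independent oracle: classical sum (O-E)^2 / E
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        assert chi2 == pytest.approx(((O - E) ** 2 / E).sum(), rel=1e-9)
        # and scipy's contingency test as a second, external oracle
        sp_chi2, sp_p, sp_dof, _ = stats.chi2_contingency(O, correction=False)
        assert chi2 == pytest.approx(sp_chi2, rel=1e-9) and dof == sp_dof


def test_residual_scale_equivariance_sqrt_k():
    O = np.array([[30, 10, 25], [12, 28, 20]])
    r1 = pearson_residuals(table(O)).r.to_numpy()
    r9 = pearson_residuals(table(9 * O)).r.to_numpy()
    np.testing.assert_allclose(r9, 3.0 * r1, atol=1e-9)


def test_residual_rows_decompose_to_zero_sum():
    rng = np.random.default_rng(5)
    O = rng.integers(1, 100, size=(2, 6))
    res = pearson_residuals(table(O))
    weighted = (res.r * np.sqrt(res.E)).sum(axis=1)
    np.testing.assert_allclose(weighted.to_numpy(), 0.0, atol=1e-9)


def test_empty_subset_column_warned_and_excluded_from_dof():
    with pytest.warns(UserWarning, match="empty subset"):
        res = pearson_residuals(table([[5, 0, 7], [6, 0, 4]]))
    assert (res.r["C1"] == 0).all()
    _, dof, _ = gof_test(table([[5, 0, 7], [6, 0, 4]]))
    assert dof == 1  # (2-1) * (2-1): the empty column does not count
    with pytest.raises(ValidationError):
        pearson_residuals(table([[0, 0], [0, 0]]))


def test_bonferroni_threshold_derivation():
    alpha, cutoff = bonferroni_alpha(0.01, 18)
    assert f"{alpha:.2g}" == "0.00056"
    # the adopted working threshold 3.5 is conservative for this level
    assert 2 * stats.norm.sf(3.5) == pytest.approx(4.653e-4, rel=1e-3)
    assert 2 * stats.norm.sf(3.5) <= alpha
    alpha1, cutoff1 = bonferroni_alpha(0.05, 1)
    assert alpha1 == 0.05 and cutoff1 == pytest.approx(1.9600, abs=1e-4)
    with pytest.raises(ValidationError):
        bonferroni_alpha(1.5, 18)


def test_classification_of_reported_residual_magnitudes():
    r = pd.DataFrame(
        [[-10.57, 3.34, -2.74], [10.57, -3.34, 2.74]],
        index=["WT", "MT"], columns=["C10", "C13", "C5"],
    )
    res = pearson_residuals(table([[1, 1, 1], [1, 1, 1]], subsets=["C10", "C13", "C5"]))
    res.r = r
    calls = classify_subsets(res, threshold=3.5, test_group="MT")
    # r = 10.57 clears the conservative cutoff; -3.34 and 2.74 do not
    assert calls.tolist() == ["augmented", "unchanged", "unchanged"]
    with pytest.raises(ValidationError):
        classify_subsets(res, test_group="XX")


def test_null_calibration_of_exceedance_rates():
    """Under proportional sampling, |r| exceedance is bounded by the nominal
    normal tail (the test is conservative) and matches the margin-adjusted
    normal prediction: Var(r_ij) = (1 - T_i/T_tot)(1 - T_j/T_tot)."""
    rng = np.random.default_rng(11)
    exceed, total = 0, 0
    for _ in range(400):
        O = rng.multinomial(20_000, np.full(10, 0.1), size=2)
        r = pearson_residuals(table(O)).r.to_numpy()[1]
        exceed += (np.abs(r) > 2).sum()
        total += r.size
    rate = exceed / total
    nominal = 2 * stats.norm.sf(2)  # 0.0455, the conservative bound
    adjusted_sd = np.sqrt((1 - 0.5) * (1 - 0.1))
    predicted = 2 * stats.norm.sf(2 / adjusted_sd)  # ~0.0029
    assert rate <= nominal
    assert rate == pytest.approx(predicted, abs=0.003)


def test_mosaic_geometry_normalization_and_bands():
    tab = table([[30, 10, 20], [10, 30, 20]])
    res = pearson_residuals(tab)
    geom = mosaic_export(tab, res)
    widths = geom.drop_duplicates("subset")["width"]
    assert widths.sum() == pytest.approx(1.0, abs=1e-12)
    for _, sub in geom.groupby("subset"):
        assert sub["height"].sum() == pytest.approx(1.0, abs=1e-12)
    # proportional table: every tile neutral
    tab0 = table([[20, 40], [10, 20]])
    geom0 = mosaic_export(tab0, pearson_residuals(tab0))
    assert (geom0["color_class"] == "neutral").all()
    # |r| = 4.5 falls in the strong band (p < 0.0001 per the legend)
    res.r.iloc[1, 0] = 4.5
    band = mosaic_export(tab, res)
    tile = band[(band.group == "MT") & (band.subset == "C0")].iloc[0]
    assert tile.color_class == "strong_augmented"


def test_analyze_composition_end_to_end_recovers_planted_shift():
    from sclandscape.simulate import CompositionScenario, gen_composition

    scn = CompositionScenario.with_fold_changes(
        6, {"WT": 10_000, "MT": 10_000}, {"C2": 0.5}
    )
    res = analyze_composition(gen_composition(scn, seed=3))
    assert res.calls["C2"] == "depleted"
    assert res.alpha_adjusted == pytest.approx(0.01 / 6)
    assert res.p_gof < 1e-6
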