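import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sclandscape.metacell import (
    compare_networks,
    metacell_profiles,
    partition_metacells,
    spearman_matrix,
)
from sclandscape.preprocess import lognormalize
from sclandscape.simulate import CompositionScenario, gen_composition, gen_expression
from tests.conftest import make_counts


def test_every_metacell_meets_size_floor():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(300, 10))
    part = partition_metacells(X, k_graph=30, min_size=20, seed=1)
    assert part.sizes().min() >= 20
    assert part.assignment.shape == (300,)
    # identical cells collapse fine too
    part_id = partition_metacells(np.ones((100, 5)), k_graph=100, min_size=20, seed=1)
    assert part_id.sizes().min() >= 20


def test_tiny_input_collapses_to_single_metacell_with_warning():
    with pytest.warns(UserWarning, match="single metacell"):
        part = partition_metacells(np.random.default_rng(1).normal(size=(5, 3)),
                                   min_size=20, seed=0)
    assert part.n_metacells == 1


def test_separated_subsets_yield_pure_metacells():
    """Metacells pool transcriptionally homogeneous neighbors, so two
    well-separated populations should never be mixed inside one pool."""
    rng = np.random.default_rng(2)
    impure = 0
    n_seeds = 12
    for seed in range(n_seeds):
        X = np.vstack([rng.normal(0, 1, size=(150, 8)),
                       rng.normal(8, 1, size=(150, 8))])
        truth = np.repeat([0, 1], 150)
        part = partition_metacells(X, k_graph=30, min_size=20, seed=seed)
        for m in range(part.n_metacells):
            members = truth[part.assignment == m]
            if members.min() != members.max():
                impure += 1
                break
    assert impure <= max(1, int(0.05 * n_seeds))


def test_profiles_use_regularized_geometric_mean():
    # identical cells reproduce their common profile exactly
    ac = make_counts(np.tile([[3], [5]], (1, 4)))
    part = partition_metacells(np.ones((4, 2)), min_size=2, k_graph=3, seed=0)
    prof = metacell_profiles(ac, part)
    merged = prof.profiles.to_numpy().mean(axis=0)
    np.testing.assert_allclose(sorted(merged), [3.0, 5.0], atol=1e-9)

    # {0, 8} pools to exp((ln 1 + ln 9)/2) - 1 = 2: geometric, not arithmetic
    ac2 = make_counts([[0, 8], [8, 0]])
    part2 = partition_metacells(np.ones((2, 2)), min_size=2, k_graph=1, seed=0)
    prof2 = metacell_profiles(ac2, part2)
    np.testing.assert_allclose(prof2.profiles.to_numpy().ravel(), [2.0, 2.0],
                               atol=1e-12)


def test_profiles_invariant_to_cell_order():
    rng = np.random.default_rng(3)
    raw = rng.poisson(3.0, size=(6, 30)) + 1
    ac = make_counts(raw)
    part = partition_metacells(rng.normal(size=(30, 4)), k_graph=10, min_size=10, seed=4)
    prof = metacell_profiles(ac, part)
    perm = rng.permutation(30)
    ac_p = make_counts(raw[:, perm], cell_ids=[f"c{i}" for i in perm])
    from sclandscape.metacell import MetacellPartition
    part_p = MetacellPartition(part.assignment[perm], part.min_size, part.k_graph, 4)
    prof_p = metacell_profiles(ac_p, part_p)
    np.testing.assert_allclose(prof.profiles.to_numpy(), prof_p.profiles.to_numpy(),
                               atol=1e-12)


def test_spearman_matches_scipy_and_handles_degenerate_genes():
    rng = np.random.default_rng(5)
    prof = metacell_profiles(
        make_counts(rng.poisson(5, size=(4, 100)) + 1),
        partition_metacells(rng.normal(size=(100, 3)), k_graph=20, min_size=15, seed=6),
    )
    genes = list(prof.profiles.columns)
    got = spearman_matrix(prof, genes)
    expected = sps.spearmanr(prof.profiles[genes].to_numpy()).statistic
    np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-12)
    assert np.allclose(np.diag(got), 1.0)
    # a perfectly monotone pair and a constant gene
    from sclandscape.metacell import MetacellExpression
    toy = MetacellExpression(profiles=pd.DataFrame(
        {"a": [1, 2, 3, 4, 5], "b": [2, 4, 9, 16, 30], "c": [7, 7, 7, 7, 7]}))
    corr = spearman_matrix(toy, ["a", "b", "c"])
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert np.isnan(corr.loc["a", "c"])


def test_identical_groups_have_zero_delta():
    rng = np.random.default_rng(6)
    prof = metacell_profiles(
        make_counts(rng.poisson(4, size=(5, 80)) + 1,
                    gene_ids=["RBPJ", "NOTCH1", "ITGAE", "RGS1", "PDCD1"]),
        partition_metacells(rng.normal(size=(80, 3)), k_graph=15, min_size=10, seed=7),
    )
    cmp_df = compare_networks(prof, prof, ["RBPJ"], ["NOTCH1", "ITGAE", "RGS1"])
    assert (cmp_df["delta"].abs() < 1e-12).all()


def _grouped_dataset(seed):
    # a single subset per group: correlation networks are compared within
    # one cell state, as in the anchored-regulator analysis
    scn = CompositionScenario.with_fold_changes(1, {"WT": 500, "MT": 500}, {})
    labels = gen_composition(scn, seed=seed)
    names = ["RBPJ", "NOTCH1", "ITGAE"] + [f"G{i:05d}" for i in range(37)]
    ac = gen_expression(
        labels, 40, {}, seed=seed, gene_names=names, base_mean_median=1.0,
        coexpression_plan=[{"genes": ["RBPJ", "NOTCH1", "ITGAE"],
                            "subset": "C0", "group": "WT", "sd": 1.0}],
    )
    return ac, labels


def test_planted_group_specific_coregulation_is_recovered():
    """Co-regulation planted only in WT shows up as positive delta for the
    planted anchor-target pairs."""
    ac, labels = _grouped_dataset(seed=8)
    profs = {}
    rng_space = lognormalize(ac)
    for grp in ("WT", "MT"):
        mask = (labels["group"] == grp).to_numpy()
        sub = make_counts(ac.counts.toarray()[:, mask], gene_ids=ac.gene_ids,
                          cell_ids=[ac.cell_ids[i] for i in np.flatnonzero(mask)])
        expr = rng_space.values[:, np.flatnonzero(mask)].toarray().T
        part = partition_metacells(expr, k_graph=30, min_size=15, seed=9)
        profs[grp] = metacell_profiles(sub, part)
    cmp_df = compare_networks(profs["WT"], profs["MT"], ["RBPJ"],
                              ["NOTCH1", "ITGAE"])
    assert (cmp_df["delta"] > 0.2).all()
    assert (cmp_df["rho_WT"] > cmp_df["rho_MT"]).all()


def test_pooling_reduces_zero_fraction_and_correlation_attenuation():
    ac, labels = _grouped_dataset(seed=10)
    mask = (labels["group"] == "WT").to_numpy()
    sub_counts = ac.counts.toarray()[:, mask]
    sub = make_counts(sub_counts, gene_ids=ac.gene_ids,
                      cell_ids=[f"w{i}" for i in range(mask.sum())])
    norm = lognormalize(sub)
    part = partition_metacells(norm.values.toarray().T, k_graph=30, min_size=15,
                               seed=11)
    prof = metacell_profiles(sub, part)
    zero_before = (sub_counts == 0).mean()
    zero_after = (prof.profiles.to_numpy() < 1e-12).mean()
    assert zero_after <= zero_before
    # pooled-profile correlation of the planted pair beats the cell-level one
    cell_rho = sps.spearmanr(sub_counts[0], sub_counts[1]).statistic
    mc_rho = sps.spearmanr(prof.profiles["RBPJ"], prof.profiles["NOTCH1"]).statistic
    assert mc_rho > cell_rho
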