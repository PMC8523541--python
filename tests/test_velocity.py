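import numpy as np
import pandas as pd
import pytest

from sclandscape.simulate import CompositionScenario, KineticsSpec, gen_composition, gen_kinetics
from sclandscape.velocity import (
    GammaFit,
    VelocityField,
    compute_velocity,
    embed_arrows,
    fit_gamma,
    subset_transitions,
    transition_kernel,
)


def uniform_labels(n, subset="C0"):
    return pd.DataFrame(
        {"patient": "P1", "group": "WT", "cluster": subset},
        index=[f"c{i}" for i in range(n)],
    )


class TestGammaFit:
    def test_exact_proportionality_recovers_slope(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(1, 50, size=(5, 100))
        u = 0.7 * s
        fit = fit_gamma(s, u)
        np.testing.assert_allclose(fit.gamma.to_numpy(), 0.7, atol=1e-12)
        # doubling u doubles the slope
        fit2 = fit_gamma(s, 2 * u)
        np.testing.assert_allclose(fit2.gamma.to_numpy(), 1.4, atol=1e-12)

    def test_steady_state_parameter_recovery_within_5_percent(self):
        """A heterogeneous population of steady-state subsets gives the
        spliced axis real dynamic range; the extreme-quantile slope then
        recovers gamma within 5% for expression-rich genes."""
        rng = np.random.default_rng(0)
        alpha = rng.uniform(5, 40, 40)
        gamma = rng.uniform(0.3, 1.5, 40)
        labels = pd.concat([
            uniform_labels(800, "C0"),
            uniform_labels(800, "C1").set_axis([f"d{i}" for i in range(800)]),
            uniform_labels(800, "C2").set_axis([f"e{i}" for i in range(800)]),
        ])
        spec = KineticsSpec(
            alpha=alpha, gamma=gamma,
            subset_alpha_scale={"C0": np.full(40, 0.5), "C1": np.full(40, 1.0),
                                "C2": np.full(40, 2.0)},
        )
        s, u, _ = gen_kinetics(labels, spec, seed=0)
        ids = [f"G{i:05d}" for i in range(40)]
        fit = fit_gamma(s, u, gene_ids=ids, q=0.1, smoothing_k=50)
        mean_s = np.asarray(s.mean(axis=1)).ravel()
        rich = [i for i in range(40) if mean_s[i] >= 5 and ids[i] in fit.gamma]
        assert len(rich) >= 20
        rel = np.abs(fit.gamma[[ids[i] for i in rich]].to_numpy()
                     - gamma[rich]) / gamma[rich]
        assert (rel <= 0.05).all()

    def test_insufficient_cells_marked_unfit(self):
        s = np.zeros((1, 30))
        u = np.ones((1, 30))
        fit = fit_gamma(s, u)
        assert len(fit.gamma) == 0


class TestVelocityField:
    def test_self_smoothing_returns_raw_residuals(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(1, 20, size=(4, 400))
        u = 0.5 * s + rng.normal(0, 0.1, size=(4, 400))
        fit = fit_gamma(s, u, smoothing_k=1)
        vel = compute_velocity(fit, s, u, smoothing_k=1)
        kept = [int(g[1:]) for g in vel.gene_ids]
        expected = u[kept] - fit.gamma.to_numpy()[:, None] * s[kept]
        np.testing.assert_allclose(vel.v, expected, atol=1e-12)

    def test_steady_state_velocity_centers_at_zero(self):
        labels = uniform_labels(1000)
        spec = KineticsSpec(alpha=np.full(20, 20.0), gamma=np.full(20, 0.8))
        s, u, _ = gen_kinetics(labels, spec, seed=3)
        fit = fit_gamma(s, u)
        vel = compute_velocity(fit, s, u, smoothing_k=30)
        scale = np.asarray(u.mean(axis=1)).ravel().mean()
        assert np.abs(vel.v.mean(axis=1)).max() < 0.1 * scale

    def test_induced_cells_have_positive_velocity(self):
        # cells early on the induction path toward a higher-alpha state carry
        # unspliced excess: u > gamma * s
        labels = uniform_labels(400, "C0")
        spec = KineticsSpec(
            alpha=np.full(10, 5.0), gamma=np.full(10, 0.5),
            subset_alpha_scale={"C1": np.full(10, 6.0)},
            transit={"C0": ("C1", 0.5)},
            transit_time_range=(0.05, 0.3),
        )
        s, u, truth = gen_kinetics(labels, spec, seed=4)
        fit = fit_gamma(s, u)
        vel = compute_velocity(fit, s, u, smoothing_k=1)
        transiting = truth["transiting"]
        assert vel.v[:, transiting].mean() > vel.v[:, ~transiting].mean()
        assert vel.v[:, transiting].mean() > 0


def two_cluster_construction(n_per=100, seed=5):
    """Two separated blobs in spliced space; A-cells' velocities point at
    B's centroid, B-cells' at their own centroid (stationary)."""
    rng = np.random.default_rng(seed)
    n_genes = 8
    a_center = rng.uniform(2, 6, n_genes)
    b_center = a_center + rng.uniform(3, 6, n_genes)
    s = np.vstack([
        a_center + rng.normal(0, 0.3, size=(n_per, n_genes)),
        b_center + rng.normal(0, 0.3, size=(n_per, n_genes)),
    ]).T  # genes x cells
    v = np.zeros_like(s)
    v[:, :n_per] = (b_center[:, None] - s[:, :n_per])
    labels = np.array(["A"] * n_per + ["B"] * n_per)
    vel = VelocityField(v=v, gene_ids=[f"g{i}" for i in range(n_genes)],
                        cell_ids=[f"c{i}" for i in range(2 * n_per)], smoothing_k=1)
    return vel, s, labels


class TestTransitionKernel:
    def test_zero_velocity_gives_uniform_rows(self):
        vel, s, _ = two_cluster_construction()
        vel.v[:] = 0.0
        with pytest.warns(UserWarning, match="uniform kernel"):
            model = transition_kernel(vel, s, k=20)
        row = model.P[0].toarray().ravel()
        nz = row[row > 0]
        np.testing.assert_allclose(nz, 1.0 / 20, atol=1e-12)

    def test_rows_sum_to_one(self):
        vel, s, _ = two_cluster_construction()
        model = transition_kernel(vel, s, k=50)
        np.testing.assert_allclose(
            np.asarray(model.P.sum(axis=1)).ravel(), 1.0, atol=1e-9
        )

    def test_sigma_limit_concentrates_on_best_neighbor(self):
        vel, s, labels = two_cluster_construction()
        with pytest.warns(UserWarning):  # B-cells are stationary (v = 0)
            model = transition_kernel(vel, s, k=30, sigma=1e-4)
        # every directed (A) cell puts essentially all mass on its argmax
        row_max = model.P.max(axis=1).toarray().ravel()
        assert row_max[labels == "A"].min() > 0.99

    def test_directed_cells_send_mass_to_target_subset(self):
        vel, s, labels = two_cluster_construction()
        model = transition_kernel(vel, s, k=150, sigma=0.05)
        onehot_b = (labels == "B").astype(float)
        mass_to_b = model.P @ onehot_b
        a_cells = labels == "A"
        assert (mass_to_b[a_cells] > 1 - mass_to_b[a_cells]).mean() >= 0.9

    def test_kernel_invariant_to_constant_gene_shift(self):
        vel, s, _ = two_cluster_construction()
        m1 = transition_kernel(vel, s, k=40)
        m2 = transition_kernel(vel, s + 7.3, k=40)
        assert abs(m1.P - m2.P).max() < 1e-9

    def test_cell_permutation_permutes_kernel_consistently(self):
        vel, s, _ = two_cluster_construction(n_per=40)
        model = transition_kernel(vel, s, k=20)
        rng = np.random.default_rng(6)
        perm = rng.permutation(80)
        vel_p = VelocityField(v=vel.v[:, perm],
                              gene_ids=vel.gene_ids,
                              cell_ids=[vel.cell_ids[i] for i in perm],
                              smoothing_k=1)
        model_p = transition_kernel(vel_p, s[:, perm], k=20)
        expected = model.P[perm][:, perm]
        assert abs(model_p.P - expected).max() < 1e-9


class TestSubsetTransitions:
    def test_rows_sum_to_one_and_uniform_kernel_matches_composition(self):
        vel, s, labels = two_cluster_construction()
        vel.v[:] = 0.0
        with pytest.warns(UserWarning):
            model = transition_kernel(vel, s, k=199)  # candidates = everyone else
        model = subset_transitions(model, labels)
        np.testing.assert_allclose(model.M.sum(axis=1), 1.0, atol=1e-6)
        # uniform kernel over all other cells: mass to B = candidate share
        assert model.M.loc["A", "B"] == pytest.approx(100 / 199, abs=1e-9)

    def test_persistence_decreases_with_transiting_fraction(self):
        """The larger the fraction of a subset in transit toward another
        state, the lower the subset's persistence probability."""
        persistence = []
        for phi in (0.0, 0.25, 0.5):
            labels = pd.concat([uniform_labels(250, "C0"),
                                uniform_labels(250, "C1").set_axis(
                                    [f"d{i}" for i in range(250)])])
            spec = KineticsSpec(
                alpha=np.full(12, 6.0), gamma=np.full(12, 0.6),
                subset_alpha_scale={"C1": np.full(12, 2.0)},
                transit={"C0": ("C1", phi)},
                transit_time_range=(0.5, 3.0),
            )
            s, u, _ = gen_kinetics(labels, spec, seed=7)
            fit = fit_gamma(s, u, smoothing_k=30, q=0.1)
            vel = compute_velocity(fit, s, u, smoothing_k=10)
            keep = [int(g[1:]) for g in vel.gene_ids]
            model = transition_kernel(vel, s.toarray()[keep], k=150, sigma=0.05)
            model = subset_transitions(model, labels["cluster"].to_numpy())
            np.testing.assert_allclose(model.M.sum(axis=1), 1.0, atol=1e-6)
            persistence.append(model.persistence["C0"])
        assert persistence[0] > persistence[1] > persistence[2]


class TestEmbedding:
    def test_arrow_geometry(self):
        vel, s, labels = two_cluster_construction(n_per=30)
        model = transition_kernel(vel, s, k=59, sigma=0.05)
        rng = np.random.default_rng(8)
        emb = np.vstack([rng.normal(0, 0.2, size=(30, 2)),
                         rng.normal(5, 0.2, size=(30, 2))])
        arrows = embed_arrows(model, emb)
        a_arrows = arrows.iloc[:30]
        # A-cells' arrows point toward B's embedding region (positive x and y)
        assert a_arrows["dx"].mean() > 1 and a_arrows["dy"].mean() > 1
        # a row concentrated on one neighbor yields exactly that displacement
        import scipy.sparse as sp
        P = sp.lil_matrix((3, 3))
        P[0, 2] = 1.0
        P[1, 0] = 1.0
        P[2, 1] = 1.0
        from sclandscape.velocity import TransitionModel
        toy = TransitionModel(P=P.tocsr(), sigma=0.05, cell_ids=["a", "b", "c"])
        e = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        got = embed_arrows(toy, e)
        np.testing.assert_allclose(got[["dx", "dy"]].to_numpy(),
                                   [[0, 2], [-1, 0], [1, -2]], atol=1e-12)
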