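import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import spatialedge as se
from spatialedge.velocity import (
    MAGNITUDE_SCALE,
    PerturbationSpec,
    StateGraph,
    _project_velocity,
    estimate_gamma,
)


def toy_result(velocity, embedding, seed=0, **overrides):
    n, g = velocity.shape
    d = embedding.shape[1]
    defaults = dict(
        spot_ids=np.array([f"s{i}" for i in range(n)]),
        genes=np.array([f"g{j}" for j in range(g)]),
        gamma=pd.Series(np.ones(g), index=[f"g{j}" for j in range(g)]),
        ms=np.ones((n, g)),
        mu=np.ones((n, g)),
        velocity=velocity,
        embedding=embedding,
        loadings=np.zeros((g, d)),
        embedded_velocity=np.zeros((n, d)),
        neighbors=np.zeros((n, 2), dtype=int),
    )
    defaults.update(overrides)
    return se.VelocityResult(**defaults)


class TestGamma:
    def test_exact_line_through_origin(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0.5, 10, size=(300, 4))
        u = 0.5 * s
        assert np.allclose(estimate_gamma(s, u), 0.5)

    def test_zero_unspliced_gives_zero_gamma_and_velocity(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(1, 5, size=(100, 2))
        u = np.zeros_like(s)
        gam = estimate_gamma(s, u)
        assert np.allclose(gam, 0.0)
        assert np.allclose(u - gam * s, 0.0)

    def test_zero_spliced_signal_masked(self):
        s = np.zeros((50, 1))
        u = np.ones((50, 1))
        assert np.isnan(estimate_gamma(s, u)).all()

    def test_recovery_on_simulated_kinetics(self):
        bench = se.simulate_gamma_benchmark(n_spots=800, n_genes=60, seed=2)
        vr = se.compute_velocity(bench, subset=None)
        rel = np.abs(
            vr.gamma.to_numpy() - bench.var["gamma_true"].to_numpy()
        ) / bench.var["gamma_true"].to_numpy()
        assert np.median(rel) < 0.10

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            estimate_gamma(np.ones((5, 2)), np.ones((5, 3)))


class TestVelocity:
    def test_steady_state_spots_have_zero_velocity(self, velocity_result):
        vr = velocity_result
        gam = vr.gamma.to_numpy()
        manual = vr.mu - np.nan_to_num(gam)[None, :] * vr.ms
        manual[:, np.isnan(gam)] = 0.0
        assert np.allclose(vr.velocity, manual)
        # a synthetic spot exactly at u = gamma*s
        s = np.abs(np.random.default_rng(0).normal(2, 1, size=(1, 10)))
        assert np.allclose((0.7 * s) - 0.7 * s, 0.0)

    def test_doubling_gamma_flips_sign_where_below_line(self, velocity_result):
        vr = velocity_result
        gam = np.nan_to_num(vr.gamma.to_numpy())
        v2 = vr.mu - 2 * gam[None, :] * vr.ms
        below = vr.mu < gam[None, :] * vr.ms  # already negative
        assert (v2[below] <= vr.velocity[below]).all()
        flipped = (vr.velocity > 0) & (vr.mu < 2 * gam[None, :] * vr.ms)
        assert (v2[flipped] < 0).all()

    def test_tc_spots_point_toward_leading_edge(self, annotated, velocity_result):
        vr = velocity_result
        labels = annotated.obs.loc[vr.spot_ids, "region"]
        tc = (labels == "TC").to_numpy()
        le = (labels == "LE").to_numpy()
        le_centroid = vr.embedding[le].mean(axis=0)
        dots = np.einsum(
            "nd,nd->n", vr.embedded_velocity[tc], le_centroid[None, :] - vr.embedding[tc]
        )
        assert (dots > 0).mean() >= 0.90

    def test_deterministic(self, annotated):
        v1 = se.compute_velocity(annotated)
        v2 = se.compute_velocity(annotated)
        assert np.array_equal(v1.velocity, v2.velocity)
        assert np.array_equal(v1.embedded_velocity, v2.embedded_velocity)


class TestConfidence:
    def test_identical_velocities_confidence_one(self):
        rng = np.random.default_rng(0)
        n = 80
        v = np.tile(rng.normal(size=20), (n, 1))
        vr = toy_result(v, rng.normal(size=(n, 5)))
        conf = se.velocity_confidence(vr, k=10)
        assert np.allclose(conf, 1.0)

    def test_random_velocities_center_on_zero(self):
        rng = np.random.default_rng(1)
        n = 1000
        vr = toy_result(rng.normal(size=(n, 30)), rng.normal(size=(n, 5)))
        conf = se.velocity_confidence(vr, k=30)
        se_mean = conf.std(ddof=1) / np.sqrt(n)
        assert abs(conf.mean()) <= 3 * max(se_mean, 0.01)

    def test_scrambled_spots_fall_in_lowest_decile(self):
        detections = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, g = 500, 40
            v = rng.normal(size=g)[None, :] + 0.3 * rng.normal(size=(n, g))
            scrambled = rng.choice(n, size=50, replace=False)
            v[scrambled] = rng.normal(size=(50, g))
            vr = toy_result(v, rng.normal(size=(n, 10)))
            conf = se.velocity_confidence(vr, k=30)
            cutoff = np.quantile(conf, 0.1)
            if (conf.iloc[scrambled] <= cutoff).mean() >= 0.5:
                detections += 1
        assert detections >= 8

    def test_zero_variance_velocity_warned_and_zeroed(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(60, 10))
        v[0] = 3.0  # constant vector: correlation undefined
        vr = toy_result(v, rng.normal(size=(60, 4)))
        with pytest.warns(UserWarning, match="zero-variance"):
            conf = se.velocity_confidence(vr, k=10)
        assert conf.iloc[0] == 0.0


class TestVectorField:
    def test_linear_field_reproduced(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 3))
        A = rng.normal(size=(3, 3))
        v = x @ A.T
        vf = se.fit_vector_field(x, v, ridge=1e-8)
        assert np.abs(vf.predict(x) - v).max() < 1e-3
        assert vf.train_r2 > 0.999999

    def test_infinite_ridge_limit_is_mean_velocity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 3))
        v = rng.normal(size=(100, 2))
        vf = se.fit_vector_field(x, v, ridge=1e12)
        assert np.allclose(vf.predict(x), v.mean(axis=0), atol=1e-6)

    def test_fitted_field_preserves_flow_direction(self, annotated, velocity_result):
        vr = velocity_result
        vf = se.fit_vector_field(vr.embedding, vr.embedded_velocity)
        f = vf.predict(vr.embedding)
        labels = annotated.obs.loc[vr.spot_ids, "region"]
        tc = (labels == "TC").to_numpy()
        le_centroid = vr.embedding[(labels == "LE").to_numpy()].mean(axis=0)
        dots = np.einsum(
            "nd,nd->n", f[tc], le_centroid[None, :] - vr.embedding[tc]
        )
        assert (dots > 0).mean() >= 0.90

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            se.fit_vector_field(np.ones((3, 5)), np.ones((3, 5)))


class TestTransitionMatrix:
    def test_rows_stochastic(self, velocity_result):
        P = se.build_transition_matrix(
            velocity_result.embedding, velocity_result.embedded_velocity
        )
        rowsum = np.asarray(P.sum(axis=1)).ravel()
        assert np.allclose(rowsum, 1.0, atol=1e-9)
        assert P.min() >= 0
        assert np.all(P.diagonal() == 0)

    def test_softmax_limit_concentrates_on_aligned_neighbor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 2))
        v = np.zeros((40, 2))
        # spot 0's velocity points exactly at one of its neighbors
        from sklearn.neighbors import NearestNeighbors

        nbr = NearestNeighbors(n_neighbors=5).fit(x)
        idx = nbr.kneighbors(return_distance=False)
        target = idx[0, 2]
        v[0] = x[target] - x[0]
        P = se.build_transition_matrix(x, v, k=5, sigma=1e-4)
        assert P[0, target] > 0.999

    def test_zero_velocity_spot_uniform_over_neighbors(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        v = np.zeros((30, 3))
        P = se.build_transition_matrix(x, v, k=6, sigma=0.1).toarray()
        for i in range(30):
            nz = P[i][P[i] > 0]
            assert len(nz) == 6
            assert np.allclose(nz, 1 / 6)

    def test_matches_brute_force_on_random_spots(self, velocity_result):
        vr = velocity_result
        k, sigma = 30, 0.1
        P = se.build_transition_matrix(vr.embedding, vr.embedded_velocity, k, sigma)
        rng = np.random.default_rng(2)
        x, v = vr.embedding, vr.embedded_velocity
        n = x.shape[0]
        for i in rng.choice(n, size=min(200, n), replace=False):
            d2 = ((x - x[i]) ** 2).sum(axis=1)
            d2[i] = np.inf
            nbrs = np.argsort(d2, kind="stable")[:k]
            w = np.zeros(k)
            vi = v[i]
            vnorm = np.linalg.norm(vi)
            for jj, j in enumerate(nbrs):
                delta = x[j] - x[i]
                if vnorm <= 1e-12:
                    w[jj] = 1.0
                else:
                    cos = vi @ delta / (vnorm * np.linalg.norm(delta))
                    w[jj] = np.exp(cos / sigma - 1 / sigma)
            w /= w.sum()
            row = np.asarray(P[i].todense()).ravel()
            expected = np.zeros(n)
            expected[nbrs] = w
            assert np.allclose(row, expected, atol=1e-9)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            se.build_transition_matrix(np.ones((5, 2)), np.ones((5, 2)), k=5)


class TestStateGraph:
    def test_rows_stochastic_and_signature_sums(self, engine):
        g = engine.baseline_graph()
        assert np.allclose(g.Q.sum(axis=1), 1.0, atol=1e-9)
        assert (g.Q.to_numpy() >= 0).all()
        assert g.edge_outgoing == pytest.approx(
            g.Q.loc["LE", "transitory"] + g.Q.loc["LE", "TC"]
        )
        assert g.core_incoming == pytest.approx(
            g.Q.loc["LE", "TC"] + g.Q.loc["transitory", "TC"]
        )

    def test_signature_arithmetic_on_fixed_matrix(self):
        Q = pd.DataFrame(
            [[0.8, 0.15, 0.05], [0.25, 0.55, 0.2], [0.1, 0.2, 0.7]],
            index=["TC", "transitory", "LE"],
            columns=["TC", "transitory", "LE"],
        )
        g = StateGraph(Q=Q)
        assert g.edge_outgoing == pytest.approx(0.3)   # 0.2 + 0.1
        assert g.core_incoming == pytest.approx(0.35)  # 0.1 + 0.25

    def test_baseline_flow_runs_core_to_edge(self, engine):
        Q = engine.baseline_graph().Q
        outward = Q.loc["TC", "LE"] + Q.loc["TC", "transitory"]
        inward = Q.loc["LE", "TC"] + Q.loc["LE", "transitory"]
        assert outward > inward

    def test_coarse_graph_matches_manual_average(self, velocity_result, annotated):
        P = se.build_transition_matrix(
            velocity_result.embedding, velocity_result.embedded_velocity
        )
        labels = annotated.obs.loc[velocity_result.spot_ids, "region"]
        g = se.coarse_state_graph(P, labels)
        Pd = P.toarray()
        lab = labels.to_numpy()
        for a in ("TC", "transitory", "LE"):
            for b in ("TC", "transitory", "LE"):
                manual = Pd[np.ix_(lab == a, lab == b)].sum(axis=1).mean()
                assert g.Q.loc[a, b] == pytest.approx(manual, abs=1e-12)

    def test_empty_state_raises(self):
        P = sparse.eye(4, format="csr")
        with pytest.raises(ValueError):
            se.coarse_state_graph(P, ["TC", "TC", "LE", "LE"] )


class TestPerturbation:
    def test_zero_magnitude_is_noop(self, engine, annotated):
        drivers = annotated.uns["gene_sets"]["edge_drivers"]
        spec = PerturbationSpec(targets={g: 0.0 for g in drivers})
        base = engine.baseline_graph()
        pert = engine.perturbed_graph(spec)
        assert np.allclose(base.Q, pert.Q)

    def test_downregulating_le_drivers_reverses_flow(self, engine, annotated):
        drivers = annotated.uns["gene_sets"]["edge_drivers"]
        base = engine.baseline_graph()
        down = engine.perturbed_graph(
            PerturbationSpec.from_directions({g: "down" for g in drivers})
        )
        assert down.edge_outgoing > base.edge_outgoing
        up = engine.perturbed_graph(
            PerturbationSpec.from_directions({g: "up" for g in drivers})
        )
        assert up.edge_outgoing <= base.edge_outgoing + 1e-6

    def test_apply_perturbation_overrides_target_columns(self, velocity_result):
        vr = velocity_result
        gene = vr.genes[5]
        out = se.apply_perturbation(vr, PerturbationSpec(targets={gene: -200.0}))
        sd = vr.ms[:, 5].std()
        assert np.allclose(out.velocity[:, 5], -sd)
        mask = np.ones(len(vr.genes), dtype=bool)
        mask[5] = False
        assert np.array_equal(out.velocity[:, mask], vr.velocity[:, mask])
        assert np.allclose(
            out.embedded_velocity,
            _project_velocity(out.velocity, vr.ms, vr.loadings),
        )

    def test_checkpoint_magnitude_scales_five_sd(self, velocity_result):
        vr = velocity_result
        gene = vr.genes[5]
        out = se.apply_perturbation(vr, PerturbationSpec(targets={gene: -1000.0}))
        assert np.allclose(out.velocity[:, 5], -5 * vr.ms[:, 5].std())

    def test_unexpressed_targets_dropped_and_all_dropped_raises(self, velocity_result):
        with pytest.warns(UserWarning, match="not measured"):
            with pytest.raises(ValueError):
                se.apply_perturbation(
                    velocity_result, PerturbationSpec(targets={"NOPE": -200.0})
                )

    def test_engine_matches_full_recomputation(self, engine, velocity_result, annotated):
        drivers = annotated.uns["gene_sets"]["edge_drivers"]
        spec = PerturbationSpec.from_directions({g: "down" for g in drivers})
        fast = engine.perturbed_graph(spec)
        slow_vr = se.apply_perturbation(velocity_result, spec)
        field = engine._field(slow_vr.embedded_velocity)
        P = se.build_transition_matrix(slow_vr.embedding, field, k=engine.k,
                                       sigma=engine.sigma)
        slow = se.coarse_state_graph(P, engine.labels)
        assert np.allclose(fast.Q, slow.Q, atol=1e-9)

    def test_edge_outgoing_ranking_stable_across_sigma(self, velocity_result, annotated):
        labels = annotated.obs.loc[velocity_result.spot_ids, "region"]
        drivers = annotated.uns["gene_sets"]["edge_drivers"]
        down = PerturbationSpec.from_directions({g: "down" for g in drivers})
        up = PerturbationSpec.from_directions({g: "up" for g in drivers})
        for sigma in (0.02, 0.1, 0.5):
            eng = se.PerturbationEngine(velocity_result, labels, sigma=sigma)
            e_down = eng.perturbed_graph(down).edge_outgoing
            e_base = eng.baseline_graph().edge_outgoing
            e_up = eng.perturbed_graph(up).edge_outgoing
            assert e_down > e_base >= e_up - 1e-9
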