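"""Weisfeiler-Lehman propagation and the Wasserstein graph distance.

The propagation oracle is a nested-loop re-evaluation of the update rule;
the OT oracles are the 1-D sorted closed form (scipy's univariate
Wasserstein distance) and feasibility bounds of the transport polytope.
"""

import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from conftest import random_graph
from spatialcompare.graphs import SpatialGraph, build_delaunay
from spatialcompare.io_core import SpatialSample
from spatialcompare.synthetic import SynthSpec, generate_dataset
from spatialcompare.wwl import (
    exact_ot,
    pairwise_wwl,
    sinkhorn_ot,
    wasserstein_wl_distance,
    wl_propagate_continuous,
    wl_refine_discrete,
)


def loop_propagate(features, graph, iterations):
    """Nested-loop reference for the continuous WL update."""
    a = np.array(features, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    nbrs = {v: [] for v in range(graph.n_nodes)}
    for u, v in graph.edges:
        nbrs[u].append(v)
        nbrs[v].append(u)
    out = [a.copy()]
    for _ in range(iterations):
        nxt = np.zeros_like(a)
        for v in range(graph.n_nodes):
            if nbrs[v]:
                avg = sum(a[u] for u in nbrs[v]) / len(nbrs[v])
            else:
                avg = a[v]
            nxt[v] = 0.5 * (a[v] + avg)
        a = nxt
        out.append(a.copy())
    return out


def sample_from(features, coords=None):
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if coords is None:
        coords = np.random.default_rng(0).uniform(size=(n, 2))
    return SpatialSample(
        sample_id=f"s{abs(hash(features.tobytes())) % 10**6}",
        condition="A", coords=coords, expression=features,
    )


class TestDiscreteWL:
    def test_edgeless_labels_stable(self):
        g = SpatialGraph(n_nodes=3, edges=np.empty((0, 2), dtype=int))
        steps = wl_refine_discrete(["A", "B", "A"], g, iterations=3)
        for s in steps[1:]:
            np.testing.assert_array_equal(s, steps[1])
        assert len(set(steps[0])) == 2

    def test_path_center_separates(self):
        g = SpatialGraph(n_nodes=3, edges=np.array([[0, 1], [1, 2]]))
        steps = wl_refine_discrete(["A", "A", "A"], g, iterations=1)
        assert steps[0][0] == steps[0][1] == steps[0][2]
        assert steps[1][0] == steps[1][2] != steps[1][1]

    def test_isomorphic_graphs_share_histograms(self, rng):
        for _ in range(10):
            g = random_graph(rng, n_max=15)
            labels = rng.choice(list("AB"), size=g.n_nodes)
            perm = rng.permutation(g.n_nodes)
            g2 = SpatialGraph(
                n_nodes=g.n_nodes,
                edges=perm[g.edges] if g.n_edges else g.edges,
            )
            labels2 = np.empty(g.n_nodes, dtype=object)
            labels2[perm] = labels
            table: dict = {}
            s1 = wl_refine_discrete(labels, g, 3, label_table=table)
            s2 = wl_refine_discrete(labels2, g2, 3, label_table=table)
            for a, b in zip(s1, s2):
                assert sorted(a) == sorted(b)


class TestContinuousWL:
    def test_constant_features_fixed_point(self, triangle):
        x = np.full((3, 2), 7.0)
        emb = wl_propagate_continuous(x, triangle, iterations=4)
        for it in emb.iterates:
            np.testing.assert_allclose(it, 7.0)

    def test_two_node_hand_calculation(self):
        g = SpatialGraph(n_nodes=2, edges=np.array([[0, 1]]))
        emb = wl_propagate_continuous(np.array([0.0, 2.0]), g, iterations=1)
        np.testing.assert_allclose(emb.iterates[1].ravel(), [1.0, 1.0])

    def test_matches_loop_oracle(self, rng):
        for _ in range(50):
            g = random_graph(rng, n_max=12)
            X = rng.normal(size=(g.n_nodes, 3))
            emb = wl_propagate_continuous(X, g, iterations=3)
            want = loop_propagate(X, g, 3)
            for a, b in zip(emb.iterates, want):
                np.testing.assert_allclose(a, b, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        g = random_graph(rng, n_max=15)
        X = rng.normal(size=(g.n_nodes, 2))
        perm = rng.permutation(g.n_nodes)
        g2 = SpatialGraph(
            n_nodes=g.n_nodes, edges=perm[g.edges] if g.n_edges else g.edges
        )
        X2 = np.empty_like(X)
        X2[perm] = X
        e1 = wl_propagate_continuous(X, g, 3).concatenated
        e2 = wl_propagate_continuous(X2, g2, 3).concatenated
        np.testing.assert_allclose(e2[perm], e1, atol=1e-12)

    def test_isolated_node_keeps_attribute(self):
        g = SpatialGraph(n_nodes=2, edges=np.empty((0, 2), dtype=int))
        emb = wl_propagate_continuous(np.array([1.0, -3.0]), g, iterations=3)
        for it in emb.iterates:
            np.testing.assert_allclose(it.ravel(), [1.0, -3.0])


class TestTransport:
    def test_plan_marginals_and_cost_consistency(self, rng):
        D = rng.uniform(size=(6, 9))
        res = exact_ot(D)
        np.testing.assert_allclose(res.transport_plan.sum(axis=1), 1 / 6, atol=1e-8)
        np.testing.assert_allclose(res.transport_plan.sum(axis=0), 1 / 9, atol=1e-8)
        assert res.distance == pytest.approx(
            float((res.transport_plan * D).sum()), abs=1e-8
        )

    def test_exact_beats_feasible_plans(self, rng):
        D = rng.uniform(size=(5, 5))
        res = exact_ot(D)
        for _ in range(20):
            perm = rng.permutation(5)
            feasible_cost = D[np.arange(5), perm].mean()
            assert res.distance <= feasible_cost + 1e-12

    def test_scalar_case_matches_sorted_1d_form(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        res = exact_ot(np.abs(a[:, None] - b[None, :]))
        assert res.distance == pytest.approx(
            wasserstein_distance(a, b), abs=1e-8
        )

    def test_sinkhorn_near_exact(self, rng):
        D = rng.uniform(size=(8, 8))
        ex = exact_ot(D).distance
        sk = sinkhorn_ot(D, epsilon=0.002).distance
        assert sk == pytest.approx(ex, rel=0.05)


class TestWWLDistance:
    def test_self_distance_zero(self, rng):
        coords = rng.uniform(size=(20, 2))
        X = rng.normal(size=(20, 3))
        s = sample_from(X, coords)
        g = build_delaunay(coords)
        res = wasserstein_wl_distance(s, g, s, g)
        assert res.distance == pytest.approx(0.0, abs=1e-10)

    def test_single_node_pair_closed_form(self):
        """Isolated nodes keep their attribute, so with H=3 the
        concatenated embeddings are (0,0,0,0) and (3,3,3,3): W = 6."""
        g = SpatialGraph(n_nodes=1, edges=np.empty((0, 2), dtype=int))
        sa = SpatialSample("a", "A", np.array([[0.0, 0]]), np.array([[0.0]]))
        sb = SpatialSample("b", "B", np.array([[0.0, 0]]), np.array([[3.0]]))
        res = wasserstein_wl_distance(sa, g, sb, g, iterations=3)
        assert res.distance == pytest.approx(6.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(5):
            ca, cb = rng.uniform(size=(10, 2)), rng.uniform(size=(14, 2))
            sa = sample_from(rng.normal(size=(10, 2)), ca)
            sb = sample_from(rng.normal(size=(14, 2)), cb)
            ga, gb = build_delaunay(ca), build_delaunay(cb)
            d1 = wasserstein_wl_distance(sa, ga, sb, gb).distance
            d2 = wasserstein_wl_distance(sb, gb, sa, ga).distance
            assert d1 == pytest.approx(d2, abs=1e-8)

    def test_h0_reduces_to_raw_feature_ot(self, rng):
        ca, cb = rng.uniform(size=(8, 2)), rng.uniform(size=(8, 2))
        Xa, Xb = rng.normal(size=(8, 1)), rng.normal(size=(8, 1))
        res = wasserstein_wl_distance(
            sample_from(Xa, ca), build_delaunay(ca),
            sample_from(Xb, cb), build_delaunay(cb), iterations=0,
        )
        assert res.distance == pytest.approx(
            wasserstein_distance(Xa.ravel(), Xb.ravel()), abs=1e-8
        )

    def test_feature_scaling_linearity(self, rng):
        ca, cb = rng.uniform(size=(9, 2)), rng.uniform(size=(11, 2))
        Xa, Xb = rng.normal(size=(9, 3)), rng.normal(size=(11, 3))
        ga, gb = build_delaunay(ca), build_delaunay(cb)
        d1 = wasserstein_wl_distance(
            sample_from(Xa, ca), ga, sample_from(Xb, cb), gb
        ).distance
        d3 = wasserstein_wl_distance(
            sample_from(3 * Xa, ca), ga, sample_from(3 * Xb, cb), gb
        ).distance
        assert d3 == pytest.approx(3 * d1, rel=1e-8)

    def test_feature_dim_mismatch(self, rng):
        ca = rng.uniform(size=(5, 2))
        ga = build_delaunay(ca)
        with pytest.raises(ValueError, match="feature dim"):
            wasserstein_wl_distance(
                sample_from(rng.normal(size=(5, 2)), ca), ga,
                sample_from(rng.normal(size=(5, 3)), ca), ga,
            )

    def test_full_rank_pca_is_a_rotation(self, rng):
        """Projecting onto all principal components is a rigid rotation
        of feature space and leaves the distance unchanged."""
        ca, cb = rng.uniform(size=(10, 2)), rng.uniform(size=(12, 2))
        Xa, Xb = rng.normal(size=(10, 4)), rng.normal(size=(12, 4))
        ga, gb = build_delaunay(ca), build_delaunay(cb)
        d0 = wasserstein_wl_distance(
            sample_from(Xa, ca), ga, sample_from(Xb, cb), gb, iterations=0
        ).distance
        d_pca = wasserstein_wl_distance(
            sample_from(Xa, ca), ga, sample_from(Xb, cb), gb,
            iterations=0, pca_components=4,
        ).distance
        assert d_pca == pytest.approx(d0, abs=1e-8)

    def test_cap_triggers(self, rng):
        ca = rng.uniform(size=(30, 2))
        s = sample_from(rng.normal(size=(30, 2)), ca)
        g = build_delaunay(ca)
        with pytest.raises(ValueError, match="subsample"):
            wasserstein_wl_distance(s, g, s, g, cell_cap=100)


class TestPairwise:
    def test_cross_condition_pair_count(self):
        spec = SynthSpec(
            seed=3, n_cells=30, n_types=2, expression_dim=3,
            n_samples_per_condition={"A": 2, "B": 3},
        )
        ds = generate_dataset(spec)
        graphs = {s.sample_id: build_delaunay(s.coords) for s in ds}
        tab = pairwise_wwl(ds, graphs, condition_pairs=[("A", "B")])
        assert len(tab) == 6

    def test_duplicate_samples_zero_distance(self, rng):
        spec = SynthSpec(
            seed=5, n_cells=25, n_types=2, expression_dim=3,
            n_samples_per_condition={"A": 1, "B": 1},
        )
        ds = generate_dataset(spec)
        # duplicate sample A_0 as a fake member of condition B
        import copy

        dup = copy.deepcopy(ds.samples[0])
        dup.sample_id = "dup"
        dup.condition = "B"
        ds.samples.append(dup)
        graphs = {s.sample_id: build_delaunay(s.coords) for s in ds}
        tab = pairwise_wwl(ds, graphs, all_pairs=True)
        row = tab[(tab.sample_a == "A_0") & (tab.sample_b == "dup")]
        assert row["value"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_triangle_inequality_on_triples(self, rng):
        spec = SynthSpec(
            seed=9, n_cells=20, n_types=2, expression_dim=2,
            n_samples_per_condition={"A": 3, "B": 3},
        )
        ds = generate_dataset(spec)
        graphs = {s.sample_id: build_delaunay(s.coords) for s in ds}
        tab = pairwise_wwl(ds, graphs, all_pairs=True)
        d = {
            (r.sample_a, r.sample_b): r.value for r in tab.itertuples()
        }
        def dist(a, b):
            return 0.0 if a == b else d[tuple(sorted((a, b)))]
        ids = ds.sample_ids
        for _ in range(50):
            a, b, c = rng.choice(ids, size=3, replace=False)
            assert dist(a, c) <= dist(a, b) + dist(b, c) + 1e-9
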