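"""Neighborhood enrichment and the differential niche model.

The permutation-test oracle enumerates all distinct label arrangements
exactly on small fixtures; the model tests simulate designs at known
ground truth (null calibration, effect recovery, overdispersion).
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from spatialcompare.graphs import SpatialGraph, build_delaunay
from spatialcompare.neighborhood import (
    build_niche_design,
    choose_family,
    fit_niche_model,
    flatten_upper,
    nhood_enrichment,
    upper_pair_names,
)
from spatialcompare.synthetic import simulate_enrichment_design


def exact_null(labels, edges, pair):
    """Exact permutation mean/variance of a pair count by enumerating
    all distinct arrangements of the label multiset."""
    counts = []
    for perm in set(itertools.permutations(labels)):
        c = 0
        for u, v in edges:
            if {perm[u], perm[v]} == set(pair) and (
                perm[u] != perm[v] or pair[0] == pair[1]
            ):
                c += 1
        counts.append(c)
    counts = np.array(counts, dtype=float)
    return counts.mean(), counts.var()


class TestEnrichment:
    def test_single_label_zero_z(self, path4):
        res = nhood_enrichment(path4, pd.Categorical(["A"] * 4), n_perms=50, seed=0)
        assert res.pair_counts[0, 0] == 3  # |E|
        assert res.zscores[0, 0] == 0.0    # permutation-invariant

    def test_path4_exact_enumeration(self, path4):
        """A,B,A,B on the path: observed AB count 3; over the 6 distinct
        arrangements the AB count has mean 2 and variance 2/3."""
        labels = ["A", "B", "A", "B"]
        mean, var = exact_null(labels, path4.edges, ("A", "B"))
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(2.0 / 3.0)
        res = nhood_enrichment(path4, pd.Categorical(labels), n_perms=50_000, seed=3)
        assert res.pair_counts[0, 1] == 3
        # Monte-Carlo moments within 3 standard errors of the exact values
        se_mean = np.sqrt(var / 50_000)
        assert res.perm_mean[0, 1] == pytest.approx(mean, abs=3 * se_mean)
        se_sd = np.sqrt(var) / np.sqrt(2 * 50_000)
        assert res.perm_sd[0, 1] == pytest.approx(np.sqrt(var), abs=3 * se_sd)
        want_z = (3 - mean) / np.sqrt(var)
        assert res.zscores[0, 1] == pytest.approx(want_z, rel=0.05)

    def test_symmetry_and_edge_total(self, rng):
        g = build_delaunay(rng.uniform(size=(50, 2)))
        labels = pd.Categorical(rng.choice(list("ABC"), size=50))
        res = nhood_enrichment(g, labels, n_perms=200, seed=1)
        np.testing.assert_array_equal(res.pair_counts, res.pair_counts.T)
        np.testing.assert_allclose(res.zscores, res.zscores.T)
        iu = np.triu_indices(3)
        assert res.pair_counts[iu].sum() == g.n_edges

    def test_random_labels_calibrated(self, rng):
        """Under random labeling the z-scores are centred near 0."""
        g = build_delaunay(rng.uniform(size=(120, 2)))
        zs = []
        for rep in range(20):
            labels = pd.Categorical(rng.choice(list("AB"), size=120))
            res = nhood_enrichment(g, labels, n_perms=1000, seed=rep)
            zs.append(flatten_upper(res.zscores))
        mean_z = np.mean(zs)
        se = np.std(zs) / np.sqrt(np.size(zs))
        assert abs(mean_z) <= 3 * se + 0.05

    def test_node_reindexing_invariance(self, rng):
        g = build_delaunay(rng.uniform(size=(30, 2)))
        labels = rng.choice(list("AB"), size=30)
        perm = rng.permutation(30)
        g2 = SpatialGraph(n_nodes=30, edges=perm[g.edges])
        res1 = nhood_enrichment(g, pd.Categorical(labels), 3000, seed=5)
        labels2 = np.empty(30, dtype=object)
        labels2[perm] = labels
        res2 = nhood_enrichment(g2, pd.Categorical(labels2), 3000, seed=5)
        np.testing.assert_array_equal(res1.pair_counts, res2.pair_counts)
        np.testing.assert_allclose(res1.zscores, res2.zscores, atol=0.15)


class TestFlatten:
    def test_lengths(self):
        for n in (1, 2, 3, 5):
            m = np.eye(n)
            assert len(flatten_upper(m)) == n * (n + 1) // 2

    def test_identity_2x2(self):
        np.testing.assert_array_equal(flatten_upper(np.eye(2)), [1, 0, 1])

    def test_order_is_row_major_upper(self):
        m = np.array([[1.0, 2, 3], [2, 4, 5], [3, 5, 6]])
        np.testing.assert_array_equal(flatten_upper(m), [1, 2, 3, 4, 5, 6])
        assert upper_pair_names(["A", "B", "C"]) == [
            "A|A", "A|B", "A|C", "B|B", "B|C", "C|C",
        ]

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            flatten_upper(np.array([[0.0, 1], [0, 0]]))


class TestChooseFamily:
    def test_all_positive_gaussian(self):
        assert choose_family(np.ones((5, 3), dtype=int)) == "gaussian"

    def test_always_zero_pair_quasipoisson(self):
        c = np.ones((5, 3), dtype=int)
        c[:, 1] = 0
        assert choose_family(c) == "quasipoisson"

    def test_boundary_strict_inequality(self):
        c = np.ones((5, 3), dtype=int)
        c[0, 1] = 0  # zero in exactly 20% of samples
        assert choose_family(c, sparsity_threshold=0.2) == "gaussian"
        c[1, 1] = 0  # 40% > 20%
        assert choose_family(c, sparsity_threshold=0.2) == "quasipoisson"


class TestNicheModel:
    def test_effect_recovery(self):
        """A z-score shift of 2 in one pair under condition B is
        recovered by the B-vs-A contrast within 3 standard errors."""
        design = simulate_enrichment_design(
            {"A": 10, "B": 10}, n_types=4,
            effect={("B", "type_0|type_1"): 2.0}, seed=11,
        )
        fit = fit_niche_model(design)
        row = fit.contrasts[fit.contrasts["pair"] == "type_0|type_1"].iloc[0]
        assert row["estimate"] == pytest.approx(2.0, abs=3 * row["se"])
        assert row["p"] < 0.05

    def test_batch_offset_absorbed(self):
        """A pure batch offset does not masquerade as a condition
        effect."""
        design = simulate_enrichment_design(
            {"A": 10, "B": 10}, n_types=3, batch_sd=3.0, seed=5,
        )
        fit = fit_niche_model(design)
        assert (fit.contrasts["p"] < 0.01).mean() < 0.5
        batch_terms = fit.coefficients[
            fit.coefficients["term"].str.startswith("batch")
        ]
        assert len(batch_terms) == 1

    def test_quasipoisson_detects_overdispersion(self):
        design = simulate_enrichment_design(
            {"A": 10, "B": 10}, n_types=3, family="quasipoisson",
            nb_dispersion=4.0, seed=2,
        )
        fit = fit_niche_model(design)
        assert fit.family == "quasipoisson"
        assert fit.dispersion is not None and fit.dispersion > 1.0

    def test_families_agree_on_sign_of_strong_effects(self):
        effect = {("B", "type_0|type_1"): 0.8}
        d_counts = simulate_enrichment_design(
            {"A": 12, "B": 12}, n_types=3, family="quasipoisson",
            effect=effect, seed=9,
        )
        fit_qp = fit_niche_model(d_counts)
        d_gauss = simulate_enrichment_design(
            {"A": 12, "B": 12}, n_types=3, family="gaussian",
            effect={("B", "type_0|type_1"): 2.0}, seed=9,
        )
        fit_g = fit_niche_model(d_gauss)
        r_qp = fit_qp.contrasts.set_index("pair").loc["type_0|type_1"]
        r_g = fit_g.contrasts.set_index("pair").loc["type_0|type_1"]
        assert np.sign(r_qp["t"]) == np.sign(r_g["t"]) == 1.0

    def test_single_condition_rejected(self):
        design = simulate_enrichment_design({"A": 6}, n_types=3, seed=0)
        with pytest.raises(ValueError, match="condition"):
            fit_niche_model(design)

    def test_bh_adjustment_present(self):
        design = simulate_enrichment_design({"A": 8, "B": 8}, n_types=4, seed=0)
        fit = fit_niche_model(design)
        assert {"p", "p_adj", "significant"} <= set(fit.contrasts.columns)
        assert np.all(fit.contrasts["p_adj"] >= fit.contrasts["p"] - 1e-12)


class TestEndToEndDesign:
    def test_design_from_enrichments(self, small_dataset):
        graphs = {
            s.sample_id: build_delaunay(s.coords) for s in small_dataset
        }
        enr = {
            s.sample_id: nhood_enrichment(
                graphs[s.sample_id], s.labels, n_perms=100, seed=0
            )
            for s in small_dataset
        }
        design = build_niche_design(small_dataset, enr, family="gaussian")
        n = len(small_dataset.label_categories)
        assert design.response.shape == (len(small_dataset), n * (n + 1) // 2)
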