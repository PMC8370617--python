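"""PCA/DAPC ordination, UPGMA dendrograms and minimum spanning networks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from landracekit import (
    DistanceMatrix,
    GenotypeMatrix,
    ValidationError,
    dapc,
    minimum_spanning_network,
    msn_over_clones,
    pca,
    sample_dendrogram,
)


def make(dosage, ids=None):
    X = np.asarray(dosage, dtype=float)
    ids = ids or [f"S{i}" for i in range(X.shape[0])]
    return GenotypeMatrix(ids, [f"L{j}" for j in range(X.shape[1])], X)


class TestPCA:
    def test_rank_one_matrix_single_axis(self):
        # samples deviate from the centroid along a single direction
        X = np.array([[0, 0, 0], [2, 1, 0], [2, 1, 0], [0, 0, 0]], dtype=float)
        res = pca(make(X))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalues_match_dense_eigensolver(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(5, 3)).astype(float)
        res = pca(make(X))
        Xc = X - X.mean(axis=0)
        want = np.sort(np.linalg.eigvalsh(np.cov(Xc, rowvar=False)))[::-1]
        got = np.sort(res.eigenvalues)[::-1][: len(want)]
        assert np.allclose(got, want, atol=1e-10)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(20, 30)).astype(float)
        res = pca(make(X))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)
        assert res.cumulative_variance == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 3, size=(15, 25)).astype(float)
        S = pca(make(X)).scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(12, 18)).astype(float)
        eig = pca(make(X)).eigenvalues
        assert (np.diff(eig) <= 1e-12).all() and (eig >= -1e-12).all()

    def test_missing_data_mean_imputed(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(10, 12)).astype(float)
        X[rng.random(X.shape) < 0.1] = np.nan
        res = pca(make(X))
        assert np.isfinite(res.scores.to_numpy()).all()

    def test_axes_truncated_with_warning(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(4, 3)).astype(float)
        with pytest.warns(UserWarning, match="truncating"):
            res = pca(make(X), n_axes=10)
        assert res.n_axes <= 3


class TestDAPC:
    def _two_zone(self, delta=0.3, n=40, loci=200, seed=0):
        rng = np.random.default_rng(seed)
        pa = rng.uniform(0.2, 0.5, loci)
        Xa = rng.binomial(2, pa, size=(n, loci)).astype(float)
        Xb = rng.binomial(2, np.clip(pa + delta, 0, 1), size=(n, loci)).astype(float)
        G = make(np.vstack([Xa, Xb]))
        grouping = pd.Series(["A"] * n + ["B"] * n, index=G.sample_ids)
        return G, grouping

    def test_separated_zones_fully_assigned(self):
        G, grouping = self._two_zone()
        res = dapc(G, grouping, n_pca_axes=20)
        assert (res.group_assignment == grouping).all()
        assert res.n_discriminants == 1

    def test_null_populations_near_chance(self):
        accs = []
        for seed in range(5):
            G, grouping = self._two_zone(delta=0.0, n=100, loci=50, seed=seed)
            res = dapc(G, grouping, n_pca_axes=2)
            accs.append(float((res.group_assignment == grouping).mean()))
        assert np.mean(accs) < 0.65

    def test_seven_groups_six_discriminants(self, sim_default):
        G, meta, _ = sim_default
        coll = meta.collected_ids
        res = dapc(G.subset(samples=coll), meta.zone_of(coll), n_pca_axes=30)
        assert res.n_discriminants == 6
        assert res.posterior.shape[1] == 7

    def test_singleton_group_rejected(self):
        G, grouping = self._two_zone(n=5)
        grouping.iloc[0] = "C"
        with pytest.raises(ValidationError, match="single sample"):
            dapc(G, grouping, n_pca_axes=3)

    def test_sample_order_equivariance(self):
        G, grouping = self._two_zone(seed=3)
        res = dapc(G, grouping, n_pca_axes=10)
        rng = np.random.default_rng(9)
        perm = rng.permutation(G.n_samples)
        Gp = GenotypeMatrix([G.sample_ids[i] for i in perm], G.locus_ids, G.dosage[perm])
        resp = dapc(Gp, grouping, n_pca_axes=10)
        assert (resp.group_assignment.loc[G.sample_ids] == res.group_assignment).all()


def dmat(v, ids=None, bounded=True):
    v = np.asarray(v, dtype=float)
    ids = ids or [f"N{i}" for i in range(v.shape[0])]
    return DistanceMatrix(ids, v, bounded=bounded)


class TestDendrogram:
    def test_upgma_hand_example(self):
        D = dmat([[0, 2, 6], [2, 0, 6], [6, 6, 0]], ids=["A", "B", "C"], bounded=False)
        tree = sample_dendrogram(D)
        depth = {t.taxon.label: t.distance_from_root() for t in tree.leaf_node_iter()}
        assert depth == {"A": 3.0, "B": 3.0, "C": 3.0}  # ultrametric
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(2.0)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(6.0)

    def test_two_samples_cherry_at_half_distance(self):
        tree = sample_dendrogram(dmat([[0, 0.4], [0.4, 0]], ids=["A", "B"]))
        depth = {t.taxon.label: t.distance_from_root() for t in tree.leaf_node_iter()}
        assert depth["A"] == pytest.approx(0.2) and depth["B"] == pytest.approx(0.2)

    def test_zero_distance_duplicates(self):
        D = dmat([[0, 0, 0.5], [0, 0, 0.5], [0.5, 0.5, 0]], ids=["A", "A2", "C"])
        tree = sample_dendrogram(D)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["A2"]) == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            sample_dendrogram(dmat([[0.0]], ids=["A"]))

    def test_nj_method_dispatch(self):
        D = dmat([[0, 0.2, 0.4], [0.2, 0, 0.3], [0.4, 0.3, 0]], ids=["A", "B", "C"])
        tree = sample_dendrogram(D, method="nj")
        assert {t.label for t in tree.taxon_namespace} == {"A", "B", "C"}


def brute_force_mst_weight(v):
    n = v.shape[0]
    edges = list(itertools.combinations(range(n), 2))
    best = np.inf
    for sel in itertools.combinations(edges, n - 1):
        g = nx.Graph(list(sel))
        if g.number_of_nodes() == n and nx.is_tree(g):
            best = min(best, sum(v[i, j] for i, j in sel))
    return best


class TestMSN:
    def test_three_node_chain(self):
        net = minimum_spanning_network(
            dmat([[0, 1, 3], [1, 0, 2], [3, 2, 0]], bounded=False)
        )
        kinds = {frozenset(e): d["kind"] for *e, d in net.edges(data=True)}
        assert kinds == {
            frozenset({"N0", "N1"}): "mst",
            frozenset({"N1", "N2"}): "mst",
        }

    def test_equilateral_triangle_reticulation(self):
        net = minimum_spanning_network(dmat([[0, 1, 1], [1, 0, 1], [1, 1, 0]], bounded=False))
        kinds = sorted(d["kind"] for _, _, d in net.edges(data=True))
        assert kinds == ["mst", "mst", "reticulation"]

    def test_mst_weight_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            v = rng.uniform(0.1, 1.0, size=(n, n))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            net = minimum_spanning_network(dmat(v, bounded=False))
            w = sum(
                d["weight"] for _, _, d in net.edges(data=True) if d["kind"] == "mst"
            )
            assert w == pytest.approx(brute_force_mst_weight(v), abs=1e-12)

    def test_reticulation_ties_an_mst_edge(self):
        rng = np.random.default_rng(78)
        v = rng.choice([0.2, 0.4, 0.6], size=(8, 8))
        v = np.triu(v, 1)
        v = v + v.T
        net = minimum_spanning_network(dmat(v, bounded=False))
        mst = nx.Graph(
            [(u, w) for u, w, d in net.edges(data=True) if d["kind"] == "mst"]
        )
        for u, w, d in net.edges(data=True):
            if d["kind"] == "reticulation":
                path = nx.shortest_path(mst, u, w)
                pmax = max(
                    net.edges[a, b]["weight"] for a, b in zip(path[:-1], path[1:])
                )
                assert d["weight"] <= pmax + 1e-9

    def test_msn_over_clones_nodes_are_representatives(self, sim_default):
        from landracekit import (
            calibrate_threshold,
            call_clones,
            hamming_distance,
            replicate_pair_distances,
        )

        G, meta, _ = sim_default
        D = hamming_distance(G)
        reps = replicate_pair_distances(D, meta)
        part = call_clones(D, calibrate_threshold(reps.distances), G=G)
        net = msn_over_clones(D, part, meta)
        assert net.number_of_nodes() == part.n_groups
        some = next(iter(net.nodes))
        assert "members" in net.nodes[some]
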