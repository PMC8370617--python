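"""Shannon, allele frequencies, Fst (WC84 oracle), Nei distance, NJ."""

import numpy as np
import pandas as pd
import pytest

from landracekit import (
    DistanceMatrix,
    GenotypeMatrix,
    ValidationError,
    allele_frequencies,
    diversity_report,
    nei_distance,
    nei_distance_matrix,
    neighbor_joining,
    pairwise_fst,
    shannon_by_zone,
    shannon_index,
)


class TestShannon:
    def test_uniform_maximum(self):
        assert shannon_index([1, 1, 1, 1]) == pytest.approx(np.log(4), abs=1e-12)

    def test_hand_value(self):
        assert shannon_index([2, 1, 1]) == pytest.approx(1.0397207708399179, abs=1e-12)

    def test_single_clone_zero(self):
        assert shannon_index([7]) == 0.0

    def test_zero_counts_excluded(self):
        assert shannon_index([2, 1, 1, 0, 0]) == pytest.approx(shannon_index([2, 1, 1]))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 50, size=rng.integers(1, 10))
            h = shannon_index(counts)
            assert -1e-12 <= h <= np.log(len(counts)) + 1e-12

    def test_errors(self):
        with pytest.raises(ValidationError):
            shannon_index([0, 0])
        with pytest.raises(ValidationError):
            shannon_index([-1, 2])


def make(dosage, ids=None):
    X = np.asarray(dosage, dtype=float)
    ids = ids or [f"S{i}" for i in range(X.shape[0])]
    return GenotypeMatrix(ids, [f"L{j}" for j in range(X.shape[1])], X)


class TestAlleleFrequencies:
    def test_hand_values(self):
        G = make([[0], [1], [2]])
        grouping = pd.Series({"S0": "Z", "S1": "Z", "S2": "Z"})
        f, n = allele_frequencies(G, grouping)
        assert f.loc["Z", "L0"] == pytest.approx(0.5)
        assert n.loc["Z", "L0"] == 3

    def test_fixed_and_undefined(self):
        G = make([[2, np.nan], [2, np.nan]])
        f, _ = allele_frequencies(G, pd.Series({"S0": "Z", "S1": "Z"}))
        assert f.loc["Z", "L0"] == 1.0
        assert np.isnan(f.loc["Z", "L1"])


def wc84_oracle(Xa, Xb):
    """Independently coded scalar-loop Weir & Cockerham (1984) theta."""
    suma = sumall = 0.0
    r = 2
    for l in range(Xa.shape[1]):
        ga = Xa[:, l][~np.isnan(Xa[:, l])]
        gb = Xb[:, l][~np.isnan(Xb[:, l])]
        na, nb = len(ga), len(gb)
        if na < 1 or nb < 1 or na + nb <= 2:
            continue
        pa, pb = ga.sum() / (2 * na), gb.sum() / (2 * nb)
        ha, hb = (ga == 1).mean(), (gb == 1).mean()
        nbar = (na + nb) / r
        nc = (r * nbar - (na**2 + nb**2) / (r * nbar)) / (r - 1)
        pbar = (na * pa + nb * pb) / (r * nbar)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (na * ha + nb * hb) / (r * nbar)
        a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        suma += a
        sumall += a + b + c
    return suma / sumall


class TestFst:
    def test_fixed_difference_is_one(self):
        # pop1 all AA (dosage 0), pop2 all aa (dosage 2), one locus
        Xa, Xb = np.zeros((10, 1)), np.full((10, 1), 2.0)
        G = make(np.vstack([Xa, Xb]))
        grouping = pd.Series(["P1"] * 10 + ["P2"] * 10, index=G.sample_ids)
        assert pairwise_fst(G, grouping).loc["P1", "P2"] == pytest.approx(1.0)
        assert wc84_oracle(Xa, Xb) == pytest.approx(1.0)

    def test_matches_scalar_oracle_with_missing_data(self):
        rng = np.random.default_rng(17)
        Xa = rng.integers(0, 3, size=(15, 40)).astype(float)
        Xb = rng.integers(0, 3, size=(12, 40)).astype(float)
        Xa[rng.random(Xa.shape) < 0.15] = np.nan
        Xb[rng.random(Xb.shape) < 0.15] = np.nan
        G = make(np.vstack([Xa, Xb]))
        grouping = pd.Series(["A"] * 15 + ["B"] * 12, index=G.sample_ids)
        got = pairwise_fst(G, grouping).loc["A", "B"]
        assert got == pytest.approx(wc84_oracle(Xa, Xb), abs=1e-12)

    def test_null_two_samples_of_one_population(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(0.1, 0.9, 500)
        X = rng.binomial(2, p, size=(400, 500)).astype(float)
        G = make(X)
        grouping = pd.Series(["A"] * 200 + ["B"] * 200, index=G.sample_ids)
        assert abs(pairwise_fst(G, grouping).loc["A", "B"]) < 0.01

    def test_locus_order_invariance(self):
        rng = np.random.default_rng(29)
        X = rng.integers(0, 3, size=(30, 50)).astype(float)
        grouping = pd.Series(["A"] * 15 + ["B"] * 15, index=[f"S{i}" for i in range(30)])
        f1 = pairwise_fst(make(X), grouping).loc["A", "B"]
        perm = rng.permutation(50)
        f2 = pairwise_fst(make(X[:, perm]), grouping).loc["A", "B"]
        assert f1 == pytest.approx(f2, abs=1e-14)

    def test_small_zone_raises(self):
        G = make([[0], [1], [2]])
        grouping = pd.Series({"S0": "A", "S1": "A", "S2": "B"})
        with pytest.raises(ValidationError, match="B"):
            pairwise_fst(G, grouping)

    def test_nei87_estimator_runs_and_agrees_in_sign(self):
        rng = np.random.default_rng(31)
        Xa = rng.binomial(2, 0.2, size=(40, 200)).astype(float)
        Xb = rng.binomial(2, 0.6, size=(40, 200)).astype(float)
        G = make(np.vstack([Xa, Xb]))
        grouping = pd.Series(["A"] * 40 + ["B"] * 40, index=G.sample_ids)
        wc = pairwise_fst(G, grouping, estimator="WC84").loc["A", "B"]
        gst = pairwise_fst(G, grouping, estimator="Nei87").loc["A", "B"]
        assert wc > 0.1 and gst > 0.1


class TestNeiDistance:
    def test_identical_zero(self):
        x = np.array([0.2, 0.5, 0.9])
        assert nei_distance(x, x) == 0.0

    def test_hand_value(self):
        # Jxy = .5, Jx = .82, Jy = .5 -> I = .5/sqrt(.41), D = 0.2473
        assert nei_distance([0.9], [0.5]) == pytest.approx(0.2473, abs=5e-5)

    def test_clamp_at_fixed_opposite(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert nei_distance([1.0], [0.0], max_distance=10.0) == 10.0

    def test_symmetric_and_monotone(self):
        x = np.full(20, 0.5)
        prev = -1.0
        for y in (0.5, 0.6, 0.7, 0.8, 0.9):
            d = nei_distance(x, np.full(20, y))
            assert d == pytest.approx(nei_distance(np.full(20, y), x))
            assert d > prev
            prev = d

    def test_undefined_loci_skipped_and_error_when_none(self):
        assert nei_distance([0.5, np.nan], [0.5, 0.9]) == 0.0
        with pytest.raises(ValidationError):
            nei_distance([np.nan], [0.5])

    def test_matrix(self):
        f = pd.DataFrame([[0.1, 0.2], [0.1, 0.2], [0.9, 0.8]],
                         index=["A", "B", "C"], columns=["L1", "L2"])
        D = nei_distance_matrix(f)
        assert D.get("A", "B") == 0.0 and D.get("A", "C") > 0


def additive_distances(terminal, internal):
    """4-taxon tree ((A,B),(C,D)) with terminal lengths and one internal edge."""
    a, b, c, d = terminal
    return np.array(
        [
            [0, a + b, a + internal + c, a + internal + d],
            [a + b, 0, b + internal + c, b + internal + d],
            [a + internal + c, b + internal + c, 0, c + d],
            [a + internal + d, b + internal + d, c + d, 0],
        ]
    )


def tree_path_lengths(tree, ids):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
                           bounded=False)
        tree = neighbor_joining(D)
        got = tree_path_lengths(tree, ["A", "B", "C"])
        assert np.allclose(got, D.values, atol=1e-12)

    def test_additive_four_taxon_recovery(self):
        rng = np.random.default_rng(13)
        ids = ["A", "B", "C", "D"]
        for _ in range(25):
            d = additive_distances(rng.uniform(0.1, 1.0, 4), rng.uniform(0.1, 1.0))
            tree = neighbor_joining(DistanceMatrix(ids, d, bounded=False))
            assert np.abs(tree_path_lengths(tree, ids) - d).max() < 1e-9

    def test_equidistant_star_zero_internal(self):
        n = 5
        d = np.full((n, n), 0.4)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix([f"T{i}" for i in range(n)], d, bounded=False))
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.head_node.is_internal() and e.length is not None]
        assert max(internal, default=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_scikit_bio_on_additive_input(self):
        """Independent cross-check: on tree-additive distances both this NJ
        and scikit-bio's recover the generating path lengths."""
        import skbio

        rng = np.random.default_rng(19)
        ids = [f"T{i}" for i in range(6)]
        for _ in range(5):
            t = rng.uniform(0.1, 1.0, 6)
            e = rng.uniform(0.1, 1.0, 3)  # edges to three cherries
            d = np.zeros((6, 6))
            for i in range(6):
                for j in range(6):
                    if i == j:
                        continue
                    ci, cj = i // 2, j // 2
                    d[i, j] = t[i] + t[j] + (0.0 if ci == cj else e[ci] + e[cj])
            mine = neighbor_joining(DistanceMatrix(ids, d, bounded=False))
            assert np.abs(tree_path_lengths(mine, ids) - d).max() < 1e-9
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
            ref_d = ref.tip_tip_distances(endpoints=ids).data
            assert np.abs(ref_d - d).max() < 1e-6

    def test_too_few_taxa(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]]),
                                            bounded=False))

    def test_newick_round_trip(self):
        import dendropy

        D = DistanceMatrix(["A", "B", "C", "D"],
                           additive_distances([0.1, 0.2, 0.3, 0.4], 0.5), bounded=False)
        tree = neighbor_joining(D)
        txt = tree.as_string(schema="newick")
        back = dendropy.Tree.get(data=txt, schema="newick", preserve_underscores=True)
        assert {t.label for t in back.taxon_namespace} == {"A", "B", "C", "D"}


class TestDiversityReport:
    def test_end_to_end(self, sim_default):
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
        rep = diversity_report(G, part, meta)
        assert set(rep.shannon.index) <= set(meta.table["zone"].dropna().unique())
        assert (rep.shannon >= 0).all()
        # H <= ln(number of clones observed in the zone)
        sh = shannon_by_zone(part, meta)
        from landracekit import zone_clone_abundances

        ab = zone_clone_abundances(part, meta)
        for z, h in sh.items():
            assert h <= np.log(len(ab[z])) + 1e-9
        assert np.isfinite(rep.fst.to_numpy()).all()
        d = rep.to_dict()
        assert "zone_tree_newick" in d and d["zone_tree_newick"].endswith(";")
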