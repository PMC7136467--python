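"""Weir-Cockerham theta, Reynolds distances, neighbor joining."""

import io

import numpy as np
import pytest

from pigpopgen.differentiation import (DistanceMatrix, nj_tree,
                                       pairwise_fst_matrix,
                                       reynolds_distance, wc_fst)

from conftest import make_dataset


def wc84_single_locus(counts_by_pop):
    """Independent scalar transcription of the WC84 variance components for
    one biallelic locus; counts are (AA, Aa, aa) per population, counting
    the A allele."""
    r = len(counts_by_pop)
    n = [sum(c) for c in counts_by_pop]
    p = [(2 * aa + ab) / (2 * ni)
         for (aa, ab, _), ni in zip(counts_by_pop, n)]
    h = [ab / ni for (_, ab, _), ni in zip(counts_by_pop, n)]
    nbar = sum(n) / r
    nsum = sum(n)
    nc = (nsum - sum(x * x for x in n) / nsum) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / nsum
    s2 = sum(ni * (pi - pbar) ** 2
             for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / nsum
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c, a / (a + b + c)


def _dataset_from_counts(counts_by_pop):
    """One locus; genotypes expanded from per-population (AA, Aa, aa)."""
    calls, pops = [], []
    for k, (aa, ab, bb) in enumerate(counts_by_pop):
        calls += [[2]] * aa + [[1]] * ab + [[0]] * bb
        pops += [f"P{k + 1}"] * (aa + ab + bb)
    return make_dataset(np.array(calls, dtype=np.int8), populations=pops)


class TestWcFst:
    def test_complete_fixation_gives_one(self):
        ds = _dataset_from_counts([(10, 0, 0), (0, 0, 10)])
        assert wc_fst(ds, ("P1", "P2")).theta_multilocus == pytest.approx(
            1.0, abs=1e-12)

    def test_identical_tables_negative_bias(self):
        ds = _dataset_from_counts([(4, 4, 2), (4, 4, 2)])
        theta = wc_fst(ds, ("P1", "P2")).theta_multilocus
        *_, oracle = wc84_single_locus([(4, 4, 2), (4, 4, 2)])
        assert theta <= 0
        assert theta == pytest.approx(oracle, abs=1e-12)

    def test_matches_hand_oracle_to_machine_precision(self):
        tables = [(4, 4, 2), (1, 4, 5)]
        ds = _dataset_from_counts(tables)
        res = wc_fst(ds, ("P1", "P2"))
        a, b, c, theta = wc84_single_locus(tables)
        row = res.per_locus.iloc[0]
        assert row["a"] == pytest.approx(a, abs=1e-12)
        assert row["b"] == pytest.approx(b, abs=1e-12)
        assert row["c"] == pytest.approx(c, abs=1e-12)
        assert res.theta_multilocus == pytest.approx(theta, abs=1e-12)
        # value frozen from the oracle before wiring the comparison
        assert res.theta_multilocus == pytest.approx(0.11522633744855965,
                                                     abs=1e-12)

    def test_allele_swap_and_population_order_invariance(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(20, 60)).astype(np.int8)
        pops = ["A"] * 10 + ["B"] * 10
        t1 = wc_fst(make_dataset(calls, populations=pops),
                    ("A", "B")).theta_multilocus
        swapped = calls.copy()
        flip = rng.random(60) < 0.5
        swapped[:, flip] = 2 - swapped[:, flip]
        t2 = wc_fst(make_dataset(swapped, populations=pops),
                    ("A", "B")).theta_multilocus
        t3 = wc_fst(make_dataset(calls, populations=pops),
                    ("B", "A")).theta_multilocus
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert t1 == pytest.approx(t3, abs=1e-12)

    def test_monomorphic_loci_excluded_and_counted(self):
        calls = np.zeros((8, 2), dtype=np.int8)
        calls[:4, 1] = 2        # locus 2 polymorphic between pops
        ds = make_dataset(calls, populations=["A"] * 4 + ["B"] * 4)
        res = wc_fst(ds, ("A", "B"))
        assert res.n_loci_used == 1
        assert res.n_loci_excluded == 1


class TestPairwiseMatrix:
    def test_three_population_shape_and_symmetry(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(30, 100)).astype(np.int8)
        pops = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        dm, per_pop, grand = pairwise_fst_matrix(
            make_dataset(calls, populations=pops))
        assert dm.values.shape == (3, 3)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        assert len(per_pop) == 3

    def test_split_half_of_one_population_near_zero(self):
        from pigpopgen.synthetic_data import SimConfig, simulate_panel
        cfg = SimConfig(n_pops=1, drift=(0.2,), n_per_pop=(40,),
                        n_snps=5000, seed=17)
        ds, _, _ = simulate_panel(cfg)
        ds.samples.loc[20:, "population"] = "HALF2"
        theta = wc_fst(ds, ("POP1", "HALF2")).theta_multilocus
        assert abs(theta) < 0.02

    def test_tiny_population_excluded_with_warning(self):
        calls = np.zeros((5, 10), dtype=np.int8)
        calls[::2] = 2
        ds = make_dataset(calls, populations=["A", "A", "B", "B", "C"])
        with pytest.warns(UserWarning, match="excluding"):
            dm, _, _ = pairwise_fst_matrix(ds)
        assert dm.labels == ["A", "B"]


class TestReynolds:
    def test_transform_values(self):
        dm = DistanceMatrix(labels=["A", "B", "C"],
                            values=np.array([[0, 0.25, 0.0],
                                             [0.25, 0, -0.01],
                                             [0.0, -0.01, 0]]))
        with pytest.warns(UserWarning, match="clamped"):
            rey = reynolds_distance(dm)
        assert rey.get("A", "B") == pytest.approx(-np.log(0.75))
        assert rey.get("A", "C") == 0.0
        assert rey.get("B", "C") == 0.0          # negative theta clamped

    def test_monotone_in_theta(self):
        thetas = np.array([0.05, 0.1, 0.2, 0.4])
        d = -np.log(1 - thetas)
        assert (np.diff(d) > 0).all()


def _patristic(newick, labels):
    from skbio import TreeNode
    tree = TreeNode.read(io.StringIO(newick))
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tree.find(labels[i]).distance(
                tree.find(labels[j]))
    return out


class TestNjTree:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(labels=["A", "B", "C"],
                           values=np.array([[0, 3.0, 4.0],
                                            [3.0, 0, 5.0],
                                            [4.0, 5.0, 0]]))
        tree = nj_tree(D)
        assert tree.raw_lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert tree.raw_lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert tree.raw_lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) with a 1-unit internal edge
        labels = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels=labels, values=D))
        assert np.abs(_patristic(tree.newick, labels) - D).max() < 1e-9

    def test_additive_five_taxon_exact_recovery(self):
        # caterpillar tree with all branch lengths distinct
        labels = ["A", "B", "C", "D", "E"]
        #       A:1, B:2 join X; X-Y edge 1.5; C:3 on Y; Y-Z edge 0.5;
        #       D:4, E:5 on Z
        D = np.zeros((5, 5))
        path = {("A", "B"): 3, ("A", "C"): 5.5, ("A", "D"): 7,
                ("A", "E"): 8, ("B", "C"): 6.5, ("B", "D"): 8,
                ("B", "E"): 9, ("C", "D"): 7.5, ("C", "E"): 8.5,
                ("D", "E"): 9}
        for (x, y), v in path.items():
            i, j = labels.index(x), labels.index(y)
            D[i, j] = D[j, i] = v
        tree = nj_tree(DistanceMatrix(labels=labels, values=D))
        assert np.abs(_patristic(tree.newick, labels) - D).max() < 1e-9

    def test_topology_agrees_with_reference_nj(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(23)
        pts = rng.random((6, 3))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        labels = [f"t{i}" for i in range(6)]
        mine = nj_tree(DistanceMatrix(labels=labels, values=D))
        theirs = sk_nj(SkDM(D, ids=labels))
        from skbio import TreeNode
        mine_t = TreeNode.read(io.StringIO(mine.newick))
        assert mine_t.compare_rfd(theirs) == 0.0

    def test_ultrametric_matches_single_linkage_cherries(self):
        labels = ["A", "B", "C", "D", "E"]
        D = np.array([[0, .2, .6, .6, 1],
                      [.2, 0, .6, .6, 1],
                      [.6, .6, 0, .2, 1],
                      [.6, .6, .2, 0, 1],
                      [1, 1, 1, 1, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels=labels, values=D))
        from skbio import TreeNode
        t = TreeNode.read(io.StringIO(tree.newick))
        # the single-linkage topology pairs (A,B) and (C,D)
        assert t.find("A").parent is t.find("B").parent
        assert t.find("C").parent is t.find("D").parent

    def test_incomplete_matrix_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["A", "B", "C"], values=D))
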