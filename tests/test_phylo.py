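"""Distances, neighbor joining (vs brute-force oracle) and bootstrap."""
import itertools

import numpy as np
import pytest

from cctpr import phylo
from cctpr.errors import MatrixError, RaggedAlignmentError, \
    UndefinedDistanceError
from cctpr.seqio import AMINO_ACIDS


# ---------------------------------------------------------------- distances


def test_identical_sequences_have_zero_distance():
    assert phylo.pairwise_distance("MEEVDMEEVD", "MEEVDMEEVD") == 0.0


def test_single_mismatch_quarter_distance():
    assert phylo.pairwise_distance("AAAA", "AAAT") == pytest.approx(0.25)


def test_pairwise_distance_symmetry_sweep():
    rng = np.random.default_rng(5)
    for _ in range(25):
        a = "".join(rng.choice(list(AMINO_ACIDS), rng.integers(10, 40)))
        b = "".join(rng.choice(list(AMINO_ACIDS), rng.integers(10, 40)))
        assert phylo.pairwise_distance(a, b) == \
            pytest.approx(phylo.pairwise_distance(b, a))


def test_empty_sequence_rejected():
    with pytest.raises(UndefinedDistanceError):
        phylo.pairwise_distance("", "MEEVD")


def test_asymmetric_matrix_rejected():
    with pytest.raises(MatrixError):
        phylo.DistanceMatrix(("A", "B"),
                             np.array([[0.0, 0.1], [0.2, 0.0]]))


# ------------------------------------------------------------------- oracle


def _four_taxon_oracle(labels, d):
    """Brute force: enumerate the 3 unrooted 4-taxon topologies, fit the five
    branch lengths by least squares on path-incidence equations, and return
    the (split, branch-length map) of the additive fit."""
    best = None
    for split in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        (a, b), (c, e) = split
        # unknowns: x_a, x_b, x_c, x_e (pendant) + m (internal)
        pairs = list(itertools.combinations(range(4), 2))
        rows, rhs = [], []
        for i, j in pairs:
            row = [0.0] * 5
            row[i] = 1.0
            row[j] = 1.0
            same_side = {i, j} in ({a, b}, {c, e})
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            rhs.append(d[i, j])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs),
                                       rcond=None)
        predicted = np.array(rows) @ sol
        err = np.max(np.abs(predicted - rhs))
        if best is None or err < best[0]:
            best = (err, split, sol)
    err, split, sol = best
    assert err < 1e-9, "matrix is not additive"
    return split, sol


def _additive_matrix():
    # pendant branches 1,2,4,5 and internal branch 3 on split {A,B}|{C,D}
    labels = ("A", "B", "C", "D")
    d = np.array(
        [
            [0.0, 3.0, 8.0, 9.0],
            [3.0, 0.0, 9.0, 10.0],
            [8.0, 9.0, 0.0, 9.0],
            [9.0, 10.0, 9.0, 0.0],
        ]
    )
    return labels, d


def test_nj_matches_brute_force_four_taxon_oracle():
    labels, d = _additive_matrix()
    split, sol = _four_taxon_oracle(labels, d)
    assert split == ((0, 1), (2, 3))
    np.testing.assert_allclose(sol, [1, 2, 4, 5, 3], atol=1e-9)

    tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
    assert frozenset({"A", "B"}) in tree.bipartitions() or \
        frozenset({"C", "D"}) in tree.bipartitions()
    td = tree.tip_distances()
    idx = {l: i for i, l in enumerate(td.labels)}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            assert td.values[idx[a], idx[b]] == pytest.approx(d[i, j],
                                                              abs=1e-9)


def test_nj_reproduces_path_distances_of_random_additive_matrices():
    rng = np.random.default_rng(99)
    for _ in range(5):
        # random additive matrix from a random caterpillar tree on 6 taxa
        n = 6
        labels = tuple(f"t{i}" for i in range(n))
        # build tree distances by random ultrametric-free construction:
        # join taxa sequentially with random positive branch lengths
        pend = rng.uniform(0.05, 1.0, size=n)
        internal = rng.uniform(0.05, 1.0, size=n - 3)
        # path distances on a caterpillar: t0,t1 at one end, tn-1 at other
        pos = np.concatenate([[0.0], np.cumsum(internal)])  # spine nodes
        attach = [0, 0] + list(range(1, n - 3)) + [n - 4, n - 4] \
            if n > 4 else [0, 0, 0, 0]
        attach = attach[:n]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                spine = abs(pos[attach[i]] - pos[attach[j]])
                d[i, j] = d[j, i] = pend[i] + pend[j] + spine
        tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
        td = tree.tip_distances()
        idx = {l: i for i, l in enumerate(td.labels)}
        for i in range(n):
            for j in range(n):
                assert td.values[idx[labels[i]], idx[labels[j]]] == \
                    pytest.approx(d[i, j], abs=1e-9)


def test_nj_invariant_under_label_permutation():
    labels, d = _additive_matrix()
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
    perm = [2, 0, 3, 1]
    plabels = tuple(labels[i] for i in perm)
    pd = d[np.ix_(perm, perm)]
    ptree = phylo.neighbor_joining(phylo.DistanceMatrix(plabels, pd))
    assert tree.bipartitions() == ptree.bipartitions()


def test_two_taxa_split_the_distance():
    tree = phylo.neighbor_joining(
        phylo.DistanceMatrix(("A", "B"), np.array([[0.0, 0.4], [0.4, 0.0]]))
    )
    assert tree.to_newick() == "(A:0.2,B:0.2);"


# ---------------------------------------------------------------- bootstrap


def _clade_alignment():
    rng = np.random.default_rng(12)
    base = "".join(rng.choice(list(AMINO_ACIDS), 40))
    variant = "".join("K" if c in "AILV" else c for c in base)
    return [
        ("x1", base),
        ("x2", "D" + base[1:]),
        ("y1", variant),
        ("y2", "E" + variant[1:]),
    ]


def test_bootstrap_is_seed_reproducible():
    aln = _clade_alignment()
    a = phylo.bootstrap_support(aln, n_replicates=50, seed=3)
    b = phylo.bootstrap_support(aln, n_replicates=50, seed=3)
    assert a.to_newick() == b.to_newick()


def test_bootstrap_identical_rows_degenerate_case():
    aln = [("a", "MEEVD"), ("b", "MEEVD"), ("c", "MEEVD"), ("d", "MEEVD")]
    tree = phylo.bootstrap_support(aln, n_replicates=10, seed=0)
    for node in tree.tree.non_tips(include_self=False):
        if node.name is not None:
            assert int(node.name) == 10


def test_bootstrap_strong_bipartition_gets_high_support():
    aln = _clade_alignment()
    tree = phylo.bootstrap_support(aln, n_replicates=200, seed=4)
    parts = tree.bipartitions()
    target = frozenset({"y1", "y2"}) if frozenset({"y1", "y2"}) in parts \
        else frozenset({"x1", "x2"})
    # read the support off the internal node
    supports = [int(n.name) for n in tree.tree.non_tips(include_self=False)
                if n.name is not None]
    assert supports and max(supports) >= 190


def test_ragged_alignment_rejected():
    with pytest.raises(RaggedAlignmentError):
        phylo.bootstrap_support([("a", "MEEVD"), ("b", "MEEV")],
                                n_replicates=5, seed=0)


def test_fixture_concatenated_alignment_tree(at_rows, os_rows):
    rows = [r for r in at_rows + os_rows if not r.is_reference]
    aln = phylo.concatenated_motif_alignment(rows)
    assert len(aln) == 71
    assert all(len(s) == 102 for _, s in aln)
    dm = phylo.distance_matrix_from_alignment(aln)
    tree = phylo.neighbor_joining(dm)
    leaves = set(tree.leaf_names())
    assert {"AtTTL1", "AtTTL2", "AtTTL3", "AtTTL4",
            "Os01g11920", "Os05g11990", "Os01g42960"} <= leaves
    assert len(leaves) == 71


def test_newick_round_trip(tmp_path):
    import io

    import skbio

    labels, d = _additive_matrix()
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, d))
    from cctpr.seqio import write_newick

    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = skbio.TreeNode.read(io.StringIO(path.read_text()))
    assert {t.name for t in back.tips()} == set(labels)
    wrapped = phylo.PhyloTree(tree=back)
    assert wrapped.bipartitions() == tree.bipartitions()
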