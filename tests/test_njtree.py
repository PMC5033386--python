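"""Neighbor joining, bootstrap supports and midpoint rooting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_alignment
from transpoly.codon import SaturationError
from transpoly.njtree import (
    Node,
    bipartitions,
    bootstrap_support,
    midpoint_root,
    nj_tree,
)


def leaf_dists(root):
    """Pairwise leaf path-length matrix from a rooted tree."""
    paths = {}

    def walk(node, acc):
        if node.is_leaf:
            paths[node.label] = acc
            return
        for c in node.children:
            walk(c, acc + [(c, c.length)])

    walk(root, [])
    labels = sorted(paths)
    D = {}
    for a in labels:
        for b in labels:
            if a >= b:
                continue
            ea = {id(n): l for n, l in paths[a]}
            eb = {id(n): l for n, l in paths[b]}
            d = sum(l for i, l in ea.items() if i not in eb)
            d += sum(l for i, l in eb.items() if i not in ea)
            D[(a, b)] = d
    return labels, D


def test_additive_four_taxon_exact_recovery():
    # tree ((A:1,B:2):1,(C:3,D:1)): AB=3, AC=5, AD=3, BC=6, BD=4, CD=4
    labels = ["A", "B", "C", "D"]
    D = np.array(
        [
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ],
        dtype=float,
    )
    tree = nj_tree(D, labels)
    assert bipartitions(tree) == {frozenset({"C", "D"})}
    _, dd = leaf_dists(tree)
    for (a, b), expected in {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 3,
        ("B", "C"): 6, ("B", "D"): 4, ("C", "D"): 4,
    }.items():
        assert dd[(a, b)] == pytest.approx(expected)


def test_three_taxa_three_point_formulas():
    D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    tree = nj_tree(D, ["x", "y", "z"])
    _, dd = leaf_dists(tree)
    assert dd[("x", "y")] == pytest.approx(2)
    assert dd[("x", "z")] == pytest.approx(3)
    assert dd[("y", "z")] == pytest.approx(5)


def test_too_few_taxa_and_nan_errors():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])
    D = np.zeros((3, 3))
    D[0, 1] = D[1, 0] = np.nan
    with pytest.raises(SaturationError, match="a.*b"):
        nj_tree(D, ["a", "b", "c"])


def test_equidistant_matrix_permutation_invariant():
    labels = ["t1", "t2", "t3", "t4", "t5"]
    D = np.full((5, 5), 1.0)
    np.fill_diagonal(D, 0.0)
    ref = nj_tree(D, labels).newick()
    rng = np.random.default_rng(0)
    for _ in range(5):
        perm = rng.permutation(5)
        tree = nj_tree(D[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert tree.newick() == ref


def random_additive_tree(rng, n):
    """Random topology + strictly positive branch lengths."""
    nodes = [Node(label=f"t{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        new = Node(children=[a, b])
        nodes = [nd for q, nd in enumerate(nodes) if q not in (i, j)] + [new]
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 2.0))
    return Node(children=nodes)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(4, 12), st.integers(0, 10_000))
def test_nj_recovers_random_additive_trees(n, seed):
    rng = np.random.default_rng(seed)
    true = random_additive_tree(rng, n)
    labels, dd = leaf_dists(true)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = dd[(a, b)]
    rec = nj_tree(D, labels)
    assert bipartitions(rec) == bipartitions(true)
    _, dd2 = leaf_dists(rec)
    for k, v in dd.items():
        assert dd2[k] == pytest.approx(v, abs=1e-8)


def test_nj_matches_dendropy_on_random_matrix():
    """Independent cross-check: dendropy's NJ yields the same bipartitions."""
    import dendropy

    rng = np.random.default_rng(5)
    true = random_additive_tree(rng, 8)
    labels, dd = leaf_dists(true)
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                D[i, j] = D[j, i] = dd[(a, b)]
    mine = nj_tree(D, labels)
    csv = "," + ",".join(labels) + "\n"
    for i, a in enumerate(labels):
        csv += a + "," + ",".join(str(D[i, j]) for j in range(n)) + "\n"
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=io.StringIO(csv), delimiter=","
    )
    dtree = pdm.nj_tree()
    theirs = set()
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        theirs.add(frozenset(t.taxon.label for t in nd.leaf_iter()))
    anchor = min(labels)
    full = frozenset(labels)
    theirs = {(full - s if anchor in s else s) for s in theirs}
    theirs = {s for s in theirs if 2 <= len(s) <= n - 2}
    assert bipartitions(mine) == theirs


def test_bootstrap_unanimous_for_clean_clades():
    # two clades separated by a 12-site block, 1-site differences within
    base1 = "A" * 12 + "C" * 48
    base2 = "G" * 12 + "C" * 48
    aln = make_alignment(
        [
            base1,
            base1[:20] + "T" + base1[21:],
            base1[:30] + "T" + base1[31:],
            base2,
            base2[:40] + "T" + base2[41:],
            base2[:50] + "T" + base2[51:],
        ]
    )
    st_ = bootstrap_support(aln, reps=100, seed=1)
    deep = [s for b, s in st_.supports.items() if len(b) == 3]
    assert deep and all(s == pytest.approx(1.0) for s in deep)


def test_bootstrap_deterministic_under_seed(default_sim):
    _, aln, _, _ = default_sim
    sub = aln.subset(list(range(12)))
    a = bootstrap_support(sub, reps=100, seed=9)
    b = bootstrap_support(sub, reps=100, seed=9)
    assert a.supports == b.supports
    assert a.newick() == b.newick()


def test_midpoint_two_leaf_center():
    tree = Node(children=[Node(label="a", length=2.0), Node(label="b", length=4.0)])
    rooted = midpoint_root(tree)
    lens = sorted(c.length for c in rooted.children)
    assert lens == pytest.approx([3.0, 3.0])


def test_midpoint_roots_on_longest_path():
    # ((A:1,B:1):0,C:4): midpoint lies on C's branch
    inner = Node(children=[Node(label="A", length=1), Node(label="B", length=1)], length=0.0)
    tree = Node(children=[inner, Node(label="C", length=4)])
    rooted = midpoint_root(tree)
    sides = {frozenset(c.leaf_labels()): c.length for c in rooted.children}
    assert frozenset({"C"}) in sides
    assert sides[frozenset({"C"})] == pytest.approx(2.5)
    # leaf-to-leaf distances preserved
    _, dd = leaf_dists(rooted)
    assert dd[("A", "C")] == pytest.approx(5.0)
    assert dd[("A", "B")] == pytest.approx(2.0)


def test_rooting_preserves_bipartition_supports(default_sim):
    _, aln, _, _ = default_sim
    sub = aln.subset(list(range(10)))
    st_ = bootstrap_support(sub, reps=100, seed=3)
    rooted = midpoint_root(st_.root)
    # every original bipartition is still a bipartition of the rooted tree
    assert bipartitions(st_.root) == bipartitions(rooted)


def test_bootstrap_support_converges_with_replicates(default_sim):
    """Supports at increasing replicate counts agree within binomial error."""
    _, aln, _, _ = default_sim
    sub = aln.subset(list(range(10)))
    s100 = bootstrap_support(sub, reps=100, seed=21).supports
    s500 = bootstrap_support(sub, reps=500, seed=22).supports
    s2000 = bootstrap_support(sub, reps=2000, seed=23).supports
    for b in s2000:
        se = (s2000[b] * (1 - s2000[b]) / 500) ** 0.5
        assert abs(s500[b] - s2000[b]) <= max(4 * se, 0.03)
        se100 = (s2000[b] * (1 - s2000[b]) / 100) ** 0.5
        assert abs(s100[b] - s2000[b]) <= max(4 * se100, 0.06)
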