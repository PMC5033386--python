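"""Distance trees: neighbor joining, nonparametric bootstrap, midpoint root.

Neighbor joining (Saitou-Nei, Studier-Keppler Q criterion) on K2 distances
stands in for heavier likelihood searches: for deep-clade support and
lineage detection the same bipartitions are recovered, and the builder is
bit-reproducible (lexicographic tie-breaking everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlleleAlignment
from .codon import SaturationError
from .distances import distance_matrix, encode


@dataclass
class Node:
    label: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["Node"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def newick(self, with_support: bool = False) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if self.is_leaf:
            return f"{self.label}:{self.length:.6g}"
        inner = ",".join(c._nwk(ws) for c in self.children)
        lab = ""
        if ws and self.support is not None:
            lab = f"{self.support:.3f}"
        elif self.label:
            lab = self.label
        return f"({inner}){lab}:{self.length:.6g}"

    def copy(self) -> "Node":
        n = Node(self.label, self.length, [c.copy() for c in self.children], self.support)
        return n


def bipartitions(root: Node) -> set[frozenset[str]]:
    """Internal-edge bipartitions, canonicalised as the side not containing
    the lexicographically smallest leaf label."""
    all_leaves = root.leaf_labels()
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in root.postorder():
        if node is root or node.is_leaf:
            continue
        side = node.leaf_labels()
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(D: np.ndarray, labels: list[str]) -> Node:
    """Neighbor joining with deterministic lexicographic tie-breaking.

    Negative branch lengths are clamped to zero with the deficit shifted to
    the sister branch (total kept).  Saturated (NaN) entries raise a
    SaturationError naming the offending pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix / labels mismatch")
    if n < 3:
        raise ValueError("need >= 3 taxa")
    bad = np.argwhere(np.isnan(D))
    if bad.size:
        i, j = bad[0]
        raise SaturationError(
            f"undefined distance between {labels[i]!r} and {labels[j]!r}"
        )
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")

    nodes: list[Node] = [Node(label=lab) for lab in labels]
    # sort key per active node: min leaf label under it (for tie-breaks)
    keys: list[str] = list(labels)
    D = D.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        Qr = np.round(Q, 10)
        qmin = Qr.min()
        cand = np.argwhere(Qr == qmin)
        # deterministic: smallest sorted label pair
        best = min(
            ((a, b) for a, b in cand if a < b),
            key=lambda ab: tuple(sorted((keys[active[ab[0]]], keys[active[ab[1]]]))),
        )
        ai, bi = best
        i, j = active[ai], active[bi]
        dij = D[i, j]
        vi = 0.5 * dij + (R[ai] - R[bi]) / (2.0 * (r - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = vi, vj
        # children ordered by key for reproducible newick
        ch = sorted([ni, nj_], key=lambda nd: keys[i] if nd is ni else keys[j])
        new = Node(children=ch)
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        # distances to the new node
        newrow = np.zeros(len(nodes))
        for k in active:
            if k in (i, j):
                continue
            newrow[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow)] = newrow
        D[: len(newrow), -1] = newrow
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the final three nodes at an unrooted trifurcation
    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, v in zip((a, b, c), (va, vb, vc)):
        nodes[idx].length = max(v, 0.0)
    ch = sorted([nodes[a], nodes[b], nodes[c]], key=lambda nd: min(nd.leaf_labels()))
    return Node(children=ch)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class SupportedTree:
    """A tree plus per-bipartition bootstrap support in [0, 1]."""

    root: Node
    supports: dict[frozenset[str], float]
    reps_used: int = 0
    reps_dropped: int = 0

    def annotate(self) -> None:
        """Attach supports to internal nodes of the current rooting."""
        all_leaves = self.root.leaf_labels()
        anchor = min(all_leaves)
        for node in self.root.postorder():
            if node.is_leaf or node is self.root:
                continue
            side = node.leaf_labels()
            if anchor in side:
                side = all_leaves - side
            node.support = self.supports.get(side)

    def newick(self) -> str:
        self.annotate()
        return self.root.newick(with_support=True)


def bootstrap_support(
    aln: AlleleAlignment,
    reps: int = 500,
    model: str = "k2",
    seed: int | None = None,
) -> SupportedTree:
    """NJ tree with column-resampling bootstrap bipartition supports.

    Replicates with saturated distances are dropped and counted; more than
    10% dropped raises.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    mat = np.vstack([encode(s) for s in aln.seqs])
    L = mat.shape[1]

    def matrix_from(m: np.ndarray) -> np.ndarray:
        seqs = ["".join("ACGTN"[b] if b >= 0 else "N" for b in row) for row in m]
        return distance_matrix(seqs, model=model, on_saturation="raise")

    D0 = matrix_from(mat)
    tree = nj_tree(D0, aln.labels)
    orig_bips = bipartitions(tree)
    counts = {b: 0 for b in orig_bips}

    rng = np.random.default_rng(seed)
    used = dropped = 0
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        try:
            Db = matrix_from(mat[:, cols])
            tb = nj_tree(Db, aln.labels)
        except SaturationError:
            dropped += 1
            continue
        used += 1
        rep_bips = bipartitions(tb)
        for b in orig_bips:
            if b in rep_bips:
                counts[b] += 1
    if dropped > 0.1 * reps:
        raise SaturationError(f"{dropped}/{reps} bootstrap replicates saturated")
    supports = {b: (counts[b] / used if used else 0.0) for b in orig_bips}
    st = SupportedTree(root=tree, supports=supports, reps_used=used, reps_dropped=dropped)
    st.annotate()
    return st


# ---------------------------------------------------------------------------
# midpoint rooting (adjacency-based rerooting)


def _adjacency(root: Node):
    """Undirected edge map over a fresh copy of the tree's nodes."""
    adj: dict[int, list[tuple[Node, float]]] = {}
    objs: dict[int, Node] = {}

    def add(a: Node, b: Node, w: float) -> None:
        adj.setdefault(id(a), []).append((b, w))
        adj.setdefault(id(b), []).append((a, w))
        objs[id(a)] = a
        objs[id(b)] = b

    for node in root.postorder():
        for c in node.children:
            add(node, c, c.length)
    objs[id(root)] = root
    adj.setdefault(id(root), [])
    return adj, objs


def _build_rooted(adj, start: Node, came_from: int | None, length: float) -> Node:
    kids = [
        _build_rooted(adj, nb, id(start), w)
        for nb, w in adj[id(start)]
        if id(nb) != came_from
    ]
    if not kids:
        return Node(label=start.label, length=length)
    n = Node(label=start.label if start.label else None, length=length)
    n.children = sorted(kids, key=lambda k: min(k.leaf_labels()))
    return n


def midpoint_root(tree: Node) -> Node:
    """Reroot at the midpoint of the longest leaf-to-leaf path.

    Bipartition supports are unaffected (they attach to edges); leaf-to-leaf
    path lengths are preserved.
    """
    tree = tree.copy()
    adj, _ = _adjacency(tree)
    leaves = tree.leaves()
    if len(leaves) < 2:
        return tree

    def dists_from(src: Node) -> dict[int, tuple[float, Node | None]]:
        """BFS distances and predecessor links from src."""
        seen = {id(src): (0.0, None)}
        stack = [src]
        while stack:
            cur = stack.pop()
            d0, _ = seen[id(cur)]
            for nb, w in adj[id(cur)]:
                if id(nb) not in seen:
                    seen[id(nb)] = (d0 + w, cur)
                    stack.append(nb)
        return seen

    best = None  # (dist, (labA, labB), leafA, leafB, dmap)
    for lf in leaves:
        dmap = dists_from(lf)
        for other in leaves:
            if other is lf:
                continue
            d = dmap[id(other)][0]
            key = (d, tuple(sorted((lf.label, other.label))))
            if best is None or key[0] > best[0] + 1e-12 or (
                abs(key[0] - best[0]) <= 1e-12 and key[1] < best[1]
            ):
                best = (key[0], key[1], lf, other, dmap)
    dmax, _, la, lb, dmap = best
    half = dmax / 2.0
    # walk back from lb toward la along predecessor links until the
    # midpoint edge is crossed
    node = lb
    while True:
        d_node = dmap[id(node)][0]
        pred = dmap[id(node)][1]
        if pred is None:
            break
        d_pred = dmap[id(pred)][0]
        if d_pred <= half <= d_node + 1e-12:
            break
        node = pred
    pred = dmap[id(node)][1]
    if pred is None:  # degenerate: root exactly at la
        return _finish_root(_build_rooted(adj, la, None, 0.0))
    edge_len = d_node - dmap[id(pred)][0]
    toward_pred = d_node - half  # distance from node up to midpoint
    toward_pred = min(max(toward_pred, 0.0), edge_len)
    # splice a root point into edge (node, pred)
    root = Node()
    adj[id(node)] = [(nb, w) for nb, w in adj[id(node)] if id(nb) != id(pred)]
    adj[id(pred)] = [(nb, w) for nb, w in adj[id(pred)] if id(nb) != id(node)]
    adj[id(root)] = [(node, toward_pred), (pred, edge_len - toward_pred)]
    adj[id(node)].append((root, toward_pred))
    adj[id(pred)].append((root, edge_len - toward_pred))
    return _finish_root(_build_rooted(adj, root, None, 0.0))


def _finish_root(root: Node) -> Node:
    """Suppress unary internal nodes left over from rerooting."""
    changed = True
    while changed:
        changed = False
        for node in list(root.postorder()):
            for i, c in enumerate(node.children):
                if not c.is_leaf and len(c.children) == 1:
                    g = c.children[0]
                    g.length += c.length
                    node.children[i] = g
                    changed = True
        if not root.is_leaf and len(root.children) == 1:
            root = root.children[0]
            root.length = 0.0
            changed = True
    for node in root.postorder():
        if node.children:
            node.children.sort(key=lambda k: min(k.leaf_labels()))
    return root


__all__ = [
    "Node",
    "nj_tree",
    "bootstrap_support",
    "midpoint_root",
    "bipartitions",
    "SupportedTree",
]
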