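"""Neighbor-joining trees, Newick IO and bipartition utilities.

Implements classic Saitou–Nei neighbor joining on a distance matrix, with
two determinism rules pinned down so results are reproducible across runs:
ties in the Q-criterion are broken toward the smallest (i, j) pair in the
current active-node order (original label order, merged nodes taking the
position of their first-listed child), and negative branch lengths are
clamped to zero with the deficit transferred to the sibling branch.

Trees are dendropy objects, so Newick serialization, leaf iteration and
round-tripping come for free; bootstrap supports are stored as internal-node
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be nonnegative")

    def __len__(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))


def _clamped_pair(d_ij: float, li: float) -> tuple[float, float]:
    """Split edge d_ij into (li, lj), clamping negatives to 0 and moving the
    deficit onto the sibling branch."""
    lj = d_ij - li
    if li < 0:
        return 0.0, max(d_ij, 0.0)
    if lj < 0:
        return max(d_ij, 0.0), 0.0
    return li, lj


def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Unrooted neighbor-joining tree from a distance matrix (>= 3 labels)."""
    n0 = len(dist)
    if n0 < 3:
        raise ValueError(f"neighbor joining requires >= 3 labels, got {n0}")

    taxa = dendropy.TaxonNamespace(dist.labels)
    nodes: list[dendropy.Node] = []
    for label in dist.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    D = dist.values.astype(float).copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest (i, j) pair among Q minima, i < j in active order
        qmin = Q.min()
        ii, jj = np.nonzero(np.isclose(Q, qmin, rtol=0.0, atol=1e-12))
        pairs = sorted((int(a), int(b)) for a, b in zip(ii, jj) if a < b)
        i, j = pairs[0]

        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (n - 2))
        li, lj = _clamped_pair(d_ij, li)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        d_new[i] = 0.0
        # merged node takes position i; j is removed
        D[i, :] = d_new
        D[:, i] = d_new
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        nodes[i] = parent
        del nodes[j]

    # final three-node join: exact three-point formulas around a central node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        max(0.0, 0.5 * (d01 + d02 - d12)),
        max(0.0, 0.5 * (d01 + d12 - d02)),
        max(0.0, 0.5 * (d02 + d12 - d01)),
    ]
    center = dendropy.Node()
    for node, length in zip(nodes, lengths):
        center.add_child(node)
        node.edge.length = length

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Internal-branch bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves into two sets; the canonical key is
    the smaller set (ties broken lexicographically), so keys are comparable
    across trees on the same leaves. Leaf edges (trivial splits) excluded.
    """
    all_leaves = frozenset(leaf_labels(tree))
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - below
        if not below or not other:
            continue
        key = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[key] = node
    return out


def collapse_zero_branches(tree: dendropy.Tree, tol: float = 0.0) -> dendropy.Tree:
    """Collapse internal edges with length <= tol into polytomies (in place).

    Unresolved splits (zero-length internal branches, e.g. NJ on identical
    sequences) then disappear instead of presenting an arbitrary resolution.
    """
    for edge in list(tree.preorder_edge_iter()):
        head = edge.head_node
        if head is None or head.is_leaf() or edge.tail_node is None:
            continue
        if edge.length is not None and edge.length <= tol:
            edge.collapse()
    return tree


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (small trees; simple traversal)."""
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    labels = [leaf.taxon.label for leaf in leaves]
    # undirected adjacency
    adj: dict[dendropy.Node, list[tuple[dendropy.Node, float]]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, w))
            adj.setdefault(child, []).append((node, w))
    n = len(leaves)
    values = np.zeros((n, n))
    index = {leaf: k for k, leaf in enumerate(leaves)}
    for k, start in enumerate(leaves):
        seen = {start: 0.0}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt, w in adj.get(cur, ()):
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        for leaf, dist in seen.items():
            if leaf in index:
                values[k, index[leaf]] = dist
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values)


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree))


def read_newick(source: str | bytes, path: bool = False) -> dendropy.Tree:
    if path:
        tree = dendropy.Tree.get(path=str(source), schema="newick")
    else:
        tree = dendropy.Tree.get(data=source, schema="newick")
    tree.is_rooted = False
    return tree
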