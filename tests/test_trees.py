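"""Neighbor joining, Newick round-trips, bipartition utilities."""

import itertools

import dendropy
import numpy as np
import pytest

from clonetrace.trees import (
    DistanceMatrix,
    bipartitions,
    collapse_zero_branches,
    nj_tree,
    patristic_distances,
    read_newick,
    to_newick,
)


def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree with positive branch lengths, built by
    sequential leaf attachment; returns a dendropy tree."""
    labels = [f"t{i}" for i in range(n_taxa)]
    taxa = dendropy.TaxonNamespace(labels)
    a = dendropy.Node(taxon=taxa.get_taxon(labels[0]))
    b = dendropy.Node(taxon=taxa.get_taxon(labels[1]))
    c = dendropy.Node(taxon=taxa.get_taxon(labels[2]))
    center = dendropy.Node()
    for node in (a, b, c):
        center.add_child(node)
        node.edge.length = float(rng.uniform(0.5, 2.0))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    for label in labels[3:]:
        edges = [
            e for e in tree.preorder_edge_iter() if e.tail_node is not None
        ]
        edge = edges[rng.integers(0, len(edges))]
        head, tail = edge.head_node, edge.tail_node
        split = dendropy.Node()
        tail.remove_child(head)
        tail.add_child(split)
        old_len = edge.length if edge.length is not None else 1.0
        frac = float(rng.uniform(0.2, 0.8))
        split.edge.length = old_len * frac
        split.add_child(head)
        head.edge.length = old_len * (1 - frac)
        leaf = dendropy.Node(taxon=taxa.get_taxon(label))
        split.add_child(leaf)
        leaf.edge.length = float(rng.uniform(0.5, 2.0))
    return tree


def five_taxon_topologies(labels):
    """All 15 unrooted binary topologies on 5 taxa, as bipartition pairs:
    two disjoint cherries {a,b} / {c,d} with the fifth taxon in the middle."""
    out = []
    for cherry1 in itertools.combinations(labels, 2):
        rest = [x for x in labels if x not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            key = frozenset([frozenset(cherry1), frozenset(cherry2)])
            if key not in [k for k, _ in out]:
                out.append((key, (tuple(cherry1), tuple(cherry2))))
    return out


def five_taxon_lsq_residual(d, labels, cherry1, cherry2):
    """Least-squares residual fitting the caterpillar topology with cherries
    cherry1/cherry2 to distance matrix d (7 branch unknowns, 10 path rows)."""
    mid = [x for x in labels if x not in cherry1 + cherry2][0]
    order = list(cherry1) + list(cherry2) + [mid]
    # branch order: 5 pendants (in `order`), internal v1-m, v2-m
    rows, y = [], []
    idx = {lab: i for i, lab in enumerate(order)}
    li = {lab: labels.index(lab) for lab in labels}

    def path(u, v):
        row = [0.0] * 7
        row[idx[u]] = 1
        row[idx[v]] = 1
        u_in1, v_in1 = u in cherry1, v in cherry1
        u_in2, v_in2 = u in cherry2, v in cherry2
        if u_in1 != v_in1 and not (u == mid or v == mid):
            row[5] = 1
        if u_in2 != v_in2 and not (u == mid or v == mid):
            row[6] = 1
        if (u == mid and v_in1) or (v == mid and u_in1):
            row[5] = 1
        if (u == mid and v_in2) or (v == mid and u_in2):
            row[6] = 1
        return row

    for u, v in itertools.combinations(labels, 2):
        rows.append(path(u, v))
        y.append(d[li[u], li[v]])
    A = np.asarray(rows)
    y = np.asarray(y)
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ sol - y) ** 2))


class TestNJTree:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = nj_tree(d)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]])))

    def test_five_taxon_additive_recovery_against_enumeration(self):
        """NJ must pick the unique topology with zero least-squares residual
        among all 15 five-taxon topologies."""
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(5)]
        for _ in range(10):
            gen = random_additive_tree(5, rng)
            d = patristic_distances(gen)
            d = DistanceMatrix(labels, d.to_dataframe().loc[labels, labels].to_numpy())
            residuals = {}
            for key, (c1, c2) in five_taxon_topologies(labels):
                residuals[key] = five_taxon_lsq_residual(d.values, labels, c1, c2)
            best = min(residuals, key=residuals.get)
            assert residuals[best] < 1e-18
            nj = nj_tree(d)
            nj_key = frozenset(bipartitions(nj).keys())
            assert nj_key == best

    @pytest.mark.parametrize("n_taxa", [6, 8])
    def test_additive_recovery_and_branch_lengths(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(5):
            gen = random_additive_tree(n_taxa, rng)
            d = patristic_distances(gen)
            nj = nj_tree(d)
            assert set(bipartitions(nj)) == set(bipartitions(gen))
            # additivity: the NJ tree reproduces the input distances exactly
            back = patristic_distances(nj)
            order = [back.labels.index(lab) for lab in d.labels]
            np.testing.assert_allclose(
                back.values[np.ix_(order, order)], d.values, atol=1e-9
            )

    def test_matches_independent_nj_implementation(self):
        """Cross-check topologies against scikit-bio's neighbor joining on
        random (non-additive) matrices."""
        import skbio

        rng = np.random.default_rng(3)
        for n in (5, 6, 7):
            labels = [f"s{i}" for i in range(n)]
            m = rng.uniform(0.2, 1.0, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            ours = nj_tree(DistanceMatrix(labels, m))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
            their_bips = set()
            all_labels = frozenset(labels)
            for node in theirs.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 0 < len(below) < n:
                    their_bips.add(
                        min(below, all_labels - below, key=lambda s: (len(s), tuple(sorted(s))))
                    )
            ours_bips = set(bipartitions(ours))
            assert ours_bips == their_bips

    def test_deterministic_under_ties(self):
        d = DistanceMatrix(list("abcd"), np.ones((4, 4)) - np.eye(4))
        t1, t2 = nj_tree(d), nj_tree(d)
        assert to_newick(t1) == to_newick(t2)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = 6
            m = rng.uniform(0.1, 1.0, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            tree = nj_tree(DistanceMatrix([f"x{i}" for i in range(n)], m))
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0


class TestNewick:
    def test_roundtrip_preserves_topology_lengths_and_supports(self):
        rng = np.random.default_rng(4)
        for n in (5, 12, 20):
            tree = random_additive_tree(n, rng)
            for k, node in enumerate(tree.preorder_internal_node_iter()):
                if node is not tree.seed_node:
                    node.label = str(50 + k)
            text = to_newick(tree)
            back = read_newick(text)
            assert set(bipartitions(back)) == set(bipartitions(tree))
            orig = {
                frozenset(key): (node.label, round(node.edge.length or 0, 9))
                for key, node in bipartitions(tree).items()
            }
            rt = {
                frozenset(key): (node.label, round(node.edge.length or 0, 9))
                for key, node in bipartitions(back).items()
            }
            assert orig == rt

    def test_collapse_zero_branches_makes_star(self):
        d = DistanceMatrix(list("abcde"), np.zeros((5, 5)))
        tree = collapse_zero_branches(nj_tree(d))
        assert len(bipartitions(tree)) == 0
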