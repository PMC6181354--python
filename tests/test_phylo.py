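import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from domarch.phylo import (
    DistanceMatrix,
    bootstrap_support,
    kimura_distance_matrix,
    neighbor_joining,
    nontrivial_bipartitions,
    p_distance_matrix,
    robinson_foulds,
    transfer_labels,
)
from domarch.seq_io import SeqRecord, ValidationError


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


# --- brute-force oracle: enumerate unrooted topologies, least-squares fit ---

def _enumerate_topologies(labels):
    """All unrooted binary topologies as edge lists (recursive leaf insertion)."""
    if len(labels) == 3:
        yield [("*root", l) for l in labels]
        return
    last = labels[-1]
    for edges in _enumerate_topologies(labels[:-1]):
        for i, (u, v) in enumerate(edges):
            mid = f"#in{len(edges)}_{i}"
            new = edges[:i] + edges[i + 1:]
            new += [(u, mid), (mid, v), (mid, last)]
            yield new


def _fit_branch_lengths(edges, labels, dm):
    """Least-squares branch lengths for a topology; returns residual."""
    nodes = {n for e in edges for n in e}
    adj = {n: [] for n in nodes}
    for k, (u, v) in enumerate(edges):
        adj[u].append((v, k))
        adj[v].append((u, k))

    def path(a, b):
        stack = [(a, None, [])]
        seen = set()
        while stack:
            node, _, used = stack.pop()
            if node == b:
                return used
            seen.add(node)
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    stack.append((nxt, node, used + [eidx]))
        raise AssertionError("disconnected topology")

    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    idx = {l: i for i, l in enumerate(labels)}
    for r, (a, b) in enumerate(pairs):
        for eidx in path(a, b):
            A[r, eidx] = 1.0
        y[r] = dm.matrix[idx[a], idx[b]]
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return np.linalg.norm(A @ sol - y)


def oracle_nj_topology(dm):
    """The unique additive topology found by exhaustive enumeration."""
    best = None
    for edges in _enumerate_topologies(dm.ids):
        resid = _fit_branch_lengths(edges, dm.ids, dm)
        if best is None or resid < best[0]:
            best = (resid, edges)
    return best


def _random_additive_matrix(rng, labels):
    """Distances from a random unrooted binary tree with positive branches."""
    topologies = list(_enumerate_topologies(labels))
    edges = topologies[rng.integers(len(topologies))]
    lengths = {e: rng.uniform(0.2, 1.0) for e in edges}
    nodes = {n for e in edges for n in e}
    adj = {n: [] for n in nodes}
    for (u, v) in edges:
        adj[u].append((v, lengths[(u, v)]))
        adj[v].append((u, lengths[(u, v)]))

    def dist(a, b):
        stack = [(a, 0.0, {a})]
        while stack:
            node, d, seen = stack.pop()
            if node == b:
                return d
            for nxt, w in adj[node]:
                if nxt not in seen:
                    stack.append((nxt, d + w, seen | {nxt}))

    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = dist(labels[i], labels[j])
    return DistanceMatrix(ids=list(labels), matrix=m)


class TestDistances:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix(["AAAA", "AAAA"])
        assert dm.matrix[0, 1] == 0.0

    def test_quarter_distance(self):
        assert p_distance_matrix(["AAAA", "AAAT"]).matrix[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        assert p_distance_matrix(["A-AA", "AGAT"]).matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_names_pair(self):
        recs = [SeqRecord(id="x", seq="A--"), SeqRecord(id="y", seq="-GG")]
        with pytest.raises(ValidationError, match="x.*y"):
            p_distance_matrix(recs)

    def test_kimura_exceeds_p(self):
        dm_p = p_distance_matrix(["AAAAAAAA", "AAAATTTT"])
        dm_k = kimura_distance_matrix(["AAAAAAAA", "AAAATTTT"])
        assert dm_k.matrix[0, 1] > dm_p.matrix[0, 1]


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(ids=["a", "b", "c"],
                            matrix=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(ids=["a", "b"], matrix=np.array([[0, 0.5], [0.5, 0]]))
        tree = neighbor_joining(dm)
        assert _patristic(tree)("a", "b") == pytest.approx(0.5)

    def test_four_taxon_additive_recovery(self):
        # distances from tree ((a:2,b:1):3,c:2,d:3) are recovered exactly
        m = np.array([[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 5], [8, 7, 5, 0]], float)
        dm = DistanceMatrix(ids=list("abcd"), matrix=m)
        tree = neighbor_joining(dm)
        pat = _patristic(tree)
        for i, a in enumerate("abcd"):
            for b in "abcd"[i + 1:]:
                assert pat(a, b) == pytest.approx(dm.matrix["abcd".index(a),
                                                            "abcd".index(b)])

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_matrices_match_enumeration_oracle(self, rng, n_taxa):
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(50):
            dm = _random_additive_matrix(rng, labels)
            tree = neighbor_joining(dm)
            _, oracle_edges = oracle_nj_topology(dm)
            # compare bipartitions of NJ tree vs oracle topology
            oracle_tree = _edges_to_tree(oracle_edges, labels)
            assert robinson_foulds(tree, oracle_tree) == 0
            # and branch lengths are additive: patristic == input distances
            pat = _patristic(tree)
            for i, j in itertools.combinations(range(n_taxa), 2):
                assert pat(labels[i], labels[j]) == pytest.approx(
                    dm.matrix[i, j], abs=1e-8)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(ids=["a", "b"], matrix=np.array([[0, 1], [2, 0]], float))


def _edges_to_tree(edges, labels):
    nodes = {n for e in edges for n in e}
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    root = next(n for n in nodes if n not in labels)

    def newick(node, parent):
        children = [c for c in adj[node] if c != parent]
        if not children:
            return node
        return "(" + ",".join(newick(c, node) for c in children) + ")"

    return _tree(newick(root, None) + ";")


class TestRobinsonFoulds:
    def test_identical_zero(self):
        t = _tree("((a,b),(c,d));")
        assert robinson_foulds(t, _tree("((a,b),(c,d));")) == 0

    def test_conflicting_quartets(self):
        assert robinson_foulds(_tree("((a,b),(c,d));"), _tree("((a,c),(b,d));")) == 2

    def test_rotation_invariance(self):
        assert robinson_foulds(_tree("((a,b),(c,d));"), _tree("((d,c),(b,a));")) == 0

    def test_leaf_set_mismatch(self):
        with pytest.raises(ValidationError, match="e"):
            robinson_foulds(_tree("((a,b),(c,d));"), _tree("((a,b),(c,e));"))

    def test_metric_axioms_and_dendropy_agreement(self, rng):
        labels = [f"t{i}" for i in range(6)]
        trees = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            dm = _random_additive_matrix(r, labels)
            trees.append(neighbor_joining(dm))
        tns = dendropy.TaxonNamespace()
        for t1, t2 in itertools.combinations(trees, 2):
            d12 = robinson_foulds(t1, t2)
            d21 = robinson_foulds(t2, t1)
            assert d12 == d21 >= 0
            # cross-check against dendropy's symmetric difference
            a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                                  schema="newick", taxon_namespace=tns)
            b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                                  schema="newick", taxon_namespace=tns)
            a.encode_bipartitions()
            b.encode_bipartitions()
            assert d12 == treecompare.symmetric_difference(a, b)
        for t in trees:
            assert robinson_foulds(t, t) == 0


class TestBootstrap:
    def test_two_clades_full_support(self, two_clade_alignment):
        tree = bootstrap_support(two_clade_alignment, n_replicates=200, seed=5)
        supports = [int(n.label) for n in tree.preorder_node_iter()
                    if n.label and not n.is_leaf()]
        assert supports and all(s == 200 for s in supports)

    def test_same_seed_identical(self, two_clade_alignment):
        t1 = bootstrap_support(two_clade_alignment, n_replicates=50, seed=9)
        t2 = bootstrap_support(two_clade_alignment, n_replicates=50, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_zero_replicates_rejected(self, two_clade_alignment):
        with pytest.raises(ValidationError):
            bootstrap_support(two_clade_alignment, n_replicates=0, seed=1)

    def test_row_order_invariance(self, two_clade_alignment):
        t1 = bootstrap_support(two_clade_alignment, n_replicates=50, seed=3)
        t2 = bootstrap_support(list(reversed(two_clade_alignment)),
                               n_replicates=50, seed=3)
        assert nontrivial_bipartitions(t1) == nontrivial_bipartitions(t2)


class TestTransferLabels:
    def test_leaf_inside_pure_clade(self):
        tree = _tree("(((a1:1,a2:1):1,q:1):4,(b1:1,b2:1):1);")
        pred = transfer_labels(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert pred == {"q": "A"}

    def test_equidistant_tie_unassigned(self):
        tree = _tree("(a:1,b:1,q:1);")
        pred = transfer_labels(tree, {"a": "A", "b": "B"})
        assert pred == {"q": "unassigned"}

    def test_all_labeled_empty_output(self):
        tree = _tree("(a:1,b:1);")
        assert transfer_labels(tree, {"a": "A", "b": "B"}) == {}

    def test_no_labels_rejected(self):
        with pytest.raises(ValidationError):
            transfer_labels(_tree("(a:1,b:1);"), {})
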