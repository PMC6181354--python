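"""Neighbor-joining trees, bootstrap supports, topological congruence and
label transfer.

Distances default to the p-distance with pairwise deletion of gapped sites.
NJ is the standard Saitou–Nei agglomeration with a deterministic tie-break
(first minimal Q cell in active-node order) and Phylip-compatible clamping
of negative branch-length estimates to zero; trees are dendropy objects so
Newick round-trips and patristic distances come for free.  Congruence is
the Robinson–Foulds symmetric difference over non-trivial bipartitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .seq_io import SeqRecord, ValidationError

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(m < 0):
            raise ValidationError("negative distances")
        self.matrix = m


def _rows(alignment) -> tuple[list[str], list[str]]:
    ids = [r.id if isinstance(r, SeqRecord) else f"t{i}"
           for i, r in enumerate(alignment)]
    rows = [r.seq if isinstance(r, SeqRecord) else r for r in alignment]
    width = {len(r) for r in rows}
    if len(width) > 1:
        raise ValidationError("ragged alignment")
    return ids, rows


def p_distance_matrix(alignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gap-containing sites."""
    ids, rows = _rows(alignment)
    if len(rows) < 2:
        raise ValidationError("need at least two rows for a distance matrix")
    arr = np.array([list(r) for r in rows])
    nongap = arr != GAP
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValidationError(
                    f"no comparable columns between {ids[i]} and {ids[j]}")
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / comparable
    return DistanceMatrix(ids=ids, matrix=d)


def kimura_distance_matrix(alignment) -> DistanceMatrix:
    """Kimura-corrected protein distance: -ln(1 - p - p^2/5)."""
    dm = p_distance_matrix(alignment)
    p = dm.matrix
    arg = 1.0 - p - p * p / 5.0
    if np.any(arg <= 0):
        raise ValidationError("p-distance too large for Kimura correction")
    return DistanceMatrix(ids=dm.ids, matrix=np.where(p > 0, -np.log(arg), 0.0))


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree.

    Ties in the Q matrix resolve to the first minimal cell in active-node
    order; negative branch-length estimates are clamped to zero (the raw
    value is logged).
    """
    n = len(dm.ids)
    if n < 2:
        raise ValidationError("neighbor joining needs at least two taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def clamp(v: float) -> float:
        if v < 0:
            logger.debug("negative NJ branch length %.6g clamped to 0", v)
            return 0.0
        return v

    nodes = []
    for tid in dm.ids:
        node = dendropy.Node(taxon=taxa.get_taxon(tid))
        nodes.append(node)

    if n == 2:
        # single edge of length d, represented as two child edges summing to d
        root = dendropy.Node()
        d = float(dm.matrix[0, 1])
        for node, length in zip(nodes, (d, 0.0)):
            node.edge.length = length
            root.add_child(node)
        tree.seed_node = root
        return tree

    active = list(range(n))
    D = dm.matrix.astype(float).copy()
    node_of = {i: nodes[i] for i in range(n)}
    next_idx = n
    Dmap = {(i, j): D[i, j] for i in range(n) for j in range(n)}

    def dist(i, j):
        return Dmap[(i, j)] if i <= j else Dmap[(j, i)]

    def set_dist(i, j, v):
        Dmap[(min(i, j), max(i, j))] = v

    while len(active) > 3:
        m = len(active)
        totals = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dist(i, j) - totals[i] - totals[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        new = dendropy.Node()
        node_of[i].edge.length = clamp(li)
        node_of[j].edge.length = clamp(lj)
        new.add_child(node_of[i])
        new.add_child(node_of[j])
        u = next_idx
        next_idx += 1
        node_of[u] = new
        for k in active:
            if k in (i, j):
                continue
            set_dist(u, k, 0.5 * (dist(i, k) + dist(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    root = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        li = 0.5 * (dist(i, j) + dist(i, k) - dist(j, k))
        lj = 0.5 * (dist(i, j) + dist(j, k) - dist(i, k))
        lk = 0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
        for idx, length in zip((i, j, k), (li, lj, lk)):
            node_of[idx].edge.length = clamp(length)
            root.add_child(node_of[idx])
    else:  # exactly 2 left (n == 3 collapses via the closed form above)
        i, j = active
        d = dist(i, j)
        node_of[i].edge.length = clamp(d)
        node_of[j].edge.length = 0.0
        root.add_child(node_of[i])
        root.add_child(node_of[j])
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions, Robinson–Foulds, bootstrap

def leaf_labels(tree: dendropy.Tree) -> set:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def nontrivial_bipartitions(tree: dendropy.Tree) -> set:
    """Canonical non-trivial bipartitions as frozensets of leaf labels.

    Each internal edge splits the leaves; the side *not* containing the
    lexicographically smallest label is the canonical representation, which
    makes the set independent of rooting and child rotation.
    """
    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    bips = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(all_leaves - side)
        if 2 <= len(side) <= len(all_leaves) - 2:
            bips.add(side)
    return bips


def robinson_foulds(tree1: dendropy.Tree, tree2: dendropy.Tree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    l1, l2 = leaf_labels(tree1), leaf_labels(tree2)
    if l1 != l2:
        raise ValidationError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)} "
            f"only-in-second={sorted(l2 - l1)}")
    return len(nontrivial_bipartitions(tree1) ^ nontrivial_bipartitions(tree2))


def bootstrap_support(alignment, n_replicates: int = 1000, seed: int | None = None,
                      distance: str = "p") -> dendropy.Tree:
    """NJ tree of the full alignment with bootstrap counts on internal edges.

    Columns are resampled with replacement per replicate; an internal edge's
    support is the number of replicate trees containing the same bipartition
    (a count out of ``n_replicates``, Phylip convention).
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if seed is None:
        raise ValidationError("bootstrap requires an explicit seed")
    dist_fn = {"p": p_distance_matrix, "kimura": kimura_distance_matrix}[distance]
    ids, rows = _rows(alignment)
    width = len(rows[0])
    records = [SeqRecord(id=i, seq=s) for i, s in zip(ids, rows)]

    tree = neighbor_joining(dist_fn(records))
    counts: dict[frozenset, int] = {b: 0 for b in nontrivial_bipartitions(tree)}

    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in rows])
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        sample = ["".join(row) for row in arr[:, cols]]
        rep_records = [SeqRecord(id=i, seq=s) for i, s in zip(ids, sample)]
        rep_tree = neighbor_joining(dist_fn(rep_records))
        for b in nontrivial_bipartitions(rep_tree):
            if b in counts:
                counts[b] += 1

    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(all_leaves - side)
        if side in counts:
            node.label = str(counts[side])
    return tree


def transfer_labels(tree: dendropy.Tree, labels: dict) -> dict:
    """Assign each unlabeled leaf the label of its nearest labeled leaf.

    Nearness is patristic distance; exact ties between different labels give
    ``"unassigned"``.  Returns predictions for unlabeled leaves only.
    """
    if not labels:
        raise ValidationError("no labeled leaves supplied")
    leaves = leaf_labels(tree)
    unknown_ids = sorted(set(labels) - leaves)
    if unknown_ids:
        raise ValidationError(f"labels given for absent leaves: {unknown_ids}")
    pdm = tree.phylogenetic_distance_matrix()
    taxon = {t.label: t for t in tree.taxon_namespace if t.label in leaves}
    predictions = {}
    for leaf in sorted(leaves - set(labels)):
        best_d, best_labels = None, set()
        for lid, lab in labels.items():
            d = pdm.patristic_distance(taxon[leaf], taxon[lid])
            if best_d is None or d < best_d - 1e-12:
                best_d, best_labels = d, {lab}
            elif abs(d - best_d) <= 1e-12:
                best_labels.add(lab)
        predictions[leaf] = best_labels.pop() if len(best_labels) == 1 else "unassigned"
    return predictions
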