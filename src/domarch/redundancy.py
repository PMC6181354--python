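"""Redundancy removal within an architecture.

Reimplements the intent of blastclust-style clustering — single-linkage
components over pairs exceeding an identity threshold at sufficient mutual
coverage — plus the length-deviation filter applied to pre-cut domains.
Pairwise identity comes from Biopython global alignment (BLOSUM62, affine
gaps), appropriate because the inputs are domains of similar length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import SeqRecord, ValidationError


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 80.0   # percent
    coverage_threshold: float = 90.0   # percent of the shorter sequence
    linkage: str = "single"

    def __post_init__(self):
        for t in (self.identity_threshold, self.coverage_threshold):
            if not 0 < t <= 100:
                raise ValidationError(f"threshold {t} outside (0, 100]")


@dataclass(frozen=True)
class FilterParams:
    length_tolerance: int = 15  # residues either side of the mean

    def __post_init__(self):
        if self.length_tolerance < 0:
            raise ValidationError("length tolerance must be >= 0")


def _make_aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0,
                  gap_extend: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_identity(a: str | SeqRecord, b: str | SeqRecord,
                      aligner: Align.PairwiseAligner | None = None):
    """Global-alignment identity and coverage, both in percent.

    identity = identical pairs / mutually non-gap columns * 100;
    coverage = mutually non-gap columns / length of the shorter sequence * 100.
    """
    sa = a.seq if isinstance(a, SeqRecord) else a
    sb = b.seq if isinstance(b, SeqRecord) else b
    if not sa or not sb:
        raise ValidationError("cannot align an empty sequence")
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(sa, sb)[0]
    row_a, row_b = alignment[0], alignment[1]
    both = ident = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                ident += 1
    if both == 0:
        return 0.0, 0.0
    identity = 100.0 * ident / both
    coverage = 100.0 * both / min(len(sa), len(sb))
    return identity, coverage


def cluster_sequences(records: list[SeqRecord], params: ClusterParams | None = None):
    """Single-linkage clusters of near-identical sequences.

    Edges connect pairs with identity >= threshold AND coverage >= threshold.
    Returns ``(clusters, representatives)``: clusters are lists of ids sorted
    by descending size (ties by smallest member id); each representative is
    the longest member, ties broken by lexicographically smallest id.
    """
    if not records:
        raise ValidationError("cluster_sequences needs at least one record")
    params = params or ClusterParams()
    aligner = _make_aligner()

    parent = {r.id: r.id for r in records}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i, a in enumerate(records):
        for b in records[i + 1:]:
            ident, cov = pairwise_identity(a, b, aligner)
            if ident >= params.identity_threshold and cov >= params.coverage_threshold:
                union(a.id, b.id)

    by_root: dict[str, list[str]] = {}
    for r in records:
        by_root.setdefault(find(r.id), []).append(r.id)
    clusters = sorted(
        (sorted(members) for members in by_root.values()),
        key=lambda c: (-len(c), c[0]),
    )
    length = {r.id: len(r.seq) for r in records}
    representatives = [min(c, key=lambda i: (-length[i], i)) for c in clusters]
    return clusters, representatives


def length_filter(records: list[SeqRecord], params: FilterParams | None = None):
    """Keep records within ``length_tolerance`` residues of the mean length.

    The mean is the arithmetic mean of *all* input lengths, computed once.
    Returns ``(kept, removed_ids)``.
    """
    if not records:
        raise ValidationError("length_filter needs at least one record")
    params = params or FilterParams()
    mean = sum(len(r.seq) for r in records) / len(records)
    kept, removed = [], []
    for r in records:
        if abs(len(r.seq) - mean) <= params.length_tolerance:
            kept.append(r)
        else:
            removed.append(r.id)
    return kept, removed
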