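"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators, all pure functions of (config, seed):

* protein families partitioned into domain architectures with planted
  column classes (universally conserved / focal-architecture-specific /
  variable) at controllable conservation levels and indel rates;
* pairs of alignments evolved independently down one shared tree, for
  congruence tests;
* ideal poly-alanine α-helices written as PDB text, for solvent-accessibility
  fixtures;
* mutation tables with known per-region counts.

Planted labels are guaranteed, not merely probable: "variable" columns and
the non-focal part of focal-specific columns are rejection-sampled until no
property class reaches the consensus threshold in the emitting block, since
a uniform background column of modest depth frequently qualifies for the
large hydrophobic class by chance.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .fingerprint import ConsensusParams, UNCONSERVED, column_consensus
from .mutmap import DomainRegion
from .seq_io import MutationRecord, SeqRecord, ValidationError
from .surface import ResidueSet

AA = "ACDEFGHIKLMNPQRSTVWY"

UNIVERSAL = "universal"
FOCAL_SPECIFIC = "focal_specific"
VARIABLE = "variable"


@dataclass(frozen=True)
class FamilyConfig:
    n_architectures: int = 3
    sequences_per_architecture: int = 10
    alignment_length: int = 120
    n_universal: int = 20
    n_focal_specific: int = 20
    conservation: float = 1.0      # per planted class, probability of the planted state
    indel_rate: float = 0.0        # per-cell gap probability
    plant_class_focal: bool = False  # plant focal columns as a property class (I/L/V)
    background: tuple = tuple(1.0 / 20 for _ in AA)  # uniform over the 20 residues
    seed: int = 0
    consensus: ConsensusParams = field(default_factory=ConsensusParams)

    def __post_init__(self):
        if self.n_universal + self.n_focal_specific > self.alignment_length:
            raise ValidationError("planted column counts exceed alignment length")
        if not 0 <= self.conservation <= 1 or not 0 <= self.indel_rate < 1:
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.n_architectures < 2 or self.sequences_per_architecture < 1:
            raise ValidationError("need >= 2 architectures with >= 1 sequence each")


@dataclass
class SyntheticTruth:
    column_labels: list            # per reference column
    architecture_of: dict          # seq id -> architecture name
    clade_of: dict = field(default_factory=dict)


@dataclass
class FamilyData:
    alignments: dict               # architecture name -> list[SeqRecord]
    hits: list                     # DomainHit-compatible tuples via seq_io.DomainHit
    truth: SyntheticTruth
    config: FamilyConfig

    @property
    def focal(self) -> str:
        return sorted(self.alignments)[0]


def _draw_background(rng, n, background) -> list:
    idx = rng.choice(len(AA), size=n, p=np.asarray(background))
    return [AA[i] for i in idx]


def _unconserved_block(rng, n, background, params) -> list:
    """Background residues for one architecture block with no qualifying class."""
    for _ in range(10_000):
        block = _draw_background(rng, n, background)
        if column_consensus(block, params).symbol == UNCONSERVED:
            return block
    raise ValidationError(
        "could not sample an unconserved column; block too small for the threshold")


def generate_families(config: FamilyConfig):
    """Generate per-architecture alignments, a domain-hit table and truth labels."""
    from .seq_io import DomainHit  # local import to keep module load light

    rng = np.random.default_rng(config.seed)
    n_arch = config.n_architectures
    depth = config.sequences_per_architecture
    width = config.alignment_length
    arch_names = [f"ARCH{k + 1}" for k in range(n_arch)]
    focal = arch_names[0]

    labels = ([UNIVERSAL] * config.n_universal
              + [FOCAL_SPECIFIC] * config.n_focal_specific
              + [VARIABLE] * (width - config.n_universal - config.n_focal_specific))
    labels = [labels[i] for i in rng.permutation(width)]

    columns = {a: [] for a in arch_names}
    focal_class = "ILV"
    for label in labels:
        if label == UNIVERSAL:
            planted = AA[rng.integers(len(AA))]
            for a in arch_names:
                col = [planted if rng.random() < config.conservation
                       else AA[rng.integers(len(AA))] for _ in range(depth)]
                columns[a].append(col)
        elif label == FOCAL_SPECIFIC:
            if config.plant_class_focal:
                draw = lambda: focal_class[rng.integers(len(focal_class))]
            else:
                planted = AA[rng.integers(len(AA))]
                draw = lambda: planted
            columns[focal].append(
                [draw() if rng.random() < config.conservation
                 else AA[rng.integers(len(AA))] for _ in range(depth)])
            for a in arch_names[1:]:
                columns[a].append(
                    _unconserved_block(rng, depth, config.background, config.consensus))
        else:
            for a in arch_names:
                columns[a].append(
                    _unconserved_block(rng, depth, config.background, config.consensus))

    alignments, hits, arch_of = {}, [], {}
    for k, a in enumerate(arch_names):
        rows = ["".join(columns[a][c][r] for c in range(width)) for r in range(depth)]
        if config.indel_rate > 0:
            rows = ["".join("-" if rng.random() < config.indel_rate else ch
                            for ch in row) for row in rows]
        records = []
        for r, row in enumerate(rows):
            sid = f"{a}_s{r:02d}"
            records.append(SeqRecord(id=sid, seq=row))
            arch_of[sid] = a
            # distinct domain combination per architecture
            ungapped = len(row.replace("-", ""))
            half = max(1, ungapped // 2)
            if k == 0:
                hits.append(DomainHit(seq_id=sid, domain="ARID", start=1, end=half))
                hits.append(DomainHit(seq_id=sid, domain="BAF250_C",
                                      start=half + 1, end=ungapped))
            elif k == 1:
                hits.append(DomainHit(seq_id=sid, domain="ARID", start=1, end=ungapped))
            else:
                hits.append(DomainHit(seq_id=sid, domain="ARID", start=1, end=half))
                hits.append(DomainHit(seq_id=sid, domain=f"PARTNER{k}",
                                      start=half + 1, end=ungapped))
        alignments[a] = records

    truth = SyntheticTruth(column_labels=labels, architecture_of=arch_of)
    return FamilyData(alignments=alignments, hits=hits, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Co-evolved alignment pairs

@dataclass(frozen=True)
class CoevolutionConfig:
    n_taxa: int = 8
    length_a: int = 300
    length_b: int = 300
    mutation_rate: float = 1.0      # substitutions per site per unit branch length
    branch_length_range: tuple = (0.05, 0.25)
    seed: int = 0


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self, label=None, length=0.0):
        self.children = []
        self.length = length
        self.label = label


def _random_tree(rng, n_taxa, br_range):
    nodes = [_Node(label=f"t{i + 1}") for i in range(n_taxa)]
    for node in nodes:
        node.length = rng.uniform(*br_range)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = _Node(length=rng.uniform(*br_range))
        parent.children = [nodes[i], nodes[j]]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0
    return root


def _newick(node) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.6f}"
    inner = ",".join(_newick(c) for c in node.children)
    return f"({inner}):{node.length:.6f}"


def _evolve(node, seq, rng, rate, out):
    if node.children:
        for child in node.children:
            p = 1.0 - math.exp(-rate * child.length)
            mutated = [AA[rng.integers(len(AA))] if rng.random() < p else c
                       for c in seq]
            _evolve(child, mutated, rng, rate, out)
    else:
        out[node.label] = "".join(seq)


def generate_coevolved_pair(config: CoevolutionConfig):
    """Two alignments evolved independently down one shared random tree.

    Substitution is Jukes–Cantor-style uniform replacement over the 20
    residues.  Returns ``(alignment_a, alignment_b, tree)`` with the tree as
    a dendropy object.
    """
    rng = np.random.default_rng(config.seed)
    root = _random_tree(rng, config.n_taxa, config.branch_length_range)
    newick = _newick(root) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True)

    alignments = []
    for length in (config.length_a, config.length_b):
        ancestral = [AA[rng.integers(len(AA))] for _ in range(length)]
        out: dict = {}
        _evolve(root, ancestral, rng, config.mutation_rate, out)
        alignments.append([SeqRecord(id=lab, seq=out[lab]) for lab in sorted(out)])
    return alignments[0], alignments[1], tree


# ---------------------------------------------------------------------------
# Ideal helix PDB

_HELIX_TWIST = math.radians(100.0)  # per residue
_HELIX_RISE = 1.5                   # Å per residue
_CA_RADIUS = 2.3                    # Å from the helical axis


def generate_helix_pdb(n_residues: int, face_half_width_deg: float = 60.0):
    """PDB text for an ideal poly-alanine α-helix plus a planted face truth.

    Backbone N, CA, C, O per residue on a 100°/1.5 Å helix.  Residues whose
    CA azimuth lies within ``face_half_width_deg`` of 0° form the planted
    "conserved face" recorded in the returned :class:`ResidueSet`.
    """
    if n_residues < 4:
        raise ValidationError("helix needs at least 4 residues")
    lines, face = [], {}
    serial = 1
    offsets = {  # (radius, angle offset rad, z offset) per backbone atom
        "N": (1.6, -0.45, -0.9),
        "CA": (_CA_RADIUS, 0.0, 0.0),
        "C": (1.7, 0.45, 0.6),
        "O": (2.0, 0.70, 1.1),
    }
    for i in range(n_residues):
        theta = _HELIX_TWIST * i
        azimuth = math.degrees(theta) % 360.0
        if min(azimuth, 360.0 - azimuth) <= face_half_width_deg:
            face[i + 1] = "A"
        for name, (radius, dth, dz) in offsets.items():
            x = radius * math.cos(theta + dth)
            y = radius * math.sin(theta + dth)
            z = _HELIX_RISE * i + dz
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    truth = ResidueSet(name="planted-face", residues=face)
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# Mutation tables

def generate_mutation_table(regions: list[DomainRegion], n_in_region: dict,
                            n_outside: int, seed: int):
    """Random mutation records with known per-region counts.

    Positions are sampled without replacement inside each named region and
    outside all regions; ref/alt residues are random and distinct.  Returns
    ``(mutations, truth_counts)`` with ``truth_counts`` mapping region name
    (and "none") to the planted number of distinct mutated residues.
    """
    rng = np.random.default_rng(seed)
    by_name = {r.name: r for r in regions}
    unknown = sorted(set(n_in_region) - set(by_name))
    if unknown:
        raise ValidationError(f"unknown regions in request: {unknown}")

    def random_mutation(pos):
        ref = AA[rng.integers(len(AA))]
        alt = AA[rng.integers(len(AA))]
        while alt == ref:
            alt = AA[rng.integers(len(AA))]
        return MutationRecord(position=int(pos), ref_aa=ref, alt_aa=alt)

    mutations, truth = [], {}
    for name in sorted(n_in_region):
        region, n = by_name[name], n_in_region[name]
        if n > region.end - region.start + 1:
            raise ValidationError(f"region {name} too small for {n} distinct positions")
        positions = rng.choice(
            np.arange(region.start, region.end + 1), size=n, replace=False)
        mutations.extend(random_mutation(p) for p in sorted(positions))
        truth[name] = n

    if n_outside > 0:
        limit = max((r.end for r in regions), default=0) + 500
        covered = set()
        for r in regions:
            covered.update(range(r.start, r.end + 1))
        outside_pool = np.array(sorted(set(range(1, limit + 1)) - covered))
        positions = rng.choice(outside_pool, size=n_outside, replace=False)
        mutations.extend(random_mutation(p) for p in sorted(positions))
    truth["none"] = n_outside
    return mutations, truth
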