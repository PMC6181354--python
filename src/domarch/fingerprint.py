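"""Property-class consensus fingerprints and position classification.

For each alignment column a consensus symbol is derived at a conservation
threshold (default 70%): a single residue letter if one residue alone
reaches the threshold, otherwise the symbol of the *most discriminating*
(smallest) biochemical equivalence class whose members jointly reach it,
otherwise '.'.  Comparing per-architecture fingerprints across a shared
reference alignment classifies every column as

* ``universal`` — a compatible property is conserved in every architecture,
* ``focal_specific`` — conserved in the focal architecture while the pooled
  remainder of the family is unconserved at the same threshold,
* ``variable`` — anything else.

The equivalence classes are the standard MView set: alcohol, aliphatic,
aromatic, charged, hydrophobic, negative, polar, positive, small, tiny and
turn-like.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seq_io import SeqRecord, ValidationError

GAP = "-"
UNCONSERVED = "."

#: MView biochemical equivalence classes: symbol -> member residues.
DEFAULT_CLASSES: dict[str, frozenset] = {
    "o": frozenset("ST"),                # alcohol
    "l": frozenset("ILV"),               # aliphatic
    "a": frozenset("FHWY"),              # aromatic
    "c": frozenset("DEHKR"),             # charged
    "h": frozenset("ACFGHIKLMRTVWY"),    # hydrophobic
    "-": frozenset("DE"),                # negative
    "p": frozenset("CDEHKNQRST"),        # polar
    "+": frozenset("HKR"),               # positive
    "s": frozenset("ACDGNPSTV"),         # small
    "u": frozenset("AGS"),               # tiny
    "t": frozenset("ACDEGHKNQRST"),      # turn-like
}

#: Order used only to break exact ties in class size (legend order).
DEFAULT_PRIORITY = ["o", "l", "a", "c", "h", "-", "p", "+", "s", "u", "t"]

_STANDARD = frozenset("ACDEFGHIKLMNPQRSTVWY")
_EPS = 1e-9


@dataclass(frozen=True)
class ConsensusParams:
    threshold: float = 0.70
    gap_symbol_out: str = UNCONSERVED
    count_gaps: bool = True  # gaps count in the denominator (gappy columns read unconserved)
    class_priority: tuple = tuple(DEFAULT_PRIORITY)

    def __post_init__(self):
        if not 0.5 < self.threshold <= 1.0:
            raise ValidationError(f"consensus threshold {self.threshold} outside (0.5, 1]")


@dataclass(frozen=True)
class ColumnConsensus:
    symbol: str                    # residue letter, class symbol, or '.'
    members: frozenset             # residue set the symbol stands for (empty for '.')
    fraction: float                # achieved fraction of the column


@dataclass
class ConsensusFingerprint:
    architecture: str
    columns: list[ColumnConsensus]

    @property
    def symbols(self) -> str:
        return "".join(c.symbol for c in self.columns)

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class PositionClassification:
    """Per-column labels plus the per-architecture symbols supporting them."""

    labels: list[str]                        # universal | focal_specific | variable
    per_architecture: dict[str, str] = field(default_factory=dict)  # arch -> symbol string
    pooled_nonfocal: str = ""


def column_consensus(column, params: ConsensusParams | None = None,
                     classes: dict | None = None) -> ColumnConsensus:
    """Consensus symbol for one alignment column (residues and gaps).

    The denominator is the full column depth when ``count_gaps`` (default),
    else the number of residue rows.  'X' is tolerated but contributes to no
    residue or class; other non-standard letters raise.
    """
    params = params or ConsensusParams()
    classes = DEFAULT_CLASSES if classes is None else classes
    column = [c.upper() for c in column]
    if not column:
        raise ValidationError("empty alignment column")
    for c in column:
        if c not in _STANDARD and c not in (GAP, "X"):
            raise ValidationError(f"non-standard residue letter {c!r} in column")

    counts = Counter(c for c in column if c in _STANDARD)
    denom = len(column) if params.count_gaps else max(sum(counts.values()), 1)
    need = params.threshold * denom - _EPS

    if counts:
        best_res, best_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if best_n >= need:
            return ColumnConsensus(best_res, frozenset(best_res), best_n / denom)

    # smallest qualifying class; exact size ties resolved by priority order
    order = {sym: i for i, sym in enumerate(params.class_priority)}
    best = None
    for sym, members in classes.items():
        n = sum(counts[r] for r in members)
        if n >= need:
            key = (len(members), order.get(sym, len(order)))
            if best is None or key < best[0]:
                best = (key, sym, members, n)
    if best is not None:
        _, sym, members, n = best
        return ColumnConsensus(sym, frozenset(members), n / denom)
    return ColumnConsensus(params.gap_symbol_out, frozenset(), 0.0)


def fingerprint(alignment: list[SeqRecord] | list[str],
                params: ConsensusParams | None = None,
                classes: dict | None = None,
                architecture: str = "") -> ConsensusFingerprint:
    """Column-wise consensus over an equal-width alignment."""
    rows = [r.seq if isinstance(r, SeqRecord) else r for r in alignment]
    if not rows:
        raise ValidationError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValidationError("ragged alignment")
    cols = [column_consensus([row[i] for row in rows], params, classes)
            for i in range(width)]
    return ConsensusFingerprint(architecture=architecture, columns=cols)


UNIVERSAL = "universal"
FOCAL_SPECIFIC = "focal_specific"
VARIABLE = "variable"


def classify_positions(alignments_by_architecture: dict,
                       focal: str,
                       params: ConsensusParams | None = None,
                       classes: dict | None = None) -> PositionClassification:
    """Classify reference-alignment columns as universal / focal-specific / variable.

    ``alignments_by_architecture`` maps architecture name -> rows already
    expressed in shared reference-alignment coordinates (equal width across
    architectures; gaps propagate as unconserved).  A column is *universal*
    when every architecture shows a consensus symbol and the winning residue
    sets share at least one member (letters count as singletons); it is
    *focal-specific* when the focal architecture shows a symbol, the column
    is not universal, and pooling all non-focal rows yields no consensus at
    the same threshold.
    """
    params = params or ConsensusParams()
    if focal not in alignments_by_architecture:
        raise ValidationError(f"focal architecture {focal!r} missing from input")

    rows_by_arch = {
        arch: [r.seq if isinstance(r, SeqRecord) else r for r in rows]
        for arch, rows in alignments_by_architecture.items()
    }
    widths = {len(r) for rows in rows_by_arch.values() for r in rows}
    if len(widths) != 1:
        raise ValidationError(f"architectures disagree on alignment width: {sorted(widths)}")
    width = widths.pop()

    fps = {arch: fingerprint(rows, params, classes, architecture=arch)
           for arch, rows in rows_by_arch.items()}
    pooled_rows = [r for arch, rows in rows_by_arch.items() if arch != focal
                   for r in rows]
    pooled_fp = fingerprint(pooled_rows, params, classes) if pooled_rows else None

    labels = []
    for i in range(width):
        cols = {arch: fp.columns[i] for arch, fp in fps.items()}
        all_conserved = all(c.symbol != UNCONSERVED for c in cols.values())
        if all_conserved:
            shared = None
            for c in cols.values():
                shared = c.members if shared is None else shared & c.members
            if shared:
                labels.append(UNIVERSAL)
                continue
        focal_col = cols[focal]
        pooled_unconserved = (pooled_fp is None
                              or pooled_fp.columns[i].symbol == UNCONSERVED)
        if focal_col.symbol != UNCONSERVED and pooled_unconserved:
            labels.append(FOCAL_SPECIFIC)
        else:
            labels.append(VARIABLE)

    return PositionClassification(
        labels=labels,
        per_architecture={arch: fp.symbols for arch, fp in fps.items()},
        pooled_nonfocal=pooled_fp.symbols if pooled_fp else "",
    )
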