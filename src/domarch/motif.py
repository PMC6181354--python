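"""Degenerate protein-motif compilation and scanning.

Patterns are whitespace-separated tokens over residue classes, in the style
of the β-catenin-binding motif ``D x Ө Ө x Ф x(2,7) E``: fixed residues,
the any-residue wildcard ``x``, named residue classes (Ө hydrophobic,
Ф aromatic by default), and bounded wildcard runs ``x(min,max)``.  Scanning
enumerates every start and run-length assignment and reports distinct
(start, end) spans, Patmatdb-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_io import SeqRecord, ValidationError

#: Default class bindings.  Ф is the aromatic set; Ө is a permissive
#: hydrophobic set that includes proline (required by the known
#: ARM-groove-binding peptides, two of which place P at a Ө slot).
DEFAULT_MOTIF_CLASSES = {
    "Ө": frozenset("ACFGILMPVWY"),
    "Ф": frozenset("FWYH"),
}

_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
ANY = "x"


@dataclass(frozen=True)
class Element:
    kind: str                    # "fixed" | "any" | "class" | "run"
    residue: str = ""            # for fixed
    members: frozenset = frozenset()  # for class
    min_len: int = 1
    max_len: int = 1
    symbol: str = ""


@dataclass(frozen=True)
class MotifPattern:
    elements: tuple
    text: str = ""

    def __post_init__(self):
        if not self.elements:
            raise ValidationError("pattern with no elements")

    @property
    def min_length(self) -> int:
        return sum(e.min_len for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    seq_id: str
    start: int      # 1-based inclusive
    end: int        # 1-based inclusive
    subsequence: str
    run_lengths: tuple = ()


def compile_pattern(text: str, classes: dict | None = None) -> MotifPattern:
    """Compile a whitespace-tokenized pattern string.

    Class symbols supplied in ``classes`` take precedence over residue
    letters, so ASCII class aliases (e.g. ``O``/``F`` from a classes table)
    are honoured.  Unknown symbols and inverted run bounds raise.
    """
    classes = DEFAULT_MOTIF_CLASSES if classes is None else classes
    elements = []
    for token in text.split():
        if token.startswith(f"{ANY}(") or (token[0] in classes and "(" in token):
            sym, _, bounds = token.partition("(")
            if not bounds.endswith(")"):
                raise ValidationError(f"malformed run token {token!r}")
            try:
                lo, hi = (int(v) for v in bounds[:-1].split(","))
            except ValueError as exc:
                raise ValidationError(f"malformed run bounds in {token!r}") from exc
            if lo < 0 or lo > hi:
                raise ValidationError(f"invalid run bounds ({lo},{hi}) in {token!r}")
            members = classes.get(sym, _RESIDUES if sym == ANY else None)
            if members is None:
                raise ValidationError(f"unknown class symbol {sym!r}")
            elements.append(Element(kind="run", members=frozenset(members),
                                    min_len=lo, max_len=hi, symbol=sym))
        elif token in classes:
            elements.append(Element(kind="class", members=classes[token], symbol=token))
        elif token == ANY:
            elements.append(Element(kind="any", symbol=ANY))
        elif len(token) == 1 and token.upper() in _RESIDUES:
            elements.append(Element(kind="fixed", residue=token.upper(), symbol=token))
        else:
            raise ValidationError(f"unknown pattern token {token!r}")
    return MotifPattern(elements=tuple(elements), text=text)


def _match_here(seq: str, pos: int, elements, runs: tuple):
    """Yield (end_pos, run_lengths) for matches of elements starting at pos."""
    if not elements:
        yield pos, runs
        return
    e, rest = elements[0], elements[1:]
    if e.kind == "fixed":
        if pos < len(seq) and seq[pos] == e.residue:
            yield from _match_here(seq, pos + 1, rest, runs)
    elif e.kind == "any":
        if pos < len(seq):
            yield from _match_here(seq, pos + 1, rest, runs)
    elif e.kind == "class":
        if pos < len(seq) and seq[pos] in e.members:
            yield from _match_here(seq, pos + 1, rest, runs)
    else:  # run
        for length in range(e.min_len, e.max_len + 1):
            segment = seq[pos:pos + length]
            if len(segment) < length:
                break
            if all(c in e.members for c in segment):
                yield from _match_here(seq, pos + length, rest, runs + (length,))
            elif e.symbol != ANY:
                break  # extending an already-failing class run cannot succeed


def scan(record: SeqRecord | str, pattern: MotifPattern,
         all_expansions: bool = False) -> list[MotifMatch]:
    """All matches of ``pattern`` in a sequence, sorted by (start, end).

    By default distinct (start, end) spans are reported once (the smallest
    run assignment is kept); ``all_expansions=True`` retains every
    run-length assignment.
    """
    seq = record.seq if isinstance(record, SeqRecord) else record
    seq_id = record.id if isinstance(record, SeqRecord) else ""
    seq = seq.upper()
    matches = []
    for start in range(len(seq) - pattern.min_length + 1):
        for end_pos, runs in _match_here(seq, start, pattern.elements, ()):
            matches.append(MotifMatch(
                seq_id=seq_id, start=start + 1, end=end_pos,
                subsequence=seq[start:end_pos], run_lengths=runs))
    matches.sort(key=lambda m: (m.start, m.end, m.run_lengths))
    if all_expansions:
        return matches
    seen, out = set(), []
    for m in matches:
        if (m.start, m.end) not in seen:
            seen.add((m.start, m.end))
            out.append(m)
    return out
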