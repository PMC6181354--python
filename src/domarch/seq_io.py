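"""Readers and writers for the formats every pipeline stage consumes.

FASTA (plain and aligned), pfamscan-like domain-hit TSV, minimal PDB
coordinates, mutation TSV and Newick trees.  Sequence and tree parsing is
delegated to Biopython and dendropy; tables go through pandas.  The PDB
reader is deliberately minimal: fixed-column ``ATOM`` records, first MODEL
only, altloc ' '/'A' — the pipeline needs coordinates, residue numbering
and per-atom radii, nothing else.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "DomainHit",
    "Atom",
    "Structure",
    "MutationRecord",
    "ParseError",
    "ValidationError",
    "DEFAULT_RADII",
    "read_fasta",
    "write_fasta",
    "read_domain_hits",
    "write_domain_hits",
    "read_structure",
    "read_mutations",
    "write_mutations",
    "read_newick",
    "write_newick",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class ParseError(ValueError):
    """Raised when an input file is syntactically malformed."""


class ValidationError(ValueError):
    """Raised when a parsed record violates a domain invariant."""


@dataclass(frozen=True)
class SeqRecord:
    """A named protein sequence (uppercase; '-' allowed in aligned contexts)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record with empty id")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True, order=True)
class DomainHit:
    """A named domain interval on a sequence, 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    domain: str = field(compare=False, default="")

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"domain hit {self.domain} on {self.seq_id}: "
                f"invalid interval {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float
    radius: float


@dataclass
class Structure:
    """A minimal coordinate set: ATOM records with assigned vdW radii."""

    atoms: list[Atom]

    def residues(self) -> list[tuple[str, int, str]]:
        """Distinct (chain, res_seq, res_name) in order of first appearance."""
        seen, out = set(), []
        for a in self.atoms:
            key = (a.chain, a.res_seq, a.res_name)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def atom(self, res_seq: int, atom_name: str, chain: str | None = None) -> Atom:
        for a in self.atoms:
            if a.res_seq == res_seq and a.atom_name == atom_name:
                if chain is None or a.chain == chain:
                    return a
        raise KeyError(f"no atom {atom_name} in residue {res_seq}"
                       + (f" chain {chain}" if chain else ""))


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation on protein coordinates (1-based)."""

    position: int
    ref_aa: str
    alt_aa: str
    effect: str = "missense"

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"mutation position {self.position} < 1")
        if self.effect == "missense" and self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"missense mutation at {self.position} with ref == alt ({self.ref_aa})"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SeqRecord]:
    """Read FASTA records in file order; uppercase, '*' stripped from termini.

    Raises :class:`ParseError` (naming the line) if sequence data precedes
    the first header.
    """
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            break
        raise ParseError(f"line {lineno}: sequence data before first '>' header")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().strip("*")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i:i + width] + "\n")


def read_alignment(path) -> list[SeqRecord]:
    """Read an aligned FASTA and check that all rows have equal length."""
    records = read_fasta(path)
    if records:
        widths = {len(r.seq) for r in records}
        if len(widths) > 1:
            raise ValidationError(f"ragged alignment in {path}: row lengths {sorted(widths)}")
    return records


# ---------------------------------------------------------------------------
# Domain-hit TSV (seq_id, domain, start, end; '#' comments; header optional)

_HIT_COLUMNS = ["seq_id", "domain", "start", "end"]


_HEADER_WORDS = {"seq_id", "seqid", "id", "domain", "start", "end"}


def _looks_like_header(fields: list[str]) -> bool:
    return any(f.strip().lower() in _HEADER_WORDS for f in fields)


def read_domain_hits(path) -> list[DomainHit]:
    """Read a pfamscan-like TSV; hits returned sorted by (seq_id, start)."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines()
                 if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        return []
    first = lines[0].split("\t")
    if _looks_like_header(first):
        lines = lines[1:]
    hits = []
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) < 4:
            raise ParseError(f"domain-hit row {lineno}: expected 4 tab-separated fields")
        seq_id, domain, s, e = fields[0], fields[1], fields[2], fields[3]
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise ParseError(f"domain-hit row {lineno}: non-integer coordinate") from exc
        hits.append(DomainHit(seq_id=seq_id, domain=domain, start=start, end=end))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.end))
    return hits


def write_domain_hits(hits, path) -> None:
    df = pd.DataFrame(
        [(h.seq_id, h.domain, h.start, h.end) for h in hits], columns=_HIT_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal PDB

# NACCESS/Chothia-style van der Waals radii (Å), by element.
DEFAULT_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "H": 1.00, "P": 1.90}
DEFAULT_RADIUS = 1.80


def _element_of(atom_name: str, element_field: str) -> str:
    if element_field.strip():
        return element_field.strip().upper()
    name = atom_name.strip()
    # PDB atom names like " CA ", "1HB ": first alphabetic character is the element
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_structure(path, radii: dict | None = None,
                   default_radius: float = DEFAULT_RADIUS) -> Structure:
    """Parse ATOM records of the first MODEL (altloc ' ' or 'A') of a PDB file."""
    radii = DEFAULT_RADII if radii is None else radii
    atoms = []
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "ENDMDL":
                break  # first model only
            if rec != "ATOM":
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            atom_name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain = line[21].strip()
            res_seq = int(line[22:26])
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValidationError(f"non-finite coordinate in {path}")
            element = _element_of(atom_name, line[76:78] if len(line) >= 78 else "")
            radius = radii.get(element, default_radius)
            atoms.append(Atom(chain, res_seq, res_name, atom_name, x, y, z, radius))
    if not atoms:
        raise ValidationError(f"no ATOM records in {path}")
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# Mutation TSV (position, ref_aa, alt_aa, effect)

def read_mutations(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"position", "ref_aa", "alt_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"mutation table missing columns: {sorted(missing)}")
    if "effect" not in df.columns:
        df["effect"] = "missense"
    return [
        MutationRecord(position=int(row.position), ref_aa=str(row.ref_aa),
                       alt_aa=str(row.alt_aa), effect=str(row.effect))
        for row in df.itertuples()
    ]


def write_mutations(records, path) -> None:
    df = pd.DataFrame(
        [(m.position, m.ref_aa, m.alt_aa, m.effect) for m in records],
        columns=["position", "ref_aa", "alt_aa", "effect"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick

def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"failed to parse Newick from {path}: {exc}") from exc


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True)
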