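"""Canonical domain architectures.

A protein's architecture is the ordered list of its assigned domains with
consecutive duplicate runs collapsed (three tandem PLU-1 copies and two
tandem copies are the same combination).  Sequences are grouped by
architecture and domain subsequences extracted for downstream alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_io import DomainHit, SeqRecord, ValidationError

NO_DOMAIN = "no-domain"


@dataclass(frozen=True)
class Architecture:
    """An ordered domain combination with consecutive repeats collapsed."""

    domains: tuple[str, ...]

    def __post_init__(self):
        if not self.domains:
            raise ValidationError("empty architecture")

    def __str__(self) -> str:
        return "+".join(self.domains)


def normalize_architecture(domains, collapse_all: bool = False) -> Architecture:
    """Collapse duplicate runs in an ordered domain-name list.

    By default only *consecutive* runs collapse; non-adjacent repeats remain
    distinct because order is part of the context.  ``collapse_all=True``
    keeps only the first occurrence of each name.
    """
    domains = list(domains)
    if not domains:
        raise ValidationError("cannot normalize an empty domain list")
    out: list[str] = []
    for d in domains:
        if collapse_all:
            if d not in out:
                out.append(d)
        elif not out or out[-1] != d:
            out.append(d)
    return Architecture(domains=tuple(out))


def resolve_overlaps(hits: list[DomainHit], scores: dict | None = None) -> list[DomainHit]:
    """Drop hits overlapping a better hit on the same sequence.

    "Better" = higher bitscore when ``scores`` maps (seq_id, domain, start, end)
    to a score, else the earlier-start hit.  pfamscan output is normally
    pre-resolved; this is a safety net.
    """
    def score(h):
        if scores is not None:
            return scores.get((h.seq_id, h.domain, h.start, h.end), 0.0)
        return 0.0

    kept: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (h.seq_id, -score(h), h.start, h.end)):
        clash = any(k.seq_id == h.seq_id and not (h.end < k.start or h.start > k.end)
                    for k in kept)
        if not clash:
            kept.append(h)
    kept.sort(key=lambda h: (h.seq_id, h.start))
    return kept


def group_by_architecture(hits, sequences, collapse_all: bool = False):
    """Partition sequence ids by their normalized architecture.

    Returns ``{architecture-or-NO_DOMAIN: sorted list of sequence ids}``.
    Sequences without hits fall under the reserved :data:`NO_DOMAIN` key.
    Raises on hit seq_ids absent from ``sequences``.
    """
    seq_ids = {s.id if isinstance(s, SeqRecord) else s for s in sequences}
    dangling = sorted({h.seq_id for h in hits} - seq_ids)
    if dangling:
        raise ValidationError(f"domain hits reference unknown sequences: {dangling}")

    by_seq: dict[str, list[DomainHit]] = {}
    for h in sorted(hits, key=lambda h: (h.seq_id, h.start)):
        by_seq.setdefault(h.seq_id, []).append(h)

    groups: dict[object, list[str]] = {}
    for sid in sorted(seq_ids):
        if sid in by_seq:
            arch = normalize_architecture(
                [h.domain for h in by_seq[sid]], collapse_all=collapse_all)
            groups.setdefault(arch, []).append(sid)
        else:
            groups.setdefault(NO_DOMAIN, []).append(sid)
    return groups


def extract_domain(record: SeqRecord, hit: DomainHit) -> SeqRecord:
    """Cut the 1-based inclusive interval of ``hit`` out of ``record``."""
    if hit.end > len(record.seq):
        raise ValidationError(
            f"hit {hit.domain} {hit.start}-{hit.end} exceeds {record.id} "
            f"length {len(record.seq)}"
        )
    sub = record.seq[hit.start - 1:hit.end]
    return SeqRecord(id=f"{record.id}/{hit.start}-{hit.end}", seq=sub,
                     description=hit.domain)
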