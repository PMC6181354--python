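"""Mapping somatic missense mutations onto domain regions.

Mutations (1-based protein positions) are assigned to non-overlapping
domain regions, intersected with functional residue sets (DNA-binding,
architecture-specific conserved) and summarized per region.  Counting is
over distinct mutated residues — recurrent mutations at one position
collapse — with record counts retained separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_io import MutationRecord, ValidationError
from .surface import ResidueSet

NONE_REGION = "none"


@dataclass(frozen=True)
class DomainRegion:
    name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"region {self.name}: start {self.start} > end {self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


def _check_disjoint(regions) -> None:
    ordered = sorted(regions, key=lambda r: r.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValidationError(f"overlapping regions {a.name} and {b.name}")


def assign_domain(mutations, regions) -> list[tuple[MutationRecord, str]]:
    """Annotate each mutation with the region containing it, or "none"."""
    _check_disjoint(regions)
    out = []
    for m in mutations:
        region = next((r.name for r in regions if m.position in r), NONE_REGION)
        out.append((m, region))
    return out


def intersect_with_set(mutations, residue_set: ResidueSet):
    """Mutations falling in the set; count is over distinct positions."""
    hits = [m for m in mutations if m.position in residue_set.positions]
    return hits, len({m.position for m in hits})


def dedupe(mutations) -> list[MutationRecord]:
    """Collapse duplicate (position, alt) records, keeping first occurrence."""
    seen, out = set(), []
    for m in mutations:
        key = (m.position, m.alt_aa)
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def summarize(mutations, regions, residue_sets=(), exposure=None) -> dict:
    """Deterministic summary of mutation placement.

    Returns a dict with ``per_region`` (n_records / n_distinct_residues per
    region and "none"), ``per_set`` (distinct-position overlap per residue
    set), and optionally ``per_exposure_class`` when an exposure map
    (position -> class) is given.
    """
    mutations = dedupe(mutations)
    assigned = assign_domain(mutations, regions)
    per_region = {r.name: {"n_records": 0, "n_distinct_residues": 0} for r in regions}
    per_region[NONE_REGION] = {"n_records": 0, "n_distinct_residues": 0}
    positions_by_region: dict[str, set] = {}
    for m, region in assigned:
        per_region[region]["n_records"] += 1
        positions_by_region.setdefault(region, set()).add(m.position)
    for region, positions in positions_by_region.items():
        per_region[region]["n_distinct_residues"] = len(positions)

    per_set = {}
    for rset in residue_sets:
        _, count = intersect_with_set(mutations, rset)
        per_set[rset.name] = count

    summary = {"per_region": per_region, "per_set": per_set,
               "n_mutations": len(mutations),
               "n_distinct_positions": len({m.position for m in mutations})}
    if exposure is not None:
        per_class: dict[str, int] = {}
        for m in mutations:
            cls = exposure.get(m.position, "unmapped")
            per_class[cls] = per_class.get(cls, 0) + 1
        summary["per_exposure_class"] = per_class
    return summary
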