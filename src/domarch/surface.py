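"""Solvent accessibility and surface intersection analysis.

SASA is computed with the Shrake–Rupley point-sampling algorithm: for each
atom, quasi-uniform points (golden-spiral lattice) on the sphere of radius
r + probe are tested against every neighbour's expanded sphere, and the
exposed fraction scales the analytic sphere area.  Residue SASA is the sum
over its atoms; relative SASA normalizes by the residue's maximal exposure
in an extended Gly-X-Gly tripeptide.  Downstream helpers classify exposure,
intersect conserved residue sets with exposed ones, and measure inter-atom
distances (e.g. the ~32 Å lysine separation on an ARM-repeat groove).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seq_io import Structure, ValidationError

#: Theoretical maximum accessibilities (Å²) of residue X in extended
#: Gly-X-Gly tripeptides (Tien et al. 2013).
MAX_ASA_GXG = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

EXPOSED = "exposed"
PARTIAL = "partial"
BURIED = "buried"


@dataclass(frozen=True)
class ExposureThresholds:
    exposed_min: float = 25.0  # relative SASA % at or above which a residue is exposed
    buried_max: float = 7.0    # relative SASA % at or below which a residue is buried

    def __post_init__(self):
        if not 0 <= self.buried_max < self.exposed_min <= 100:
            raise ValidationError(
                f"invalid exposure thresholds: buried_max={self.buried_max}, "
                f"exposed_min={self.exposed_min}")


@dataclass
class ResidueSet:
    """Named set of 1-based residue positions with residue-letter annotations."""

    name: str
    residues: dict  # position -> single-letter annotation ('' if unknown)

    def __post_init__(self):
        if len(set(self.residues)) != len(self.residues):
            raise ValidationError(f"duplicate positions in residue set {self.name}")

    @property
    def positions(self) -> set:
        return set(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(structure: Structure, probe_radius: float = 1.4,
         n_sphere_points: int = 92):
    """Shrake–Rupley SASA.

    Returns ``(per_atom, per_residue)``: a list of areas (Å²) parallel to
    ``structure.atoms`` and a dict keyed by (chain, res_seq, res_name).
    """
    atoms = structure.atoms
    if not atoms:
        raise ValidationError("empty structure")
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array([a.radius for a in atoms])
    if np.any(radii <= 0):
        raise ValidationError("atom without a positive radius")
    expanded = radii + probe_radius
    unit = sphere_points(n_sphere_points)

    per_atom = []
    for i in range(len(atoms)):
        pts = coords[i] + expanded[i] * unit
        # neighbours whose expanded spheres can occlude points of atom i
        delta = coords - coords[i]
        d2 = np.einsum("ij,ij->i", delta, delta)
        cutoff = (expanded + expanded[i]) ** 2
        neigh = np.where((d2 < cutoff) & (np.arange(len(atoms)) != i))[0]
        exposed_mask = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            dd = pts - coords[j]
            inside = np.einsum("ij,ij->i", dd, dd) < expanded[j] ** 2
            exposed_mask &= ~inside
            if not exposed_mask.any():
                break
        frac = exposed_mask.sum() / n_sphere_points
        per_atom.append(frac * 4.0 * math.pi * expanded[i] ** 2)

    per_residue: dict = {}
    for a, area in zip(atoms, per_atom):
        key = (a.chain, a.res_seq, a.res_name)
        per_residue[key] = per_residue.get(key, 0.0) + area
    return per_atom, per_residue


def relative_sasa(per_residue: dict, reference: dict | None = None) -> dict:
    """Relative SASA in percent: 100 * area / max-area(residue type).

    May mildly exceed 100 for termini.  Raises for residue types absent
    from the reference table.
    """
    reference = MAX_ASA_GXG if reference is None else reference
    out = {}
    for (chain, res_seq, res_name), area in per_residue.items():
        if res_name not in reference:
            raise ValidationError(f"residue type {res_name} missing from reference table")
        out[(chain, res_seq, res_name)] = 100.0 * area / reference[res_name]
    return out


def exposure_class(rel_percent: float,
                   thresholds: ExposureThresholds | None = None) -> str:
    thresholds = thresholds or ExposureThresholds()
    if rel_percent < 0:
        raise ValidationError(f"negative relative SASA {rel_percent}")
    if rel_percent >= thresholds.exposed_min:
        return EXPOSED
    if rel_percent <= thresholds.buried_max:
        return BURIED
    return PARTIAL


def exposure_map(structure: Structure, thresholds: ExposureThresholds | None = None,
                 probe_radius: float = 1.4, n_sphere_points: int = 92) -> dict:
    """Position -> exposure class for every residue of a structure."""
    _, per_res = sasa(structure, probe_radius, n_sphere_points)
    rel = relative_sasa(per_res)
    return {res_seq: exposure_class(pct, thresholds)
            for (chain, res_seq, res_name), pct in rel.items()}


def conserved_exposed(conserved: ResidueSet, exposure: dict,
                      offset: int = 0):
    """Intersect a conserved residue set with the exposed residues.

    ``exposure`` maps structure residue numbers to exposure classes;
    ``offset`` converts set positions to structure numbering
    (structure_pos = set_pos + offset).  Returns ``(ResidueSet, unmapped)``
    where ``unmapped`` lists set positions absent from the exposure map.
    """
    hits, unmapped = {}, []
    for pos, aa in conserved.residues.items():
        spos = pos + offset
        if spos not in exposure:
            unmapped.append(pos)
        elif exposure[spos] == EXPOSED:
            hits[pos] = aa
    return ResidueSet(name=f"{conserved.name}&exposed", residues=hits), sorted(unmapped)


def atom_distance(structure: Structure, res1: int, res2: int,
                  atom_name: str = "CA", chain: str | None = None) -> float:
    """Euclidean distance (Å) between the named atoms of two residues."""
    a = structure.atom(res1, atom_name, chain)
    b = structure.atom(res2, atom_name, chain)
    return math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
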