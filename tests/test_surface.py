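import math

import numpy as np
import pytest

from domarch.seq_io import Atom, Structure, read_structure, ValidationError
from domarch.surface import (
    EXPOSED,
    ExposureThresholds,
    MAX_ASA_GXG,
    ResidueSet,
    atom_distance,
    conserved_exposed,
    exposure_class,
    exposure_map,
    relative_sasa,
    sasa,
    sphere_points,
)


def _atom(x, y, z, radius=1.87, res_seq=1, name="CA", res_name="ALA"):
    return Atom("A", res_seq, res_name, name, x, y, z, radius)


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        r = 1.87
        per_atom, _ = sasa(Structure(atoms=[_atom(0, 0, 0, r)]))
        analytic = 4 * math.pi * (r + 1.4) ** 2
        assert abs(per_atom[0] - analytic) / analytic <= 0.02

    def test_distant_atoms_full_spheres(self):
        s = Structure(atoms=[_atom(0, 0, 0), _atom(100, 0, 0, res_seq=2)])
        per_atom, _ = sasa(s)
        analytic = 4 * math.pi * (1.87 + 1.4) ** 2
        for a in per_atom:
            assert a == pytest.approx(analytic, rel=0.02)

    def test_coincident_atoms_occluded_symmetrically(self):
        s = Structure(atoms=[_atom(0, 0, 0), _atom(0, 0, 0, res_seq=2)])
        per_atom, _ = sasa(s)
        full = 4 * math.pi * (1.87 + 1.4) ** 2
        assert per_atom[0] < full and per_atom[1] < full
        assert per_atom[0] == pytest.approx(per_atom[1])

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(-3, 3, size=(10, 3))
        atoms = [_atom(*c, res_seq=i + 1) for i, c in enumerate(coords)]
        base, _ = sasa(Structure(atoms=atoms))
        # rotate 40 degrees about z and translate
        th = math.radians(40)
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        moved = coords @ R.T + np.array([5.0, -2.0, 7.0])
        moved_atoms = [_atom(*c, res_seq=i + 1) for i, c in enumerate(moved)]
        rotated, _ = sasa(Structure(atoms=moved_atoms))
        assert sum(rotated) == pytest.approx(sum(base), rel=0.02)

    def test_point_count_convergence(self, rng):
        coords = rng.uniform(-3, 3, size=(10, 3))
        atoms = [_atom(*c, res_seq=i + 1) for i, c in enumerate(coords)]
        s = Structure(atoms=atoms)
        coarse, _ = sasa(s, n_sphere_points=92)
        fine, _ = sasa(s, n_sphere_points=960)
        assert sum(coarse) == pytest.approx(sum(fine), rel=0.01)

    def test_sphere_points_unit_norm(self):
        pts = sphere_points(92)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_biotite_cross_check(self, helix12):
        """Independent Shrake–Rupley implementation agrees on a helix."""
        import biotite.structure as biotite_struc
        import biotite.structure.io.pdb as pdb_io
        path, _ = helix12
        s = read_structure(path)
        per_atom, _ = sasa(s, n_sphere_points=960)
        pdb_file = pdb_io.PDBFile.read(str(path))
        arr = pdb_io.get_structure(pdb_file, model=1)
        radii = np.array([a.radius for a in s.atoms])
        ref = biotite_struc.sasa(arr, probe_radius=1.4, point_number=960,
                                 vdw_radii=radii)
        assert sum(per_atom) == pytest.approx(float(np.nansum(ref)), rel=0.03)


class TestRelativeSasa:
    def test_reference_area_is_100_percent(self):
        rel = relative_sasa({("A", 1, "ALA"): MAX_ASA_GXG["ALA"]})
        assert rel[("A", 1, "ALA")] == pytest.approx(100.0)

    def test_zero_area(self):
        assert relative_sasa({("A", 1, "GLY"): 0.0})[("A", 1, "GLY")] == 0.0

    def test_unknown_residue_type(self):
        with pytest.raises(ValidationError):
            relative_sasa({("A", 1, "UNK"): 50.0})


class TestExposureClass:
    @pytest.mark.parametrize("rel,expected", [
        (30.0, "exposed"), (25.0, "exposed"),
        (15.0, "partial"), (7.0, "buried"), (0.0, "buried"),
    ])
    def test_default_boundaries(self, rel, expected):
        assert exposure_class(rel) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            exposure_class(-1.0)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError):
            ExposureThresholds(exposed_min=5, buried_max=10)


class TestConservedExposed:
    def test_simple_intersection(self):
        conserved = ResidueSet(name="c", residues={10: "K", 20: "R"})
        hits, unmapped = conserved_exposed(conserved, {20: EXPOSED, 30: EXPOSED, 10: "buried"})
        assert hits.positions == {20} and unmapped == []

    def test_empty_conserved_set(self):
        hits, _ = conserved_exposed(ResidueSet(name="c", residues={}), {1: EXPOSED})
        assert len(hits) == 0

    def test_unmapped_positions_reported(self):
        conserved = ResidueSet(name="c", residues={5: "A", 99: "B"})
        hits, unmapped = conserved_exposed(conserved, {5: EXPOSED})
        assert hits.positions == {5} and unmapped == [99]

    def test_offset_mapping(self):
        # set positions are UniProt numbering; structure numbering shifted by -1000
        conserved = ResidueSet(name="c", residues={1005: "K"})
        hits, _ = conserved_exposed(conserved, {5: EXPOSED}, offset=-1000)
        assert hits.positions == {1005}

    def test_helix_face_recovered(self, helix12):
        path, truth = helix12
        s = read_structure(path)
        em = exposure_map(s)
        hits, unmapped = conserved_exposed(truth, em)
        # an isolated short helix has no burial: every planted position recovered
        assert hits.positions == truth.positions and unmapped == []


class TestAtomDistance:
    def test_pythagorean(self):
        s = Structure(atoms=[_atom(0, 0, 0), _atom(3, 4, 0, res_seq=2)])
        assert atom_distance(s, 1, 2) == pytest.approx(5.0)

    def test_same_atom_zero(self):
        s = Structure(atoms=[_atom(0, 0, 0)])
        assert atom_distance(s, 1, 1) == 0.0

    def test_missing_atom_named(self):
        s = Structure(atoms=[_atom(0, 0, 0)])
        with pytest.raises(KeyError, match="NZ"):
            atom_distance(s, 1, 1, atom_name="NZ")
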