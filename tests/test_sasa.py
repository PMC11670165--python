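"""Shrake-Rupley SASA, the Ala-X-Ala reference table and RSA calls.

The independent cross-check recomputes per-residue areas with biotite's
own SASA implementation using the same radii and probe.
"""

from __future__ import annotations

import copy
import math

import numpy as np
import pytest

from vartriage.sasa import (
    NACCESS_RADII,
    MaxSasaTable,
    RadiiSet,
    classify_exposure,
    compute_max_sasa,
    golden_spiral_points,
    max_sasa_table,
    relative_accessibility,
    shrake_rupley,
)
from vartriage.structmodel import Atom, Chain, Residue, StructureModel, build_fixture


def single_atom_model(element="C", name="CB", coords=(0.0, 0.0, 0.0)):
    res = Residue(chain_id="A", number=1, name="ALA",
                  atoms=[Atom(name=name, element=element, coords=np.array(coords))])
    return StructureModel("single", [Chain("A", [res])])


def two_atom_model(separation: float):
    r1 = Residue(chain_id="A", number=1, name="ALA",
                 atoms=[Atom(name="CB", element="C", coords=np.zeros(3))])
    r2 = Residue(chain_id="A", number=2, name="ALA",
                 atoms=[Atom(name="CB", element="C",
                             coords=np.array([separation, 0.0, 0.0]))])
    return StructureModel("pair", [Chain("A", [r1, r2])])


def to_biotite(model: StructureModel):
    import biotite.structure as struc

    atoms = []
    for res in model.residues():
        for atom in res.heavy_atoms():
            a = struc.Atom(atom.coords, chain_id=res.chain_id, res_id=res.number,
                           res_name=res.name, atom_name=atom.name,
                           element=atom.element)
            atoms.append(a)
    return struc.array(atoms)


def biotite_residue_sasa(model: StructureModel, probe=1.4, n_points=960):
    """Independent per-residue SASA with identical radii and probe."""
    import biotite.structure as struc

    arr = to_biotite(model)
    radii = np.array([
        NACCESS_RADII.radius_of(rn, an, el)
        for rn, an, el in zip(arr.res_name, arr.atom_name, arr.element)
    ])
    per_atom = struc.sasa(arr, probe_radius=probe, vdw_radii=radii,
                          point_number=n_points)
    out: dict[int, float] = {}
    for res_id, area in zip(arr.res_id, per_atom):
        out[int(res_id)] = out.get(int(res_id), 0.0) + float(area)
    return out


class TestGoldenSpiral:
    def test_points_on_unit_sphere(self):
        pts = golden_spiral_points(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_quasi_uniform_centroid(self):
        pts = golden_spiral_points(960)
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-3


class TestShrakeRupley:
    def test_single_atom_closed_form(self):
        result = shrake_rupley(single_atom_model())
        expected = 4.0 * math.pi * (1.87 + 1.4) ** 2
        assert result.atom_areas[0] == pytest.approx(expected, rel=5e-3)

    def test_additivity_at_infinite_separation(self):
        single = shrake_rupley(single_atom_model()).atom_areas[0]
        pair = shrake_rupley(two_atom_model(100.0))
        assert pair.atom_areas.sum() == pytest.approx(2 * single, rel=1e-9)

    def test_enclosed_atom_has_zero_area(self):
        # shell of atoms on a sphere tight enough to occlude the centre
        shell_pts = golden_spiral_points(60) * 3.0
        residues = [Residue(chain_id="A", number=1, name="ALA",
                            atoms=[Atom(name="CB", element="C", coords=np.zeros(3))])]
        for i, p in enumerate(shell_pts):
            residues.append(Residue(
                chain_id="A", number=i + 2, name="ALA",
                atoms=[Atom(name="CB", element="C", coords=p)]))
        model = StructureModel("shell", [Chain("A", residues)])
        result = shrake_rupley(model)
        assert result.atom_areas[0] == 0.0

    def test_occlusion_monotone_under_atom_removal(self, tripeptide_arg):
        # a row of overlapping spheres; dropping the end atom can only
        # expose the others.  Atoms whose two nearest neighbours are
        # unchanged keep their exact sampling lattice, so the comparison
        # is pointwise exact there; the total is monotone regardless.
        def row_model(n):
            residues = [
                Residue(chain_id="A", number=i + 1, name="ALA",
                        atoms=[Atom(name="CB", element="C",
                                    coords=np.array([2.0 * i, 0.0, 0.0]))])
                for i in range(n)
            ]
            return StructureModel("row", [Chain("A", residues)])

        full = shrake_rupley(row_model(5))
        part = shrake_rupley(row_model(4))
        assert np.all(part.atom_areas[:3] >= full.atom_areas[:3] - 1e-12)
        assert part.atom_areas.sum() >= full.atom_areas[:4].sum() - 1e-12

    def test_occlusion_monotone_on_peptide(self, tripeptide_arg):
        def per_atom(model, result):
            keys = [(res.id, atom.name) for res in model.residues()
                    for atom in res.heavy_atoms()]
            return dict(zip(keys, result.atom_areas))

        full = per_atom(tripeptide_arg, shrake_rupley(tripeptide_arg))
        pruned = copy.deepcopy(tripeptide_arg)
        removed = pruned.residues()[1].atoms.pop()   # drop one Arg side-chain atom
        assert not removed.is_hydrogen
        part = per_atom(pruned, shrake_rupley(pruned))
        # removal perturbs nearby sampling frames, so allow lattice noise
        # on individual atoms; the aggregate must not shrink
        assert sum(part.values()) >= sum(full[k] for k in part) - 1e-9
        for key, area in part.items():
            assert area >= full[key] - 2.0, key

    def test_rigid_motion_invariance(self, decapeptide):
        base = shrake_rupley(decapeptide)
        moved = copy.deepcopy(decapeptide)
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = np.array([5.0, -3.0, 11.0])
        for res in moved.residues():
            for atom in res.atoms:
                atom.coords = q @ atom.coords + t
        again = shrake_rupley(moved)
        np.testing.assert_allclose(again.atom_areas, base.atom_areas, rtol=1e-6)

    def test_convergence_doubling_points(self, decapeptide):
        coarse = shrake_rupley(decapeptide, n_points=960)
        fine = shrake_rupley(decapeptide, n_points=1920)
        for rid, area in coarse.residue_areas.items():
            assert fine.residue_areas[rid] == pytest.approx(area, rel=0.01)

    def test_matches_independent_implementation(self):
        model = build_fixture("helix", "ARNDCQEGHILKMFPSTWYVARNDCQEGHI"
                                       "LKMFPSTWYVARNDCQEGHI")
        assert len(model.residues()) == 50
        ours = shrake_rupley(model, n_points=2000)
        theirs = biotite_residue_sasa(model, n_points=2000)
        for rid, area in ours.residue_areas.items():
            ref = theirs[rid[1]]
            assert area == pytest.approx(ref, rel=0.02, abs=0.5), rid

    def test_unresolvable_radius_raises(self):
        model = single_atom_model(element="U")
        with pytest.raises(KeyError, match="radius"):
            shrake_rupley(model)

    def test_fallback_radius(self):
        model = single_atom_model(element="U")
        radii = RadiiSet(name="fallback", by_element={"C": 1.87}, fallback=1.7)
        result = shrake_rupley(model, radii=radii)
        assert result.atom_areas[0] == pytest.approx(
            4 * math.pi * (1.7 + 1.4) ** 2, rel=5e-3)


class TestMaxSasaTable:
    @pytest.fixture()
    def table(self):
        return max_sasa_table()

    def test_glycine_smallest(self, table):
        assert min(table.values, key=table.values.get) == "G"

    def test_tryptophan_near_largest(self, table):
        ranked = sorted(table.values, key=table.values.get, reverse=True)
        assert "W" in ranked[:2]

    def test_deterministic(self, table):
        again = {aa: compute_max_sasa(aa) for aa in ("G", "W", "R")}
        for aa, v in again.items():
            assert v == table.values[aa]

    def test_all_twenty_covered(self, table):
        assert len(table.values) == 20
        assert all(v > 0 for v in table.values.values())

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            MaxSasaTable(values={"A": 0.0})


class TestRsa:
    def test_self_normalization(self, tripeptide_arg):
        table = max_sasa_table()
        value = relative_accessibility(tripeptide_arg,
                                       tripeptide_arg.residues()[1], table)
        assert value == pytest.approx(100.0, abs=0.5)

    def test_buried_core_low_rsa(self):
        # centre residue of a compact helix bundle approximation: bury an
        # Ala inside a dense shell of atoms
        shell = golden_spiral_points(200) * 4.5
        residues = [Residue(chain_id="A", number=1, name="ALA", atoms=[
            Atom(name=n, element=n[0], coords=c) for n, c in
            zip(("N", "CA", "C", "O", "CB"),
                np.array([[0.0, 0, 0], [1.2, 0, 0], [1.8, 1, 0],
                          [1.2, 2, 0], [-0.6, 1, 1]]))])]
        for i, p in enumerate(shell):
            residues.append(Residue(chain_id="A", number=i + 2, name="GLY",
                                    atoms=[Atom(name="CA", element="C", coords=p)]))
        model = StructureModel("globule", [Chain("A", residues)])
        table = max_sasa_table()
        value = relative_accessibility(model, model.residues()[0], table)
        assert value < 5.0

    def test_unknown_residue_type(self, tripeptide_arg):
        table = MaxSasaTable(values={"A": 110.0})
        with pytest.raises(KeyError):
            relative_accessibility(tripeptide_arg, tripeptide_arg.residues()[1],
                                   table)


class TestClassifyExposure:
    @pytest.mark.parametrize("rsa,expected", [
        (57.2, "exposed"),     # solvent-exposed interface arginine
        (3.1, "buried"),       # core tyrosine
        (20.0, "buried"),      # boundary: exposure requires strictly >20
        (20.01, "exposed"),
        (0.0, "buried"),
    ])
    def test_threshold_rule(self, rsa, expected):
        assert classify_exposure(rsa) == expected

    def test_negative_rsa_rejected(self):
        with pytest.raises(ValueError):
            classify_exposure(-1.0)
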