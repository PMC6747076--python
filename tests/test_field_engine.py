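"""Lattice fields: closed forms, symmetries, I/O and descriptor assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from fuzzcomfa import field_engine as fe
from fuzzcomfa.field_engine import (
    Atom,
    CARBON_PROBE,
    GridSpec,
    Molecule,
    ProbeSpec,
    STERIC_CUTOFF_KCAL,
    UnderdeterminedAlignmentError,
    assemble_descriptor_table,
    compute_field_block,
    electrostatic_field,
    make_grid,
    read_structures,
    steric_field,
    superpose_on_framework,
    write_sdf,
)


def single_atom(element="C", coords=(0.0, 0.0, 0.0), charge=0.0, mol_id="m"):
    return Molecule(mol_id, [Atom.from_element(element, coords, charge)])


def methane():
    d = 1.09 / np.sqrt(3)
    atoms = [Atom.from_element("C", (0, 0, 0), -0.4)]
    for sx, sy, sz in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]:
        atoms.append(Atom.from_element("H", (sx * d, sy * d, sz * d), 0.1))
    return Molecule("methane", atoms)


class TestStructureIO:
    def test_sdf_round_trip(self, tmp_path):
        path = tmp_path / "mols.sdf"
        write_sdf([methane()], path)
        mols = read_structures(path)
        assert len(mols) == 1
        m = mols[0]
        assert len(m.atoms) == 5
        assert sum(a.partial_charge for a in m.atoms) == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(m.coords, methane().coords, atol=1e-4)

    def test_custom_radii_round_trip(self, tmp_path):
        mol = single_atom()
        mol.atoms[0].vdw_radius = 1.234
        path = tmp_path / "m.sdf"
        write_sdf([mol], path)
        back = read_structures(path)[0]
        assert back.atoms[0].vdw_radius == pytest.approx(1.234, abs=1e-6)

    def test_mol2_route_matches_sdf(self, tmp_path):
        """The same structure read through MOL2 (Tripos charges) agrees with
        the SDF route to within coordinate precision."""
        sdf = tmp_path / "m.sdf"
        write_sdf([methane()], sdf)
        via_sdf = read_structures(sdf)[0]

        mol2 = tmp_path / "m.mol2"
        m = methane()
        lines = ["@<TRIPOS>MOLECULE", "methane", f"{len(m.atoms)} 0 0 0 0",
                 "SMALL", "USER_CHARGES", "@<TRIPOS>ATOM"]
        for i, a in enumerate(m.atoms, 1):
            x, y, z = a.coords
            typ = "C.3" if a.element == "C" else "H"
            lines.append(
                f"{i} {a.element}{i} {x:.4f} {y:.4f} {z:.4f} {typ} 1 MOL "
                f"{a.partial_charge:.4f}"
            )
        mol2.write_text("\n".join(lines) + "\n")
        via_mol2 = read_structures(mol2)[0]
        assert np.allclose(via_mol2.coords, via_sdf.coords, atol=1e-6)
        assert np.allclose(via_mol2.charges, via_sdf.charges, atol=1e-6)

    def test_missing_charges_error(self, tmp_path):
        from rdkit import Chem
        from rdkit.Geometry import Point3D

        rw = Chem.RWMol()
        rw.AddAtom(Chem.Atom("C"))
        conf = Chem.Conformer(1)
        conf.SetAtomPosition(0, Point3D(0, 0, 0))
        mol = rw.GetMol()
        mol.AddConformer(conf)
        path = str(tmp_path / "nocharge.sdf")
        w = Chem.SDWriter(path)
        w.write(mol)
        w.close()
        with pytest.raises(ValueError, match="charges"):
            read_structures(path)
        # a charge hook substitutes
        out = read_structures(path, charge_hook=lambda m: [0.5] * m.GetNumAtoms())
        assert out[0].charges[0] == 0.5

    def test_corrupt_file_raises(self, tmp_path):
        bad = tmp_path / "bad.mol2"
        bad.write_text("not a structure\n")
        with pytest.raises(ValueError):
            read_structures(bad)

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError, match="Xe"):
            Atom.from_element("Xe", (0, 0, 0))


class TestSuperposition:
    def test_template_onto_itself(self):
        m = methane()
        m.framework_map = {i: i for i in range(5)}
        moved, rmsd = superpose_on_framework(m, methane())
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(moved.coords, methane().coords, atol=1e-10)

    def test_recovers_rigid_motion(self):
        template = methane()
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        m = methane().transformed(rot, np.array([1.0, -2.0, 3.0]))
        m.framework_map = {i: i for i in range(5)}
        moved, rmsd = superpose_on_framework(m, template)
        assert rmsd <= 1e-6
        assert np.allclose(moved.coords, template.coords, atol=1e-6)

    def test_known_displacement_rmsd(self):
        """Mapped atoms displaced along +x by d after optimal alignment of a
        symmetric pattern: RMSD has a closed form.

        Four atoms at (+-1, +-1, 0) displaced alternately by +-d along z:
        optimal rotation is identity (antisymmetric displacement), RMSD = d.
        """
        d = 0.2
        base = [(1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0)]
        template = Molecule(
            "t", [Atom.from_element("C", c) for c in base]
        )
        shifted = [
            (x, y, z + (d if (x * y) > 0 else -d)) for x, y, z in base
        ]
        mol = Molecule(
            "m", [Atom.from_element("C", c) for c in shifted],
            framework_map={i: i for i in range(4)},
        )
        _, rmsd = superpose_on_framework(mol, template)
        # oracle: exhaustive small-angle search confirms identity is optimal
        assert rmsd == pytest.approx(d, abs=1e-6)

    def test_underdetermined_cases(self):
        template = methane()
        m = methane()
        m.framework_map = {0: 0, 1: 1}
        with pytest.raises(UnderdeterminedAlignmentError):
            superpose_on_framework(m, template)
        collinear = Molecule(
            "c",
            [Atom.from_element("C", (float(i), 0, 0)) for i in range(3)],
            framework_map={i: i for i in range(3)},
        )
        with pytest.raises(UnderdeterminedAlignmentError):
            superpose_on_framework(collinear, collinear)


class TestGrid:
    def test_single_atom_lattice_arithmetic(self):
        grid = make_grid([single_atom()], spacing=2.0, margin=4.0)
        assert grid.counts == (5, 5, 5)
        assert grid.origin == (-4.0, -4.0, -4.0)
        pts = grid.points()
        assert pts.shape == (125, 3)
        assert np.allclose(pts.mean(axis=0), [0, 0, 0])

    def test_degenerate_axis_expanded(self):
        grid = make_grid([single_atom()], spacing=2.0, margin=0.0)
        assert all(c >= 2 for c in grid.counts)

    def test_encloses_all_molecules(self):
        m1 = single_atom(coords=(-3.0, 0.0, 0.0))
        m2 = single_atom(coords=(5.0, 2.0, -1.0), mol_id="m2")
        grid = make_grid([m1, m2], spacing=2.0, margin=2.0)
        pts = grid.points()
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        allc = np.vstack([m1.coords, m2.coords])
        assert (lo <= allc.min(axis=0)).all() and (hi >= allc.max(axis=0)).all()


class TestStericField:
    def test_far_point_is_zero(self):
        mol = single_atom()
        grid = GridSpec((60.0, 0.0, 0.0), 1.0, (2, 2, 2))
        vals = steric_field(mol, grid)
        assert np.abs(vals).max() < 1e-6

    def test_lj_minimum_closed_form(self):
        """At separation R_atom + R_probe the LJ energy is exactly -eps."""
        mol = single_atom("C")
        r_min = 1.70 + CARBON_PROBE.vdw_radius
        grid = GridSpec((r_min, 0.0, 0.0), 1.0, (2, 2, 2))
        vals = steric_field(mol, grid)
        eps = np.sqrt(0.107 * CARBON_PROBE.lj_epsilon)
        assert vals[0] == pytest.approx(-eps, rel=1e-9)

    def test_close_contact_truncated(self):
        mol = single_atom()
        grid = GridSpec((0.5, 0.0, 0.0), 0.5, (2, 2, 2))
        vals = steric_field(mol, grid)
        assert vals[0] == STERIC_CUTOFF_KCAL

    def test_coincident_point_gets_cutoff(self):
        mol = single_atom()
        grid = GridSpec((0.0, 0.0, 0.0), 1.0, (2, 2, 2))
        assert steric_field(mol, grid)[0] == STERIC_CUTOFF_KCAL


class TestElectrostaticField:
    def test_zero_probe_charge(self):
        mol = single_atom(charge=0.7)
        grid = GridSpec((2.0, 0.0, 0.0), 1.0, (2, 2, 2))
        vals = electrostatic_field(mol, grid, ProbeSpec(charge=0.0))
        assert np.allclose(vals, 0.0)

    def test_coulomb_distance_dielectric_then_cutoff(self):
        """q=+1 at 2 A from a +1 probe: 332.0636/(2*2) = 83.0 -> clipped."""
        mol = single_atom(charge=1.0)
        grid = GridSpec((2.0, 0.0, 0.0), 1.0, (2, 2, 2))
        vals = electrostatic_field(mol, grid)
        assert vals[0] == STERIC_CUTOFF_KCAL
        # at 4 A the unclipped value is 332.0636/16
        grid_far = GridSpec((4.0, 0.0, 0.0), 1.0, (2, 2, 2))
        far = electrostatic_field(mol, grid_far)
        assert far[0] == pytest.approx(332.0636 / 16.0, rel=1e-9)

    def test_sign_flip_negates_field(self):
        mol = Molecule("m", [
            Atom.from_element("N", (0.0, 0.0, 0.0), -0.3),
            Atom.from_element("H", (1.0, 0.0, 0.0), 0.3),
        ])
        flipped = Molecule("f", [
            Atom.from_element("N", (0.0, 0.0, 0.0), 0.3),
            Atom.from_element("H", (1.0, 0.0, 0.0), -0.3),
        ])
        grid = make_grid([mol], spacing=2.0, margin=4.0)
        a = electrostatic_field(mol, grid)
        b = electrostatic_field(flipped, grid)
        unclipped = (np.abs(a) < STERIC_CUTOFF_KCAL) & (np.abs(b) < STERIC_CUTOFF_KCAL)
        assert np.allclose(a[unclipped], -b[unclipped], atol=1e-10)


class TestFieldSymmetries:
    def test_rigid_motion_equivariance(self):
        """Rotating molecule and lattice together leaves both fields
        unchanged point-for-point."""
        mol = methane()
        grid = make_grid([mol], spacing=2.0, margin=4.0)
        s0 = steric_field(mol, grid)
        e0 = electrostatic_field(mol, grid)

        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        tr = np.array([0.7, -1.3, 2.1])
        moved = mol.transformed(rot, tr)
        pts = grid.points() @ rot.T + tr  # same lattice, rigidly moved

        def field_at(points, m, kind):
            coords, out = m.coords, []
            # direct evaluation at arbitrary points via a 2x1x1 grid trick
            vals = []
            for p in points:
                g = GridSpec(tuple(p), 1.0, (2, 2, 2))
                f = steric_field(m, g) if kind == "s" else electrostatic_field(m, g)
                vals.append(f[0])
            return np.array(vals)

        s1 = field_at(pts, moved, "s")
        e1 = field_at(pts, moved, "e")
        assert np.allclose(s0, s1, atol=1e-8)
        assert np.allclose(e0, e1, atol=1e-8)

    def test_mirror_symmetry(self):
        mol = methane()
        grid = make_grid([mol], spacing=2.0, margin=4.0)
        s0 = steric_field(mol, grid)
        mirror = np.diag([-1.0, 1.0, 1.0])
        mirrored = mol.transformed(mirror, np.zeros(3))
        # the lattice is symmetric about x=0 here, so mirroring the molecule
        # reverses the x-ordering of the field
        nx, ny, nz = grid.counts
        s1 = steric_field(mirrored, grid).reshape(nx, ny, nz)
        assert np.allclose(s0.reshape(nx, ny, nz), s1[::-1, :, :], atol=1e-8)

    def test_two_atom_additivity_outside_cutoff(self):
        a = single_atom(coords=(-1.0, 0.0, 0.0), charge=0.2, mol_id="a")
        b = single_atom(coords=(1.0, 0.0, 0.0), charge=-0.1, mol_id="b")
        ab = Molecule("ab", [a.atoms[0], b.atoms[0]])
        grid = make_grid([ab], spacing=2.0, margin=4.0)
        sa, sb, sab = (steric_field(m, grid) for m in (a, b, ab))
        ok = (sa < STERIC_CUTOFF_KCAL) & (sb < STERIC_CUTOFF_KCAL) & (
            sab < STERIC_CUTOFF_KCAL)
        assert np.allclose(sab[ok], (sa + sb)[ok], atol=1e-8)
        ea, eb, eab = (electrostatic_field(m, grid) for m in (a, b, ab))
        okE = (np.abs(ea) < 30) & (np.abs(eb) < 30) & (np.abs(eab) < 30)
        assert np.allclose(eab[okE], (ea + eb)[okE], atol=1e-8)


class TestDescriptorAssembly:
    def test_identical_molecules_identical_rows(self):
        m1, m2 = methane(), methane()
        m2.id = "methane2"
        grid = make_grid([m1], spacing=2.0, margin=4.0)
        blocks = [compute_field_block(m, grid) for m in (m1, m2)]
        # add a third, different molecule so columns have spread
        m3 = single_atom(charge=0.4, mol_id="probe3")
        blocks.append(compute_field_block(m3, grid))
        y = pd.Series([0.1, 0.1, 0.9], index=["methane", "methane2", "probe3"])
        table = assemble_descriptor_table(blocks, y, min_sigma=0.0)
        assert np.allclose(table.X.loc["methane"], table.X.loc["methane2"])

    def test_min_sigma_filter_and_empty_error(self, synthetic_default):
        mols, y, _ = synthetic_default
        grid = make_grid(mols[:6])
        blocks = [compute_field_block(m, grid) for m in mols[:6]]
        with pytest.raises(ValueError, match="min_sigma"):
            assemble_descriptor_table(blocks, y[:6], min_sigma=1e9)
        loose = assemble_descriptor_table(blocks, y[:6], min_sigma=0.0)
        tight = assemble_descriptor_table(blocks, y[:6], min_sigma=0.5)
        assert tight.X.shape[1] < loose.X.shape[1]
        # no all-constant columns survive
        assert (tight.X.std(axis=0) > 0).all()

    def test_column_count_and_block_scaling(self, synthetic_default):
        _, _, table = synthetic_default
        meta = table.column_meta
        assert table.X.shape[1] == len(meta)
        assert set(meta["field"]) == {"steric", "electrostatic"}
        # block scaling equalizes total variance between the two fields
        var = table.X.var(axis=0, ddof=1)
        v_s = var[meta.index[meta["field"] == "steric"]].sum()
        v_e = var[meta.index[meta["field"] == "electrostatic"]].sum()
        assert v_s == pytest.approx(v_e, rel=1e-6)

    def test_grid_mismatch_raises(self):
        m = methane()
        g1 = make_grid([m], spacing=2.0, margin=4.0)
        g2 = make_grid([m], spacing=2.0, margin=6.0)
        b1 = compute_field_block(m, g1)
        b2 = compute_field_block(m, g2)
        y = pd.Series([0.1, 0.2], index=["methane", "methane"])
        with pytest.raises(ValueError, match="grid"):
            assemble_descriptor_table([b1, b2], y)

    def test_transform_matches_training_rows(self, synthetic_default):
        """Re-transforming the training molecules through the stored
        preprocessing reproduces the training design matrix."""
        mols, y, table = synthetic_default
        blocks = [compute_field_block(m, table.grid) for m in mols]
        X2 = table.transform(blocks)
        assert np.allclose(X2.to_numpy(), table.X.to_numpy(), atol=1e-10)
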