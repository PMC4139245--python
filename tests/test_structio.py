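import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexshell.errors import (
    CapacityError,
    EmptyStructureError,
    PDBParseError,
    ValidationError,
)
from hexshell.structio import (
    Atom,
    CrystalCell,
    RigidTransform,
    StructureModel,
    apply_transform,
    chain_label,
    expand_neighbors,
    lattice_translation_length,
    load_config,
    radii_from_config,
    read_structure,
    write_structure,
)

TYPE_I_CELL = CrystalCell(45.2, 93.3, 63.1, 90.0, 105.0, 90.0, "P 1 21 1")
HEX_CELL = CrystalCell(67.2, 67.2, 20.0, 90.0, 90.0, 120.0, "P 622")


def one_atom_model(pos=(1.0, 2.0, 3.0)):
    return StructureModel.from_atoms(
        [Atom(1, "CA", "C", 1, "ALA", "A", np.array(pos), 1.7)]
    )


class TestPDBRoundTrip:
    def test_single_atom_round_trip(self, tmp_path):
        path = tmp_path / "one.pdb"
        write_structure(one_atom_model(), path)
        back = read_structure(path)
        assert back.n_atoms == 1
        np.testing.assert_allclose(back.coords[0], [1.0, 2.0, 3.0], atol=1e-3)
        assert back.elements[0] == "C"

    def test_hexamer_round_trip_to_pdb_precision(self, ideal_hexamer, tmp_path):
        path = tmp_path / "hex.pdb"
        write_structure(ideal_hexamer, path)
        back = read_structure(path)
        assert back.n_atoms == ideal_hexamer.n_atoms
        assert back.chains == ideal_hexamer.chains
        np.testing.assert_allclose(back.coords, ideal_hexamer.coords, atol=1e-3)
        # idempotence: a second round trip is exact
        path2 = tmp_path / "hex2.pdb"
        write_structure(back, path2)
        again = read_structure(path2)
        np.testing.assert_allclose(again.coords, back.coords, atol=0)

    def test_cell_round_trip(self, tmp_path):
        model = one_atom_model()
        model.cell = TYPE_I_CELL
        path = tmp_path / "cell.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.cell is not None
        assert back.cell.a == pytest.approx(45.2)
        assert back.cell.b == pytest.approx(93.3)
        assert back.cell.c == pytest.approx(63.1)
        assert back.cell.beta == pytest.approx(105.0)
        assert back.cell.space_group_label == "P 1 21 1"

    def test_gemmi_reads_our_output(self, ideal_hexamer, tmp_path):
        gemmi = pytest.importorskip("gemmi")
        path = tmp_path / "hex.pdb"
        write_structure(ideal_hexamer, path)
        st_ = gemmi.read_structure(str(path))
        atoms = [a for mdl in st_ for ch in mdl for res in ch for a in res]
        assert len(atoms) == ideal_hexamer.n_atoms
        theirs = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
        np.testing.assert_allclose(
            np.sort(theirs, axis=0), np.sort(ideal_hexamer.coords, axis=0), atol=1e-3
        )

    def test_many_chain_assembly_uses_two_char_labels(self, ideal_hexamer, tmp_path):
        # 12 hexamers -> 72 chains, beyond the 62 single-character labels
        assembly = expand_neighbors(
            ideal_hexamer, HEX_CELL, [(i, j, 0) for i in range(4) for j in range(3)]
        )
        assert len(assembly.chains) == 72
        assert any(len(c) == 2 for c in assembly.chains)
        path = tmp_path / "big.pdb"
        write_structure(assembly, path)
        text = path.read_text()
        assert text.count("\nTER") + text.startswith("TER") == 72
        back = read_structure(path)
        assert back.chains == assembly.chains

    def test_malformed_coordinates_report_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        good = "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C"
        bad = good[:30] + "  xx.xxx" + good[38:]
        path.write_text(good + "\n" + bad + "\n")
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(path)

    def test_empty_structure_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_structure(path)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C",
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path)
        assert model.n_atoms == 1
        assert model.coords[0, 0] == pytest.approx(5.0)

    def test_hetatm_flagged(self, tmp_path):
        lines = [
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C",
            "HETATM    2  O1  GOL A 201      10.000   0.000   0.000  1.00  0.00           O",
        ]
        path = tmp_path / "het.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path)
        assert list(model.het) == [False, True]

    def test_capacity_error_above_serial_width(self):
        model = one_atom_model()
        # fake a big model cheaply by patching the atom count check path
        big = model.copy()
        with pytest.raises(CapacityError):
            big_n = 100000
            big2 = StructureModel(
                serials=np.arange(big_n),
                names=np.full(big_n, "X", dtype=object),
                elements=np.full(big_n, "C", dtype=object),
                res_numbers=np.arange(big_n),
                res_names=np.full(big_n, "ALA", dtype=object),
                chain_ids=np.full(big_n, "A", dtype=object),
                coords=np.zeros((big_n, 3)),
                radii=np.full(big_n, 1.7),
                het=np.zeros(big_n, dtype=bool),
            )
            write_structure(big2, "/dev/null")


class TestRigidTransform:
    def test_identity_leaves_coordinates(self, ideal_hexamer):
        out = apply_transform(ideal_hexamer, RigidTransform.identity())
        np.testing.assert_array_equal(out.coords, ideal_hexamer.coords)

    def test_sixty_degree_rotation_superposes_hexamer(self, aligned_hexamer):
        t = RigidTransform.rotation_about_axis([0, 0, 1], 60.0)
        rotated = apply_transform(aligned_hexamer, t)
        # chain k rotates onto chain k+1: compare against rolled coordinates
        per = aligned_hexamer.n_atoms // 6
        rolled = np.roll(aligned_hexamer.coords.reshape(6, per, 3), -1, axis=0)
        rmsd = np.sqrt(np.mean(np.sum((rotated.coords.reshape(6, per, 3) - rolled) ** 2, axis=-1)))
        assert rmsd < 1e-6

    def test_translation_by_lattice_spacing(self, ideal_hexamer):
        t = RigidTransform.translation_by([67.2, 0.0, 0.0])
        moved = apply_transform(ideal_hexamer, t)
        shift = np.linalg.norm(moved.center() - ideal_hexamer.center())
        assert shift == pytest.approx(67.2, abs=1e-9)

    def test_distances_preserved(self, ideal_hexamer):
        t = RigidTransform.rotation_about_axis([1, 2, 3], 37.0, center=[5, -4, 2])
        moved = apply_transform(ideal_hexamer, t)
        d0 = np.linalg.norm(ideal_hexamer.coords[0] - ideal_hexamer.coords[-1])
        d1 = np.linalg.norm(moved.coords[0] - moved.coords[-1])
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    def test_reflection_rejected(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_compose_and_inverse(self):
        t = RigidTransform.rotation_about_axis([0, 1, 0], 45.0, center=[1, 2, 3])
        ident = t.compose(t.inverse())
        np.testing.assert_allclose(ident.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(ident.translation, 0.0, atol=1e-12)


class TestLatticeGeometry:
    def test_type_one_cell_ac_diagonal(self):
        # the 1-D tiling direction of the first mutant crystal form
        assert lattice_translation_length(TYPE_I_CELL, (1, 0, 1)) == pytest.approx(
            67.4, abs=0.1
        )

    def test_a_axis_reads_a(self):
        assert lattice_translation_length(TYPE_I_CELL, (1, 0, 0)) == pytest.approx(45.2)

    def test_orthogonal_closed_form(self):
        cell = CrystalCell(3, 4, 5)
        assert lattice_translation_length(cell, (1, 1, 1)) == pytest.approx(
            math.sqrt(50), abs=1e-9
        )

    def test_zero_triple_rejected(self):
        with pytest.raises(ValidationError):
            lattice_translation_length(TYPE_I_CELL, (0, 0, 0))

    @given(
        u=st.integers(-4, 4), v=st.integers(-4, 4), w=st.integers(-4, 4)
    )
    @settings(max_examples=50, deadline=None)
    def test_sign_flip_symmetry(self, u, v, w):
        if (u, v, w) == (0, 0, 0):
            return
        a = lattice_translation_length(TYPE_I_CELL, (u, v, w))
        b = lattice_translation_length(TYPE_I_CELL, (-u, -v, -w))
        assert a == pytest.approx(b, rel=1e-12)

    @given(
        u=st.integers(-3, 3), v=st.integers(-3, 3), w=st.integers(-3, 3),
        a=st.floats(1.0, 100.0), b=st.floats(1.0, 100.0), c=st.floats(1.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_orthorhombic_equals_euclidean_norm(self, u, v, w, a, b, c):
        if (u, v, w) == (0, 0, 0):
            return
        cell = CrystalCell(a, b, c)
        expected = math.sqrt((u * a) ** 2 + (v * b) ** 2 + (w * c) ** 2)
        assert lattice_translation_length(cell, (u, v, w)) == pytest.approx(
            expected, rel=1e-9
        )


class TestExpandNeighbors:
    def test_identity_expansion(self, ideal_hexamer):
        out = expand_neighbors(ideal_hexamer, HEX_CELL, [(0, 0, 0)])
        np.testing.assert_allclose(out.coords, ideal_hexamer.coords, atol=0)

    def test_six_in_plane_neighbors_at_native_spacing(self, ideal_hexamer):
        indices = [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (1, 1, 0), (-1, -1, 0)]
        out = expand_neighbors(ideal_hexamer, HEX_CELL, indices)
        from hexshell.symtile import hexamer_centers

        centers = hexamer_centers(out)
        d = np.linalg.norm(centers[1:] - centers[0], axis=1)
        np.testing.assert_allclose(d, 67.2, atol=1e-9)

    def test_pair_along_type_one_diagonal(self, ideal_hexamer):
        out = expand_neighbors(ideal_hexamer, TYPE_I_CELL, [(0, 0, 0), (1, 0, 1)])
        from hexshell.symtile import hexamer_centers

        centers = hexamer_centers(out)
        assert np.linalg.norm(centers[1] - centers[0]) == pytest.approx(67.4, abs=0.1)

    def test_internal_geometry_preserved(self, ideal_hexamer):
        out = expand_neighbors(ideal_hexamer, HEX_CELL, [(0, 0, 0), (2, 1, 0)])
        n = ideal_hexamer.n_atoms
        for sl in (slice(0, n), slice(n, 2 * n)):
            d = np.linalg.norm(out.coords[sl][0] - out.coords[sl][-1])
            d0 = np.linalg.norm(ideal_hexamer.coords[0] - ideal_hexamer.coords[-1])
            assert d == pytest.approx(d0, abs=1e-9)

    def test_duplicate_indices_rejected(self, ideal_hexamer):
        with pytest.raises(ValidationError):
            expand_neighbors(ideal_hexamer, HEX_CELL, [(0, 0, 0), (0, 0, 0)])


class TestConfig:
    def test_radii_override(self, tmp_path):
        cfg = tmp_path / "radii.cfg"
        cfg.write_text("# AREAIMOL-style radii\nradius.C = 1.90\nradius.N = 1.70\n")
        table = radii_from_config(load_config(cfg))
        assert table["C"] == 1.90
        assert table["N"] == 1.70
        assert table["O"] == 1.52  # untouched default

    def test_chain_label_scheme(self):
        assert chain_label(0) == "A"
        assert chain_label(61) == "9"
        assert chain_label(62) == "AA"
        assert chain_label(63) == "AB"
        labels = {chain_label(i) for i in range(200)}
        assert len(labels) == 200
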