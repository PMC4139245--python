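import numpy as np
import pytest

from hexshell.errors import SelectionError, ValidationError
from hexshell.porecontact import (
    compare_interfaces,
    detect_hbonds,
    pore_profile,
    probe_fit,
)
from hexshell.structio import (
    Atom,
    RigidTransform,
    StructureModel,
    apply_transform,
)
from hexshell.symtile import fit_symmetry_axis
from hexshell.synthgen import HexamerSpec, make_ideal_hexamer


def polar_pair(distance, with_antecedent=True, antecedent_angle_deg=180.0):
    """An N (with optional covalent antecedent C) and an O ``distance`` apart."""
    atoms = [
        Atom(1, "N", "N", 1, "GLY", "A", np.array([0.0, 0.0, 0.0]), 1.55),
        Atom(2, "O", "O", 2, "GLY", "B", np.array([distance, 0.0, 0.0]), 1.52),
    ]
    if with_antecedent:
        th = np.radians(antecedent_angle_deg)
        atoms.append(
            Atom(
                3, "CA", "C", 1, "GLY", "A",
                np.array([1.4 * np.cos(th), 1.4 * np.sin(th), 0.0]), 1.7,
            )
        )
    return StructureModel.from_atoms(atoms)


class TestHBondDetection:
    def test_single_bond_at_hbond_distance(self):
        bonds = detect_hbonds(polar_pair(2.9), require_geometry=True)
        assert len(bonds) == 1
        b = bonds[0]
        assert b.donor_atom == "N" and b.acceptor_atom == "O"
        assert b.distance == pytest.approx(2.9)

    def test_beyond_cutoff_empty(self):
        assert detect_hbonds(polar_pair(4.0)) == []

    def test_geometry_filter_rejects_blocked_donor(self):
        # antecedent between donor and acceptor: angle 0 -> rejected
        model = polar_pair(2.9, antecedent_angle_deg=0.0)
        assert detect_hbonds(model, require_geometry=True) == []
        assert len(detect_hbonds(model, require_geometry=False)) == 1

    def test_covalent_range_excluded(self):
        assert detect_hbonds(polar_pair(1.3)) == []

    def test_classification_uses_chain_groups(self, hexamer_pair):
        bonds = detect_hbonds(hexamer_pair, d_max=6.0)
        classes = {b.bond_class for b in bonds}
        assert "inter-hexamer" in classes
        inter = [b for b in bonds if b.bond_class == "inter-hexamer"]
        # residue-26 amine pairs face each other across the interface
        assert any(
            b.donor_residue == 26 and b.acceptor_residue == 26 for b in inter
        )

    def test_invariant_under_rigid_motion(self, hexamer_pair):
        t = RigidTransform.rotation_about_axis([1, 1, 0], 53.0, center=[3, 4, 5])
        moved = apply_transform(hexamer_pair, t)
        a = detect_hbonds(hexamer_pair, d_max=6.0)
        b = detect_hbonds(moved, d_max=6.0)
        assert [x.key for x in a] == [y.key for y in b]
        np.testing.assert_allclose(
            [x.distance for x in a], [y.distance for y in b], atol=1e-9
        )


class TestInterfaceComparison:
    def test_identical_reports_all_shared(self):
        bonds = detect_hbonds(polar_pair(2.9))
        cmp = compare_interfaces(bonds, bonds)
        assert len(cmp.shared) == 1
        assert cmp.only_a == [] and cmp.only_b == []

    def test_disjoint_reports(self):
        a = detect_hbonds(polar_pair(2.9))
        other = StructureModel.from_atoms(
            [
                Atom(1, "NZ", "N", 26, "LYS", "A", np.array([0.0, 0.0, 0.0]), 1.55),
                Atom(2, "O", "O", 79, "ARG", "B", np.array([2.9, 0.0, 0.0]), 1.52),
            ]
        )
        b = detect_hbonds(other)
        cmp = compare_interfaces(a, b)
        assert cmp.shared == []
        assert len(cmp.only_a) == 1 and len(cmp.only_b) == 1

    def test_native_versus_mutant_style_contrast(self):
        # one inventory with a single lysine-to-carbonyl bond, the other with
        # an arginine bonding three partners: 0 shared, 1 only-A, 3 only-B
        def bond_model(pairs):
            atoms = []
            serial = 1
            for k, (dres, dname, ares, aname) in enumerate(pairs):
                z = 10.0 * k
                atoms.append(Atom(serial, "NZ" if dname == "LYS" else "NH1", "N",
                                  dres, dname, "A", np.array([0.0, 0.0, z]), 1.55))
                serial += 1
                atoms.append(Atom(serial, "O", "O", ares, aname, "B",
                                  np.array([2.9, 0.0, z]), 1.52))
                serial += 1
            return StructureModel.from_atoms(atoms)

        native = detect_hbonds(bond_model([(26, "LYS", 80, "GLY")]))
        mutant = detect_hbonds(
            bond_model([(79, "ARG", 22, "ASP"), (79, "ARG", 83, "GLY"),
                        (79, "ARG", 84, "GLY")])
        )
        cmp = compare_interfaces(native, mutant)
        assert len(cmp.shared) == 0
        assert len(cmp.only_a) == 1
        assert len(cmp.only_b) == 3

    def test_empty_vs_empty(self):
        cmp = compare_interfaces([], [])
        assert cmp.shared == [] and cmp.only_a == [] and cmp.only_b == []


class TestPoreProfile:
    def test_cross_separations_of_ideal_hexamer(self, ideal_hexamer):
        fit = fit_symmetry_axis(ideal_hexamer, 6)
        prof = pore_profile(ideal_hexamer, fit)
        seps = list(prof.cross_separations.values())
        assert len(seps) == 3
        np.testing.assert_allclose(seps, 9.0, atol=1e-9)  # 2 x 4.5 A circle
        assert prof.anisotropy == pytest.approx(0.0, abs=1e-9)
        assert prof.min_radius == pytest.approx(4.5 - 1.55, abs=0.05)

    def test_stretched_pore_is_anisotropic(self, ideal_hexamer):
        # stretch one cross axis by 0.7 A on both sides
        stretched = ideal_hexamer.copy()
        mask = (stretched.res_numbers == 40) & np.isin(
            stretched.chain_ids.astype(str), ["A", "D"]
        )
        xy = stretched.coords[mask][:, :2]
        direction = xy / np.linalg.norm(xy, axis=1, keepdims=True)
        stretched.coords[mask, :2] += 0.7 * direction
        fit = fit_symmetry_axis(stretched, 6)
        prof = pore_profile(stretched, fit)
        seps = prof.cross_separations
        sep_ad = seps[("A", "D")]
        others = [v for k, v in seps.items() if k != ("A", "D")]
        assert sep_ad > max(others)
        assert prof.anisotropy == pytest.approx(1.4, abs=0.1)

    def test_ring_of_atoms_closed_form(self):
        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        atoms = [
            Atom(i + 1, "X", "C", 1, "ALA", "ABCDEF"[i % 6],
                 np.array([3 * np.cos(a), 3 * np.sin(a), 0.0]), 1.5)
            for i, a in enumerate(angles)
        ]
        model = StructureModel.from_atoms(atoms)
        from hexshell.symtile import SymmetryFit

        fit = SymmetryFit(np.array([0, 0, 1.0]), np.zeros(3), 6, 0.0)
        with pytest.raises(SelectionError):
            pore_profile(model, fit)  # no residue-40 pore-loop atoms
        prof = pore_profile(model, fit, loop_atom_spec=(1, "X"))
        assert prof.min_radius == pytest.approx(1.5, abs=1e-9)

    def test_missing_loop_atom_names_chain(self, ideal_hexamer):
        fit = fit_symmetry_axis(ideal_hexamer, 6)
        with pytest.raises(SelectionError, match="chain A"):
            pore_profile(ideal_hexamer, fit, loop_atom_spec=(40, "CA"))

    def test_min_radius_non_increasing_when_atoms_added(self, ideal_hexamer):
        fit = fit_symmetry_axis(ideal_hexamer, 6)
        base = pore_profile(ideal_hexamer, fit)
        # narrow the pore by moving one body residue ring inward
        extra = ideal_hexamer.copy()
        mask = extra.res_numbers == 101
        extra.coords[mask, 0] *= 0.4
        prof2 = pore_profile(extra, fit)
        assert prof2.min_radius <= base.min_radius + 1e-9


class TestProbeFit:
    def test_zero_probe_always_passes(self, ideal_hexamer):
        fit = fit_symmetry_axis(ideal_hexamer, 6)
        prof = pore_profile(ideal_hexamer, fit)
        res = probe_fit(prof, 0.0)
        assert all(res.passes)
        assert res.spans_thickness

    def test_oversized_probe_always_fails(self, ideal_hexamer):
        fit = fit_symmetry_axis(ideal_hexamer, 6)
        prof = pore_profile(ideal_hexamer, fit)
        res = probe_fit(prof, 100.0)
        assert not any(res.passes)

    def test_glycerol_scale_probe_passes_through(self):
        # pore sized for a 3.0-A minimum radius; a 2.6-A probe passes
        spec = HexamerSpec(pore_radius=4.55)
        hx = make_ideal_hexamer(spec)
        fit = fit_symmetry_axis(hx, 6)
        prof = pore_profile(hx, fit)
        assert prof.min_radius == pytest.approx(3.0, abs=0.05)
        res = probe_fit(prof, 2.6)
        assert res.spans_thickness

    def test_negative_probe_rejected(self, ideal_hexamer):
        fit = fit_symmetry_axis(ideal_hexamer, 6)
        prof = pore_profile(ideal_hexamer, fit)
        with pytest.raises(ValidationError):
            probe_fit(prof, -1.0)
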