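import numpy as np
import pytest

from tham.databank import (AtomType, LocalFrameDef, assign_atom_types,
                           build_bank, derive_atom_types, detect_bonds,
                           local_frame, read_bank, resolve_frame_refs,
                           transfer, write_bank)
from tham.density import make_fixture, rotate_spec
from tham.errors import BankError, InvalidParameterError, ParseError
from tham.scattering import form_factor_multipole

from .conftest import random_rotation


class TestBonds:
    def test_water_topology(self, water_spec):
        adj = detect_bonds(water_spec.elements, water_spec.positions)
        assert sorted(adj[0]) == [1, 2]
        assert adj[1] == [0] and adj[2] == [0]

    def test_single_atom(self):
        assert detect_bonds(["C"], [[0, 0, 0]]) == [[]]

    def test_distant_atoms_unbonded(self):
        adj = detect_bonds(["C", "C"], [[0, 0, 0], [10.0, 0, 0]])
        assert adj == [[], []]

    def test_overlapping_atoms_rejected(self):
        with pytest.raises(InvalidParameterError, match="overlap"):
            detect_bonds(["C", "C"], [[0, 0, 0], [0.1, 0, 0]])


class TestTyping:
    def test_water_types(self, water_spec):
        adj = detect_bonds(water_spec.elements, water_spec.positions)
        types = derive_atom_types(water_spec.elements, adj)
        assert set(types) == {"O(HH)", "H(O)"}
        labels = assign_atom_types(water_spec.elements, adj,
                                   list(types.values()))
        assert labels == ["O(HH)", "H(O)", "H(O)"]

    def test_missing_type_flags_untyped(self):
        elements = ["C", "H", "H", "H", "H"]
        d = 1.09 / np.sqrt(3)
        pos = [[0, 0, 0], [d, d, d], [-d, -d, d], [-d, d, -d], [d, -d, -d]]
        adj = detect_bonds(elements, pos)
        bank_types = [AtomType("H(C)", "H", ("C",),
                               LocalFrameDef("C", "H"))]
        labels = assign_atom_types(elements, adj, bank_types)
        assert labels[0] is None
        assert labels[1:] == ["H(C)"] * 4

    def test_permutation_invariance(self, water_spec):
        adj = detect_bonds(water_spec.elements, water_spec.positions)
        types = list(derive_atom_types(water_spec.elements, adj).values())
        labels = assign_atom_types(water_spec.elements, adj, types)
        perm = [2, 0, 1]
        elements_p = [water_spec.elements[i] for i in perm]
        pos_p = water_spec.positions[perm]
        adj_p = detect_bonds(elements_p, pos_p)
        labels_p = assign_atom_types(elements_p, adj_p, types)
        assert labels_p == [labels[i] for i in perm]

    def test_ambiguous_bank_rejected(self):
        type_a = AtomType("A", "O", ("H", "H"), LocalFrameDef("H", "H"))
        type_b = AtomType("B", "O", ("H", "H"), LocalFrameDef("H", "H"))
        with pytest.raises(BankError, match="ambiguous"):
            assign_atom_types(["O"], [[]], [type_a, type_b])


class TestLocalFrame:
    def test_z_axis_by_construction(self):
        pos = np.array([[0, 0, 0], [0, 0, 1.0], [0.8, 0, 1.5]])
        M = local_frame(pos, 0, 1, 2)
        np.testing.assert_allclose(M[2], [0, 0, 1.0], atol=1e-14)
        assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-12)

    def test_rigid_rotation_covariance(self):
        rng = np.random.default_rng(0)
        pos = np.array([[0, 0, 0], [0, 0, 1.0], [0.8, 0.3, 1.5]])
        M = local_frame(pos, 0, 1, 2)
        rot = random_rotation(rng)
        M_new = local_frame(pos @ rot.T, 0, 1, 2)
        np.testing.assert_allclose(M_new, M @ rot.T, atol=1e-10)

    def test_handedness_for_random_geometries(self):
        rng = np.random.default_rng(1)
        n_ok = 0
        while n_ok < 100:
            pos = rng.normal(size=(3, 3))
            try:
                M = local_frame(pos, 0, 1, 2)
            except (BankError, InvalidParameterError):
                continue
            assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-12)
            n_ok += 1

    def test_collinear_references_rejected(self):
        pos = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 2.0]])
        with pytest.raises(BankError, match="collinear"):
            local_frame(pos, 0, 1, 2)

    def test_terminal_atom_uses_second_shell(self, water_spec):
        adj = detect_bonds(water_spec.elements, water_spec.positions)
        frame_def = LocalFrameDef(z_ref="O", xz_ref="H")
        z_idx, xz_idx = resolve_frame_refs(water_spec.elements,
                                           water_spec.positions, adj, 1,
                                           frame_def)
        assert z_idx == 0 and xz_idx == 2


class TestBuildBank:
    def test_single_instance_average(self, water_spec, water_bank):
        assert {e.atom_type.label for e in water_bank} == {"O(HH)", "H(O)"}
        by_label = {e.atom_type.label: e for e in water_bank}
        assert by_label["O(HH)"].n_instances == 1
        assert by_label["H(O)"].n_instances == 2

    def test_rotated_instances_average_to_same_entry(self, water_spec):
        rng = np.random.default_rng(2)
        rotated = rotate_spec(water_spec, random_rotation(rng))
        bank2 = build_bank([water_spec, rotated])
        bank1 = build_bank([water_spec])
        e1 = {e.atom_type.label: e for e in bank1}
        e2 = {e.atom_type.label: e for e in bank2}
        for label in e1:
            np.testing.assert_allclose(e2[label].density.coefficients,
                                       e1[label].density.coefficients,
                                       atol=1e-8)

    def test_averaging_idempotence(self, water_spec, water_bank):
        bank3 = build_bank([water_spec, water_spec, water_spec])
        e1 = {e.atom_type.label: e for e in water_bank}
        for e in bank3:
            np.testing.assert_allclose(
                e.density.coefficients,
                e1[e.atom_type.label].density.coefficients, atol=1e-12)

    def test_mean_population_linearity(self, water_spec):
        other = make_fixture("water-like", seed=5)
        bank_a = build_bank([water_spec])
        bank_b = build_bank([other])
        bank_ab = build_bank([water_spec, other])
        for label in ("O(HH)", "H(O)"):
            pa = next(e for e in bank_a
                      if e.atom_type.label == label).density.population
            pb = next(e for e in bank_b
                      if e.atom_type.label == label).density.population
            pab = next(e for e in bank_ab
                       if e.atom_type.label == label).density.population
            assert pab == pytest.approx((pa + pb) / 2, abs=1e-10)

    def test_bank_from_all_fixtures(self):
        """Types shared across fixtures (e.g. hydroxyl H) resolve frames
        in every environment, falling back when the preferred reference
        element is absent."""
        specs = [make_fixture(n, seed=0)
                 for n in ("water-like", "ethanol-like", "urea-like")]
        entries = build_bank(specs)
        labels = {e.atom_type.label for e in entries}
        assert "H(O)" in labels and "O(CH)" in labels
        ho = next(e for e in entries if e.atom_type.label == "H(O)")
        assert ho.n_instances == 3  # two water H, one hydroxyl H

    def test_missing_type_instance_rejected(self, water_spec):
        ghost = AtomType("N(CC)", "N", ("C", "C"), LocalFrameDef("C", "C"))
        with pytest.raises(BankError, match="no instance"):
            build_bank([water_spec], types=[ghost])


class TestBankIO:
    def test_round_trip_identity(self, water_bank, tmp_path):
        path = tmp_path / "bank.txt"
        write_bank(water_bank, path)
        restored = read_bank(path)
        assert len(restored) == len(water_bank)
        for a, b in zip(water_bank, restored):
            assert a.atom_type == b.atom_type
            assert a.n_instances == b.n_instances
            np.testing.assert_array_equal(a.density.coefficients,
                                          b.density.coefficients)
            np.testing.assert_array_equal(a.density.radial_grid.nodes,
                                          b.density.radial_grid.nodes)

    def test_truncated_coefficient_block(self, water_bank, tmp_path):
        path = tmp_path / "bank.txt"
        write_bank(water_bank, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-3]) + "\n")
        with pytest.raises(ParseError, match="coefficient rows"):
            read_bank(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bank.txt"
        path.write_text("NOT-A-BANK v9\n")
        with pytest.raises(ParseError, match="header"):
            read_bank(path)

    def test_52_entry_bank_capacity(self, water_bank, tmp_path):
        """A bank of 52 types (the scale of a small-molecule databank)
        writes, reads and validates."""
        template = water_bank[0]
        entries = []
        for k in range(52):
            t = AtomType(label=f"T{k}(HH)", element="O",
                         neighbor_signature=("H", "H"),
                         frame=LocalFrameDef("H", "H"))
            entries.append(type(template)(atom_type=t,
                                          density=template.density,
                                          n_instances=3))
        path = tmp_path / "big.txt"
        write_bank(entries, path)
        restored = read_bank(path)
        assert len(restored) == 52


class TestTransfer:
    def test_self_transfer_fidelity(self, water_spec, water_bank):
        """Transferred form factors on the bank's own source match the
        directly projected ones within 1e-8."""
        from tham.databank import (detect_bonds, derive_atom_types,
                                   resolve_frame_refs, local_frame)
        from tham.density import atomic_density_on_grid
        from tham.multipole import project_multipoles
        from tham.quadrature import (angular_grid, atomic_grid,
                                     element_radial_scale,
                                     mura_knowles_radial)
        tr = transfer(water_bank, water_spec.elements, water_spec.positions)
        rng = np.random.default_rng(3)
        u = rng.normal(size=(100, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        S = u * rng.uniform(0.05, 1.5, 100)[:, None]
        adj = detect_bonds(water_spec.elements, water_spec.positions)
        ang = angular_grid(590)
        for i in range(water_spec.n_atoms):
            t = tr[i]
            el = water_spec.elements[i]
            grid = atomic_grid(
                mura_knowles_radial(75, element_radial_scale(el)), ang)
            values = atomic_density_on_grid(water_spec, i, grid, t.frame)
            md = project_multipoles(values, grid, l_max=7)
            f_direct = form_factor_multipole(md, S @ t.frame.T)
            f_transfer = form_factor_multipole(t.density, S @ t.frame.T)
            if i == 0:  # O averaged over 1 instance: identical
                np.testing.assert_allclose(f_transfer, f_direct, atol=1e-8)

    def test_rotated_copy_covariance(self, water_spec, water_bank):
        """Bank from the original applied to a rotated copy reproduces the
        rotated copy's own form factors within 1e-6 relative."""
        rng = np.random.default_rng(4)
        rot = random_rotation(rng)
        rotated = rotate_spec(water_spec, rot)
        bank_rot = build_bank([rotated])
        tr_a = transfer(water_bank, rotated.elements, rotated.positions)
        tr_b = transfer(bank_rot, rotated.elements, rotated.positions)
        u = rng.normal(size=(100, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        S = u * rng.uniform(0.05, 1.5, 100)[:, None]
        for a, b in zip(tr_a, tr_b):
            fa = form_factor_multipole(a.density, S @ a.frame.T)
            fb = form_factor_multipole(b.density, S @ b.frame.T)
            f0 = abs(form_factor_multipole(b.density, np.zeros(3)))
            assert np.max(np.abs(fa - fb)) / f0 < 1e-6

    def test_equivalent_atoms_share_entry(self, water_spec, water_bank):
        tr = transfer(water_bank, water_spec.elements, water_spec.positions)
        assert tr[1].density is tr[2].density
        assert np.max(np.abs(tr[1].frame - tr[2].frame)) > 1e-3

    def test_untyped_policies(self, water_bank):
        elements = ["O", "O"]
        pos = [[0, 0, 0], [0, 0, 1.4]]
        with pytest.raises(BankError, match="no bank type"):
            transfer(water_bank, elements, pos, policy="strict")
        out = transfer(water_bank, elements, pos, policy="skip")
        assert out == [None, None]

    def test_perturbed_fixture_error_is_larger(self, water_spec,
                                               water_bank):
        """Transferring to a perturbed-density structure gives a larger
        (but finite) deviation than self-transfer."""
        from tham.density import DensitySpec, Deformation
        perturbed = DensitySpec(
            elements=water_spec.elements,
            positions=water_spec.positions,
            atom_densities=water_spec.atom_densities,
            deformations=tuple(
                Deformation(center=d.center, amplitude=1.2 * d.amplitude,
                            exponent=d.exponent)
                for d in water_spec.deformations),
            name="water-like-perturbed")
        bank_p = build_bank([perturbed])
        rng = np.random.default_rng(6)
        u = rng.normal(size=(50, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        S = u * rng.uniform(0.05, 1.5, 50)[:, None]
        tr_orig = transfer(water_bank, perturbed.elements,
                           perturbed.positions)
        tr_self = transfer(bank_p, perturbed.elements, perturbed.positions)
        dev = 0.0
        for a, b in zip(tr_orig, tr_self):
            fa = form_factor_multipole(a.density, S @ a.frame.T)
            fb = form_factor_multipole(b.density, S @ b.frame.T)
            dev = max(dev, float(np.max(np.abs(fa - fb))))
        assert 1e-8 < dev < 1.0
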