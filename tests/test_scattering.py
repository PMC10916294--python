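import numpy as np
import pytest

from tham.density import (analytic_molecular_ff, atomic_density_on_grid,
                          rotate_spec)
from tham.errors import InvalidParameterError
from tham.multipole import project_multipoles
from tham.quadrature import (angular_grid, atomic_grid, element_radial_scale,
                             mura_knowles_radial)
from tham.scattering import (ScatteringVector, form_factor_direct,
                             form_factor_multipole, hankel_transform,
                             rotate_scattering)

from .conftest import random_rotation


@pytest.fixture(scope="module")
def grid():
    return atomic_grid(mura_knowles_radial(75, 5.0), angular_grid(590))


@pytest.fixture(scope="module")
def oxygen_projection(water_spec):
    grid = atomic_grid(mura_knowles_radial(75, element_radial_scale("O")),
                       angular_grid(590))
    values = atomic_density_on_grid(water_spec, 0, grid)
    return grid, values, project_multipoles(values, grid, l_max=9)


def random_s(rng, n, s_max=1.5, s_min=0.05):
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * rng.uniform(s_min, s_max, n)[:, None]


class TestDirect:
    def test_zero_angle_gives_population(self, grid):
        rho = np.exp(-np.sum(grid.points ** 2, axis=1)) / np.pi ** 1.5
        f0 = form_factor_direct(rho, grid, np.zeros(3))
        assert f0.imag == pytest.approx(0.0, abs=1e-12)
        assert f0.real == pytest.approx(1.0, abs=1e-6)

    def test_unit_gaussian_closed_form(self, grid):
        rho = np.exp(-np.sum(grid.points ** 2, axis=1))
        f = form_factor_direct(rho, grid, [0.5, 0.0, 0.0])
        expected = np.pi ** 1.5 * np.exp(-np.pi ** 2 * 0.25)
        assert f.real == pytest.approx(expected, abs=1e-8)

    def test_centrosymmetric_density_is_real(self, grid):
        rho = np.exp(-2.0 * np.sum(grid.points ** 2, axis=1))
        f = form_factor_direct(rho, grid, [0.3, -0.4, 0.2])
        assert abs(f.imag) < 1e-10


class TestHankel:
    def test_gaussian_monopole_at_zero(self, grid):
        md = project_multipoles(
            np.exp(-np.sum(grid.points ** 2, axis=1)), grid, l_max=2)
        h0 = hankel_transform(md, 0, 0.0)
        expected = np.sqrt(4 * np.pi) * np.sqrt(np.pi) / 4
        assert h0[0] == pytest.approx(expected, abs=1e-8)

    def test_large_s_decay(self, water_spec):
        """Riemann-Lebesgue decay: at s=20 1/A every Hankel row is tiny.

        The radial quadrature must resolve the j_l oscillations (period
        1/(2 pi s)), so this check runs on a 300-node grid.
        """
        grid = atomic_grid(mura_knowles_radial(300, 4.34),
                           angular_grid(590))
        values = atomic_density_on_grid(water_spec, 0, grid)
        md = project_multipoles(values, grid, l_max=5)
        for l in (0, 2, 5):
            assert np.max(np.abs(hankel_transform(md, l, 20.0))) < 1e-6

    def test_higher_rows_of_monopole_vanish(self, grid):
        md = project_multipoles(
            np.exp(-np.sum(grid.points ** 2, axis=1)), grid, l_max=3)
        assert np.max(np.abs(hankel_transform(md, 2, 0.7))) < 1e-12


class TestMultipoleRoute:
    def test_spherical_atom_matches_direct(self, grid):
        rho = np.exp(-np.sum(grid.points ** 2, axis=1))
        md = project_multipoles(rho, grid, l_max=0)
        rng = np.random.default_rng(1)
        for S in random_s(rng, 5):
            fm = form_factor_multipole(md, S, l_max=0)
            fd = form_factor_direct(rho, grid, S)
            assert fm == pytest.approx(fd, abs=1e-8)

    def test_fixture_atom_l7_accuracy(self, oxygen_projection):
        """Multipole route vs direct summation: < 1e-3 relative at L=7."""
        grid, values, md = oxygen_projection
        rng = np.random.default_rng(2)
        S = random_s(rng, 50)
        fm = form_factor_multipole(md, S, l_max=7)
        fd = form_factor_direct(values, grid, S)
        f0 = abs(form_factor_direct(values, grid, np.zeros(3)))
        assert np.max(np.abs(fm - fd)) / f0 < 1e-3

    def test_truncation_sweep_non_increasing(self, oxygen_projection):
        grid, values, md = oxygen_projection
        rng = np.random.default_rng(3)
        S = random_s(rng, 30)
        fd = form_factor_direct(values, grid, S)
        f0 = abs(form_factor_direct(values, grid, np.zeros(3)))
        errs = []
        for l_max in (3, 5, 7, 9):
            fm = form_factor_multipole(md, S, l_max=l_max)
            errs.append(np.max(np.abs(fm - fd)) / f0)
        assert all(b <= a * 1.05 for a, b in zip(errs, errs[1:]))

    def test_zero_angle_only_monopole(self, oxygen_projection):
        _, values, md = oxygen_projection
        f0 = form_factor_multipole(md, np.zeros(3))
        assert f0.imag == pytest.approx(0.0, abs=1e-14)
        assert f0.real == pytest.approx(md.population, rel=1e-12)


class TestRotation:
    def test_identity(self):
        sv = ScatteringVector([0.1, 0.2, 0.3])
        out = rotate_scattering(sv, np.eye(3))
        np.testing.assert_allclose(out.S, sv.S, atol=0)

    def test_isometry(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            rot = random_rotation(rng)
            S = rng.normal(size=3)
            assert np.linalg.norm(rotate_scattering(S, rot)) == \
                pytest.approx(np.linalg.norm(S), abs=1e-12)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(InvalidParameterError):
            rotate_scattering([1.0, 0, 0], np.diag([1.0, 2.0, 1.0]))

    def test_rotational_covariance_of_form_factors(self, water_spec):
        """f_rotated-density(S) = f_original(R^T S) through the pipeline."""
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        rotated = rotate_spec(water_spec, rot)
        grid = atomic_grid(mura_knowles_radial(75, 4.34), angular_grid(590))
        vals_rot = atomic_density_on_grid(rotated, 0, grid)
        md_orig = project_multipoles(
            atomic_density_on_grid(water_spec, 0, grid), grid, l_max=9)
        S = random_s(rng, 10, s_max=1.0)
        f_rot_direct = form_factor_direct(vals_rot, grid, S)
        f_from_md = form_factor_multipole(md_orig, S @ rot)
        f0 = abs(form_factor_multipole(md_orig, np.zeros(3)))
        assert np.max(np.abs(f_rot_direct - f_from_md)) / f0 < 1e-3


class TestGlobalInvariants:
    def test_friedel_symmetry(self, oxygen_projection):
        grid, values, md = oxygen_projection
        rng = np.random.default_rng(6)
        S = random_s(rng, 10)
        for route in (lambda v: form_factor_direct(values, grid, v),
                      lambda v: form_factor_multipole(md, v)):
            f_plus = np.array([route(s) for s in S])
            f_minus = np.array([route(-s) for s in S])
            np.testing.assert_allclose(f_minus, np.conj(f_plus), atol=1e-12)

    def test_end_to_end_reconstruction(self, all_fixture_specs):
        """Sum of atomic form factors with phases reproduces the analytic
        molecular transform within 1e-4 relative for |S| <= 1.5 1/A."""
        rng = np.random.default_rng(7)
        ang = angular_grid(590)
        for spec in all_fixture_specs.values():
            S = random_s(rng, 25)
            total = np.zeros(len(S), complex)
            f0_total = 0.0
            for i, el in enumerate(spec.elements):
                grid = atomic_grid(
                    mura_knowles_radial(75, element_radial_scale(el)), ang)
                values = atomic_density_on_grid(spec, i, grid)
                md = project_multipoles(values, grid, l_max=9)
                total += form_factor_multipole(md, S) * np.exp(
                    2j * np.pi * (S @ spec.positions[i]))
                f0_total += form_factor_multipole(md, np.zeros(3)).real
            ref = analytic_molecular_ff(spec, S)
            denom = np.abs(ref)
            assert np.max(np.abs(total - ref) / denom) < 1e-4
            assert f0_total == pytest.approx(spec.total_electron_count,
                                             rel=1e-5)
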