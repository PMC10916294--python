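"""Multipole expansion of grid-sampled atomic densities.

A density sampled on a product grid is converted to per-(l, m) radial
functions

    rho_lm(r_i) = sum_p w_p^ang rho(r_i u_p) y_lm(u_p),

(angular weights summing to 4*pi) and reconstructed as
rho(r) = sum_lm rho_lm(|r|) y_lm(r/|r|) with spline radial
interpolation in the grid's uniform mapped coordinate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_interp_spline

from .errors import InvalidParameterError
from .harmonics import harmonic_table, n_harmonics
from .quadrature import AtomicGrid, RadialGrid

__all__ = ["MultipoleDensity", "project_multipoles", "reconstruct_density",
           "resample_radial"]

log = logging.getLogger(__name__)

_SQ4PI = np.sqrt(4 * np.pi)


@dataclass(frozen=True)
class MultipoleDensity:
    """Radial functions rho_lm(r_i) in canonical (l, m) order."""
    l_max: int
    radial_grid: RadialGrid
    coefficients: np.ndarray  # ((l_max+1)^2, n_rad), e/A^3

    def __post_init__(self):
        coeffs = np.asarray(self.coefficients, float)
        object.__setattr__(self, "coefficients", coeffs)
        if coeffs.shape != (n_harmonics(self.l_max),
                            self.radial_grid.n_points):
            raise InvalidParameterError(
                f"coefficient array must have shape "
                f"({n_harmonics(self.l_max)}, {self.radial_grid.n_points}), "
                f"got {coeffs.shape}")
        if not np.all(np.isfinite(coeffs)):
            raise InvalidParameterError("non-finite multipole coefficients")

    @property
    def population(self) -> float:
        """Electron count from the monopole: sqrt(4 pi) int rho_00 r^2 dr."""
        return _SQ4PI * self.radial_grid.integrate(self.coefficients[0])

    def row(self, l: int, m: int) -> np.ndarray:
        from .harmonics import lm_index
        return self.coefficients[lm_index(l, m)]

    def _to_x(self, r):
        # the grid's uniform mapped coordinate: r = -scale ln(1 - x^3)
        return np.cbrt(-np.expm1(-np.asarray(r, float)
                                 / self.radial_grid.scale))

    def _splines(self):
        # interpolate in the uniform mapped coordinate x, where the nodes
        # are equispaced: a quintic spline there is far more accurate than
        # a cubic in r on the stretched outer nodes
        cache = getattr(self, "_spline_cache", None)
        if cache is None:
            x = self._to_x(self.radial_grid.nodes)
            k = min(5, len(x) - 1)
            spline = make_interp_spline(x, self.coefficients, k=k, axis=1)

            def cache(r):
                return spline(self._to_x(r))

            object.__setattr__(self, "_spline_cache", cache)
        return cache


def project_multipoles(values: np.ndarray, grid: AtomicGrid,
                       l_max: int) -> MultipoleDensity:
    """Project density samples on a product grid onto spherical harmonics.

    ``values`` holds the density at ``grid.points`` (flattened r-major or
    shaped (n_rad, n_ang)).  Requires an angular grid exact to at least
    2*l_max so that harmonic orthonormality holds under the grid weights.
    """
    if l_max < 0:
        raise InvalidParameterError("l_max must be >= 0")
    if grid.angular.degree < 2 * l_max:
        raise InvalidParameterError(
            f"angular grid of degree {grid.angular.degree} cannot project "
            f"l_max={l_max}; need degree >= {2 * l_max} "
            f"(e.g. a larger grid from the supported set)")
    vals = np.asarray(values, float).reshape(grid.shape)
    table = harmonic_table(l_max, grid.angular)          # (n_lm, n_ang)
    coeffs = (table * grid.angular.weights) @ vals.T     # (n_lm, n_rad)
    return MultipoleDensity(l_max=l_max, radial_grid=grid.radial,
                            coefficients=coeffs)


def reconstruct_density(md: MultipoleDensity, points) -> float | np.ndarray:
    """Evaluate sum_lm rho_lm(|r|) y_lm(r_hat) at arbitrary point(s).

    Radii between grid nodes are spline-interpolated; points beyond the
    outermost node return 0 (logged); the short extrapolation below the
    innermost node uses the spline's natural extension.
    """
    pts = np.asarray(points, float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    r = np.linalg.norm(pts, axis=1)
    out = np.zeros(len(pts))
    r_max = md.radial_grid.nodes[-1]
    beyond = r > r_max
    if np.any(beyond):
        log.debug("reconstruct_density: %d points beyond outermost node "
                  "(%.3f A) set to 0", int(beyond.sum()), r_max)
    inside = ~beyond
    if np.any(inside):
        ri = r[inside]
        radial = md._splines()(ri)                       # (n_lm, n_inside)
        with np.errstate(invalid="ignore"):
            units = np.where(ri[:, None] > 0, pts[inside] / ri[:, None],
                             [0.0, 0.0, 1.0])
        table = harmonic_table(md.l_max, units)          # (n_lm, n_inside)
        out[inside] = np.sum(radial * table, axis=0)
    return float(out[0]) if single else out


def resample_radial(md: MultipoleDensity,
                    target: RadialGrid) -> MultipoleDensity:
    """Interpolate all (l, m) rows onto a different radial grid.

    The target's outer reach must stay within the source range; grids of
    the same scale but different node counts overhang each other by a few
    per cent at both ends, so an outer overhang of up to 15% is tolerated
    and filled with zeros (any real density there is already below the
    grid's resolution), while larger overhangs are an extrapolation error.
    The short inner extension uses the spline's natural end behaviour.
    Monopole population drift above 1e-4 relative is logged as a warning.
    """
    src = md.radial_grid
    if src.nodes is target.nodes or (
            target.n_points == src.n_points
            and np.array_equal(target.nodes, src.nodes)):
        return MultipoleDensity(l_max=md.l_max, radial_grid=target,
                                coefficients=md.coefficients.copy())
    if target.nodes[-1] > 1.15 * src.nodes[-1]:
        raise InvalidParameterError(
            "resample target range "
            f"[{target.nodes[0]:.3g}, {target.nodes[-1]:.3g}] exceeds "
            f"source range [{src.nodes[0]:.3g}, {src.nodes[-1]:.3g}]")
    coeffs = md._splines()(target.nodes)
    beyond = target.nodes > src.nodes[-1]
    if np.any(beyond):
        log.debug("resample_radial: %d target nodes beyond the source "
                  "range filled with 0", int(beyond.sum()))
        coeffs[:, beyond] = 0.0
    out = MultipoleDensity(l_max=md.l_max, radial_grid=target,
                           coefficients=coeffs)
    pop0, pop1 = md.population, out.population
    if pop0 != 0 and abs(pop1 - pop0) > 1e-4 * abs(pop0):
        log.warning("resample_radial: population drift %.3e relative "
                    "(%.6f -> %.6f e)", abs(pop1 - pop0) / abs(pop0),
                    pop0, pop1)
    return out
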