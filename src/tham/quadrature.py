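"""Radial, angular and product integration grids.

Conventions: lengths in angstrom.  A RadialGrid approximates
``int_0^inf g(r) r^2 dr = sum_i w_i r_i^2 g(r_i)``; angular weights sum to
4*pi, so multipole projections read as plain weighted sums; the product
AtomicGrid carries combined weights ``w_rad * r^2 * w_ang`` and reproduces
3D integrals of atom-centred densities.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _angular_orbits
from .angular_design import grid_from_orbits
from .errors import InvalidParameterError

__all__ = ["RadialGrid", "AngularGrid", "AtomicGrid", "mura_knowles_radial",
           "angular_grid", "lebedev_angular", "atomic_grid",
           "SUPPORTED_ANGULAR_SIZES", "element_radial_scale"]

#: supported angular grid sizes (Lebedev-Laikov family point counts)
SUPPORTED_ANGULAR_SIZES = tuple(sorted(_angular_orbits.ORBITS))


@dataclass(frozen=True)
class RadialGrid:
    """Radial quadrature nodes and weights (without the r^2 factor)."""
    nodes: np.ndarray
    weights: np.ndarray
    scale: float

    def __post_init__(self):
        object.__setattr__(self, "nodes", np.asarray(self.nodes, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if np.any(np.diff(self.nodes) <= 0) or np.any(self.nodes <= 0):
            raise InvalidParameterError("radial nodes must be positive and "
                                        "strictly increasing")
        if np.any(self.weights <= 0):
            raise InvalidParameterError("radial weights must be positive")

    @property
    def n_points(self) -> int:
        return len(self.nodes)

    def integrate(self, g_values: np.ndarray) -> float:
        """Approximate int g(r) r^2 dr from samples at the nodes."""
        return float(np.sum(self.weights * self.nodes ** 2 * g_values))


@dataclass(frozen=True)
class AngularGrid:
    """Unit directions and weights summing to 4*pi; exact to ``degree``."""
    directions: np.ndarray
    weights: np.ndarray
    degree: int = 0

    def __post_init__(self):
        object.__setattr__(self, "directions",
                           np.asarray(self.directions, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        norms = np.linalg.norm(self.directions, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-12:
            raise InvalidParameterError("angular directions must be unit "
                                        "vectors")
        if abs(self.weights.sum() - 4 * np.pi) > 1e-9:
            raise InvalidParameterError("angular weights must sum to 4*pi")

    @property
    def n_points(self) -> int:
        return len(self.directions)


@dataclass(frozen=True)
class AtomicGrid:
    """Product grid: points r_i * u_j with combined weights w_i r_i^2 w_j."""
    radial: RadialGrid
    angular: AngularGrid
    points: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        r = self.radial.nodes
        u = self.angular.directions
        pts = (r[:, None, None] * u[None, :, :]).reshape(-1, 3)
        w = (self.radial.weights[:, None] * r[:, None] ** 2
             * self.angular.weights[None, :]).reshape(-1)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_radial, n_angular) layout of the flattened point list."""
        return (self.radial.n_points, self.angular.n_points)

    def integrate(self, values: np.ndarray) -> float:
        """Approximate int rho d3r from samples at the grid points."""
        return float(np.sum(self.weights * np.ravel(values)))


def mura_knowles_radial(n_points: int, scale: float) -> RadialGrid:
    """Mura-Knowles log3 radial grid.

    Nodes follow r(x) = -scale * ln(1 - x^3) at the uniform abscissae
    x_i = i/(n+1); weights carry the Jacobian dr/dx and the uniform step,
    so that ``sum w_i r_i^2 g(r_i)`` approximates ``int g r^2 dr``.

    Parameters
    ----------
    n_points : int, >= 10
    scale : float, > 0
        Grid scale in angstrom; larger values push nodes outward.
    """
    if n_points < 10:
        raise InvalidParameterError("n_points must be >= 10")
    if not scale > 0:
        raise InvalidParameterError("scale must be positive")
    h = 1.0 / (n_points + 1)
    x = h * np.arange(1, n_points + 1)
    nodes = -scale * np.log1p(-x ** 3)
    jac = scale * 3.0 * x ** 2 / (1.0 - x ** 3)
    return RadialGrid(nodes=nodes, weights=h * jac, scale=float(scale))


def angular_grid(n_points: int) -> AngularGrid:
    """Octahedrally symmetric angular quadrature with ``n_points`` nodes.

    Point counts follow the Lebedev-Laikov family; the shipped grids are
    solved from the moment equations (see :mod:`tham.angular_design`) and
    integrate spherical polynomials exactly up to the grid's stated degree.
    """
    if n_points not in _angular_orbits.ORBITS:
        raise InvalidParameterError(
            f"unsupported angular grid size {n_points}; supported sizes: "
            f"{sorted(_angular_orbits.ORBITS)}")
    degree, orbits = _angular_orbits.ORBITS[n_points]
    directions, weights = grid_from_orbits(orbits)
    if len(directions) != n_points:
        raise InvalidParameterError(
            f"internal orbit table inconsistency for n={n_points}")
    # renormalize round-off so the partition sum is exact
    weights = weights * (4 * np.pi / weights.sum())
    return AngularGrid(directions=directions, weights=weights, degree=degree)


#: alias under the family's customary name
lebedev_angular = angular_grid


def atomic_grid(radial: RadialGrid, angular: AngularGrid) -> AtomicGrid:
    """Product grid of a radial and an angular quadrature."""
    return AtomicGrid(radial=radial, angular=angular)


# per-element radial scale: 5 A scaled by covalent radius relative to carbon,
# clamped to [2.5, 7.5] A so that both H and first-row atoms are resolved
def element_radial_scale(element: str) -> float:
    from .databank import covalent_radius
    s = 5.0 * covalent_radius(element) / covalent_radius("C")
    return float(np.clip(s, 2.5, 7.5))
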