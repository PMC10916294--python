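"""Construction of octahedrally symmetric angular quadrature grids.

Grids are unions of orbits of the full octahedral group O_h acting on a
representative direction.  Orbit codes follow the customary classification:

    1: (1,0,0)         octahedron vertices, 6 points, no free parameter
    2: (1,1,0)/sqrt2   edge midpoints, 12 points, no free parameter
    3: (1,1,1)/sqrt3   cube vertices, 8 points, no free parameter
    4: (a,a,b)         2a^2 + b^2 = 1, 24 points, one parameter
    5: (a,b,0)         a^2 + b^2 = 1, 24 points, one parameter
    6: (a,b,c)         generic, 48 points, two parameters

A grid of algebraic degree d integrates every spherical polynomial of
degree <= d exactly.  By symmetry only the O_h-invariant harmonics give
non-trivial moment conditions; orbit parameters and weights are solved from
the moment equations with a damped least-squares iteration
(:func:`solve_grid`).  The shipped grids in ``_angular_orbits`` were
produced by this solver and are verified by the test suite.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import least_squares
from scipy.special import sph_harm_y

__all__ = ["orbit_points", "orbit_size", "n_free_params", "grid_from_orbits",
           "solve_grid", "max_moment_error"]

_SQ2 = np.sqrt(2.0)
_SQ3 = np.sqrt(3.0)

#: points contributed by each orbit code
_ORBIT_SIZE = {1: 6, 2: 12, 3: 8, 4: 24, 5: 24, 6: 48}
#: free angular parameters per orbit code
_ORBIT_NPAR = {1: 0, 2: 0, 3: 0, 4: 1, 5: 1, 6: 2}


def orbit_size(code: int) -> int:
    return _ORBIT_SIZE[code]


def n_free_params(code: int) -> int:
    return _ORBIT_NPAR[code]


def orbit_points(code: int, params=()) -> np.ndarray:
    """Unit vectors of one O_h orbit.

    ``params`` parametrizes the representative direction on the unit sphere:
    code 4 uses theta with a = sin(theta)/sqrt2, b = cos(theta); code 5 uses
    phi with (a, b) = (cos, sin); code 6 uses spherical (theta, phi).
    """
    if code == 1:
        return np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                         [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    if code == 2:
        s = 1.0 / _SQ2
        out = []
        for i, j in ((0, 1), (0, 2), (1, 2)):
            for si in (1, -1):
                for sj in (1, -1):
                    v = np.zeros(3)
                    v[i], v[j] = si * s, sj * s
                    out.append(v)
        return np.array(out)
    if code == 3:
        s = 1.0 / _SQ3
        return np.array([[sx * s, sy * s, sz * s]
                         for sx in (1, -1) for sy in (1, -1)
                         for sz in (1, -1)])
    if code == 4:
        (theta,) = params
        a, b = np.sin(theta) / _SQ2, np.cos(theta)
        out = []
        for bpos in range(3):
            comp = [a, a, a]
            comp[bpos] = b
            for signs in itertools.product((1, -1), repeat=3):
                out.append([signs[k] * comp[k] for k in range(3)])
        return np.array(out)
    if code == 5:
        (phi,) = params
        a, b = np.cos(phi), np.sin(phi)
        out = []
        for zpos in range(3):
            rest = [ax for ax in range(3) if ax != zpos]
            for vals in ((a, b), (b, a)):
                for s0 in (1, -1):
                    for s1 in (1, -1):
                        v = np.zeros(3)
                        v[rest[0]], v[rest[1]] = s0 * vals[0], s1 * vals[1]
                        out.append(v.copy())
        return np.array(out)
    if code == 6:
        theta, phi = params
        a = np.sin(theta) * np.cos(phi)
        b = np.sin(theta) * np.sin(phi)
        c = np.cos(theta)
        out = []
        for perm in itertools.permutations((a, b, c)):
            for signs in itertools.product((1, -1), repeat=3):
                out.append([signs[k] * perm[k] for k in range(3)])
        return np.array(out)
    raise ValueError(f"unknown orbit code {code}")


def grid_from_orbits(orbits) -> tuple[np.ndarray, np.ndarray]:
    """Assemble directions and per-point weights from (code, params, weight)."""
    pts, wts = [], []
    for code, params, weight in orbits:
        p = orbit_points(code, params)
        pts.append(p)
        wts.append(np.full(len(p), float(weight)))
    return np.vstack(pts), np.concatenate(wts)


def _invariant_lm(degree: int) -> tuple[np.ndarray, np.ndarray]:
    """(l, m) pairs whose quadrature moments are not killed by O_h symmetry.

    Only even l and cosine-type orders m = 0, 4, 8, ... survive the group
    average; all other harmonic moments vanish identically on any union of
    O_h orbits.
    """
    pairs = [(l, m) for l in range(0, degree + 1, 2)
             for m in range(0, l + 1, 4)]
    return (np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]))


def _moments(directions: np.ndarray, weights: np.ndarray,
             ls: np.ndarray, ms: np.ndarray) -> np.ndarray:
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    y = sph_harm_y(ls[:, None], ms[:, None], theta[None, :], phi[None, :])
    fac = np.where(ms[:, None] == 0, 1.0, _SQ2 * (-1.0) ** ms[:, None])
    return (fac * y.real) @ weights


def max_moment_error(orbits, degree: int) -> float:
    """Largest violated moment condition of the grid up to ``degree``.

    Checks the full harmonic moment set (not only the invariant ones), so it
    also guards against implementation errors in the orbit generators.
    """
    directions, weights = grid_from_orbits(orbits)
    pairs = [(l, m) for l in range(degree + 1) for m in range(l + 1)]
    ls = np.array([p[0] for p in pairs])
    ms = np.array([p[1] for p in pairs])
    mom = _moments(directions, weights, ls, ms)
    target = np.where((ls == 0) & (ms == 0), np.sqrt(4 * np.pi), 0.0)
    err = float(np.max(np.abs(mom - target)))
    # sine-type orders: use m<0 via the imaginary part
    theta = np.arccos(np.clip(directions[:, 2], -1.0, 1.0))
    phi = np.arctan2(directions[:, 1], directions[:, 0])
    neg = [(l, m) for l in range(degree + 1) for m in range(1, l + 1)]
    if neg:
        ls2 = np.array([p[0] for p in neg])[:, None]
        ms2 = np.array([p[1] for p in neg])[:, None]
        y = sph_harm_y(ls2, ms2, theta[None, :], phi[None, :])
        mom2 = (_SQ2 * (-1.0) ** ms2 * y.imag) @ weights
        err = max(err, float(np.max(np.abs(mom2))))
    return err


def solve_grid(structure, degree: int, seed: int = 0, tries: int = 60,
               tol: float = 5e-13):
    """Solve orbit parameters and weights for an exact grid of given degree.

    Parameters
    ----------
    structure : sequence of orbit codes, e.g. [1, 3, 4, 4, 4, 5]
    degree : target algebraic degree
    seed, tries : random multistart control (deterministic for fixed seed)
    tol : maximum acceptable moment residual

    Returns ``(orbits, err)`` with orbits as (code, params, weight) tuples.
    Raises ``RuntimeError`` when no start converges below ``tol``.
    """
    rng = np.random.default_rng(seed)
    ls, ms = _invariant_lm(degree)
    target = np.zeros(len(ls))
    target[0] = np.sqrt(4 * np.pi)
    npar = sum(_ORBIT_NPAR[c] for c in structure)
    norb = len(structure)
    npts = sum(_ORBIT_SIZE[c] for c in structure)

    def unpack(x):
        pars, w = x[:npar], x[npar:]
        orbits, i = [], 0
        for k, code in enumerate(structure):
            p = tuple(pars[i:i + _ORBIT_NPAR[code]])
            i += _ORBIT_NPAR[code]
            orbits.append((code, p, w[k]))
        return orbits

    def fun(x):
        directions, weights = grid_from_orbits(unpack(x))
        return _moments(directions, weights, ls, ms) - target

    w0 = 4 * np.pi / npts
    lo = np.concatenate([np.full(npar, 0.03), np.full(norb, 1e-9)])
    hi = np.concatenate([np.full(npar, np.pi / 2 - 0.03),
                         np.full(norb, 8 * w0)])
    best = None
    for _ in range(tries):
        x0 = np.concatenate([
            rng.uniform(0.1, np.pi / 2 - 0.1, npar),
            w0 * rng.uniform(0.5, 2.0, norb)])
        res = least_squares(fun, x0, method="trf", bounds=(lo, hi),
                            xtol=3e-16, ftol=3e-16, gtol=3e-16,
                            max_nfev=4000)
        err = float(np.max(np.abs(res.fun)))
        if best is None or err < best[1]:
            best = (res.x, err)
        if err < tol:
            break
    if best[1] >= tol:
        raise RuntimeError(
            f"no degree-{degree} grid found for structure {structure} "
            f"(best residual {best[1]:.2e})")
    return unpack(best[0]), best[1]
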