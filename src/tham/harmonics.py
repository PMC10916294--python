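"""Real (tesseral) spherical harmonics.

Orthonormal normalization, no Condon-Shortley phase:

    y_00 = 1/sqrt(4*pi),   int y_lm y_l'm' dOmega = delta_ll' delta_mm'.

The canonical index order used throughout the package (projection arrays,
databank files) is l ascending, and for each l, m running from -l to +l.
"""
from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

from .errors import InvalidParameterError

__all__ = ["real_sph_harm", "harmonic_table", "lm_order", "lm_index",
           "n_harmonics"]


def n_harmonics(l_max: int) -> int:
    """Number of (l, m) pairs with l <= l_max."""
    return (l_max + 1) ** 2


def lm_order(l_max: int) -> list[tuple[int, int]]:
    """Canonical (l, m) enumeration: l ascending, m from -l to +l."""
    return [(l, m) for l in range(l_max + 1) for m in range(-l, l + 1)]


def lm_index(l: int, m: int) -> int:
    """Row of (l, m) in the canonical order."""
    if abs(m) > l:
        raise InvalidParameterError(f"|m| = {abs(m)} exceeds l = {l}")
    return l * l + l + m


def _check_unit(u: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    norms = np.linalg.norm(u, axis=-1)
    if not np.allclose(norms, 1.0, atol=tol, rtol=0.0):
        raise InvalidParameterError(
            "direction vectors must be unit length (caller normalizes); "
            f"max |1 - |u|| = {np.max(np.abs(norms - 1.0)):.3e}")
    return u


def real_sph_harm(l: int, m: int, u) -> float | np.ndarray:
    """Evaluate the orthonormal real spherical harmonic y_lm at unit vector(s) u.

    Parameters
    ----------
    l, m : int
        Degree and order, |m| <= l.
    u : array-like, shape (..., 3)
        Unit direction vector(s); must be normalized to 1e-9.
    """
    if l < 0 or abs(m) > l:
        raise InvalidParameterError(f"invalid harmonic index (l={l}, m={m})")
    u = _check_unit(np.atleast_2d(np.asarray(u, dtype=float)))
    theta = np.arccos(np.clip(u[..., 2], -1.0, 1.0))
    phi = np.arctan2(u[..., 1], u[..., 0])
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        out = y.real
    elif m > 0:
        out = np.sqrt(2.0) * (-1.0) ** m * y.real
    else:
        out = np.sqrt(2.0) * (-1.0) ** m * y.imag
    return out[0] if out.shape == (1,) else out


def harmonic_table(l_max: int, directions) -> np.ndarray:
    """Matrix of y_lm values on a set of unit vectors.

    Rows follow the canonical (l, m) order; columns follow ``directions``.
    ``directions`` may be an AngularGrid or an (n, 3) array of unit vectors.
    """
    if l_max < 0:
        raise InvalidParameterError("l_max must be >= 0")
    dirs = getattr(directions, "directions", directions)
    dirs = _check_unit(np.atleast_2d(np.asarray(dirs, dtype=float)))
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])

    order = lm_order(l_max)
    ls = np.array([l for l, _ in order])[:, None]
    ms = np.array([m for _, m in order])[:, None]
    y = sph_harm_y(ls, np.abs(ms), theta[None, :], phi[None, :])
    sign = np.sqrt(2.0) * (-1.0) ** np.abs(ms)
    table = np.where(ms == 0, y.real,
                     np.where(ms > 0, sign * y.real, sign * y.imag))
    return np.ascontiguousarray(table)
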