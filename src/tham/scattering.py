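"""Atomic form factors: direct grid summation and the multipole/Hankel route.

Crystallographic Fourier convention f(S) = int rho(r) exp(2 pi i S.r) d3r,
S in A^-1.  The fast route expands the density in spherical harmonics and
uses the plane-wave expansion

    f(S) = sum_{l<=L} i^l 4 pi sum_m H_lm(s) y_lm(S_hat),
    H_lm(s) = int rho_lm(r) j_l(2 pi s r) r^2 dr,

with H_lm evaluated by the radial quadrature (a Hankel / Fourier-Bessel
transform of the radial function).  Local-frame transfer evaluates the
databank density at the rotated argument M.S.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import spherical_jn

from .errors import InvalidParameterError
from .harmonics import harmonic_table
from .multipole import MultipoleDensity
from .quadrature import AtomicGrid

__all__ = ["ScatteringVector", "form_factor_direct", "hankel_transform",
           "form_factor_multipole", "rotate_scattering"]


@dataclass(frozen=True)
class ScatteringVector:
    """A reciprocal-space vector S (A^-1) with magnitude and direction."""
    S: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "S", np.asarray(self.S, float).reshape(3))

    @property
    def s(self) -> float:
        return float(np.linalg.norm(self.S))

    @property
    def unit(self) -> np.ndarray:
        s = self.s
        if s == 0:
            raise InvalidParameterError("direction of the zero vector is "
                                        "undefined")
        return self.S / s


def _as_svectors(S) -> np.ndarray:
    if isinstance(S, ScatteringVector):
        return S.S.reshape(1, 3)
    arr = np.asarray(S, float)
    return arr.reshape(-1, 3)


def form_factor_direct(values: np.ndarray, grid: AtomicGrid,
                       S) -> complex | np.ndarray:
    """Form factor by direct summation over the integration grid.

    ``values`` are density samples at ``grid.points``; S may be a single
    vector, a ScatteringVector, or an (n, 3) array.  This is the oracle
    route: f(S) = sum_p w_p rho(r_p) exp(2 pi i S.r_p).
    """
    vals = np.ravel(np.asarray(values, float))
    if vals.shape[0] != grid.n_points:
        raise InvalidParameterError("values and grid are not aligned")
    Sm = _as_svectors(S)
    phase = np.exp(2j * np.pi * (grid.points @ Sm.T))   # (n_pts, n_S)
    out = (grid.weights * vals) @ phase
    single = isinstance(S, ScatteringVector) or np.asarray(S).ndim == 1
    return complex(out[0]) if single else out


def hankel_transform(md: MultipoleDensity, l: int, s) -> np.ndarray:
    """Hankel transform H_lm(s) of every order m of degree l.

    Returns an array of shape (2l+1,) for scalar s, or (2l+1, n_s).
    """
    if not 0 <= l <= md.l_max:
        raise InvalidParameterError(f"l={l} outside [0, {md.l_max}]")
    s_arr = np.atleast_1d(np.asarray(s, float))
    r = md.radial_grid.nodes
    wr2 = md.radial_grid.weights * r ** 2
    jl = spherical_jn(l, 2 * np.pi * np.outer(s_arr, r))   # (n_s, n_rad)
    rows = md.coefficients[l * l:(l + 1) * (l + 1)]        # (2l+1, n_rad)
    out = rows @ (wr2 * jl).T                              # (2l+1, n_s)
    return out[:, 0] if np.isscalar(s) or np.asarray(s).ndim == 0 else out


def form_factor_multipole(md: MultipoleDensity, S,
                          l_max: int | None = None) -> complex | np.ndarray:
    """Form factor from the multipole expansion (fast route).

    S may be a ScatteringVector, a 3-vector or an (n, 3) array; ``l_max``
    truncates the expansion (default: the density's own l_max).
    """
    if l_max is None:
        l_max = md.l_max
    if l_max > md.l_max:
        raise InvalidParameterError(f"l_max={l_max} exceeds stored "
                                    f"l_max={md.l_max}")
    Sm = _as_svectors(S)
    s = np.linalg.norm(Sm, axis=1)
    out = np.zeros(len(Sm), complex)

    zero = s == 0
    if np.any(zero):
        h00 = float(hankel_transform(md, 0, 0.0)[0])
        out[zero] = np.sqrt(4 * np.pi) * h00
    nz = ~zero
    if np.any(nz):
        units = Sm[nz] / s[nz][:, None]
        table = harmonic_table(l_max, units)               # (n_lm, n_nz)
        acc = np.zeros(nz.sum(), complex)
        for l in range(l_max + 1):
            h = hankel_transform(md, l, s[nz])             # (2l+1, n_nz)
            ylm = table[l * l:(l + 1) * (l + 1)]
            acc += (1j) ** l * 4 * np.pi * np.sum(h * ylm, axis=0)
        out[nz] = acc
    single = isinstance(S, ScatteringVector) or np.asarray(S).ndim == 1
    return complex(out[0]) if single else out


def rotate_scattering(S, M: np.ndarray):
    """Rotate a scattering vector into a local frame: returns M.S.

    M must be orthonormal (rows = local axes); the magnitude is preserved.
    """
    M = np.asarray(M, float)
    if np.max(np.abs(M @ M.T - np.eye(3))) > 1e-9:
        raise InvalidParameterError("M must be orthonormal")
    if isinstance(S, ScatteringVector):
        return ScatteringVector(M @ S.S)
    arr = np.asarray(S, float)
    if arr.ndim == 1:
        return M @ arr
    return arr @ M.T
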