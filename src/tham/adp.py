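"""Similarity metrics for anisotropic displacement parameters (ADPs).

An ADP is a symmetric positive-definite 3x3 tensor U (A^2, Cartesian)
defining a zero-mean trivariate Gaussian displacement PDF.  Two ADPs are
compared by the overlapping coefficient

    OC = int min(p1(u), p2(u)) d3u,        eta_r = 100 (1 - OC),

and by the Whitten-Spackman S_12 index built from the overlap of the
square-rooted PDFs.  OC factorizes along rays: two zero-mean Gaussians
restricted to a direction u_hat are c_i exp(-q_i r^2 / 2) with
q_i = u_hat^T U_i^-1 u_hat, which cross at most once for r > 0, so the
radial part reduces to closed erf/exponential expressions and only the
angular integral is done numerically (5810-point grid by default).
"""
from __future__ import annotations

import numpy as np
from scipy.special import erf

from .errors import InvalidParameterError
from .quadrature import AngularGrid, angular_grid

__all__ = ["check_spd", "adp_pdf", "overlap_coefficient", "eta_r", "s12"]


def check_spd(U) -> np.ndarray:
    """Validate a symmetric positive-definite tensor; returns it as array."""
    U = np.asarray(U, float)
    if U.shape != (3, 3):
        raise InvalidParameterError("ADP tensor must be 3x3")
    if np.max(np.abs(U - U.T)) > 1e-12:
        raise InvalidParameterError("ADP tensor must be symmetric")
    ev = np.linalg.eigvalsh(U)
    if ev[0] <= 0:
        raise InvalidParameterError(
            f"ADP tensor must be positive definite (eigenvalues {ev})")
    return U


def adp_pdf(U, u) -> float | np.ndarray:
    """Trivariate Gaussian displacement PDF p(u) of an ADP tensor (A^-3)."""
    U = check_spd(U)
    pts = np.asarray(u, float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    Uinv = np.linalg.inv(U)
    norm = (2 * np.pi) ** -1.5 / np.sqrt(np.linalg.det(U))
    quad = np.einsum("ni,ij,nj->n", pts, Uinv, pts)
    out = norm * np.exp(-0.5 * quad)
    return float(out[0]) if single else out


def _ray_integrals(c, a):
    """int_0^inf c r^2 exp(-a r^2) dr, elementwise."""
    return c * np.sqrt(np.pi) / (4.0 * a ** 1.5)


def _ray_partial(c, a, R):
    """int_0^R c r^2 exp(-a r^2) dr in closed form."""
    sa = np.sqrt(a)
    return c * (np.sqrt(np.pi) / (4.0 * a ** 1.5) * erf(sa * R)
                - R * np.exp(-a * R * R) / (2.0 * a))


def overlap_coefficient(U1, U2, angular: AngularGrid | None = None) -> float:
    """Overlapping coefficient OC = int min(p1, p2) d3u, in (0, 1].

    The radial integral along each quadrature direction is evaluated in
    closed form (erf); ``angular`` defaults to the 5810-point grid.
    Degenerate rays (equal decay rates q1 = q2) take the smaller-prefactor
    Gaussian over the whole ray; a non-positive crossing radius means the
    ordering never changes for r > 0 and the minimum is fixed by the
    prefactors, then by the decay rates.
    """
    U1, U2 = check_spd(U1), check_spd(U2)
    if angular is None:
        angular = angular_grid(5810)
    u = angular.directions
    I1, I2 = np.linalg.inv(U1), np.linalg.inv(U2)
    q1 = np.einsum("ni,ij,nj->n", u, I1, u)
    q2 = np.einsum("ni,ij,nj->n", u, I2, u)
    c1 = (2 * np.pi) ** -1.5 / np.sqrt(np.linalg.det(U1))
    c2 = (2 * np.pi) ** -1.5 / np.sqrt(np.linalg.det(U2))
    a1, a2 = q1 / 2.0, q2 / 2.0

    n = len(u)
    c1v, c2v = np.full(n, c1), np.full(n, c2)
    integral = np.empty(n)

    same_q = np.abs(q1 - q2) <= 1e-12 * (q1 + q2)
    # equal decay: min is the smaller prefactor everywhere (either if equal)
    if np.any(same_q):
        integral[same_q] = _ray_integrals(min(c1, c2), a1[same_q])

    diff = ~same_q
    if np.any(diff):
        with np.errstate(divide="ignore", invalid="ignore"):
            rc2 = 2.0 * np.log(c1 / c2) / (q1[diff] - q2[diff])
        crossing = rc2 > 0
        # identify which Gaussian is smaller near the origin; equal
        # prefactors fall back to the faster-decaying (larger q) one
        if c1 != c2:
            first_is_1 = np.full(diff.sum(), c1 < c2)
        else:
            first_is_1 = q1[diff] > q2[diff]
        cf = np.where(first_is_1, c1, c2)
        af = np.where(first_is_1, a1[diff], a2[diff])
        cs = np.where(first_is_1, c2, c1)
        asec = np.where(first_is_1, a2[diff], a1[diff])
        res = np.empty(diff.sum())
        no_x = ~crossing
        res[no_x] = _ray_integrals(cf[no_x], af[no_x])
        if np.any(crossing):
            R = np.sqrt(rc2[crossing])
            res[crossing] = (
                _ray_partial(cf[crossing], af[crossing], R)
                + _ray_integrals(cs[crossing], asec[crossing])
                - _ray_partial(cs[crossing], asec[crossing], R))
        integral[diff] = res
    return float(np.sum(angular.weights * integral))


def eta_r(U1, U2, angular: AngularGrid | None = None) -> float:
    """Rescaled overlap difference, percent: eta_r = 100 (1 - OC).

    Equals 50 times the L1 distance between the two displacement PDFs; 0
    iff the tensors are equal.
    """
    return 100.0 * (1.0 - overlap_coefficient(U1, U2, angular=angular))


def s12(U1, U2) -> float:
    """Whitten-Spackman S_12 similarity index, percent-like 0-100 scale.

    S12 = 100 (1 - R12) with the closed-form overlap of square-rooted
    Gaussian PDFs

        R12 = 2^{3/2} [det(U1^-1) det(U2^-1)]^{1/4}
              / det(U1^-1 + U2^-1)^{1/2}.
    """
    U1, U2 = check_spd(U1), check_spd(U2)
    I1, I2 = np.linalg.inv(U1), np.linalg.inv(U2)
    r12 = (2.0 ** 1.5 * (np.linalg.det(I1) * np.linalg.det(I2)) ** 0.25
           / np.sqrt(np.linalg.det(I1 + I2)))
    return 100.0 * (1.0 - r12)
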