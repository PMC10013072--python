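"""Stationary solutions of the layer dynamics via the self-consistency function p(B).

At a stationary state of the mean-field (Ott-Antonsen) layer dynamics the
local order parameter takes the closed form

    z*(I) = e^{i(beta + Phi*)},                 Phi* = arcsin(I/B)      (|I| < B, excitable group)
    z*(I) = rho* e^{i(beta + Phi*)},  rho* = (|I| - sqrt(I^2 - B^2))/B,
                                      Phi* = (pi/2) sign(I)            (|I| > B, oscillating group)

where B e^{i beta} = 1 + sigma Z is the effective excitability parameter.
Averaging z*(I) over the Gaussian input density g = N(r1, r2^2) yields the
self-consistency condition

    p(B) = B^2 - 2 sigma p2(B) + (sigma^2/B^2) (p1(B)^2 + p2(B)^2) - 1 = 0,

with the two integrals

    p1(B) = r1 - int_{|I|>B} I g(I) sqrt(1 - B^2/I^2) dI,
    p2(B) =      int_{|I|<B}   g(I) sqrt(B^2 - I^2)   dI.

Every positive root B of p defines one stationary branch; up to three roots
coexist, labelled B1 > B2 > B3.  The macroscopic order parameter of a branch
follows from Z = (p2 - sigma R^2) + i p1 with R = sqrt(p1^2 + p2^2)/B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad
from scipy.optimize import brentq

from .model import GAUSSIAN_TRUNCATION

__all__ = [
    "StationaryBranch",
    "p_integrals",
    "p_integral_derivatives",
    "p_function",
    "p_derivative",
    "find_stationary_states",
    "local_profile",
    "branch_from_root",
]

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-11, limit=200)


def _phi(t):
    """Standard normal density."""
    return np.exp(-0.5 * t * t) / math.sqrt(2.0 * math.pi)


def p_integrals(B: float, r1: float, r2: float) -> tuple[float, float]:
    """Self-consistency integrals (p1, p2) at effective excitability B.

    Integration is performed in standardized coordinates t = (I - r1)/r2
    (so the Gaussian weight is O(1) wide) over the truncated support
    [-8, 8]; the square-root behaviour at I = +-B is integrable and is
    resolved by the adaptive QAGS quadrature.
    """
    if not B > 0:
        raise ValueError("B must be > 0")
    if not r2 > 0:
        raise ValueError("r2 must be > 0")
    T = GAUSSIAN_TRUNCATION
    # Boundaries of the excitable window |I| < B in t-coordinates.
    t_lo = (-B - r1) / r2
    t_hi = (B - r1) / r2

    # p2: integral over |I| < B.
    a, b = max(-T, t_lo), min(T, t_hi)
    if a < b:
        p2 = quad(
            lambda t: _phi(t) * math.sqrt(max(B * B - (r1 + r2 * t) ** 2, 0.0)),
            a, b, **_QUAD_OPTS,
        )[0]
    else:
        p2 = 0.0

    # Tail integral int_{|I|>B} sign(I) g(I) sqrt(I^2 - B^2) dI.
    tail = 0.0
    a = max(-T, t_hi)
    if a < T:  # I > B side
        tail += quad(
            lambda t: _phi(t) * math.sqrt(max((r1 + r2 * t) ** 2 - B * B, 0.0)),
            a, T, **_QUAD_OPTS,
        )[0]
    b = min(T, t_lo)
    if b > -T:  # I < -B side
        tail -= quad(
            lambda t: _phi(t) * math.sqrt(max((r1 + r2 * t) ** 2 - B * B, 0.0)),
            -T, b, **_QUAD_OPTS,
        )[0]
    return r1 - tail, p2


def p_integral_derivatives(B: float, r1: float, r2: float) -> tuple[float, float]:
    """Analytic derivatives (dp1/dB, dp2/dB).

    Differentiating under the integral sign (the boundary terms vanish
    because both integrands vanish at |I| = B):

        dp2/dB =  int_{|I|<B} g(I) B / sqrt(B^2 - I^2) dI,
        dp1/dB =  int_{|I|>B} sign(I) g(I) B / sqrt(I^2 - B^2) dI.

    The inverse-square-root endpoint singularities are integrable; the
    quadrature may warn about extrapolation roundoff there, which is
    harmless at the accuracy used (validated against central differences
    of the integrals), so the warning is suppressed.
    """
    import warnings

    from scipy.integrate import IntegrationWarning

    if not B > 0:
        raise ValueError("B must be > 0")
    T = GAUSSIAN_TRUNCATION
    t_lo = (-B - r1) / r2
    t_hi = (B - r1) / r2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)

        a, b = max(-T, t_lo), min(T, t_hi)
        dp2 = 0.0
        if a < b:
            dp2 = quad(
                lambda t: _phi(t) * B / math.sqrt(max(B * B - (r1 + r2 * t) ** 2, 1e-300)),
                a, b, **_QUAD_OPTS,
            )[0]

        dp1 = 0.0
        a = max(-T, t_hi)
        if a < T:
            dp1 += quad(
                lambda t: _phi(t) * B / math.sqrt(max((r1 + r2 * t) ** 2 - B * B, 1e-300)),
                a, T, **_QUAD_OPTS,
            )[0]
        b = min(T, t_lo)
        if b > -T:
            dp1 -= quad(
                lambda t: _phi(t) * B / math.sqrt(max((r1 + r2 * t) ** 2 - B * B, 1e-300)),
                -T, b, **_QUAD_OPTS,
            )[0]
    return dp1, dp2


_GL_CACHE: dict = {}


def _leggauss_cached(n: int):
    if n not in _GL_CACHE:
        _GL_CACHE[n] = leggauss(n)
    return _GL_CACHE[n]


def p_integrals_batch(B, r1: float, r2: float, n_gl: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """(p1, p2) on a whole B grid by singularity-removing substitutions.

    The excitable-window integral uses I = B sin(u) and the tail integrals
    I = +-B cosh(u), which turn the square-root edge behaviour into smooth
    integrands handled by fixed Gauss-Legendre quadrature.  Agrees with the
    adaptive :func:`p_integrals` to ~1e-12 for r2 of order one; for very
    narrow input distributions (r2 << B/n_gl) prefer :func:`p_integrals`.
    """
    B = np.atleast_1d(np.asarray(B, dtype=float))[:, None]
    if np.any(B <= 0):
        raise ValueError("B must be > 0")
    x, w = _leggauss_cached(n_gl)
    T = GAUSSIAN_TRUNCATION

    # p2: I = B sin u over the full half-period; g truncates naturally.
    u = 0.5 * math.pi * x[None, :]
    g = np.exp(-0.5 * ((B * np.sin(u) - r1) / r2) ** 2) / (r2 * math.sqrt(2 * math.pi))
    p2 = (0.5 * math.pi) * np.einsum("ij,j->i", g * B * B * np.cos(u) ** 2, w)

    # tails: int_{|I|>B} sign(I) g(I) sqrt(I^2-B^2) dI, each side I = +-B cosh u.
    tail = np.zeros(B.shape[0])
    for sgn in (1.0, -1.0):
        hi = r1 + T * r2 if sgn > 0 else -(r1 - T * r2)  # max |I| with support on this side
        mask = hi > B[:, 0]
        if not np.any(mask):
            continue
        umax = np.arccosh(np.maximum(hi / B[:, 0], 1.0))[:, None]
        uu = 0.5 * (x[None, :] + 1.0) * umax
        g = np.exp(-0.5 * ((sgn * B * np.cosh(uu) - r1) / r2) ** 2) / (r2 * math.sqrt(2 * math.pi))
        contrib = np.einsum("ij,ij->i", g * (B * np.sinh(uu)) ** 2, 0.5 * umax * np.broadcast_to(w, uu.shape))
        tail += sgn * np.where(mask, contrib, 0.0)
    return r1 - tail, p2


def p_function(B, r1: float, r2: float, sigma: float, fast: bool = False):
    """Self-consistency function p(B); vectorized over B.

    ``fast=True`` evaluates the integrals by the fixed Gauss-Legendre path
    (used for scan grids); the default adaptive path is the reference.
    """
    if fast:
        B_arr = np.atleast_1d(np.asarray(B, dtype=float))
        p1, p2 = p_integrals_batch(B_arr, r1, r2)
        out = B_arr ** 2 - 2.0 * sigma * p2 + (sigma ** 2) * (p1 ** 2 + p2 ** 2) / B_arr ** 2 - 1.0
        return out if np.ndim(B) else float(out[0])
    B_arr = np.atleast_1d(np.asarray(B, dtype=float))
    out = np.empty_like(B_arr)
    for i, b in enumerate(B_arr):
        p1, p2 = p_integrals(b, r1, r2)
        out[i] = b * b - 2.0 * sigma * p2 + (sigma * sigma) * (p1 * p1 + p2 * p2) / (b * b) - 1.0
    return out if np.ndim(B) else float(out[0])


def p_derivative(B: float, r1: float, r2: float, sigma: float) -> float:
    """Analytic dp/dB."""
    p1, p2 = p_integrals(B, r1, r2)
    dp1, dp2 = p_integral_derivatives(B, r1, r2)
    s2 = sigma * sigma
    q = p1 * p1 + p2 * p2
    return (
        2.0 * B
        - 2.0 * sigma * dp2
        + s2 * (2.0 * (p1 * dp1 + p2 * dp2) / (B * B) - 2.0 * q / (B ** 3))
    )


@dataclass
class StationaryBranch:
    """One root B of the self-consistency equation with its macroscopic data.

    Attributes
    ----------
    B, beta : effective excitability parameter and rotation angle,
        B e^{i beta} = 1 + sigma Z.
    p1, p2 : self-consistency integrals at the root.
    R, Theta : stationary Kuramoto order parameter and mean phase.
    label : "B1", "B2", ... assigned in decreasing-B order.
    fold_proximal : True when another root lies within 1e-4 in B.
    stability : classification filled in by :mod:`rotorpool.spectrum`.
    """

    B: float
    p1: float
    p2: float
    R: float
    Theta: float
    beta: float
    label: str
    r1: float
    r2: float
    sigma: float
    fold_proximal: bool = False
    stability: Optional[str] = field(default=None)

    @property
    def Z(self) -> complex:
        """Stationary order parameter Z = (p2 - sigma R^2) + i p1."""
        return complex(self.p2 - self.sigma * self.R * self.R, self.p1)

    @property
    def activity(self) -> float:
        """Stationary population activity A = r1 - Im(Z) = r1 - p1."""
        return self.r1 - self.p1


def branch_from_root(B: float, r1: float, r2: float, sigma: float, label: str = "") -> StationaryBranch:
    """Assemble the macroscopic quantities of a stationary branch from its root B."""
    p1, p2 = p_integrals(B, r1, r2)
    R = math.sqrt(p1 * p1 + p2 * p2) / B
    if sigma > 0:
        # Z = (p2 - sigma R^2) + i p1; full-quadrant mean phase.
        Theta = math.atan2(p1, p2 - sigma * R * R)
        beta = math.atan2(sigma * p1 / B, B - sigma * p2 / B)
    else:
        Theta = math.atan2(p1, p2)
        beta = 0.0
    return StationaryBranch(B=B, p1=p1, p2=p2, R=R, Theta=Theta, beta=beta,
                            label=label, r1=r1, r2=r2, sigma=sigma)


def _scan_roots(r1: float, r2: float, sigma: float, B_min: float, B_max: float, n_scan: int) -> List[float]:
    grid = np.geomspace(B_min, B_max, n_scan)
    vals = p_function(grid, r1, r2, sigma, fast=True)
    roots = []
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        roots.append(brentq(lambda b: p_function(b, r1, r2, sigma), grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14))
    # exact zeros on the grid (rare)
    for i in np.nonzero(vals == 0.0)[0]:
        roots.append(float(grid[i]))
    return sorted(roots)


def find_stationary_states(
    r1: float,
    r2: float,
    sigma: float,
    B_min: float = 1e-3,
    B_max: Optional[float] = None,
    n_scan: int = 2000,
) -> List[StationaryBranch]:
    """All stationary branches at (r1, r2, sigma), in decreasing-B order.

    Roots of p(B) are bracketed on a log-spaced scan grid and polished by
    Brent's method.  The scan resolution is doubled automatically when two
    consecutive resolutions disagree on the root count (fold proximity
    safeguard).  Roots closer than 1e-4 in B are flagged fold-proximal,
    never merged.

    With sigma = 0 the self-consistency relation degenerates to
    p(B) = B^2 - 1 and the single branch B = 1 is returned directly.
    """
    if not r2 > 0:
        raise ValueError("r2 must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if B_max is None:
        B_max = 1.0 + sigma + abs(r1) + GAUSSIAN_TRUNCATION * r2

    if sigma == 0.0:
        return [branch_from_root(1.0, r1, r2, 0.0, label="B1")]

    roots = _scan_roots(r1, r2, sigma, B_min, B_max, n_scan)
    # fold-proximity safeguard: double resolution until the count stabilizes
    n = n_scan
    for _ in range(3):
        finer = _scan_roots(r1, r2, sigma, B_min, B_max, 2 * n)
        if len(finer) == len(roots):
            roots = finer
            break
        roots, n = finer, 2 * n

    branches = []
    roots_desc = sorted(roots, reverse=True)
    for k, B in enumerate(roots_desc):
        br = branch_from_root(B, r1, r2, sigma, label=f"B{k + 1}")
        br.fold_proximal = any(abs(B - other) < 1e-4 for other in roots_desc if other != B)
        branches.append(br)
    return branches


def local_profile(branch: StationaryBranch, I):
    """Stationary local order parameter z*(I) of a branch; vectorized over I.

    Excitable units (|I| < B) sit at the stable rest state on the unit
    circle; oscillating units (|I| > B) drift, leaving a partial local
    coherence rho* < 1.  At |I| = B the two expressions agree
    (rho* = 1, Phi* = (pi/2) sign(I)).
    """
    I_arr = np.atleast_1d(np.asarray(I, dtype=float))
    B, beta = branch.B, branch.beta
    z = np.empty(I_arr.shape, dtype=complex)
    exc = np.abs(I_arr) <= B
    # excitable group: rho* = 1, Phi* = arcsin(I/B) (stable branch, cos Phi* >= 0)
    z[exc] = np.exp(1j * (beta + np.arcsin(I_arr[exc] / B)))
    osc = ~exc
    absI = np.abs(I_arr[osc])
    rho = (absI - np.sqrt(absI * absI - B * B)) / B
    z[osc] = rho * np.exp(1j * (beta + 0.5 * math.pi * np.sign(I_arr[osc])))
    return z if np.ndim(I) else complex(z[0])
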