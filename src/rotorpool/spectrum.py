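"""Linear stability of stationary layer states: continuous and discrete spectra.

Writing the local and global order parameters as z = x + i y, Z = X + i Y,
the OA layer dynamics reads dz/dt = (F, G)(x, y, X, Y; I) with

    F = 1/2 (1 - x^2 + y^2) - I y + (sigma/2) X - (sigma/2) X (x^2 - y^2) - sigma x y Y,
    G = -x y + I x + (sigma/2) Y - sigma x y X + (sigma/2) Y (x^2 - y^2).

Linearizing around a stationary branch gives, per input I, the local
Jacobian P(I) = d(F,G)/d(x,y) and the global-feedback block
Q(I) = d(F,G)/d(X,Y).  The spectrum of the linearized mean-field operator
splits into

* a continuous part: the eigenvalues of P(I) as I ranges over the input
  support (always stable or marginally stable here), and
* a discrete part: the roots mu of det C(mu) = 0 with

      C(mu) = Id + int g(I) (P(I) - mu)^{-1} Q(I) dI,

  which decide the stability of the branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.integrate import quad_vec
from scipy.optimize import newton

from .model import GAUSSIAN_TRUNCATION
from .stationary import StationaryBranch, local_profile

__all__ = [
    "SpectrumResult",
    "jacobians",
    "continuous_spectrum",
    "characteristic_det",
    "discrete_spectrum",
    "classify_stability",
]

#: trial eigenvalues closer than this to the sampled continuous spectrum are
#: rejected (the resolvent is singular on the continuous spectrum).
EXCLUSION_MARGIN = 1e-6
DEDUP_DISTANCE = 1e-6
NEWTON_TOL = 1e-10
DET_TOL = 1e-8


def _jacobian_entries(x: float, y: float, X: float, Y: float, I: float, sigma: float):
    """Closed-form entries of P and Q at a point (x, y, X, Y, I)."""
    # At frozen Z the flow is holomorphic in z, so P inherits the
    # Cauchy-Riemann structure [[a, -b], [b, a]] with a + i b = dzdot/dz.
    p11 = -x - sigma * X * x - sigma * y * Y
    p12 = y - I + sigma * X * y - sigma * x * Y
    p21 = -y + I - sigma * y * X + sigma * Y * x
    p22 = -x - sigma * x * X - sigma * Y * y
    q11 = 0.5 * sigma * (1.0 - (x * x - y * y))
    q12 = -sigma * x * y
    q21 = -sigma * x * y
    q22 = 0.5 * sigma * (1.0 + (x * x - y * y))
    return p11, p12, p21, p22, q11, q12, q21, q22


def jacobians(I: float, branch: StationaryBranch) -> tuple[np.ndarray, np.ndarray]:
    """Local Jacobian P(I) and global-feedback block Q(I) at a branch point.

    (x0, y0) is the stationary local order parameter z*(I); (X0, Y0) the
    stationary global order parameter Z.  With sigma = 0 the dynamics has
    no global feedback and Q vanishes identically.
    """
    z0 = local_profile(branch, float(I))
    Z0 = branch.Z
    p11, p12, p21, p22, q11, q12, q21, q22 = _jacobian_entries(
        z0.real, z0.imag, Z0.real, Z0.imag, float(I), branch.sigma)
    return np.array([[p11, p12], [p21, p22]]), np.array([[q11, q12], [q21, q22]])


def continuous_spectrum(branch: StationaryBranch, n_samples: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalue curves of P(I) over the truncated input support.

    Returns (I_grid, eigs) with eigs of shape (n_samples, 2).  Excitable
    inputs |I| < B contribute real pairs, oscillating inputs complex
    conjugate pairs.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    T = GAUSSIAN_TRUNCATION
    I_grid = np.linspace(branch.r1 - T * branch.r2, branch.r1 + T * branch.r2, n_samples)
    z0 = local_profile(branch, I_grid)
    Z0 = branch.Z
    x, y = z0.real, z0.imag
    s = branch.sigma
    p11 = -x - s * Z0.real * x - s * y * Z0.imag
    p12 = y - I_grid + s * Z0.real * y - s * x * Z0.imag
    p21 = -y + I_grid - s * y * Z0.real + s * Z0.imag * x
    p22 = -x - s * x * Z0.real - s * Z0.imag * y
    tr = p11 + p22
    disc = (p11 - p22) ** 2 + 4.0 * p12 * p21  # (tr^2 - 4 det)
    sq = np.sqrt(disc.astype(complex))
    eigs = np.stack([(tr + sq) / 2.0, (tr - sq) / 2.0], axis=1)
    return I_grid, eigs


def characteristic_det(
    mu: complex,
    branch: StationaryBranch,
    continuous: Optional[np.ndarray] = None,
    quad_tol: float = 1e-10,
) -> complex:
    """det C(mu) of the discrete-spectrum characteristic equation.

    The resolvent integral runs over the truncated input support with
    adaptive Gauss-Kronrod quadrature; ``mu`` must keep a distance of at
    least 1e-6 from the (sampled) continuous spectrum, where the resolvent
    is singular.  ``continuous`` lets callers pass precomputed samples.
    """
    mu = complex(mu)
    if continuous is None:
        continuous = continuous_spectrum(branch)[1]
    if np.min(np.abs(continuous.ravel() - mu)) < EXCLUSION_MARGIN:
        raise ValueError(
            f"resolvent singular: mu={mu:.6g} within {EXCLUSION_MARGIN} of the continuous spectrum")

    B, beta, sig = branch.B, branch.beta, branch.sigma
    r1, r2 = branch.r1, branch.r2
    Z0 = branch.Z
    X0, Y0 = Z0.real, Z0.imag

    def integrand(I: float) -> np.ndarray:
        # stationary local order parameter (scalar fast path)
        if abs(I) <= B:
            ang = beta + math.asin(I / B)
            x, y = math.cos(ang), math.sin(ang)
        else:
            rho = (abs(I) - math.sqrt(I * I - B * B)) / B
            ang = beta + 0.5 * math.pi * (1.0 if I > 0 else -1.0)
            x, y = rho * math.cos(ang), rho * math.sin(ang)
        p11, p12, p21, p22, q11, q12, q21, q22 = _jacobian_entries(x, y, X0, Y0, I, sig)
        a = p11 - mu
        d = p22 - mu
        det = a * d - p12 * p21
        # (P - mu)^{-1} Q, times the Gaussian weight
        g = math.exp(-0.5 * ((I - r1) / r2) ** 2) / (r2 * math.sqrt(2.0 * math.pi))
        c11 = (d * q11 - p12 * q21) / det
        c12 = (d * q12 - p12 * q22) / det
        c21 = (-p21 * q11 + a * q21) / det
        c22 = (-p21 * q12 + a * q22) / det
        return g * np.array([c11.real, c11.imag, c12.real, c12.imag,
                             c21.real, c21.imag, c22.real, c22.imag])

    T = GAUSSIAN_TRUNCATION
    lo, hi = r1 - T * r2, r1 + T * r2
    # subdivide at the group boundaries +-B where z*(I) has kinks
    pts = sorted({lo, hi, *(p for p in (-B, B) if lo < p < hi)})
    vals = np.zeros(8)
    for a, b in zip(pts[:-1], pts[1:]):
        res, _ = quad_vec(integrand, a, b, epsabs=quad_tol, epsrel=quad_tol, limit=200)
        vals = vals + res
    c = vals[0::2] + 1j * vals[1::2]
    C = np.array([[1.0 + c[0], c[1]], [c[2], 1.0 + c[3]]])
    return complex(C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0])


#: imaginary offset used to evaluate det C just above the real axis where the
#: continuous spectrum covers it (boundary value of the analytic continuation).
EMBEDDED_OFFSET = 1e-3
#: residual tolerance for embedded real roots: on the cut the boundary-value
#: determinant keeps a small imaginary part (the Plemelj residue of the
#: resolvent integral), so |det| cannot reach the isolated-root tolerance.
EMBEDDED_DET_TOL = 0.1


def discrete_spectrum(
    branch: StationaryBranch,
    search_region: tuple[float, float, float, float] = (-2.0, 2.0, 0.0, 5.0),
    n_seeds: tuple[int, int] = (7, 5),
    n_real: int = 81,
    quad_tol: float = 1e-10,
    scan_tol: float = 1e-7,
) -> List[complex]:
    """Roots of det C(mu) = 0 in the search rectangle.

    Two passes:

    * secant iteration from a grid of complex seeds for off-axis roots,
      validated at |det C| < 1e-8 and away from the continuous spectrum;
    * a real-axis sweep of Re det C(x + i*delta), delta = 1e-3, bracketing
      sign changes.  Roots in clean stretches of the axis are re-polished
      at delta = 0 to the isolated-root tolerance; roots embedded in the
      real segment of the continuous spectrum (where the stable-node
      eigenvalues of coherent branches live) are accepted as boundary
      values of the analytic continuation, with the weaker residual bound
      |det| < 0.1 set by the Plemelj term.

    Converged roots are deduplicated at distance 1e-6 and completed with
    complex conjugates (the linearized system is real).  An empty list is
    a legitimate outcome.
    """
    re_lo, re_hi, im_lo, im_hi = search_region
    _, cont = continuous_spectrum(branch)
    cont_flat = cont.ravel()

    def f(mu):
        # loose quadrature during the search; roots are re-validated tightly
        return characteristic_det(mu, branch, continuous=cont, quad_tol=scan_tol)

    def f_tight(mu):
        return characteristic_det(mu, branch, continuous=cont, quad_tol=quad_tol)

    def far_from_continuum(mu: complex, factor: float = 10.0) -> bool:
        return bool(np.min(np.abs(cont_flat - mu)) > factor * EXCLUSION_MARGIN)

    roots: List[complex] = []

    def register(mu: complex) -> None:
        if abs(mu.imag) < DEDUP_DISTANCE:
            mu = complex(mu.real, 0.0)
        if all(abs(mu - r) > DEDUP_DISTANCE and abs(mu.conjugate() - r) > DEDUP_DISTANCE
               for r in roots):
            roots.append(mu)

    # pass 1: complex seeds
    for sr in np.linspace(re_lo, re_hi, n_seeds[0]):
        for si in np.linspace(im_lo, im_hi, n_seeds[1]):
            mu0 = complex(sr, si)
            if not far_from_continuum(mu0):
                mu0 += complex(0.0, EMBEDDED_OFFSET)
            try:
                mu = complex(newton(f, mu0, tol=1e-8, maxiter=30))
            except (RuntimeError, ValueError):
                continue
            if not (re_lo - 0.5 <= mu.real <= re_hi + 0.5 and abs(mu.imag) <= im_hi + 0.5):
                continue
            if not far_from_continuum(mu):
                continue
            try:
                mu = complex(newton(f_tight, mu, tol=NEWTON_TOL, maxiter=10))
                if not far_from_continuum(mu) or abs(f_tight(mu)) > DET_TOL:
                    continue
            except (RuntimeError, ValueError):
                continue
            register(mu)

    # pass 2: real axis, including the stretch covered by the continuous spectrum
    from scipy.optimize import brentq

    def on_real_cut(x: float) -> bool:
        # The excitable group contributes P(I) = -sqrt(B^2 - I^2) * Id, so the
        # real segment [-B, 0) is continuous spectrum exactly.
        return -branch.B - 1e-9 <= x < 0.0

    xs = np.linspace(re_lo, re_hi, n_real)
    fs = np.array([f(complex(x, EMBEDDED_OFFSET)).real for x in xs])
    for i in np.nonzero(np.sign(fs[:-1]) * np.sign(fs[1:]) < 0)[0]:
        x_root = brentq(lambda x: f(complex(x, EMBEDDED_OFFSET)).real,
                        xs[i], xs[i + 1], xtol=1e-10)
        mu = complex(x_root, 0.0)
        if not on_real_cut(x_root) and far_from_continuum(mu):
            try:
                mu = complex(newton(f_tight, complex(x_root, 0.0), tol=NEWTON_TOL, maxiter=50))
                if abs(mu.imag) > 1e-6 or abs(f_tight(mu)) > DET_TOL:
                    continue
                mu = complex(mu.real, 0.0)
            except (RuntimeError, ValueError):
                continue
        else:
            if abs(f_tight(complex(x_root, EMBEDDED_OFFSET))) > EMBEDDED_DET_TOL:
                continue
        register(mu)

    # complete conjugate pairs
    full = []
    for r in roots:
        full.append(r)
        if abs(r.imag) > DEDUP_DISTANCE:
            full.append(r.conjugate())
    return sorted(full, key=lambda m: (-m.real, abs(m.imag)))


@dataclass
class SpectrumResult:
    """Continuous curves, discrete eigenvalues and the stability verdict."""

    I_grid: np.ndarray
    continuous: np.ndarray
    discrete: List[complex]
    classification: str
    meta: dict = field(default_factory=dict)


def classify_stability(
    branch: StationaryBranch,
    discrete: Optional[List[complex]] = None,
    marginal_tol: float = 1e-7,
) -> SpectrumResult:
    """Stability classification of a branch from its discrete spectrum.

    "stable"/"unstable" by the sign of the largest real part (within
    ``marginal_tol`` of zero -> "marginal"); "node" when the leading
    eigenvalue is real, "focus" when it is a complex pair.  With an empty
    discrete spectrum the verdict falls back to the continuous part and is
    flagged "continuous-only".
    """
    I_grid, cont = continuous_spectrum(branch)
    if discrete is None:
        discrete = discrete_spectrum(branch)
    if discrete:
        lead = max(discrete, key=lambda m: m.real)
        re = lead.real
        kind = "focus" if abs(lead.imag) > DEDUP_DISTANCE else "node"
        if re > marginal_tol:
            cls = f"unstable {kind}"
        elif re < -marginal_tol:
            cls = f"stable {kind}"
        else:
            cls = "marginal"
    else:
        re = float(cont.real.max())
        cls = ("unstable" if re > marginal_tol else "stable" if re < -marginal_tol
               else "marginal") + " (continuous-only)"
    branch.stability = cls
    return SpectrumResult(I_grid=I_grid, continuous=cont, discrete=list(discrete),
                          classification=cls,
                          meta=dict(branch=branch.label, r1=branch.r1, r2=branch.r2,
                                    sigma=branch.sigma, newton_tol=NEWTON_TOL,
                                    dedup=DEDUP_DISTANCE, marginal_tol=marginal_tol))
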