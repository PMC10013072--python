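"""Shared parameter container, elementary model functions and macroscopic observables.

The model couples a heterogeneous population of N active rotators

    phi_k' = I_k - sin(phi_k) + (sigma/N) sum_j sin(phi_j - phi_k),
    I_k = r1 + r2 * nu_k,   nu_k ~ N(0, 1),

to a slow resource pool described by a Stuart-Landau (Hopf normal form)
oscillator shifted to a base level s = s1 + i*s2,

    r'   = eps * f(r - s, lam),      f(u, lam) = u * (lam + i*omega - |u|^2),
    lam' = -eps' * (lam - lam0 - gamma * A(t)),

where A(t) is the mean phase velocity (population activity).  This module
holds the parameter set, the Gaussian input density, the Kuramoto order
parameter and the resource vector field; the full right-hand sides are
assembled in :mod:`rotorpool.network` and :mod:`rotorpool.slowfast`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "ResourceState",
    "MacroState",
    "gaussian_density",
    "order_parameter",
    "resource_rhs",
    "metabolic_f",
    "GAUSSIAN_TRUNCATION",
]

#: Gaussian quadratures are truncated at mean +- GAUSSIAN_TRUNCATION * sd.
#: Mass beyond 8 standard deviations is < 1e-15, well under every integration
#: tolerance used in the package.
GAUSSIAN_TRUNCATION = 8.0


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-layer rotator/resource model.

    Defaults reproduce the reference parameter set used throughout the
    package: sigma=5, eps=eps_prime=0.05, s=(0.97, 1.2), omega=0.2,
    lambda0=-0.05, gamma=0.5, N=5000.
    """

    sigma: float = 5.0
    eps: float = 0.05
    eps_prime: Optional[float] = None  # defaults to eps
    s1: float = 0.97
    s2: float = 1.2
    omega: float = 0.2
    lambda0: float = -0.05
    gamma: float = 0.5
    N: int = 5000

    def __post_init__(self) -> None:
        if self.eps_prime is None:
            object.__setattr__(self, "eps_prime", float(self.eps))
        if not (self.eps > 0 and self.eps_prime > 0):
            raise ValueError("time-scale separations eps, eps_prime must be > 0")
        if self.sigma < 0:
            raise ValueError("coupling strength sigma must be >= 0")
        if self.gamma < 0:
            raise ValueError("adaptation strength gamma must be >= 0")
        if int(self.N) < 1:
            raise ValueError("population size N must be >= 1")
        object.__setattr__(self, "N", int(self.N))

    @property
    def s(self) -> complex:
        """Resource base level as a complex number s1 + i*s2."""
        return complex(self.s1, self.s2)

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class ResourceState:
    """State of the resource pool: complex resource r and activity lam."""

    r: complex
    lam: float

    @property
    def r1(self) -> float:
        return self.r.real

    @property
    def r2(self) -> float:
        return self.r.imag

    def __post_init__(self) -> None:
        self.r = complex(self.r)
        self.lam = float(self.lam)
        if not (np.isfinite(self.r.real) and np.isfinite(self.r.imag) and np.isfinite(self.lam)):
            raise ValueError("resource state must be finite")


@dataclass(frozen=True)
class MacroState:
    """Macroscopic observables of the population.

    Z is the complex Kuramoto order parameter, R = |Z| its modulus,
    Theta = arg(Z) the mean phase, and A the population activity (mean
    phase velocity; NaN when not supplied).
    """

    Z: complex
    R: float
    Theta: float
    A: float = field(default=math.nan)


def gaussian_density(I, r1: float, r2: float):
    """Normal density of the input distribution g(I) = N(r1, r2^2).

    Parameters
    ----------
    I : float or ndarray
        Input value(s) at which to evaluate the density.
    r1, r2 : float
        Mean and standard deviation.  ``r2`` must be positive: the
        homogeneous (delta-distribution) limit r2 -> 0 is handled by
        callers, not by this function.
    """
    if not r2 > 0:
        raise ValueError("standard deviation r2 must be > 0 (r2=0 is the homogeneous limit)")
    x = (np.asarray(I, dtype=float) - r1) / r2
    out = np.exp(-0.5 * x * x) / (r2 * math.sqrt(2.0 * math.pi))
    return out if out.ndim else float(out)


def order_parameter(phases) -> MacroState:
    """Complex order parameter Z = <e^{i phi}> of a set of phases."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("order_parameter needs at least one phase")
    Z = complex(np.exp(1j * phases).mean())
    return MacroState(Z=Z, R=abs(Z), Theta=math.atan2(Z.imag, Z.real) % (2.0 * math.pi))


def metabolic_f(u: complex, lam: float, omega: float) -> complex:
    """Hopf normal form f(u, lam) = u * (lam + i*omega - |u|^2).

    The resource subsystem r' = f(r - s, lam) has a supercritical Hopf
    bifurcation at lam = 0: stable focus at the base level s for lam < 0,
    stable limit cycle of radius sqrt(lam) around s for lam > 0.
    """
    return u * (lam + 1j * omega - (u.real * u.real + u.imag * u.imag))


def resource_rhs(state: ResourceState, params: ModelParams) -> tuple[complex, float]:
    """Time derivatives of (r, lam) excluding the activity drive.

    Returns ``(eps * f(r - s, lam), -eps' * (lam - lambda0))``.  Callers
    add the drive ``+ eps' * gamma * A`` to the lam-component.
    """
    dr = params.eps * metabolic_f(state.r - params.s, state.lam, params.omega)
    dlam = -params.eps_prime * (state.lam - params.lambda0)
    return dr, dlam
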