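"""Direct simulation of the full microscopic system.

N heterogeneous active rotators, globally coupled through the Kuramoto
order parameter and bidirectionally coupled to the slow resource pool:

    phi_k' = r1 + r2*nu_k - sin(phi_k) + sigma * Im(Z e^{-i phi_k}),
    r'     = eps * f(r - s, lam),
    lam'   = -eps' * (lam - lambda0 - gamma * A),       A = <phi_k'>.

The mean-field form of the coupling is algebraically identical to the
O(N^2) pairwise sine sum but costs O(N).  Exact finite-N identity:
A = r1 + r2*mean(nu) - Im(Z), because the coupling term averages to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.special import ndtri

from .model import MacroState, ModelParams, ResourceState, metabolic_f

__all__ = [
    "PopulationState",
    "TimeSeries",
    "init_population",
    "full_rhs",
    "simulate",
    "summarize",
]


@dataclass
class PopulationState:
    """Phases and frozen heterogeneity draws of the N rotators."""

    phases: np.ndarray
    nu: np.ndarray
    seed: Optional[int] = None  # provenance of the draws, when known

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float).copy()
        self.nu = np.asarray(self.nu, dtype=float).copy()
        if self.phases.shape != self.nu.shape or self.phases.ndim != 1:
            raise ValueError("phases and nu must be 1-d arrays of equal length")
        self.nu.setflags(write=False)  # heterogeneity is frozen after initialization

    @property
    def N(self) -> int:
        return self.phases.size


@dataclass
class TimeSeries:
    """Sampled macroscopic trajectory of a simulation.

    All arrays share the same length.  ``meta`` records parameters, seeds
    and integrator settings; ``final_state`` holds whatever is needed to
    warm-start a follow-up run (phases or an OA field, plus the resource).
    """

    t: np.ndarray
    A: np.ndarray
    R: np.ndarray
    Theta: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    lam: np.ndarray
    meta: dict = field(default_factory=dict)
    final_state: Optional[dict] = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("A", "R", "Theta", "r1", "r2", "lam"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")


def init_population(
    N: int,
    seed: int = 0,
    sampling_mode: str = "iid",
    phase_init: str = "random_uniform",
) -> PopulationState:
    """Create a population with frozen Gaussian heterogeneity.

    ``sampling_mode="iid"`` draws nu_k ~ N(0,1) with the given seed;
    ``"stratified"`` places nu_k at the equiprobable standard-normal
    quantiles Phi^{-1}((k - 1/2)/N) in ascending order, a deterministic
    variance-reduced alternative that tightens finite-size effects.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    if sampling_mode == "iid":
        nu = rng.standard_normal(N)
    elif sampling_mode == "stratified":
        nu = ndtri((np.arange(N) + 0.5) / N)
    else:
        raise ValueError(f"unknown sampling_mode {sampling_mode!r}")
    if phase_init == "random_uniform":
        phases = rng.uniform(0.0, 2.0 * math.pi, N)
    elif phase_init == "all_zero":
        phases = np.zeros(N)
    else:
        raise ValueError(f"unknown phase_init {phase_init!r}")
    return PopulationState(phases=phases, nu=nu, seed=seed)


def full_rhs(
    pop: PopulationState, res: ResourceState, params: ModelParams
) -> tuple[np.ndarray, complex, float, float]:
    """Derivatives of (phases, r, lam) plus the instantaneous activity A."""
    if not (np.all(np.isfinite(pop.phases)) and np.isfinite(res.lam)):
        raise ValueError("non-finite state")
    Z = np.exp(1j * pop.phases).mean()
    dphi = (
        res.r1
        + res.r2 * pop.nu
        - np.sin(pop.phases)
        + params.sigma * (Z.imag * np.cos(pop.phases) - Z.real * np.sin(pop.phases))
    )
    A = float(dphi.mean())
    dr = params.eps * metabolic_f(res.r - params.s, res.lam, params.omega)
    dlam = -params.eps_prime * (res.lam - params.lambda0 - params.gamma * A)
    return dphi, dr, dlam, A


@njit(cache=True)
def _net_deriv(ph, nu, r1, r2, lam, sigma, eps, epsp, s1, s2, omega, lam0, gamma,
               freeze_res, hold_lam, dph, sbuf, cbuf):
    # sin/cos evaluated once per phase and reused (the trig calls dominate)
    N = ph.size
    zx = 0.0
    zy = 0.0
    for k in range(N):
        sbuf[k] = math.sin(ph[k])
        cbuf[k] = math.cos(ph[k])
        zx += cbuf[k]
        zy += sbuf[k]
    zx /= N
    zy /= N
    A = 0.0
    for k in range(N):
        dph[k] = r1 + r2 * nu[k] - sbuf[k] + sigma * (zy * cbuf[k] - zx * sbuf[k])
        A += dph[k]
    A /= N
    if freeze_res:
        dr1 = 0.0
        dr2 = 0.0
    else:
        u1 = r1 - s1
        u2 = r2 - s2
        m2 = u1 * u1 + u2 * u2
        dr1 = eps * (u1 * lam - u2 * omega - u1 * m2)
        dr2 = eps * (u1 * omega + u2 * lam - u2 * m2)
    if hold_lam or freeze_res:
        dlam = 0.0
    else:
        dlam = -epsp * (lam - lam0 - gamma * A)
    return dr1, dr2, dlam, A, zx, zy


@njit(cache=True)
def _rk4_network(ph, nu, r1, r2, lam, sigma, eps, epsp, s1, s2, omega, lam0, gamma,
                 dt, n_steps, out_every, freeze_res, hold_lam):
    N = ph.size
    n_out = n_steps // out_every + 1
    outA = np.empty(n_out)
    outX = np.empty(n_out)
    outY = np.empty(n_out)
    outr1 = np.empty(n_out)
    outr2 = np.empty(n_out)
    outlam = np.empty(n_out)
    k1 = np.empty(N)
    k2 = np.empty(N)
    k3 = np.empty(N)
    k4 = np.empty(N)
    tmp = np.empty(N)
    sbuf = np.empty(N)
    cbuf = np.empty(N)

    j = 0
    for step in range(n_steps + 1):
        if step % out_every == 0:
            dr1, dr2, dlam, A, zx, zy = _net_deriv(
                ph, nu, r1, r2, lam, sigma, eps, epsp, s1, s2, omega, lam0, gamma,
                freeze_res, hold_lam, k1, sbuf, cbuf)
            outA[j] = A
            outX[j] = zx
            outY[j] = zy
            outr1[j] = r1
            outr2[j] = r2
            outlam[j] = lam
            j += 1
            if j == n_out and step == n_steps:
                break
        if step == n_steps:
            break
        a1, b1, c1, _, _, _ = _net_deriv(ph, nu, r1, r2, lam, sigma, eps, epsp,
                                         s1, s2, omega, lam0, gamma, freeze_res, hold_lam, k1, sbuf, cbuf)
        for k in range(N):
            tmp[k] = ph[k] + 0.5 * dt * k1[k]
        a2, b2, c2, _, _, _ = _net_deriv(tmp, nu, r1 + 0.5 * dt * a1, r2 + 0.5 * dt * b1,
                                         lam + 0.5 * dt * c1, sigma, eps, epsp, s1, s2,
                                         omega, lam0, gamma, freeze_res, hold_lam, k2, sbuf, cbuf)
        for k in range(N):
            tmp[k] = ph[k] + 0.5 * dt * k2[k]
        a3, b3, c3, _, _, _ = _net_deriv(tmp, nu, r1 + 0.5 * dt * a2, r2 + 0.5 * dt * b2,
                                         lam + 0.5 * dt * c2, sigma, eps, epsp, s1, s2,
                                         omega, lam0, gamma, freeze_res, hold_lam, k3, sbuf, cbuf)
        for k in range(N):
            tmp[k] = ph[k] + dt * k3[k]
        a4, b4, c4, _, _, _ = _net_deriv(tmp, nu, r1 + dt * a3, r2 + dt * b3,
                                         lam + dt * c3, sigma, eps, epsp, s1, s2,
                                         omega, lam0, gamma, freeze_res, hold_lam, k4, sbuf, cbuf)
        for k in range(N):
            ph[k] += dt / 6.0 * (k1[k] + 2.0 * k2[k] + 2.0 * k3[k] + k4[k])
        r1 += dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        r2 += dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        lam += dt / 6.0 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)

    return outA, outX, outY, outr1, outr2, outlam, ph, r1, r2, lam


def simulate(
    pop0: PopulationState,
    res0: ResourceState,
    params: ModelParams,
    t_end: float,
    dt_out: float = 0.5,
    method: str = "rk4",
    dt: float = 0.01,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    freeze_resources: bool = False,
    hold_lambda: bool = False,
) -> TimeSeries:
    """Integrate the coupled system for ``t_end`` fast time units.

    ``method="rk4"`` is a fixed-step (bit-reproducible) classical
    Runge-Kutta integrator with step ``dt``; ``method="rk45"`` uses the
    adaptive Dormand-Prince pair at (rtol, atol).  ``freeze_resources``
    pins (r, lam) at their initial values (layer-only runs);
    ``hold_lambda`` suspends only the lam equation (clamp protocols).

    The recorded activity A(t) is the exact instantaneous mean of the
    analytic phase right-hand sides, never a finite difference.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    nu = np.asarray(pop0.nu, dtype=float)
    meta = dict(
        engine="network", N=pop0.N, method=method, dt_out=dt_out,
        sigma=params.sigma, eps=params.eps, eps_prime=params.eps_prime,
        s1=params.s1, s2=params.s2, omega=params.omega,
        lambda0=params.lambda0, gamma=params.gamma,
        freeze_resources=freeze_resources, hold_lambda=hold_lambda,
        population_seed=pop0.seed,
    )

    if method == "rk4":
        n_steps = int(round(t_end / dt))
        out_every = max(1, int(round(dt_out / dt)))
        meta.update(dt=dt)
        outA, outX, outY, outr1, outr2, outlam, ph, r1f, r2f, lamf = _rk4_network(
            pop0.phases.copy(), nu, res0.r1, res0.r2, res0.lam,
            params.sigma, params.eps, params.eps_prime, params.s1, params.s2,
            params.omega, params.lambda0, params.gamma,
            dt, n_steps, out_every, freeze_resources, hold_lambda)
        t = np.arange(outA.size) * (out_every * dt)
        Z = outX + 1j * outY
        final = dict(phases=ph, resource=ResourceState(r=complex(r1f, r2f), lam=lamf))
    elif method == "rk45":
        meta.update(rtol=rtol, atol=atol)
        N = pop0.N

        def rhs(t, y):
            pop = PopulationState.__new__(PopulationState)
            pop.phases = y[:N]
            pop.nu = nu
            res = ResourceState.__new__(ResourceState)
            res.r = complex(y[N], y[N + 1])
            res.lam = y[N + 2]
            dphi, dr, dlam, _ = full_rhs(pop, res, params)
            if freeze_resources:
                dr, dlam = 0.0j, 0.0
            elif hold_lambda:
                dlam = 0.0
            return np.concatenate([dphi, [dr.real, dr.imag, dlam]])

        y0 = np.concatenate([pop0.phases, [res0.r1, res0.r2, res0.lam]])
        t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
        sol = solve_ivp(rhs, (0.0, t_end), y0, method="RK45", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        t = sol.t
        phases_t = sol.y[:N]
        Z = np.exp(1j * phases_t).mean(axis=0)
        outr1, outr2, outlam = sol.y[N], sol.y[N + 1], sol.y[N + 2]
        # exact instantaneous mean velocity (coupling term averages out)
        outA = outr1 + outr2 * nu.mean() - Z.imag
        final = dict(
            phases=sol.y[:N, -1].copy(),
            resource=ResourceState(r=complex(outr1[-1], outr2[-1]), lam=outlam[-1]),
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    return TimeSeries(
        t=t, A=outA, R=np.abs(Z), Theta=np.angle(Z),
        r1=np.asarray(outr1), r2=np.asarray(outr2), lam=np.asarray(outlam),
        meta=meta, final_state=final,
    )


def summarize(ts: TimeSeries, transient: float, window: float) -> dict:
    """Time averages over the final ``window`` of the series.

    The regime label is "steady" iff max lam over the window is < 0,
    otherwise "active/bursting".
    """
    t_end = ts.t[-1]
    if window > t_end - transient:
        raise ValueError("window exceeds series duration minus transient")
    sel = ts.t >= t_end - window
    lam_max = float(ts.lam[sel].max())
    return dict(
        mean_A=float(ts.A[sel].mean()),
        mean_R=float(ts.R[sel].mean()),
        R_range=float(ts.R[sel].max() - ts.R[sel].min()),
        max_lam=lam_max,
        label="steady" if lam_max < 0.0 else "active/bursting",
    )
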