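"""Slow-fast analysis: averaged slow dynamics, the coupled reduced system,
adiabatic sweeps and switching protocols.

Because the resource pool evolves a factor eps slower than the rotators,
the slow subsystem can be averaged over the fast layer attractor:

    dr/dtau   = f(r - s, lam),
    dlam/dtau = -(lam - lambda0 - gamma * <A>(r1, r2)),     tau = eps * t,

where <A>(r1, r2) is the time-averaged layer activity (an ActivityTable).
Mechanism of collective activity bursting: while (r1, r2) sits on the
oscillating side of the layer's critical line, <A> > 0 drives lam up;
once lam > 0 the resource orbits the base level s, recurrently crossing
the critical line, where <A> collapses and lam drains back toward
lambda0 < 0 — the spiral toward s then re-enters the active region.

The coupled reduced system integrates the Ott-Antonsen field together
with the slow resource equations (no averaging), which remains valid
inside bursts where averaging is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from numba import njit
from scipy.interpolate import RegularGridInterpolator

from .model import ModelParams, ResourceState
from .network import PopulationState, TimeSeries, init_population, simulate as _net_simulate
from .oa import OAField, integrate_layer, classify_theta_dynamics

__all__ = [
    "ActivityTable",
    "SweepResult",
    "average_activity_map",
    "reduced_rhs",
    "simulate_reduced_oa",
    "adiabatic_sweep",
    "apply_perturbation",
    "classify_regime",
    "count_zero_crossings",
]


def count_zero_crossings(t: np.ndarray, x: np.ndarray, transient: float = 0.0) -> int:
    """Number of strict sign changes of x(t) after the transient."""
    sel = np.asarray(t) >= transient
    s = np.sign(np.asarray(x)[sel])
    s = s[s != 0]
    return int(np.sum(s[1:] * s[:-1] < 0))


def classify_regime(t: np.ndarray, lam: np.ndarray, transient: float = 0.0) -> str:
    """Label a full-system trajectory from its resource activity lam(t).

    "steady" iff max lam < 0 over the post-transient window; otherwise
    "bursting" when lam changes sign at least twice (recurrent
    activation/deactivation), else "active".
    """
    sel = np.asarray(t) >= transient
    lam_w = np.asarray(lam)[sel]
    if lam_w.max() < 0.0:
        return "steady"
    return "bursting" if count_zero_crossings(t, lam, transient) >= 2 else "active"


@dataclass
class ActivityTable:
    """Gridded time-averaged layer activity and coherence over (r1, r2).

    Bilinear interpolation between grid nodes; queries outside the grid
    hull raise (extrapolating the layer attractor is meaningless).
    """

    r1_grid: np.ndarray
    r2_grid: np.ndarray
    mean_A: np.ndarray  # shape (len(r1_grid), len(r2_grid))
    mean_R: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r1_grid = np.asarray(self.r1_grid, float)
        self.r2_grid = np.asarray(self.r2_grid, float)
        self._A_interp = RegularGridInterpolator(
            (self.r1_grid, self.r2_grid), np.asarray(self.mean_A, float),
            method="linear", bounds_error=True)
        self._R_interp = RegularGridInterpolator(
            (self.r1_grid, self.r2_grid), np.asarray(self.mean_R, float),
            method="linear", bounds_error=True)

    def activity(self, r1: float, r2: float) -> float:
        try:
            return float(self._A_interp((r1, r2)))
        except ValueError as err:
            raise ValueError(
                f"query ({r1:.4g}, {r2:.4g}) outside the activity-table hull") from err

    def coherence(self, r1: float, r2: float) -> float:
        return float(self._R_interp((r1, r2)))


def average_activity_map(
    r1_grid,
    r2_grid,
    sigma: float,
    t_total: float = 200.0,
    window: float = 100.0,
    M: int = 201,
    amp_floor: float = 0.05,
) -> ActivityTable:
    """Tabulate <A> and <R> of the layer attractor on an (r1, r2) grid.

    Each cell integrates the OA layer from the incoherent state for
    ``t_total`` time units and averages A = r1 - Im Z and R = |Z| over the
    final ``window``.  Cells whose mean phase is classified stationary are
    refined with the closed-form stationary activity A = r1 - p1 of the
    branch matching the asymptotic order parameter.
    """
    from .stationary import find_stationary_states

    r1_grid = np.asarray(r1_grid, float)
    r2_grid = np.asarray(r2_grid, float)
    A = np.empty((r1_grid.size, r2_grid.size))
    R = np.empty_like(A)
    for i, r1 in enumerate(r1_grid):
        for j, r2 in enumerate(r2_grid):
            f0 = OAField.incoherent(M, r1=r1, r2=r2)
            traj = integrate_layer(f0, sigma, t_total, dt_out=0.5)
            sel = traj.t >= t_total - window
            A[i, j] = float(traj.A[sel].mean())
            R[i, j] = float(traj.R[sel].mean())
            if classify_theta_dynamics(traj.t, traj.Z, t_total - window, amp_floor) == "stationary":
                Zf = traj.Z[-1]
                branches = find_stationary_states(r1, r2, sigma)
                if branches:
                    best = min(branches, key=lambda b: abs(b.Z - Zf))
                    if abs(best.Z - Zf) < 0.05:
                        A[i, j] = best.activity
                        R[i, j] = best.R
    return ActivityTable(
        r1_grid=r1_grid, r2_grid=r2_grid, mean_A=A, mean_R=R,
        provenance=dict(engine="oa", sigma=sigma, t_total=t_total,
                        window=window, M=M, initial="incoherent"))


def reduced_rhs(res: ResourceState, table: ActivityTable, params: ModelParams):
    """Averaged slow dynamics in rescaled slow time tau = eps * t.

    Returns (dr/dtau, dlam/dtau) with the activity drive read from the
    table at the current resource levels.
    """
    u = res.r - params.s
    dr = u * (res.lam + 1j * params.omega - abs(u) ** 2)
    A = table.activity(res.r1, res.r2)
    dlam = -(res.lam - params.lambda0 - params.gamma * A)
    return dr, dlam


@njit(cache=True)
def _red_deriv(x, y, nodes, w, r1, r2, lam, sigma, eps, epsp, s1, s2, omega,
               lam0, gamma, hold_lam, dx, dy):
    M = x.size
    X = 0.0
    Y = 0.0
    for m in range(M):
        X += w[m] * x[m]
        Y += w[m] * y[m]
    for m in range(M):
        Im = r1 + r2 * nodes[m]
        x2 = x[m] * x[m] - y[m] * y[m]
        xy = x[m] * y[m]
        dx[m] = 0.5 * (1.0 - x2) - Im * y[m] + 0.5 * sigma * X - 0.5 * sigma * (X * x2 + 2.0 * xy * Y)
        dy[m] = -xy + Im * x[m] + 0.5 * sigma * Y - 0.5 * sigma * (2.0 * xy * X - Y * x2)
    A = r1 - Y  # mean-field activity
    u1 = r1 - s1
    u2 = r2 - s2
    m2 = u1 * u1 + u2 * u2
    dr1 = eps * (u1 * lam - u2 * omega - u1 * m2)
    dr2 = eps * (u1 * omega + u2 * lam - u2 * m2)
    dlam = 0.0 if hold_lam else -epsp * (lam - lam0 - gamma * A)
    return dr1, dr2, dlam, A, X, Y


@njit(cache=True)
def _rk4_reduced(x, y, nodes, w, r1, r2, lam, sigma, eps, epsp, s1, s2, omega,
                 lam0, gamma, dt, n_steps, out_every, hold_lam):
    M = x.size
    n_out = n_steps // out_every + 1
    outA = np.empty(n_out)
    outX = np.empty(n_out)
    outY = np.empty(n_out)
    outr1 = np.empty(n_out)
    outr2 = np.empty(n_out)
    outlam = np.empty(n_out)
    kx1 = np.empty(M); ky1 = np.empty(M)
    kx2 = np.empty(M); ky2 = np.empty(M)
    kx3 = np.empty(M); ky3 = np.empty(M)
    kx4 = np.empty(M); ky4 = np.empty(M)
    tx = np.empty(M); ty = np.empty(M)
    max_abs = 0.0
    j = 0
    for step in range(n_steps + 1):
        if step % out_every == 0:
            a1, b1, c1, A, X, Y = _red_deriv(x, y, nodes, w, r1, r2, lam, sigma, eps,
                                             epsp, s1, s2, omega, lam0, gamma, hold_lam, kx1, ky1)
            outA[j] = A
            outX[j] = X
            outY[j] = Y
            outr1[j] = r1
            outr2[j] = r2
            outlam[j] = lam
            for m in range(M):
                a = math.sqrt(x[m] * x[m] + y[m] * y[m])
                if a > max_abs:
                    max_abs = a
            j += 1
        if step == n_steps:
            break
        a1, b1, c1, A, X, Y = _red_deriv(x, y, nodes, w, r1, r2, lam, sigma, eps,
                                         epsp, s1, s2, omega, lam0, gamma, hold_lam, kx1, ky1)
        for m in range(M):
            tx[m] = x[m] + 0.5 * dt * kx1[m]
            ty[m] = y[m] + 0.5 * dt * ky1[m]
        a2, b2, c2, A, X, Y = _red_deriv(tx, ty, nodes, w, r1 + 0.5 * dt * a1, r2 + 0.5 * dt * b1,
                                         lam + 0.5 * dt * c1, sigma, eps, epsp, s1, s2, omega,
                                         lam0, gamma, hold_lam, kx2, ky2)
        for m in range(M):
            tx[m] = x[m] + 0.5 * dt * kx2[m]
            ty[m] = y[m] + 0.5 * dt * ky2[m]
        a3, b3, c3, A, X, Y = _red_deriv(tx, ty, nodes, w, r1 + 0.5 * dt * a2, r2 + 0.5 * dt * b2,
                                         lam + 0.5 * dt * c2, sigma, eps, epsp, s1, s2, omega,
                                         lam0, gamma, hold_lam, kx3, ky3)
        for m in range(M):
            tx[m] = x[m] + dt * kx3[m]
            ty[m] = y[m] + dt * ky3[m]
        a4, b4, c4, A, X, Y = _red_deriv(tx, ty, nodes, w, r1 + dt * a3, r2 + dt * b3,
                                         lam + dt * c3, sigma, eps, epsp, s1, s2, omega,
                                         lam0, gamma, hold_lam, kx4, ky4)
        for m in range(M):
            x[m] += dt / 6.0 * (kx1[m] + 2.0 * kx2[m] + 2.0 * kx3[m] + kx4[m])
            y[m] += dt / 6.0 * (ky1[m] + 2.0 * ky2[m] + 2.0 * ky3[m] + ky4[m])
        r1 += dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        r2 += dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        lam += dt / 6.0 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
    return outA, outX, outY, outr1, outr2, outlam, x, y, r1, r2, lam


def simulate_reduced_oa(
    params: ModelParams,
    field0: Optional[OAField] = None,
    res0: Optional[ResourceState] = None,
    t_end: float = 2000.0,
    dt_out: float = 0.5,
    dt: float = 0.01,
    M: int = 201,
    hold_lambda: bool = False,
) -> TimeSeries:
    """Integrate the coupled reduced system (OA field + slow resources).

    The Ott-Antonsen field and the resource equations are advanced
    simultaneously in fast time (no averaging):

        dz_m/dt = OA right-hand side at I_m = r1(t) + r2(t) nu_m,
        dr/dt   = eps f(r - s, lam),
        dlam/dt = -eps' (lam - lambda0 - gamma (r1 - Im Z)).

    Defaults start from the incoherent field at the base level with
    lam = lambda0.  Unit-disk invariance of the field is monitored.
    """
    if field0 is None:
        field0 = OAField.incoherent(M, r1=params.s1, r2=params.s2)
    if res0 is None:
        res0 = ResourceState(r=complex(field0.r1, field0.r2), lam=params.lambda0)
    n_steps = int(round(t_end / dt))
    out_every = max(1, int(round(dt_out / dt)))
    outA, outX, outY, outr1, outr2, outlam, xf, yf, r1f, r2f, lamf = _rk4_reduced(
        field0.z.real.copy(), field0.z.imag.copy(), field0.nodes, field0.weights,
        res0.r1, res0.r2, res0.lam, params.sigma, params.eps, params.eps_prime,
        params.s1, params.s2, params.omega, params.lambda0, params.gamma,
        dt, n_steps, out_every, hold_lambda)
    max_abs = float(np.sqrt(xf**2 + yf**2).max())
    if max_abs > 1.0 + 1e-6:
        raise RuntimeError(f"OA unit-disk invariant breached: max |z| = {max_abs:.6g}")
    t = np.arange(outA.size) * (out_every * dt)
    Z = outX + 1j * outY
    final_field = OAField(nodes=field0.nodes, weights=field0.weights,
                          z=xf + 1j * yf, r1=r1f, r2=r2f)
    return TimeSeries(
        t=t, A=outA, R=np.abs(Z), Theta=np.angle(Z),
        r1=outr1, r2=outr2, lam=outlam,
        meta=dict(engine="reduced_oa", M=field0.M, dt=dt, dt_out=dt_out,
                  sigma=params.sigma, eps=params.eps, eps_prime=params.eps_prime,
                  s1=params.s1, s2=params.s2, gamma=params.gamma,
                  hold_lambda=hold_lambda),
        final_state=dict(field=final_field,
                         resource=ResourceState(r=complex(r1f, r2f), lam=lamf)),
    )


@dataclass
class SweepResult:
    """Adiabatic continuation in the resource base level s1."""

    direction: str
    s1: np.ndarray
    mean_A: np.ndarray
    mean_R: np.ndarray
    max_lam: np.ndarray
    labels: List[str]
    meta: dict = field(default_factory=dict)

    def at(self, s1_value: float) -> dict:
        """Summary at the grid point closest to s1_value."""
        i = int(np.argmin(np.abs(self.s1 - s1_value)))
        return dict(s1=float(self.s1[i]), mean_A=float(self.mean_A[i]),
                    mean_R=float(self.mean_R[i]), max_lam=float(self.max_lam[i]),
                    label=self.labels[i])


def _initial_state(kind: str, params: ModelParams, engine: str, seed: int, M: int):
    """Warm-up initial condition for a sweep chain.

    "steady" starts near the base level with resting resources (the
    chain's first transient settles into the quiescent state where one
    exists).  The resource starts slightly off s: the base level is an
    exact equilibrium of the resource equation at every lam, so a state
    placed exactly on it could never respond to a later activation of
    lam — the small offset plays the role of the fluctuations any finite
    system carries.  "oscillatory" starts with the resource displaced
    into the active region and lam > 0 (inside the bursting basin).
    """
    if kind == "steady":
        res = ResourceState(r=params.s + 0.05, lam=params.lambda0)
    elif kind == "oscillatory":
        res = ResourceState(r=params.s + 0.4, lam=0.15)
    else:
        raise ValueError(f"unknown initial-state kind {kind!r}")
    if engine == "network":
        pop = init_population(params.N, seed=seed, phase_init="random_uniform")
        return dict(pop=pop, resource=res)
    return dict(field=OAField.incoherent(M, r1=res.r1, r2=res.r2), resource=res)


def adiabatic_sweep(
    s1_start: float,
    s1_end: float,
    delta_s1: float,
    params: ModelParams,
    engine: str = "reduced_oa",
    t_sim: float = 700.0,
    window: float = 500.0,
    seed: int = 0,
    M: int = 201,
    dt: float = 0.01,
    init: Optional[Union[str, dict]] = None,
) -> SweepResult:
    """Chain of simulations stepping the base level s1 by delta_s1.

    Each step is warm-started from the predecessor's final state and
    summarized over its last ``window`` time units.  Sweeps up
    conventionally start from the steady state, sweeps down from an
    oscillatory state (``init`` overrides).  The reference protocol is
    7000/5000 time units per step with delta_s1 = 0.002; shorter windows
    preserve the regime labels and keep runs affordable.
    """
    if delta_s1 == 0:
        raise ValueError("delta_s1 must be nonzero")
    direction = "up" if s1_end > s1_start else "down"
    delta = abs(delta_s1) if direction == "up" else -abs(delta_s1)
    n_step = int(round((s1_end - s1_start) / delta)) + 1
    s1_values = s1_start + delta * np.arange(n_step)

    if init is None:
        init = "steady" if direction == "up" else "oscillatory"
    state = _initial_state(init, params.with_(s1=s1_start), engine, seed, M) if isinstance(init, str) else dict(init)

    mean_A = np.empty(n_step)
    mean_R = np.empty(n_step)
    max_lam = np.empty(n_step)
    labels: List[str] = []
    for i, s1 in enumerate(s1_values):
        p_i = params.with_(s1=float(s1))
        if engine == "network":
            ts = _net_simulate(state["pop"], state["resource"], p_i, t_end=t_sim,
                               dt_out=0.5, method="rk4", dt=dt)
            state = dict(pop=PopulationState(phases=ts.final_state["phases"], nu=state["pop"].nu),
                         resource=ts.final_state["resource"])
        elif engine == "reduced_oa":
            ts = simulate_reduced_oa(p_i, field0=state["field"], res0=state["resource"],
                                     t_end=t_sim, dt_out=0.5, dt=dt)
            state = dict(field=ts.final_state["field"], resource=ts.final_state["resource"])
        else:
            raise ValueError(f"unknown engine {engine!r}")
        sel = ts.t >= t_sim - window
        mean_A[i] = ts.A[sel].mean()
        mean_R[i] = ts.R[sel].mean()
        max_lam[i] = ts.lam[sel].max()
        labels.append(classify_regime(ts.t, ts.lam, t_sim - window))
    return SweepResult(
        direction=direction, s1=s1_values, mean_A=mean_A, mean_R=mean_R,
        max_lam=max_lam, labels=labels,
        meta=dict(engine=engine, t_sim=t_sim, window=window, delta_s1=delta,
                  seed=seed, M=M, dt=dt, init=init if isinstance(init, str) else "custom"))


def _segment(state: dict, params: ModelParams, t_end: float, engine: str,
             dt: float, dt_out: float, hold_lambda: bool = False) -> TimeSeries:
    if engine == "network":
        return _net_simulate(state["pop"], state["resource"], params, t_end=t_end,
                             dt_out=dt_out, method="rk4", dt=dt, hold_lambda=hold_lambda)
    return simulate_reduced_oa(params, field0=state["field"], res0=state["resource"],
                               t_end=t_end, dt_out=dt_out, dt=dt, hold_lambda=hold_lambda)


def apply_perturbation(
    state0: dict,
    protocol: dict,
    params: ModelParams,
    engine: str = "reduced_oa",
    t_end: float = 4000.0,
    dt: float = 0.01,
    dt_out: float = 0.5,
    verdict_window: float = 1000.0,
) -> tuple[TimeSeries, dict]:
    """Run a switching experiment: evolve, perturb lam, evolve, compare.

    ``protocol`` is ``{"kind": "reset", "value": v, "t_p": t}`` (lam is set
    to v instantaneously at t) or ``{"kind": "clamp", "value": v, "t_p": t,
    "duration": D}`` (lam held at v, its equation suspended, for D time
    units).  ``state0`` holds the engine-specific initial state (pop= or
    field=, plus resource=).  The verdict compares the regime label over
    the window before t_p with the label over the final window, and
    records the resource phase (lam and its sign) at the moment the
    perturbation lands.
    """
    kind = protocol["kind"]
    t_p = float(protocol["t_p"])
    value = float(protocol["value"])
    if kind not in ("reset", "clamp"):
        raise ValueError(f"unknown perturbation kind {kind!r}")
    if kind == "clamp":
        duration = float(protocol["duration"])
        if duration <= 0:
            raise ValueError("clamp duration must be > 0")
    if not 0 < t_p < t_end:
        raise ValueError("t_p must lie inside the run")

    state = dict(state0)
    pre = _segment(state, params, t_p, engine, dt, dt_out)
    state = _advance_state(state, pre)
    lam_at_tp = float(pre.lam[-1])

    segments = [pre]
    t_offset = t_p
    res = state["resource"]
    state["resource"] = ResourceState(r=res.r, lam=value)
    if kind == "clamp":
        mid = _segment(state, params, duration, engine, dt, dt_out, hold_lambda=True)
        state = _advance_state(state, mid)
        mid.t = mid.t + t_offset
        segments.append(mid)
        t_offset += duration
    post = _segment(state, params, t_end - t_offset, engine, dt, dt_out)
    post.t = post.t + t_offset
    segments.append(post)

    ts = TimeSeries(
        t=np.concatenate([s.t for s in segments]),
        A=np.concatenate([s.A for s in segments]),
        R=np.concatenate([s.R for s in segments]),
        Theta=np.concatenate([s.Theta for s in segments]),
        r1=np.concatenate([s.r1 for s in segments]),
        r2=np.concatenate([s.r2 for s in segments]),
        lam=np.concatenate([s.lam for s in segments]),
        meta=dict(engine=engine, protocol=dict(protocol), dt=dt, dt_out=dt_out),
        final_state=segments[-1].final_state,
    )
    w = min(verdict_window, 0.5 * t_p)
    label_pre = classify_regime(pre.t, pre.lam, t_p - w)
    label_post = classify_regime(post.t - t_offset, post.lam,
                                 (t_end - t_offset) - verdict_window)
    verdict = dict(
        label_pre=label_pre,
        label_post=label_post,
        switched=label_pre != label_post,
        lam_at_perturbation=lam_at_tp,
        application_phase="active" if lam_at_tp > 0 else "inactive",
    )
    return ts, verdict


def _advance_state(state: dict, ts: TimeSeries) -> dict:
    new = dict(state)
    if "pop" in state:
        new["pop"] = PopulationState(phases=ts.final_state["phases"], nu=state["pop"].nu)
    else:
        new["field"] = ts.final_state["field"]
    new["resource"] = ts.final_state["resource"]
    return new
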