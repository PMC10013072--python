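"""Two-parameter structure of the layer dynamics in the (r1, r2) plane.

The number of stationary branches changes at folds of the self-consistency
function: parameter points where p(B) = 0 and dp/dB = 0 simultaneously.
Two fold branches (annihilating B1-B2 and B2-B3 respectively) bound the
wedge of tristability and meet at a codimension-two cusp.  Alongside the
fold curves, an operational "critical line" is computed by bisecting r1 on
the stationary-vs-oscillating classification of the Ott-Antonsen layer
started from the incoherent state — the two definitions agree closely
where the stable stationary state is the only attractor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from .oa import OAField, classify_theta_dynamics, integrate_layer
from .stationary import find_stationary_states, p_derivative, p_function

__all__ = [
    "FoldPoint",
    "FoldCurve",
    "RegimeMap",
    "count_roots",
    "fold_points_at",
    "fold_branches",
    "critical_line",
    "regime_map",
    "hopf_like_locus",
]


@dataclass
class FoldPoint:
    """A double root of p(B) at fixed (r2, sigma): fold location in r1."""

    r1: float
    r2: float
    B: float
    pair: str  # "B1-B2" (coherent pair) or "B2-B3"
    residual_p: float
    residual_dp: float


@dataclass
class FoldCurve:
    """Ordered fold points along one branch of folds."""

    branch_id: str  # "lower" (B1-B2) or "upper" (B2-B3)
    points: List[FoldPoint]
    cusp: Optional[tuple[float, float]] = None

    @property
    def r1(self) -> np.ndarray:
        return np.array([p.r1 for p in self.points])

    @property
    def r2(self) -> np.ndarray:
        return np.array([p.r2 for p in self.points])


@dataclass
class RegimeMap:
    """Gridded layer-regime summaries over the (r1, r2) plane."""

    r1_grid: np.ndarray
    r2_grid: np.ndarray
    mean_A: np.ndarray
    mean_R: np.ndarray
    R_range: np.ndarray
    theta_class: np.ndarray  # strings "stationary"/"oscillating"
    meta: dict = field(default_factory=dict)


def count_roots(r1: float, r2: float, sigma: float,
                B_min: float = 1e-3, B_max: Optional[float] = None,
                n_scan: int = 4000) -> int:
    """Number of sign changes of p(B) on a fast scan grid."""
    from .model import GAUSSIAN_TRUNCATION

    if B_max is None:
        B_max = 1.0 + sigma + abs(r1) + GAUSSIAN_TRUNCATION * r2
    grid = np.geomspace(B_min, B_max, n_scan)
    vals = p_function(grid, r1, r2, sigma, fast=True)
    s = np.sign(vals)
    return int(np.sum(s[:-1] * s[1:] < 0))


def _fold_newton(B0: float, r10: float, r2: float, sigma: float,
                 tol: float = 1e-10, max_iter: int = 40) -> tuple[float, float]:
    """Polish a double root: solve {p(B; r1) = 0, dp/dB(B; r1) = 0} for (B, r1)."""
    B, r1 = float(B0), float(r10)
    for _ in range(max_iter):
        F0 = np.array([p_function(B, r1, r2, sigma), p_derivative(B, r1, r2, sigma)])
        if np.max(np.abs(F0)) < tol:
            break
        hB = 1e-6 * max(1.0, abs(B))
        hr = 1e-7
        J = np.empty((2, 2))
        FB = np.array([p_function(B + hB, r1, r2, sigma), p_derivative(B + hB, r1, r2, sigma)])
        Fr = np.array([p_function(B, r1 + hr, r2, sigma), p_derivative(B, r1 + hr, r2, sigma)])
        J[:, 0] = (FB - F0) / hB
        J[:, 1] = (Fr - F0) / hr
        try:
            step = np.linalg.solve(J, -F0)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular Jacobian in fold Newton (cusp proximity?)")
        # damped update to stay in the admissible region
        scale = 1.0
        while B + scale * step[0] <= 0 and scale > 1e-4:
            scale *= 0.5
        B += scale * step[0]
        r1 += scale * step[1]
    else:
        raise RuntimeError(f"fold Newton did not converge at r2={r2}")
    return B, r1


def _identify_pair(r1_fold: float, r2: float, sigma: float, B_double: float) -> str:
    """Which stationary pair annihilates at the fold.

    Looks at the branch structure slightly inside the three-root region:
    the merging pair brackets B_double; "B1-B2" when it is the two largest
    roots (the coherent pair), else "B2-B3".
    """
    for d in (1e-3, 3e-3, 1e-2, 3e-2):
        for r1_in in (r1_fold - d, r1_fold + d):
            branches = find_stationary_states(r1_in, r2, sigma)
            if len(branches) >= 3:
                Bs = sorted((b.B for b in branches), reverse=True)
                gaps = [abs(0.5 * (Bs[i] + Bs[i + 1]) - B_double) for i in range(len(Bs) - 1)]
                return "B1-B2" if int(np.argmin(gaps)) == 0 else "B2-B3"
    return "unresolved"


def fold_points_at(
    sigma: float,
    r2: float,
    r1_range: tuple[float, float] = (0.05, 2.5),
    n_coarse: int = 30,
) -> List[FoldPoint]:
    """All folds in r1 at fixed (sigma, r2), by root-count bisection + Newton.

    Scans the root count of p over r1, bisects every change, recovers the
    merging pair's B from the three-root side and polishes the double-root
    condition by Newton iteration.
    """
    r1s = np.linspace(r1_range[0], r1_range[1], n_coarse)
    counts = [count_roots(r1, r2, sigma) for r1 in r1s]
    folds: List[FoldPoint] = []
    for i in range(len(r1s) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi = r1s[i], r1s[i + 1]
        c_lo = counts[i]
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            if count_roots(mid, r2, sigma) == c_lo:
                lo = mid
            else:
                hi = mid
        r1_mid = 0.5 * (lo + hi)
        # B estimate: at the fold p(B) touches zero, so the double root is the
        # local extremum of p with the smallest |p| (simple roots cross zero
        # and are local extrema of |p| only, not of p).
        from .model import GAUSSIAN_TRUNCATION

        grid = np.geomspace(1e-3, 1.0 + sigma + abs(r1_mid) + GAUSSIAN_TRUNCATION * r2, 4000)
        vals = p_function(grid, r1_mid, r2, sigma, fast=True)
        d = np.diff(vals)
        ext = np.nonzero(d[:-1] * d[1:] < 0)[0] + 1
        if ext.size == 0:
            continue
        B0 = float(grid[ext[np.argmin(np.abs(vals[ext]))]])
        B_d, r1_d = _fold_newton(B0, r1_mid, r2, sigma)
        folds.append(FoldPoint(
            r1=r1_d, r2=r2, B=B_d,
            pair=_identify_pair(r1_d, r2, sigma, B_d),
            residual_p=abs(p_function(B_d, r1_d, r2, sigma)),
            residual_dp=abs(p_derivative(B_d, r1_d, r2, sigma)),
        ))
    return folds


def fold_branches(
    sigma: float,
    r2_range: tuple[float, float] = (0.6, 2.6),
    step: float = 0.05,
    r1_range: tuple[float, float] = (0.05, 2.5),
) -> List[FoldCurve]:
    """Continue both fold branches over a range of r2.

    Plain predictor-corrector continuation in r2: the previous fold point
    seeds the Newton polish at the next r2 (with step halving on failure);
    the first point of each branch comes from a full root-count scan.  The
    cusp is recorded where the two branches approach within 2e-3.
    """
    r2_lo, r2_hi = r2_range
    first = fold_points_at(sigma, r2_lo, r1_range)
    curves: List[FoldCurve] = []
    for fp in first:
        branch_id = "lower" if fp.pair == "B1-B2" else "upper"
        pts = [fp]
        r2 = r2_lo
        B, r1 = fp.B, fp.r1
        h = step
        while r2 < r2_hi - 1e-12:
            r2_next = min(r2 + h, r2_hi)
            try:
                B_n, r1_n = _fold_newton(B, r1, r2_next, sigma)
                if abs(r1_n - r1) > 0.3:  # jumped to a different branch
                    raise RuntimeError("continuation jump")
            except RuntimeError:
                h *= 0.5
                if h < step / 64:
                    break
                continue
            r2, B, r1 = r2_next, B_n, r1_n
            pts.append(FoldPoint(r1=r1, r2=r2, B=B, pair=fp.pair,
                                 residual_p=abs(p_function(B, r1, r2, sigma)),
                                 residual_dp=abs(p_derivative(B, r1, r2, sigma))))
            h = min(step, 2 * h)
        curves.append(FoldCurve(branch_id=branch_id, points=pts))
    # cusp: closest approach of the two branches, if both were tracked
    if len(curves) == 2:
        a, b = curves
        n = min(len(a.points), len(b.points))
        if n:
            d = np.hypot(a.r1[:n] - b.r1[:n], a.r2[:n] - b.r2[:n])
            i = int(np.argmin(d))
            if d[i] < 2e-3:
                cusp = (0.5 * (a.r1[i] + b.r1[i]), 0.5 * (a.r2[i] + b.r2[i]))
                a.cusp = b.cusp = cusp
    return curves


def _classify_point(r1: float, r2: float, sigma: float, t_total: float,
                    transient: float, M: int, amp_floor: float) -> str:
    field0 = OAField.incoherent(M, r1=r1, r2=r2)
    traj = integrate_layer(field0, sigma, t_total, dt_out=0.5)
    return classify_theta_dynamics(traj.t, traj.Z, transient, amp_floor)


def critical_line(
    sigma: float,
    r2_values,
    r1_bracket: tuple[float, float] = (0.5, 1.3),
    tol: float = 2e-3,
    t_total: float = 200.0,
    transient: float = 100.0,
    M: int = 201,
    amp_floor: float = 0.05,
    with_fold: bool = True,
) -> dict:
    """Critical r1*(r2): onset of oscillating mean-phase dynamics.

    For each r2 the boundary is bisected on the Theta-classification of
    the OA layer started from the incoherent state (the simulation-based
    definition).  With ``with_fold`` the double-root (fold) prediction of
    the B1-B2 branch is solved alongside for comparison.
    """
    r2_values = np.atleast_1d(np.asarray(r2_values, float))
    r1_sim = np.empty(r2_values.size)
    r1_fold = np.full(r2_values.size, np.nan)
    for i, r2 in enumerate(r2_values):
        lo, hi = r1_bracket
        c_lo = _classify_point(lo, r2, sigma, t_total, transient, M, amp_floor)
        c_hi = _classify_point(hi, r2, sigma, t_total, transient, M, amp_floor)
        if c_lo == c_hi:
            raise ValueError(
                f"no classification change in bracket {r1_bracket} at r2={r2}: both {c_lo}")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if _classify_point(mid, r2, sigma, t_total, transient, M, amp_floor) == c_lo:
                lo = mid
            else:
                hi = mid
        r1_sim[i] = 0.5 * (lo + hi)
        if with_fold:
            for fp in fold_points_at(sigma, r2, (max(r1_bracket[0] - 0.2, 0.05), r1_bracket[1] + 0.2)):
                if fp.pair == "B1-B2":
                    r1_fold[i] = fp.r1
    return dict(r2=r2_values, r1_critical=r1_sim, r1_fold=r1_fold,
                meta=dict(sigma=sigma, tol=tol, t_total=t_total, transient=transient,
                          M=M, amp_floor=amp_floor, initial="incoherent"))


def regime_map(
    sigma: float,
    r1_range: tuple[float, float],
    r2_range: tuple[float, float],
    resolution: int = 9,
    engine: str = "oa",
    t_total: float = 200.0,
    window: float = 100.0,
    M: int = 201,
    N: int = 1000,
    seed: int = 0,
    amp_floor: float = 0.05,
) -> RegimeMap:
    """Per-cell layer summaries over an (r1, r2) grid.

    Engine "oa" integrates the mean-field layer from the incoherent state;
    engine "network" simulates a finite population with frozen resources,
    reusing one heterogeneity draw and one random initial phase vector
    across all cells.
    """
    from .model import ModelParams, ResourceState
    from .network import init_population, simulate, summarize

    r1s = np.linspace(*r1_range, resolution)
    r2s = np.linspace(*r2_range, resolution)
    shape = (r1s.size, r2s.size)
    mean_A = np.empty(shape)
    mean_R = np.empty(shape)
    R_range = np.empty(shape)
    theta = np.empty(shape, dtype=object)

    pop0 = init_population(N, seed=seed) if engine == "network" else None
    for i, r1 in enumerate(r1s):
        for j, r2 in enumerate(r2s):
            if engine == "oa":
                traj = integrate_layer(OAField.incoherent(M, r1=r1, r2=r2), sigma,
                                       t_total, dt_out=0.5)
                sel = traj.t >= t_total - window
                mean_A[i, j] = traj.A[sel].mean()
                mean_R[i, j] = traj.R[sel].mean()
                R_range[i, j] = traj.R[sel].max() - traj.R[sel].min()
                theta[i, j] = classify_theta_dynamics(traj.t, traj.Z, t_total - window, amp_floor)
            elif engine == "network":
                from .network import PopulationState
                pop = PopulationState(phases=pop0.phases.copy(), nu=pop0.nu)
                params = ModelParams(sigma=sigma, N=N)
                ts = simulate(pop, ResourceState(r=complex(r1, r2), lam=-1.0), params,
                              t_end=t_total, dt_out=0.5, freeze_resources=True)
                s = summarize(ts, t_total - window, window)
                mean_A[i, j] = s["mean_A"]
                mean_R[i, j] = s["mean_R"]
                R_range[i, j] = s["R_range"]
                th = np.unwrap(ts.Theta[ts.t >= t_total - window])
                drift = abs(th[-1] - th[0])
                ptp = np.ptp(ts.R[ts.t >= t_total - window] * np.sin(th))
                theta[i, j] = "oscillating" if (drift > 2 * math.pi or ptp > amp_floor) else "stationary"
            else:
                raise ValueError(f"unknown engine {engine!r}")
    return RegimeMap(r1_grid=r1s, r2_grid=r2s, mean_A=mean_A, mean_R=mean_R,
                     R_range=R_range, theta_class=theta,
                     meta=dict(sigma=sigma, engine=engine, t_total=t_total,
                               window=window, M=M, N=N, seed=seed))


DEDUP_IMAG = 1e-6


def hopf_like_locus(
    sigma: float,
    r1_values,
    r2_bracket: tuple[float, float] = (2.15, 2.19),
    tol: float = 5e-3,
    spectrum_kwargs: Optional[dict] = None,
) -> dict:
    """Locus where branch B3's leading complex pair crosses the imaginary axis.

    The third stationary branch changes stability in a Hopf-like scenario:
    crossing the locus from below (in r2) the leading complex-conjugate
    pair of its discrete spectrum moves from positive to (small) negative
    real parts.  The curve lives in the fold-over pocket of the lower fold
    branch (r1 near 1, r2 near 2.2 at sigma = 5) where B3 carries a
    complex pair, and is transverse to r2 there, so it is traced by
    bisecting the sign of the pair's real part in r2 at each fixed r1.
    Requires B3 (with a complex pair) at both bracket ends.
    """
    from .spectrum import discrete_spectrum

    skw = dict(spectrum_kwargs or {})

    def lead_re(r1, r2):
        branches = find_stationary_states(r1, r2, sigma)
        if len(branches) < 3:
            raise ValueError(f"branch B3 absent at ({r1:.4g}, {r2:.4g})")
        eigs = discrete_spectrum(branches[2], **skw)
        pairs = [m for m in eigs if m.imag > DEDUP_IMAG]
        if not pairs:
            raise ValueError(f"no complex pair for B3 at ({r1:.4g}, {r2:.4g})")
        return max(pairs, key=lambda m: m.real).real

    r1_values = np.atleast_1d(np.asarray(r1_values, float))
    out = np.empty(r1_values.size)
    ends = []
    for i, r1 in enumerate(r1_values):
        lo, hi = r2_bracket
        f_lo, f_hi = lead_re(r1, lo), lead_re(r1, hi)
        ends.append((f_lo, f_hi))
        if f_lo * f_hi > 0:
            raise ValueError(
                f"no stability change of B3 in r2 bracket {r2_bracket} at r1={r1}")
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if lead_re(r1, mid) * f_lo > 0:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi)
    return dict(r1=r1_values, r2_hopf=out, bracket_lead_re=ends,
                meta=dict(sigma=sigma, tol=tol))
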