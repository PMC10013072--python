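"""Configuration-driven experiments, fixtures and plain-text I/O.

Every experiment kind maps onto one library capability (simulate, layer,
stationary, spectrum, foldmap, regime_map, sweep, perturb).  A resolved
configuration (defaults merged with overrides) is echoed into the output
directory next to the data so that any run can be reproduced exactly; all
randomness is seeded and logged.  The canonical data format is delimited
columnar text with '#'-prefixed metadata headers (17 significant digits,
lossless float round-trip).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .model import ModelParams, ResourceState
from .network import PopulationState, TimeSeries, init_population, simulate, summarize
from .oa import OAField, make_quadrature

__all__ = [
    "ExperimentConfig",
    "PROTOCOLS",
    "run_experiment",
    "generate_fixtures",
    "write_timeseries",
    "read_timeseries",
    "write_branch_table",
    "read_branch_table",
]

EXPERIMENT_KINDS = (
    "simulate", "layer", "stationary", "spectrum", "foldmap",
    "regime_map", "sweep", "perturb",
)

#: Named numeric protocols.  "reference" bundles the full-length windows:
#: regime maps use 200 time units averaging the last 100; adiabatic sweeps
#: 7000/5000 with step 0.002; "scaled" divides the sweep windows by 10 and
#: coarsens the sweep step, preserving regime labels at a fraction of the cost.
PROTOCOLS = {
    "reference": dict(map_t_total=200.0, map_window=100.0,
                  sweep_t_sim=7000.0, sweep_window=5000.0, sweep_delta_s1=0.002,
                  perturb_t_end=4000.0, perturb_t_p=2000.0,
                  M=201, dt=0.01, dt_out=0.5, amp_floor=0.05),
    "scaled": dict(map_t_total=200.0, map_window=100.0,
                   sweep_t_sim=700.0, sweep_window=500.0, sweep_delta_s1=0.02,
                   perturb_t_end=4000.0, perturb_t_p=2000.0,
                   M=201, dt=0.01, dt_out=0.5, amp_floor=0.05),
}


@dataclass
class ExperimentConfig:
    """Fully specified experiment: kind, parameters, seeds, protocol."""

    kind: str
    params: dict = field(default_factory=dict)     # ModelParams overrides
    options: dict = field(default_factory=dict)    # kind-specific settings
    protocol: str = "reference"
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; choose from {EXPERIMENT_KINDS}")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        valid = {f.name for f in dataclasses.fields(ModelParams)}
        bad = set(self.params) - valid
        if bad:
            raise ValueError(f"unknown ModelParams keys: {sorted(bad)}")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["protocol_values"] = dict(PROTOCOLS[self.protocol])
        out["model_params"] = dataclasses.asdict(ModelParams(**self.params))
        out["version"] = __version__
        return out


def _fmt(x) -> str:
    return f"{float(x):.17g}"


def write_timeseries(path, ts: TimeSeries) -> None:
    """Write a TimeSeries as delimited text with a '#' metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# rotorpool timeseries v1\n")
        fh.write("# meta: " + json.dumps(_jsonable(ts.meta)) + "\n")
        fh.write("t\tA\tR\tTheta\tr1\tr2\tlambda\n")
        for row in zip(ts.t, ts.A, ts.R, ts.Theta, ts.r1, ts.r2, ts.lam):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_timeseries(path) -> TimeSeries:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta: "):
                meta = json.loads(line[len("# meta: "):])
            elif not line.startswith("#"):
                break
    data = np.loadtxt(path, skiprows=3)
    data = np.atleast_2d(data)
    return TimeSeries(t=data[:, 0], A=data[:, 1], R=data[:, 2], Theta=data[:, 3],
                      r1=data[:, 4], r2=data[:, 5], lam=data[:, 6], meta=meta)


def write_branch_table(path, branches, extra_meta: Optional[dict] = None) -> None:
    """Write stationary branches as a delimited text table."""
    with open(path, "w") as fh:
        fh.write("# rotorpool stationary branches v1\n")
        fh.write("# meta: " + json.dumps(_jsonable(extra_meta or {})) + "\n")
        fh.write("r1\tr2\tsigma\tlabel\tB\tp1\tp2\tR\tTheta\tbeta\tstability\n")
        for b in branches:
            fh.write("\t".join([
                _fmt(b.r1), _fmt(b.r2), _fmt(b.sigma), b.label, _fmt(b.B),
                _fmt(b.p1), _fmt(b.p2), _fmt(b.R), _fmt(b.Theta), _fmt(b.beta),
                b.stability or "unknown",
            ]) + "\n")


def read_branch_table(path):
    from .stationary import StationaryBranch

    branches = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("r1\t"):
                continue
            f = line.rstrip("\n").split("\t")
            branches.append(StationaryBranch(
                r1=float(f[0]), r2=float(f[1]), sigma=float(f[2]), label=f[3],
                B=float(f[4]), p1=float(f[5]), p2=float(f[6]), R=float(f[7]),
                Theta=float(f[8]), beta=float(f[9]),
                stability=None if f[10] == "unknown" else f[10]))
    return branches


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute one configured experiment; return the output directory.

    The directory receives the resolved configuration (YAML), a log with
    versions/seeds/wall time, and the experiment's data files.  Runs are
    deterministic given the configuration (fixed-step integrators, seeded
    randomness).
    """
    outdir = Path(config.outdir or f"rotorpool_{config.kind}_seed{config.seed}")
    outdir.mkdir(parents=True, exist_ok=True)
    t_wall = time.time()
    params = ModelParams(**config.params)
    proto = PROTOCOLS[config.protocol]
    opt = dict(config.options)
    log_lines = [f"rotorpool {__version__}", f"kind={config.kind}", f"seed={config.seed}"]

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)

    try:
        if config.kind == "simulate":
            pop = init_population(params.N, seed=config.seed,
                                  sampling_mode=opt.get("sampling_mode", "iid"))
            res0 = ResourceState(
                r=complex(opt.get("r1_0", params.s1 + opt.get("r_offset", 0.4)),
                          opt.get("r2_0", params.s2)),
                lam=opt.get("lam_0", 0.15))
            ts = simulate(pop, res0, params, t_end=opt.get("t_end", 2000.0),
                          dt_out=proto["dt_out"], dt=proto["dt"])
            write_timeseries(outdir / "timeseries.tsv", ts)
            s = summarize(ts, opt.get("transient", 500.0), opt.get("window", 1000.0))
            (outdir / "summary.json").write_text(json.dumps(_jsonable(s), indent=1))

        elif config.kind == "layer":
            from .oa import OAField, integrate_layer
            r1, r2 = opt.get("r1", 0.9), opt.get("r2", 2.0)
            f0 = OAField.incoherent(proto["M"], r1=r1, r2=r2)
            traj = integrate_layer(f0, params.sigma, opt.get("t_end", proto["map_t_total"]),
                                   dt_out=proto["dt_out"], dt=proto["dt"])
            ts = TimeSeries(t=traj.t, A=traj.A, R=traj.R, Theta=traj.Theta,
                            r1=traj.r1, r2=traj.r2, lam=np.full(traj.t.size, np.nan),
                            meta=traj.meta)
            write_timeseries(outdir / "layer_timeseries.tsv", ts)
            with open(outdir / "layer_Z.tsv", "w") as fh:
                fh.write("# rotorpool layer trajectory v1\n")
                fh.write("# meta: " + json.dumps(_jsonable(traj.meta)) + "\n")
                fh.write("t\tReZ\tImZ\tR\tTheta\tr1\tr2\n")
                for k in range(traj.t.size):
                    row = (traj.t[k], traj.Z[k].real, traj.Z[k].imag, traj.R[k],
                           traj.Theta[k], traj.r1[k], traj.r2[k])
                    fh.write("\t".join(_fmt(v) for v in row) + "\n")

        elif config.kind == "stationary":
            from .stationary import find_stationary_states
            r1, r2 = opt.get("r1", 0.9), opt.get("r2", 2.0)
            branches = find_stationary_states(r1, r2, params.sigma)
            write_branch_table(outdir / "branches.tsv", branches,
                               dict(r1=r1, r2=r2, sigma=params.sigma))

        elif config.kind == "spectrum":
            from .spectrum import classify_stability, discrete_spectrum
            from .stationary import find_stationary_states
            r1, r2 = opt.get("r1", 0.9), opt.get("r2", 2.0)
            branches = find_stationary_states(r1, r2, params.sigma)
            rows = []
            for b in branches:
                res = classify_stability(b)
                for mu in res.discrete:
                    rows.append(("discrete", mu.real, mu.imag, np.nan, b.label))
                for I, pair in zip(res.I_grid, res.continuous):
                    for mu in pair:
                        rows.append(("continuous", mu.real, mu.imag, I, b.label))
            with open(outdir / "spectra.tsv", "w") as fh:
                fh.write("type\tRe\tIm\tI\tbranch\n")
                for r in rows:
                    fh.write(f"{r[0]}\t{_fmt(r[1])}\t{_fmt(r[2])}\t{_fmt(r[3])}\t{r[4]}\n")
            write_branch_table(outdir / "branches.tsv", branches,
                               dict(r1=r1, r2=r2, sigma=params.sigma))

        elif config.kind == "foldmap":
            from .bifurcation import fold_branches
            curves = fold_branches(params.sigma, tuple(opt.get("r2_range", (0.6, 2.6))),
                                   step=opt.get("step", 0.05))
            with open(outdir / "folds.tsv", "w") as fh:
                fh.write("branch\tr1\tr2\tB\n")
                for c in curves:
                    for pt in c.points:
                        fh.write(f"{c.branch_id}\t{_fmt(pt.r1)}\t{_fmt(pt.r2)}\t{_fmt(pt.B)}\n")

        elif config.kind == "regime_map":
            from .bifurcation import regime_map
            rm = regime_map(params.sigma, tuple(opt.get("r1_range", (0.5, 1.3))),
                            tuple(opt.get("r2_range", (0.5, 2.5))),
                            resolution=opt.get("resolution", 7),
                            engine=opt.get("engine", "oa"),
                            t_total=proto["map_t_total"], window=proto["map_window"],
                            M=proto["M"], N=opt.get("N", 1000), seed=config.seed,
                            amp_floor=proto["amp_floor"])
            with open(outdir / "regime_map.tsv", "w") as fh:
                fh.write("r1\tr2\tquantity\tvalue\n")
                for i, r1 in enumerate(rm.r1_grid):
                    for j, r2 in enumerate(rm.r2_grid):
                        for q, arr in (("mean_A", rm.mean_A), ("mean_R", rm.mean_R),
                                       ("R_range", rm.R_range)):
                            fh.write(f"{_fmt(r1)}\t{_fmt(r2)}\t{q}\t{_fmt(arr[i, j])}\n")
                        fh.write(f"{_fmt(r1)}\t{_fmt(r2)}\ttheta_class\t{rm.theta_class[i, j]}\n")

        elif config.kind == "sweep":
            from .slowfast import adiabatic_sweep
            sw = adiabatic_sweep(
                opt.get("s1_start", 0.81), opt.get("s1_end", 1.41),
                proto["sweep_delta_s1"], params, engine=opt.get("engine", "network"),
                t_sim=proto["sweep_t_sim"], window=proto["sweep_window"],
                seed=config.seed, M=proto["M"], dt=proto["dt"])
            with open(outdir / f"sweep_{sw.direction}.tsv", "w") as fh:
                fh.write("# meta: " + json.dumps(_jsonable(sw.meta)) + "\n")
                fh.write("s1\tmean_A\tmean_R\tmax_lambda\tlabel\n")
                for k in range(sw.s1.size):
                    fh.write(f"{_fmt(sw.s1[k])}\t{_fmt(sw.mean_A[k])}\t{_fmt(sw.mean_R[k])}"
                             f"\t{_fmt(sw.max_lam[k])}\t{sw.labels[k]}\n")

        elif config.kind == "perturb":
            from .slowfast import apply_perturbation, _initial_state
            engine = opt.get("engine", "network")
            state0 = _initial_state(opt.get("initial", "steady"), params, engine,
                                    config.seed, proto["M"])
            protocol = dict(kind=opt.get("perturbation", "reset"),
                            value=opt.get("value", 20.0),
                            t_p=opt.get("t_p", proto["perturb_t_p"]))
            if protocol["kind"] == "clamp":
                protocol["duration"] = opt.get("duration", 500.0)
            ts, verdict = apply_perturbation(state0, protocol, params, engine=engine,
                                             t_end=opt.get("t_end", proto["perturb_t_end"]),
                                             dt=proto["dt"], dt_out=proto["dt_out"])
            write_timeseries(outdir / "perturb_timeseries.tsv", ts)
            (outdir / "verdict.json").write_text(json.dumps(_jsonable(verdict), indent=1))

        log_lines.append(f"status=ok wall_time={time.time() - t_wall:.2f}s")
    except Exception as err:
        log_lines.append(f"status=failed error={err!r} wall_time={time.time() - t_wall:.2f}s")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def generate_fixtures(seed: int = 0) -> dict:
    """Small deterministic inputs for tests and examples.

    Returns a 50-rotator population, a 21-node OA field at the reference
    base level, and five (r1, r2) probe points annotated with their
    stationary root counts at sigma = 5.
    """
    pop = init_population(50, seed=seed)
    nodes, weights = make_quadrature(21, "gauss_hermite")
    fld = OAField(nodes=nodes, weights=weights, z=np.zeros(21, complex),
                  r1=0.97, r2=1.2)
    points = [
        dict(r1=0.9, r2=2.0, expected="three-root"),
        dict(r1=1.1, r2=2.0, expected="one-root"),
        dict(r1=0.9, r2=2.25, expected="one-root"),
        dict(r1=0.9, r2=1.0, expected="three-root"),
        dict(r1=0.5, r2=0.5, expected="three-root"),
    ]
    return dict(population=pop, field=fld, points=points, seed=seed)
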