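"""Constrained maximization of BO% over the pore dimensions (Ds, Dc).

The loop mirrors the published workflow: perturb (Ds, Dc) -> rebuild the
voxel model -> solve the poroelastic problem -> score the stimulus -> update.
Because the voxelized objective is piecewise constant, the default method is
a penalized derivative-free local search (Nelder-Mead) seeded from a coarse
feasible grid plus topology-centroid multistarts; a finite-difference
gradient mode (SLSQP) is available as well.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import optimize as sciopt

from . import fem, geometry, mechanoreg
from .geometry import ScaffoldSpec, Topology, UnitCellSpec, chord_length, validate_cell

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "evaluate_objective",
    "optimize_geometry",
    "load_sweep",
    "feasible_grid",
    "constraint_violation",
]

log = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)


@dataclass
class OptimizerConfig:
    method: str = "derivative_free"  # or "finite_difference_gradient"
    max_evaluations: int = 120
    x0: Optional[list] = None  # explicit start points [(Ds, Dc), ...]
    xtol: float = 1e-3  # design-variable tolerance, mm
    seed: int = 0
    resolution: int = 8
    constraint_dialect: str = "as_printed"
    penalty_weight: float = 1e4
    grid_presearch: int = 4  # per-axis feasible grid evaluated before local search
    n_random_starts: int = 1

    def __post_init__(self):
        if self.method not in ("derivative_free", "finite_difference_gradient"):
            raise ValueError(f"unknown optimizer method {self.method!r}")
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be >= 1")


@dataclass
class OptimizationResult:
    Ds_opt: float
    Dc_opt: float
    BO_opt: float
    trace: pd.DataFrame  # columns Ds, Dc, BO_percent, feasible, wall_time_s
    converged: bool
    n_evaluations: int = 0


def constraint_violation(Ds: float, Dc: float, Luc: float, dialect: str = "as_printed") -> float:
    """Total constraint violation (mm) of a candidate point; 0 if feasible.

    Encodes the coherence constraints: positivity, ``Ds <= 2 Luc``, the
    cylinder upper bound (``Ds/2`` or ``Ds/sqrt(2)`` by dialect) and, for
    topology L, the chord lower bound ``Dc > sqrt(Ds^2 - Luc^2)``.
    """
    viol = 0.0
    viol += max(0.0, -Ds + 1e-9)
    viol += max(0.0, -Dc + 1e-9)
    viol += max(0.0, Ds - 2.0 * Luc)
    if Ds > 0 and Dc > 0:
        upper = Ds / 2.0 if dialect == "as_printed" else Ds / _SQRT2
        viol += max(0.0, Dc - upper)
        if Ds > Luc:
            C = float(np.sqrt(max(Ds * Ds - Luc * Luc, 0.0)))
            viol += max(0.0, C - Dc)
    return viol


def is_feasible(Ds, Dc, Luc, dialect="as_printed") -> bool:
    return constraint_violation(Ds, Dc, Luc, dialect) <= 1e-12


def feasible_grid(Luc: float, dialect: str, n: int = 5) -> list:
    """A roughly uniform n x n sample of the feasible (Ds, Dc) region."""
    pts = []
    for Ds in np.linspace(0.2 * Luc, 1.95 * Luc, n):
        lo = 1e-3
        upper = Ds / 2.0 if dialect == "as_printed" else Ds / _SQRT2
        if Ds > Luc:
            lo = max(lo, float(np.sqrt(Ds * Ds - Luc * Luc)) * 1.02)
        if lo >= upper:
            continue
        for Dc in np.linspace(lo + 0.02 * (upper - lo), upper * 0.999, n):
            if is_feasible(Ds, Dc, Luc, dialect):
                pts.append((float(Ds), float(Dc)))
    return pts


def evaluate_objective(
    Ds: float,
    Dc: float,
    scaffold: ScaffoldSpec,
    load: fem.LoadCase,
    cfg: OptimizerConfig,
    materials: Optional[dict] = None,
    stimulus_model: Optional[mechanoreg.StimulusModel] = None,
    cache: Optional[dict] = None,
) -> float:
    """BO% of one candidate geometry: full geometry -> FEM -> stimulus pipeline.

    Deterministic for fixed inputs; pass a dict as ``cache`` to memoize by
    (Ds, Dc, mode, F_UA, resolution).
    """
    if not is_feasible(Ds, Dc, scaffold.cell.Luc, cfg.constraint_dialect):
        raise geometry.ConstraintError(
            [f"(Ds={Ds}, Dc={Dc}) infeasible under dialect {cfg.constraint_dialect}"]
        )
    key = (round(Ds, 9), round(Dc, 9), load.mode, load.F_UA, cfg.resolution)
    if cache is not None and key in cache:
        log.debug("objective cache hit at %s", key)
        return cache[key]

    spec = ScaffoldSpec.create(
        Ds=Ds,
        Dc=Dc,
        L=scaffold.L,
        cells_per_side=scaffold.cells_per_side,
        constraint_dialect=cfg.constraint_dialect,
    )
    grid = geometry.assemble_scaffold(spec, cfg.resolution)
    if not np.any(grid.labels == geometry.Phase.GRANULATION):
        # pore below voxel resolution: no granulation tissue, nothing to score
        if cache is not None:
            cache[key] = 0.0
        return 0.0
    model = fem.build_fe_model(grid, materials=materials, load=load)
    result = fem.solve_consolidation(model)
    sfield = mechanoreg.compute_stimulus_field(
        result, stimulus_model or mechanoreg.StimulusModel()
    )
    bo = mechanoreg.bone_fraction(sfield, spec.L).BO_percent
    if cache is not None:
        cache[key] = bo
    return bo


def _start_points(Luc: float, cfg: OptimizerConfig, rng: np.random.Generator) -> list:
    """Topology-centroid starts plus seeded random feasible points."""
    pts = []
    if cfg.x0:
        explicit = [tuple(map(float, p)) for p in cfg.x0]
        if not any(is_feasible(p[0], p[1], Luc, cfg.constraint_dialect) for p in explicit):
            raise ValueError(
                "all configured start points are infeasible under dialect "
                f"{cfg.constraint_dialect}"
            )
        pts.extend(explicit)
    upper = 0.5 if cfg.constraint_dialect == "as_printed" else 1.0 / _SQRT2
    # centroid of topology S: Ds mid-range, Dc mid of (0, upper*Ds]
    DsS = 0.6 * Luc
    pts.append((DsS, 0.5 * upper * DsS))
    # centroid of topology L
    DsL = 1.4 * Luc
    C = float(np.sqrt(DsL**2 - Luc**2))
    pts.append((DsL, 0.5 * (C + upper * DsL)))
    for _ in range(cfg.n_random_starts):
        for _ in range(200):
            Ds = rng.uniform(0.1 * Luc, 1.99 * Luc)
            Dc = rng.uniform(1e-3, upper * Ds)
            if is_feasible(Ds, Dc, Luc, cfg.constraint_dialect):
                pts.append((float(Ds), float(Dc)))
                break
    return [p for p in pts if is_feasible(p[0], p[1], Luc, cfg.constraint_dialect)]


def optimize_geometry(
    scaffold: ScaffoldSpec,
    load: fem.LoadCase,
    cfg: OptimizerConfig,
    objective: Optional[Callable[[float, float], float]] = None,
    materials: Optional[dict] = None,
    stimulus_model: Optional[mechanoreg.StimulusModel] = None,
) -> OptimizationResult:
    """Maximize BO% over (Ds, Dc) subject to the coherence constraints.

    ``objective`` may inject a surrogate BO%(Ds, Dc) in place of the FE
    pipeline (used for optimizer verification).  Infeasible trial points are
    scored by a quadratic penalty on the constraint violation, never by
    running the pipeline.
    """
    Luc = scaffold.cell.Luc
    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}
    trace_rows: list = []
    budget = {"n": 0}

    if objective is None:

        def objective_fn(Ds, Dc):
            return evaluate_objective(
                Ds, Dc, scaffold, load, cfg, materials=materials,
                stimulus_model=stimulus_model, cache=cache,
            )

    else:
        objective_fn = objective

    def penalized_neg(x):
        Ds, Dc = float(x[0]), float(x[1])
        t0 = time.perf_counter()
        viol = constraint_violation(Ds, Dc, Luc, cfg.constraint_dialect)
        feasible = viol <= 1e-12
        if budget["n"] >= cfg.max_evaluations:
            # budget exhausted: keep returning penalties without new FE solves
            return 1e6 + cfg.penalty_weight * viol * viol
        budget["n"] += 1
        if feasible:
            bo = objective_fn(Ds, Dc)
            value = -bo
        else:
            bo = np.nan
            value = cfg.penalty_weight * viol * viol
        wall = time.perf_counter() - t0
        trace_rows.append(
            {"Ds": Ds, "Dc": Dc, "BO_percent": bo, "feasible": feasible, "wall_time_s": wall}
        )
        log.info(
            "eval %4d: Ds=%.4f Dc=%.4f BO%%=%s (%.2fs)",
            budget["n"], Ds, Dc, f"{bo:.3f}" if feasible else "penalty", wall,
        )
        return value

    starts = _start_points(Luc, cfg, rng)
    if not starts:
        raise fem.ConfigurationError("no feasible start point under the active dialect")

    if cfg.grid_presearch and cfg.grid_presearch > 1:
        grid_pts = feasible_grid(Luc, cfg.constraint_dialect, cfg.grid_presearch)
        vals = [(penalized_neg(np.array(p)), p) for p in grid_pts]
        if vals:
            best_grid = min(vals, key=lambda t: t[0])[1]
            starts = [best_grid] + starts

    converged = False
    for x0 in starts:
        if budget["n"] >= cfg.max_evaluations:
            break
        if cfg.method == "derivative_free":
            res = sciopt.minimize(
                penalized_neg,
                np.asarray(x0, dtype=float),
                method="Nelder-Mead",
                options={
                    "xatol": cfg.xtol / 10.0,
                    "fatol": 1e-8,
                    "maxfev": max(cfg.max_evaluations - budget["n"], 1),
                    "initial_simplex": _initial_simplex(x0, Luc),
                },
            )
        else:
            cons = _slsqp_constraints(Luc, cfg.constraint_dialect)
            res = sciopt.minimize(
                penalized_neg,
                np.asarray(x0, dtype=float),
                method="SLSQP",
                constraints=cons,
                options={"maxiter": max(cfg.max_evaluations - budget["n"], 1), "ftol": 1e-8},
            )
        converged = converged or bool(res.success)

    trace = pd.DataFrame(
        trace_rows, columns=["Ds", "Dc", "BO_percent", "feasible", "wall_time_s"]
    )
    feas = trace[trace["feasible"]]
    if feas.empty:
        raise fem.ConfigurationError("optimizer never reached a feasible evaluation")
    ibest = feas["BO_percent"].idxmax()
    best = feas.loc[ibest]
    return OptimizationResult(
        Ds_opt=float(best["Ds"]),
        Dc_opt=float(best["Dc"]),
        BO_opt=float(best["BO_percent"]),
        trace=trace,
        converged=converged,
        n_evaluations=len(trace),
    )


def _initial_simplex(x0, Luc):
    """Small feasibility-aware simplex: steps shrink Dc, grow Ds slightly."""
    x0 = np.asarray(x0, dtype=float)
    step = 0.08 * Luc
    return np.array(
        [x0, x0 + np.array([step, 0.0]), x0 + np.array([0.0, -min(step, 0.8 * x0[1])])]
    )


def _slsqp_constraints(Luc, dialect):
    upper = 0.5 if dialect == "as_printed" else 1.0 / _SQRT2
    cons = [
        {"type": "ineq", "fun": lambda x: x[0] - 1e-6},
        {"type": "ineq", "fun": lambda x: x[1] - 1e-6},
        {"type": "ineq", "fun": lambda x: 2.0 * Luc - x[0]},
        {"type": "ineq", "fun": lambda x: upper * x[0] - x[1]},
        # chord bound, active only for topology L (smooth max with 0)
        {
            "type": "ineq",
            "fun": lambda x: x[1] - np.sqrt(max(x[0] ** 2 - Luc**2, 0.0)),
        },
    ]
    return cons


def load_sweep(
    scaffold: ScaffoldSpec,
    loads: list,
    cfg: OptimizerConfig,
    materials: Optional[dict] = None,
    stimulus_model: Optional[mechanoreg.StimulusModel] = None,
) -> pd.DataFrame:
    """One optimization per load case; failed rows are marked, not fatal.

    Returns a table with columns mode, F_UA, Ds_opt, Dc_opt, BO_opt, failed.
    """
    if not loads:
        raise ValueError("empty load list")
    rows = []
    for load in loads:
        row = {"mode": load.mode, "F_UA": load.F_UA}
        try:
            res = optimize_geometry(
                scaffold, load, cfg, materials=materials, stimulus_model=stimulus_model
            )
            row.update(
                Ds_opt=res.Ds_opt, Dc_opt=res.Dc_opt, BO_opt=res.BO_opt,
                n_evaluations=res.n_evaluations, failed=False,
            )
        except Exception as exc:  # per-row containment: sweep continues
            log.error("sweep row (mode=%s, F_UA=%s) failed: %s", load.mode, load.F_UA, exc)
            row.update(Ds_opt=np.nan, Dc_opt=np.nan, BO_opt=np.nan,
                       n_evaluations=0, failed=True)
        rows.append(row)
    return pd.DataFrame(rows)


COMPRESSION_LOADS_MPA = (0.05, 0.1, 0.5, 1.0, 1.5)
SHEAR_LOADS_MPA = (0.01, 0.05, 0.1, 0.2, 0.5)
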