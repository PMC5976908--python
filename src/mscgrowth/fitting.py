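"""Constrained least-squares fitting of the two-compartment model.

Residuals are taken on the cumulative-PD scale (the scale on which growth
curves are reported); the cost is the plain sum of squared residuals.
Feasibility follows the biological box constraints

    0 < r1 < 1,  0 < r20 < 1,  r1 < L < 1,  0 < k < 1,  0 < T < ts,

where ``ts`` is an upper bound on the senescence midpoint (by default
1.2x the last measurement time).  The coupling ``r1 < L < 1`` is handled
by optimizing ``delta in (0, 1)`` with ``L = r1 + delta * (1 - r1)``, so a
plain box-constrained solver applies and returned parameters are strictly
feasible.

Because the problem is nonconvex, fitting uses a deterministic multistart:
the cost is screened on a full grid of starting points (default 3 per free
parameter, at 25/50/75% of each range) and the best few starts are refined
with a trust-region-reflective least-squares solver.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .datasets import GrowthDataset
from .model import (
    DEFAULT_SOLVER,
    LOG2_E,
    InitialComposition,
    ModelParameters,
    PARAMETER_NAMES,
    SimulationError,
    SolverSettings,
    semi_analytic_states,
    simulate,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ExponentialFit",
    "ExperimentBResult",
    "FitError",
    "cost",
    "model_pd",
    "fit_full",
    "fit_exponential_slope",
    "fit_experiment_b",
]

_DELTA_MIN = 1e-6  # strict-interior margin for the L = r1 + delta*(1-r1) map
_EPS = 1e-6  # strict-interior margin for the box bounds


class FitError(RuntimeError):
    """All multistart runs failed; ``diagnostics`` lists per-start errors."""

    def __init__(self, message: str, diagnostics: Sequence[str] = ()):
        super().__init__(message)
        self.diagnostics = list(diagnostics)


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_full`.

    ``ts`` is the upper bound for the midpoint time T; when ``None`` it
    defaults to 1.2x the last measurement time.  ``multistart_grid`` is the
    number of grid points per free parameter used to seed the multistart;
    ``n_refine`` starts (lowest screened cost first) are locally refined.
    """

    ts: Optional[float] = None
    initial_nondividing_fraction: float = 0.0
    multistart_grid: int = 3
    n_refine: int = 8
    cost_tol: float = 1e-10
    param_tol: float = 1e-8
    max_iter: int = 5000
    solver: SolverSettings = field(default_factory=lambda: DEFAULT_SOLVER)

    def __post_init__(self) -> None:
        if self.multistart_grid < 1:
            raise ValueError("multistart_grid must be >= 1")
        if self.n_refine < 1:
            raise ValueError("n_refine must be >= 1")
        if not (0.0 <= self.initial_nondividing_fraction < 1.0):
            raise ValueError("initial_nondividing_fraction must lie in [0, 1)")
        if self.ts is not None and self.ts <= 0:
            raise ValueError("ts must be positive when given")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus diagnostics.

    ``provenance`` maps each parameter name to how it was obtained:
    ``"fitted"``, ``"fixed"``, ``"anchored"`` (from the exponential slope),
    ``"copied"`` (from another condition's fit) or ``"swept"`` (a candidate
    value under comparison).
    """

    params: ModelParameters
    cost: float
    residuals: np.ndarray
    n_starts: int
    best_start_index: int
    converged: bool
    provenance: Mapping[str, str]
    warnings: Tuple[str, ...] = ()


@dataclass(frozen=True)
class ExponentialFit:
    """Linear regression of PD against time in the exponential phase.

    During exponential growth ``PD(t) ≈ r1 * log2(e) * t``, so the slope
    ``s`` identifies the net division rate ``r1 = s / log2(e)``.  The
    intercept is left free: ideal data pass through the origin but
    measured/digitized data need not.
    """

    slope: float
    intercept: float
    r1: float
    r_squared: float


@dataclass(frozen=True)
class ExperimentBResult:
    """Output of the hybrid two-condition fitting procedure."""

    slope_fit: ExponentialFit
    normoxic: FitResult
    hypoxic: Tuple[FitResult, ...]


def model_pd(
    params: ModelParameters,
    times: np.ndarray,
    init_fraction: float = 0.0,
    settings: SolverSettings = DEFAULT_SOLVER,
) -> np.ndarray:
    """Model-predicted cumulative PD at the measurement times.

    Uses the semi-analytic evaluator (closed-form x1 plus quadrature for
    x2, accurate to near machine precision); falls back to Runge-Kutta
    integration with ``settings`` for horizons where the semi-analytic
    exponentials would overflow.
    """
    times = np.asarray(times, dtype=float)
    init = InitialComposition.from_nondividing_fraction(init_fraction)
    if times[-1] == 0.0:
        return np.zeros_like(times)
    try:
        x1, x2 = semi_analytic_states(params, init, times)
        y = x1 + x2
        if np.any(y <= 0) or not np.all(np.isfinite(y)):
            raise SimulationError("population became nonpositive or non-finite")
        return np.log2(y / init.total)
    except OverflowError:
        pass
    grid = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    traj = simulate(params, init, grid, settings)
    return traj.pd if times[0] == 0.0 else traj.pd[1:]


def residuals(
    params: ModelParameters,
    data: GrowthDataset,
    init_fraction: float = 0.0,
    settings: SolverSettings = DEFAULT_SOLVER,
) -> np.ndarray:
    """Per-point residuals (model PD minus measured PD)."""
    return model_pd(params, data.times, init_fraction, settings) - data.pd


def cost(
    params: ModelParameters,
    data: GrowthDataset,
    init_fraction: float = 0.0,
    settings: SolverSettings = DEFAULT_SOLVER,
) -> float:
    """Sum of squared PD residuals J(theta)."""
    r = residuals(params, data, init_fraction, settings)
    return float(np.dot(r, r))


# --- internal reparameterization -------------------------------------------
# optimization vector u = (r1, r20, delta, k, T) with L = r1 + delta*(1-r1)


def _u_to_params(u: np.ndarray, fixed: Mapping[str, float], free: Sequence[str]) -> ModelParameters:
    vals = dict(fixed)
    for name, v in zip(free, u):
        vals[name] = float(v)
    r1 = vals["r1"]
    L = r1 + vals["delta"] * (1.0 - r1) if "delta" in vals else vals["L"]
    return ModelParameters(r1=r1, r20=vals["r20"], L=L, k=vals["k"], T=vals["T"])


def _params_to_internal(params: ModelParameters) -> Dict[str, float]:
    delta = (params.L - params.r1) / (1.0 - params.r1)
    return {
        "r1": params.r1,
        "r20": params.r20,
        "delta": delta,
        "k": params.k,
        "T": params.T,
    }


def fit_full(
    data: GrowthDataset,
    config: Optional[FitConfig] = None,
    fixed: Optional[Mapping[str, float]] = None,
) -> FitResult:
    """Fit the five model parameters by multistart constrained least squares.

    ``fixed`` may pin parameters by name (e.g. ``{"r1": 0.4679}``); the
    remaining ones are fitted.  Deterministic for a fixed config: starts
    come from a grid, ties (costs within 1e-9) break toward the lowest
    start index.
    """
    config = config or FitConfig()
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown fixed parameter(s): {sorted(unknown)}")

    ts = config.ts if config.ts is not None else 1.2 * float(data.times[-1])
    if ts <= 0:
        raise ValueError("upper bound ts for T must be positive")

    # internal coordinates and their boxes
    boxes = {
        "r1": (_EPS, 1.0 - _EPS),
        "r20": (_EPS, 1.0 - _EPS),
        "delta": (_DELTA_MIN, 1.0 - _DELTA_MIN),
        "k": (_EPS, 1.0 - _EPS),
        "T": (_EPS, ts - _EPS),
    }
    fixed_internal: Dict[str, float] = {}
    for name, value in fixed.items():
        if name == "L":
            fixed_internal["L"] = float(value)
        else:
            fixed_internal[name] = float(value)
    free = [
        n for n in ("r1", "r20", "delta", "k", "T")
        if n not in fixed_internal and not (n == "delta" and "L" in fixed_internal)
    ]
    if not free:
        raise ValueError("at least one parameter must be free")

    notes = []
    if data.n < len(free):
        notes.append(
            f"under-determined fit: {data.n} data points for {len(free)} free parameters"
        )

    measured = data.pd
    init_fraction = config.initial_nondividing_fraction

    def residual_fn(u: np.ndarray) -> np.ndarray:
        params = _u_to_params(u, fixed_internal, free)
        return (
            model_pd(params, data.times, init_fraction, config.solver) - measured
        )

    def cost_of(u: np.ndarray) -> float:
        r = residual_fn(u)
        return float(np.dot(r, r))

    # deterministic multistart grid at interior fractions of each box
    g = config.multistart_grid
    fracs = (np.arange(1, g + 1)) / (g + 1)  # g=3 -> 0.25, 0.5, 0.75
    axes = [[boxes[n][0] + f * (boxes[n][1] - boxes[n][0]) for f in fracs] for n in free]
    starts = [np.array(s) for s in itertools.product(*axes)]

    screened = []
    diagnostics = []
    for idx, u0 in enumerate(starts):
        try:
            screened.append((cost_of(u0), idx))
        except (SimulationError, FloatingPointError, OverflowError) as exc:
            diagnostics.append(f"start {idx}: screening failed: {exc}")
            screened.append((math.inf, idx))
    screened.sort(key=lambda t: (t[0], t[1]))

    lower = np.array([boxes[n][0] for n in free])
    upper = np.array([boxes[n][1] for n in free])
    best = None  # (cost, order_index, u, success)
    refined_any = False
    for rank, (c0, idx) in enumerate(screened[: config.n_refine]):
        if not math.isfinite(c0):
            continue
        try:
            res = optimize.least_squares(
                residual_fn,
                starts[idx],
                bounds=(lower, upper),
                method="trf",
                diff_step=1e-5,
                ftol=config.cost_tol,
                xtol=config.param_tol,
                gtol=1e-12,
                max_nfev=config.max_iter,
            )
        except (SimulationError, FloatingPointError) as exc:
            diagnostics.append(f"start {idx}: refinement failed: {exc}")
            continue
        refined_any = True
        c = float(2.0 * res.cost)  # least_squares reports 0.5 * sum of squares
        cand = (c, idx, res.x, bool(res.success))
        if best is None or c < best[0] - 1e-9 or (abs(c - best[0]) <= 1e-9 and idx < best[1]):
            best = cand

    if best is None:
        raise FitError(
            "all multistart refinements failed", diagnostics=diagnostics
        )

    u_best = np.clip(best[2], lower + 0.0, upper - 0.0)
    params = _u_to_params(u_best, fixed_internal, free)
    final_residuals = residuals(params, data, init_fraction, config.solver)
    final_cost = float(np.dot(final_residuals, final_residuals))

    provenance = {
        name: ("fixed" if name in fixed else "fitted") for name in PARAMETER_NAMES
    }
    for name in PARAMETER_NAMES:
        bound_hit = _near_bound(params, name, ts)
        if provenance[name] == "fitted" and bound_hit:
            notes.append(f"fitted parameter {name} is at/near its bound")

    return FitResult(
        params=params,
        cost=final_cost,
        residuals=final_residuals,
        n_starts=len(starts),
        best_start_index=int(best[1]),
        converged=bool(best[3]) and refined_any,
        provenance=provenance,
        warnings=tuple(notes),
    )


def _near_bound(params: ModelParameters, name: str, ts: float, rel: float = 1e-3) -> bool:
    value = getattr(params, name)
    if name == "T":
        lo, hi = 0.0, ts
    elif name == "L":
        lo, hi = params.r1, 1.0
    else:
        lo, hi = 0.0, 1.0
    span = hi - lo
    return value - lo < rel * span or hi - value < rel * span


def fit_exponential_slope(data: GrowthDataset) -> ExponentialFit:
    """Estimate r1 from the exponential-phase slope of the PD curve.

    Ordinary least squares of PD against time (free intercept); the net
    division rate is ``slope / log2(e)``.
    """
    if data.n < 2:
        raise ValueError("slope fitting needs at least two measurements")
    res = stats.linregress(data.times, data.pd)
    return ExponentialFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r1=float(res.slope) / LOG2_E,
        r_squared=float(res.rvalue) ** 2,
    )


def fit_experiment_b(
    hypoxic: GrowthDataset,
    normoxic: GrowthDataset,
    config: Optional[FitConfig] = None,
    k_hypoxia: float = 0.15,
    T_candidates: Sequence[float] = (100.0, 110.0, 120.0),
) -> ExperimentBResult:
    """Hybrid fitting when only the exponential phase was observed.

    Procedure: (i) anchor ``r1`` from the hypoxic exponential-phase slope
    (hypoxic cells divide freely over the whole observation window);
    (ii) fit the normoxic curve over the remaining four parameters with
    ``r1`` fixed; (iii) because the hypoxic data alone cannot identify a
    unique parameter set, build hypoxic parameter sets with ``r20`` and
    ``L`` copied from the normoxic fit, the supplied manual steepness
    ``k_hypoxia``, and one candidate midpoint time per entry of
    ``T_candidates``, scoring each against the hypoxic data.
    """
    if len(T_candidates) == 0:
        raise ValueError("T_candidates must be nonempty")
    config = config or FitConfig()

    slope_fit = fit_exponential_slope(hypoxic)
    r1 = slope_fit.r1
    if not (0.0 < r1 < 1.0):
        raise FitError(
            f"anchored r1 = {r1:.4g} from the hypoxic slope is infeasible"
        )

    normoxic_fit = fit_full(normoxic, config, fixed={"r1": r1})
    prov_n = dict(normoxic_fit.provenance)
    prov_n["r1"] = "anchored"
    normoxic_fit = FitResult(
        params=normoxic_fit.params,
        cost=normoxic_fit.cost,
        residuals=normoxic_fit.residuals,
        n_starts=normoxic_fit.n_starts,
        best_start_index=normoxic_fit.best_start_index,
        converged=normoxic_fit.converged,
        provenance=prov_n,
        warnings=normoxic_fit.warnings,
    )

    base = normoxic_fit.params
    hypoxic_results = []
    for T in T_candidates:
        params = ModelParameters(
            r1=r1, r20=base.r20, L=base.L, k=k_hypoxia, T=float(T)
        )
        res = residuals(
            params, hypoxic, config.initial_nondividing_fraction, config.solver
        )
        hypoxic_results.append(
            FitResult(
                params=params,
                cost=float(np.dot(res, res)),
                residuals=res,
                n_starts=0,
                best_start_index=0,
                converged=True,
                provenance={
                    "r1": "anchored",
                    "r20": "copied",
                    "L": "copied",
                    "k": "fixed",
                    "T": "swept",
                },
                warnings=(),
            )
        )
    return ExperimentBResult(
        slope_fit=slope_fit,
        normoxic=normoxic_fit,
        hypoxic=tuple(hypoxic_results),
    )
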