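"""Evolutionary trajectories as projected gradient flow of fitness.

A lineage is idealised as a point in the constrained (N, p, x) space that
moves in the direction of the steepest fitness increase, with bound
constraints handled by projection: after each step the state is clipped back
into the feasible box and, at an active bound, the outward component of the
gradient is discarded.  The full three-dimensional flow measures steepness
in a relative-group-size metric, ds^2 = (dN/N)^2 + dp^2 + dx^2 — selection
acts on proportional changes in group size, and the metric also removes the
extreme flatness of fitness in absolute N that would otherwise stall the
flow along boundary valleys.  Two-dimensional flows over the (p, x) plane
use the plain Euclidean metric there, which is what makes them cross
isofitness contours at right angles.  Pseudo-time has no biological unit;
step sizes are controlled purely numerically (backtrack on a fitness
decrease, expand while fitness keeps improving), so the recorded fitness
sequence is non-decreasing by construction.

Two-dimensional flows over the (p, x) plane use an ``n``-policy to supply
the group size: either N is solved from the fixed production optimum n*
(``FIXED_OPTIMAL_N``) or chosen to maximise fitness at each (p, x)
(``SOLVE_N_FROM_STATE``).  Because group size only enters fitness through
the distance of producer-equivalents from the average=marginal point, the
two policies agree wherever the solved N is feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import lifehistory as lh
from .lifehistory import (
    LifeHistoryParams,
    OptimumClass,
    SocialState,
    _eval_fast,
    classify,
    fitness,
    maximize_fitness,
    optimal_n,
    producer_equivalents,
)


class NPolicy(Enum):
    FIXED_OPTIMAL_N = "fixed-optimal-n"
    SOLVE_N_FROM_STATE = "solve-n-from-state"


@dataclass(frozen=True)
class TrajectoryConfig:
    """Numerical controls for gradient-flow integration."""

    step_init: float = 0.05
    step_grow: float = 1.2
    step_shrink: float = 0.5
    step_max: float = math.inf
    tol: float = 1e-8          # projected-gradient norm, relative to 1 + |pi|
    max_steps: int = 100_000
    record_stride: int = 10
    N_max: float = 1e4
    max_turn_cos: float = 0.9998  # plane flow: cap gradient rotation per step

    def __post_init__(self) -> None:
        if self.step_init <= 0 or self.tol <= 0 or self.max_steps <= 0:
            raise ValueError("step_init, tol and max_steps must be positive")


@dataclass(frozen=True)
class TrajectoryPoint:
    tau: float
    state: SocialState
    pi: float
    grad_norm: float


@dataclass(frozen=True)
class Trajectory:
    points: tuple[TrajectoryPoint, ...]
    endpoint: SocialState
    endpoint_class: OptimumClass
    converged: bool
    n_steps: int

    def to_frame(self, params: LifeHistoryParams) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            d = lh.derived(pt.state, params)
            rows.append(dict(
                tau=pt.tau, N=pt.state.N, p=pt.state.p, x=pt.state.x,
                n=d.n, m=d.m, pi=pt.pi, grad_norm=pt.grad_norm,
            ))
        return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


TRAJECTORY_COLUMNS = ["tau", "N", "p", "x", "n", "m", "pi", "grad_norm"]


def _project(z: np.ndarray, params: LifeHistoryParams, N_max: float) -> np.ndarray:
    N = min(max(z[0], 1.0), N_max)
    x = min(max(z[2], lh._X_FLOOR), params.x_max)
    p = min(max(z[1], 1.0 / N), 1.0)
    return np.array([N, p, x])


def _projected_gradient_w(
    z: np.ndarray, grad: np.ndarray, params: LifeHistoryParams, N_max: float,
    atol: float = 1e-10,
) -> np.ndarray:
    """Projected gradient in w = (ln N, p, x) coordinates.

    ``grad`` is the gradient in (N, p, x); the chain rule turns its first
    component into N * dpi/dN.  Components pointing out of the feasible box
    are dropped; at the coupled bound p >= 1/N the outward normal component
    (normal (1/N, 1, 0) in w-space) is removed so the flow can slide along
    the constraint surface.
    """
    N, p, x = z
    g = np.array([N * grad[0], grad[1], grad[2]])
    if N <= 1.0 + atol and g[0] < 0:
        g[0] = 0.0
    if N >= N_max - atol and g[0] > 0:
        g[0] = 0.0
    if x <= lh._X_FLOOR + atol and g[2] < 0:
        g[2] = 0.0
    if x >= params.x_max - atol and g[2] > 0:
        g[2] = 0.0
    if p >= 1.0 - atol and g[1] > 0:
        g[1] = 0.0
    if p - 1.0 / N <= atol * max(1.0, 1.0 / N):
        normal = np.array([1.0 / N, 1.0, 0.0])
        normal /= np.linalg.norm(normal)
        comp = float(g @ normal)
        if comp < 0:
            g = g - comp * normal
    return g


def ascend(
    params: LifeHistoryParams,
    start: SocialState,
    config: TrajectoryConfig | None = None,
) -> Trajectory:
    """Integrate the fitness-gradient flow from a feasible starting state.

    Fitness is non-decreasing along the recorded path (backtracking rejects
    any step that lowers it or leaves the feasible region).  Terminates when
    the projected-gradient norm falls below ``tol * (1 + |pi|)``, when no
    ascent step above machine size exists, or at ``max_steps``.
    """
    config = config or TrajectoryConfig()
    start.validate(params.t)
    z = _project(start.as_array(), params, config.N_max)
    out = _eval_fast(z[0], z[1], z[2], params)
    if out is None:
        raise lh.InfeasibleStateError(f"starting state {start} is infeasible")
    pi = out[0]
    step = config.step_init
    tau = 0.0
    points = [TrajectoryPoint(0.0, SocialState(*z), pi, math.nan)]
    converged = False
    k = 0

    def _move(w0: np.ndarray, d: np.ndarray, s: float) -> np.ndarray:
        w1 = w0 + s * d
        return _project(np.array([math.exp(w1[0]), w1[1], w1[2]]), params, config.N_max)

    for k in range(1, config.max_steps + 1):
        out = _eval_fast(z[0], z[1], z[2], params)
        grad = np.array(out[1:4])
        pg = _projected_gradient_w(z, grad, params, config.N_max)
        norm = float(np.linalg.norm(pg))
        if norm <= config.tol * (1.0 + abs(pi)):
            converged = True
            break
        d = pg / norm
        w = np.array([math.log(z[0]), z[1], z[2]])
        accepted = False
        while step >= 1e-14:
            z_new = _move(w, d, step)
            trial = _eval_fast(z_new[0], z_new[1], z_new[2], params)
            if trial is not None and trial[0] >= pi and not np.allclose(z_new, z):
                accepted = True
                break
            step *= config.step_shrink
        if not accepted:
            converged = True  # no ascent direction at machine resolution
            break
        # expand while fitness keeps improving (approximate line maximisation)
        for _ in range(60):
            s2 = min(step * config.step_grow, config.step_max)
            if s2 <= step:
                break
            z_try = _move(w, d, s2)
            t2 = _eval_fast(z_try[0], z_try[1], z_try[2], params)
            if t2 is not None and t2[0] > trial[0]:
                step, z_new, trial = s2, z_try, t2
            else:
                break
        z, pi = z_new, trial[0]
        tau += step
        if k % config.record_stride == 0:
            points.append(TrajectoryPoint(tau, SocialState(*z), pi, norm))
    endpoint = SocialState(*z)
    if points[-1].state != endpoint:
        points.append(TrajectoryPoint(tau, endpoint, pi, math.nan))
    return Trajectory(
        points=tuple(points),
        endpoint=endpoint,
        endpoint_class=classify(endpoint, params, atol=1e-6),
        converged=converged,
        n_steps=k,
    )


# ---------------------------------------------------------------------------
# (p, x) plane: n-policies, 2D flow, isoquants


def lift_to_state(
    p: float, x: float, params: LifeHistoryParams, n_policy: NPolicy,
    n_star: float | None = None, N_max: float = 1e4,
) -> SocialState | None:
    """Supply N for a plane point (p, x) under an n-policy; None if infeasible.

    FIXED_OPTIMAL_N solves N from n* = N*(1 - p*(t + x)) and flags the point
    when that N violates N >= 1 or p >= 1/N.  SOLVE_N_FROM_STATE clips the
    same N into the feasible interval (fitness is unimodal in N with its peak
    at n = n*, so the clipped N is the constrained optimum).
    """
    n_star = n_star if n_star is not None else optimal_n(params)
    denom = 1.0 - p * (params.t + x)
    if denom <= 0:
        return None
    N = n_star / denom
    N_lo = max(1.0, 1.0 / p)
    if n_policy is NPolicy.FIXED_OPTIMAL_N:
        if N < N_lo - 1e-12 or N > N_max:
            return None
    else:
        N = min(max(N, N_lo), N_max)
    return SocialState(N=N, p=p, x=x)


@dataclass(frozen=True)
class IsoquantField:
    """Fitness evaluated over a (p, x) lattice under an n-policy."""

    p_grid: np.ndarray
    x_grid: np.ndarray
    values: np.ndarray          # shape (len(p_grid), len(x_grid)); NaN = infeasible
    feasible: np.ndarray
    n_policy: NPolicy
    params: LifeHistoryParams
    n_star: float

    def argmax(self) -> tuple[float, float]:
        if not self.feasible.any():
            raise ValueError("field has no feasible cell")
        masked = np.where(self.feasible, self.values, -np.inf)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        return float(self.p_grid[i]), float(self.x_grid[j])


def isoquant_field(
    params: LifeHistoryParams,
    n_policy: NPolicy = NPolicy.FIXED_OPTIMAL_N,
    p_grid: Sequence[float] | None = None,
    x_grid: Sequence[float] | None = None,
    n_points: int = 101,
) -> IsoquantField:
    """Evaluate fitness on a (p, x) lattice; infeasible cells are NaN-flagged."""
    n_star = optimal_n(params)
    p_arr = np.asarray(p_grid if p_grid is not None else np.linspace(1e-3, 1.0, n_points), float)
    x_arr = np.asarray(x_grid if x_grid is not None else np.linspace(1e-3, params.x_max, n_points), float)
    vals = np.full((p_arr.size, x_arr.size), np.nan)
    feas = np.zeros_like(vals, dtype=bool)
    for i, p in enumerate(p_arr):
        for j, x in enumerate(x_arr):
            st = lift_to_state(p, x, params, n_policy, n_star=n_star)
            if st is None:
                continue
            out = _eval_fast(st.N, st.p, st.x, params)
            if out is None:
                continue
            vals[i, j] = out[0]
            feas[i, j] = True
    return IsoquantField(
        p_grid=p_arr, x_grid=x_arr, values=vals, feasible=feas,
        n_policy=n_policy, params=params, n_star=n_star,
    )


def plane_fitness(
    p: float, x: float, params: LifeHistoryParams, n_policy: NPolicy,
    n_star: float | None = None,
) -> float:
    st = lift_to_state(p, x, params, n_policy, n_star=n_star)
    if st is None:
        return math.nan
    out = _eval_fast(st.N, st.p, st.x, params)
    return math.nan if out is None else out[0]


def _plane_gradient(
    p: float, x: float, params: LifeHistoryParams, n_policy: NPolicy,
    n_star: float, h: float = 1e-7,
) -> np.ndarray | None:
    """Finite-difference gradient of plane fitness; None where not computable.

    Uses central differences in the interior and falls back to one-sided
    differences next to a feasibility boundary.
    """
    f0 = None
    out = np.empty(2)
    for i, v in enumerate((p, x)):
        hi = h * max(1.0, abs(v))
        args_p = [p, x]
        args_m = [p, x]
        args_p[i] += hi
        args_m[i] -= hi
        fp = plane_fitness(args_p[0], args_p[1], params, n_policy, n_star)
        fm = plane_fitness(args_m[0], args_m[1], params, n_policy, n_star)
        if math.isnan(fp) or math.isnan(fm):
            if f0 is None:
                f0 = plane_fitness(p, x, params, n_policy, n_star)
            if math.isnan(f0):
                return None
            if not math.isnan(fp):
                out[i] = (fp - f0) / hi
                continue
            if not math.isnan(fm):
                out[i] = (f0 - fm) / hi
                continue
            return None
        out[i] = (fp - fm) / (2.0 * hi)
    return out


@dataclass(frozen=True)
class PlaneTrajectory:
    points: tuple[tuple[float, float, float, float], ...]  # (tau, p, x, pi)
    endpoint: tuple[float, float]
    converged: bool
    n_policy: NPolicy


def ascend_plane(
    params: LifeHistoryParams,
    start: tuple[float, float],
    n_policy: NPolicy = NPolicy.FIXED_OPTIMAL_N,
    config: TrajectoryConfig | None = None,
) -> PlaneTrajectory:
    """Euclidean gradient flow of fitness over the (p, x) plane."""
    config = config or TrajectoryConfig()
    n_star = optimal_n(params)
    z = np.array(start, dtype=float)
    pi = plane_fitness(z[0], z[1], params, n_policy, n_star)
    if math.isnan(pi):
        raise lh.InfeasibleStateError(f"plane start {start} infeasible under {n_policy}")
    step = config.step_init
    tau = 0.0
    pts = [(0.0, float(z[0]), float(z[1]), pi)]
    converged = False

    p_lo = 1e-6

    def skew_slack(v: np.ndarray) -> float:
        # p >= 1/N turns into p*(n* + t + x) >= 1 when N is solved from n*
        return v[0] * (n_star + params.t + v[1]) - 1.0

    def proj(v: np.ndarray) -> np.ndarray:
        out = np.array([
            min(max(v[0], p_lo), 1.0),
            min(max(v[1], lh._X_FLOOR), params.x_max),
        ])
        if n_policy is NPolicy.FIXED_OPTIMAL_N and skew_slack(out) < 0:
            out[0] = 1.0 / (n_star + params.t + out[1])
        return out

    def masked_gradient(zz: np.ndarray) -> np.ndarray | None:
        grad = _plane_gradient(zz[0], zz[1], params, n_policy, n_star)
        if grad is None:
            return None
        g = grad.copy()
        if zz[0] >= 1.0 - 1e-10 and g[0] > 0:
            g[0] = 0.0
        if zz[1] >= params.x_max - 1e-10 and g[1] > 0:
            g[1] = 0.0
        if zz[1] <= lh._X_FLOOR + 1e-10 and g[1] < 0:
            g[1] = 0.0
        if skew_slack(zz) <= 1e-9:
            outward = np.array([n_star + params.t + zz[1], zz[0]])  # grad of slack
            if float(g @ outward) < 0:
                tangent = np.array([-zz[0] ** 2, 1.0])
                tangent /= np.linalg.norm(tangent)
                g = float(g @ tangent) * tangent
        return g

    for k in range(1, config.max_steps + 1):
        g = masked_gradient(z)
        if g is None:
            break
        norm = float(np.linalg.norm(g))
        if norm <= config.tol * (1.0 + abs(pi)):
            converged = True
            break
        d = g / norm

        def acceptable(z_new: np.ndarray, require_slope: bool):
            trial = plane_fitness(z_new[0], z_new[1], params, n_policy, n_star)
            if math.isnan(trial) or trial < pi or np.allclose(z_new, z):
                return None
            if require_slope:
                # curvature guards: do not step past the line maximum (which
                # would zigzag across stiff valleys instead of following
                # them) and do not let the gradient rotate sharply within a
                # single step (which would cut corners of the flow path)
                gn = masked_gradient(z_new)
                if gn is not None:
                    if float(gn @ d) < 0.0:
                        return None
                    gn_norm = float(np.linalg.norm(gn))
                    if gn_norm > 0 and float(gn @ d) / gn_norm < config.max_turn_cos:
                        return None
            return trial

        accepted = False
        require_slope = True
        s = step
        while True:
            z_new = proj(z + s * d)
            trial = acceptable(z_new, require_slope)
            if trial is not None:
                accepted = True
                break
            s *= config.step_shrink
            if s < 1e-10 and require_slope:
                require_slope = False
                s = step
            elif s < 1e-14:
                break
        if not accepted:
            converged = True
            break
        for _ in range(60):  # expand while still acceptable and improving
            s2 = min(s * config.step_grow, config.step_max)
            if s2 <= s:
                break
            z_try = proj(z + s2 * d)
            t2 = acceptable(z_try, require_slope)
            if t2 is not None and t2 > trial:
                s, z_new, trial = s2, z_try, t2
            else:
                break
        z, pi = z_new, trial
        tau += s
        step = min(max(s * config.step_grow, 1e-10), config.step_max)
        if k % config.record_stride == 0:
            pts.append((tau, float(z[0]), float(z[1]), pi))
    if pts[-1][1:3] != (float(z[0]), float(z[1])):
        pts.append((tau, float(z[0]), float(z[1]), pi))
    return PlaneTrajectory(points=tuple(pts), endpoint=(float(z[0]), float(z[1])),
                           converged=converged, n_policy=n_policy)


# ---------------------------------------------------------------------------
# orthogonality of gradient flow and isoquants


@dataclass(frozen=True)
class OrthogonalityReport:
    max_abs_cosine: float
    n_segments: int
    vacuous: bool


def max_abs_cosine(
    points: Sequence[tuple[float, float]],
    grad_fn: Callable[[float, float], np.ndarray | None],
    is_interior: Callable[[float, float], bool],
    grad_floor: float = 1e-8,
) -> OrthogonalityReport:
    """Worst |cosine| between path segments and the local isofitness contour.

    The contour tangent is the perpendicular of the fitness gradient at the
    segment midpoint; exact gradient flow crosses contours at right angles so
    the cosine vanishes.  Segments touching an active bound, and segments in
    a vanishing-gradient neighbourhood of the optimum (nothing left to
    cross), are excluded.
    """
    worst = 0.0
    n_used = 0
    for (p0, x0), (p1, x1) in zip(points[:-1], points[1:]):
        if not (is_interior(p0, x0) and is_interior(p1, x1)):
            continue
        d = np.array([p1 - p0, x1 - x0])
        dn = np.linalg.norm(d)
        if dn < 1e-12:
            continue
        grad = grad_fn(0.5 * (p0 + p1), 0.5 * (x0 + x1))
        if grad is None:
            continue
        gn = np.linalg.norm(grad)
        if gn < grad_floor:
            continue
        tangent = np.array([-grad[1], grad[0]]) / gn
        cos = abs(float(d @ tangent)) / dn
        worst = max(worst, cos)
        n_used += 1
    return OrthogonalityReport(max_abs_cosine=worst, n_segments=n_used,
                               vacuous=n_used == 0)


def orthogonality_check(
    trajectory: PlaneTrajectory,
    field: IsoquantField,
    bound_tol: float = 1e-6,
    grad_floor_rel: float = 1e-5,
) -> OrthogonalityReport:
    """Check a plane trajectory against the isoquants of a matching field."""
    if trajectory.n_policy is not field.n_policy:
        raise ValueError("trajectory and field use different n-policies")
    params, n_policy, n_star = field.params, field.n_policy, field.n_star
    pts = [(p, x) for (_, p, x, _) in trajectory.points]
    pi_scale = np.nanmax(np.abs(field.values)) if np.isfinite(field.values).any() else 1.0

    def is_interior(p: float, x: float) -> bool:
        if p >= 1.0 - bound_tol or x >= params.x_max - bound_tol or x <= bound_tol:
            return False
        st = lift_to_state(p, x, params, n_policy, n_star=n_star)
        if st is None:
            return False
        return st.p - 1.0 / st.N > bound_tol

    def grad_fn(p: float, x: float):
        return _plane_gradient(p, x, params, n_policy, n_star)

    return max_abs_cosine(pts, grad_fn, is_interior,
                          grad_floor=grad_floor_rel * (1.0 + pi_scale))


# ---------------------------------------------------------------------------
# regime sweep over the food intensity beta


BETA_SWEEP_COLUMNS = ["beta", "label", "converged", "N", "p", "x", "pi"]


def beta_sweep(
    params_template: LifeHistoryParams,
    betas: Sequence[float],
    initial: SocialState | None = None,
) -> pd.DataFrame:
    """Classify the fitness optimum for each food intensity in ``betas``."""
    from dataclasses import replace

    rows = []
    for beta in betas:
        if not 0 < beta < 1:
            raise ValueError(f"beta must be in (0, 1), got {beta}")
        par = replace(params_template, beta=beta)
        opt = maximize_fitness(par, initial=initial)
        rows.append(dict(
            beta=float(beta), label=opt.opt_class.value, converged=opt.converged,
            N=opt.state.N, p=opt.state.p, x=opt.state.x, pi=opt.pi,
        ))
    return pd.DataFrame(rows, columns=BETA_SWEEP_COLUMNS)
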