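"""Constrained fitness maximisation for a single-sex social group.

A group holds ``N`` coresident females, each with one unit of lifetime.  A
fraction ``p`` of them are reproductives; becoming reproductive costs a fixed
time investment ``t`` and actually reproducing costs a further variable time
``x`` (``0 < x <= 1 - t``).  Everyone else, and the off-duty time of
reproductives, goes into production, so the group fields

    n = N * (1 - p*t - p*x)

producer-equivalents.  Production follows a shifted-logistic curve

    g(n) = A * (1 / (1 + q**(n0 - n)) - 1 / (1 + q**n0)),

with g(0) = 0, increasing returns below the inflection ``n0`` and saturation
above it.  After each member's subsistence ``s``, the surplus is split
equally among reproductives, giving each reproductive energy

    m = (g(n) - N*s) / (N*p),

and surviving births per reproductive follow a Cobb-Douglas technology,
homogeneous of degree one in its energy and time inputs:

    b = f(m, x) = alpha * m**beta * x**(1 - beta),

where ``beta`` is the food intensity of reproduction (large beta: births are
mostly limited by provisioning; small beta: by maternal time).  Fitness is
the per-member rate of surviving births

    pi = p * f(m, x),

maximised over (N, p, x) subject to N >= 1, 1/N <= p <= 1, 0 < x <= 1 - t.

Two structural results shape every optimum: per-capita output is maximised
where the marginal product equals the average product (``g'(n) = g(n)/n``),
and ``x`` and ``p`` can never both be interior at an optimum — a stationary
reproductive time share forces the proportion of reproductives to its lower
bound (one reproductive per group), and a stationary proportion of
reproductives forces reproductive time against its stage-length ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import brentq, minimize

_X_FLOOR = 1e-12  # open lower bound on x handled by flooring; pi -> 0 there


class OptimizationError(RuntimeError):
    """Raised when a root or optimum cannot be located."""


class InfeasibleStateError(ValueError):
    """Raised when an operation requires a feasible (m > 0) state."""


# ---------------------------------------------------------------------------
# parameters and state


@dataclass(frozen=True)
class LifeHistoryParams:
    """Parameters of the general group fitness model.

    t      fixed reproductive investment, fraction of lifetime in [0, 1)
    s      subsistence energy per member per lifetime unit
    beta   food share (intensity) of reproduction, in (0, 1)
    alpha  births per unit composite input (scales fitness, not its argmax)
    A      production scale (energy at saturation ~ A)
    q      production steepness base (> 1); larger q = steeper logistic
    n0     production inflection, in producer-equivalents
    """

    t: float = 0.2
    s: float = 100.0
    beta: float = 0.5
    alpha: float = 1.0
    A: float = 25000.0
    q: float = 1.3
    n0: float = 12.0

    def __post_init__(self) -> None:
        if not 0 <= self.t < 1:
            raise ValueError(f"t must be in [0, 1), got {self.t}")
        if not self.s > 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.A > 0:
            raise ValueError(f"A must be > 0, got {self.A}")
        if not self.q > 1:
            raise ValueError(f"q must be > 1, got {self.q}")
        if not self.n0 > 0:
            raise ValueError(f"n0 must be > 0, got {self.n0}")

    @property
    def x_max(self) -> float:
        return 1.0 - self.t


@dataclass(frozen=True)
class SocialState:
    """The evolving triple (N, p, x)."""

    N: float
    p: float
    x: float

    def validate(self, t: float) -> None:
        if not self.N >= 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not (1.0 / self.N - 1e-12 <= self.p <= 1 + 1e-12):
            raise ValueError(f"p={self.p} outside [1/N, 1] for N={self.N}")
        if not (0 < self.x <= 1 - t + 1e-12):
            raise ValueError(f"x={self.x} outside (0, 1-t] for t={t}")

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.p, self.x], dtype=float)


@dataclass(frozen=True)
class DerivedQuantities:
    """Quantities implied by a state: producer-equivalents, energy, births, fitness."""

    n: float
    m: float
    b: float
    pi: float
    feasible: bool


class OptimumClass(Enum):
    SINGLE_REPRODUCTIVE = "single-reproductive"    # p = 1/N active, x interior
    STAGE_RESTRICTED = "stage-restricted"          # x = 1 - t active, p interior
    DOUBLE_CORNER = "double-corner"                # both bounds active
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Gradient:
    """Analytic fitness derivatives at a feasible state.

    ``n_condition`` is the producer-optimality residual ``n*g'(n) - g(n)``;
    it shares its sign with dpi_dN and vanishes where the average product of
    producers equals the marginal product.
    """

    dpi_dN: float
    dpi_dp: float
    dpi_dx: float
    n_condition: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dpi_dN, self.dpi_dp, self.dpi_dx], dtype=float)


# ---------------------------------------------------------------------------
# elementary functions


def producer_equivalents(N, p, x, t):
    """Full-time-producer equivalents ``n = N*(1 - p*t - p*x)``."""
    return N * (1.0 - p * t - p * x)


def production_g(n, params: LifeHistoryParams):
    """Shifted-logistic group production; g(0) = 0, saturates at large n."""
    n = np.asarray(n, dtype=float)
    lnq = math.log(params.q)
    z = np.exp(np.minimum((params.n0 - n) * lnq, 700.0))
    out = params.A * (1.0 / (1.0 + z) - 1.0 / (1.0 + params.q**params.n0))
    return out if out.ndim else float(out)


def production_g_prime(n, params: LifeHistoryParams):
    """Marginal product g'(n) of the shifted logistic."""
    n = np.asarray(n, dtype=float)
    lnq = math.log(params.q)
    z = np.exp(np.minimum((params.n0 - n) * lnq, 700.0))
    out = params.A * lnq * z / (1.0 + z) ** 2
    return out if out.ndim else float(out)


def energy_per_reproductive(state: SocialState, params: LifeHistoryParams) -> float:
    """Reproductive energy ``m = (g(n) - N*s)/(N*p)``; m <= 0 flags infeasibility."""
    n = producer_equivalents(state.N, state.p, state.x, params.t)
    return (production_g(n, params) - state.N * params.s) / (state.N * state.p)


def births_fn(m, x, params: LifeHistoryParams):
    """Cobb-Douglas births per reproductive, homogeneous of degree one."""
    m = np.asarray(m, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(m < 0) or np.any(x < 0):
        raise ValueError("births_fn requires non-negative m and x")
    out = params.alpha * m**params.beta * x ** (1.0 - params.beta)
    return out if out.ndim else float(out)


def derived(state: SocialState, params: LifeHistoryParams) -> DerivedQuantities:
    """n, m, b and pi at a state; infeasible states get b = pi = NaN."""
    n = producer_equivalents(state.N, state.p, state.x, params.t)
    m = (production_g(n, params) - state.N * params.s) / (state.N * state.p)
    if m <= 0 or state.x <= 0:
        return DerivedQuantities(n=n, m=m, b=math.nan, pi=math.nan, feasible=False)
    b = births_fn(m, state.x, params)
    return DerivedQuantities(n=n, m=m, b=b, pi=state.p * b, feasible=True)


def fitness(state: SocialState, params: LifeHistoryParams) -> float:
    """Per-capita fitness ``pi = p * f(m, x)``; NaN for infeasible states."""
    return derived(state, params).pi


# ---------------------------------------------------------------------------
# gradients


def _eval_fast(N: float, p: float, x: float, par: LifeHistoryParams):
    """Scalar fitness + gradient in one pass.  Returns None when infeasible.

    Output tuple: (pi, dpi_dN, dpi_dp, dpi_dx, n, m, n_condition).
    """
    t = par.t
    n = N * (1.0 - p * t - p * x)
    lnq = math.log(par.q)
    e = (par.n0 - n) * lnq
    z = math.exp(e) if e < 700.0 else math.exp(700.0)
    g = par.A * (1.0 / (1.0 + z) - 1.0 / (1.0 + par.q**par.n0))
    m = (g - N * par.s) / (N * p)
    if m <= 0.0 or x <= 0.0:
        return None
    gprime = par.A * lnq * z / (1.0 + z) ** 2
    f = par.alpha * m**par.beta * x ** (1.0 - par.beta)
    fm = par.beta * f / m
    fx = (1.0 - par.beta) * f / x
    pi = p * f
    ncond = n * gprime - g
    dpi_dN = fm * ncond / (N * N)
    dpi_dp = f - fm * ((x + t) * gprime + m)
    dpi_dx = p * (fx - fm * gprime)
    return pi, dpi_dN, dpi_dp, dpi_dx, n, m, ncond


def gradient(state: SocialState, params: LifeHistoryParams) -> Gradient:
    """Analytic partial derivatives of pi at a feasible state.

    dpi_dp = f - f_m*((x + t)*g' + m):  more reproductives add births directly
    but drain production time and reproductive energy.
    dpi_dx = p*(f_x - f_m*g'):  more maternal time adds births directly but
    costs foraging output.
    dpi_dN = f_m*(n*g'(n) - g(n))/N**2:  group size only matters through
    whether producers are below or beyond the average=marginal point.
    """
    out = _eval_fast(state.N, state.p, state.x, params)
    if out is None:
        raise InfeasibleStateError(f"state {state} is infeasible (m <= 0)")
    _, dN, dp, dx, _, _, ncond = out
    return Gradient(dpi_dN=dN, dpi_dp=dp, dpi_dx=dx, n_condition=ncond)


def numeric_gradient(
    state: SocialState, params: LifeHistoryParams, h: float = 1e-6
) -> np.ndarray:
    """Central-difference gradient of pi in (N, p, x), for cross-checking."""
    z0 = state.as_array()
    out = np.empty(3)
    for i in range(3):
        hi = h * max(1.0, abs(z0[i]))
        zp, zm = z0.copy(), z0.copy()
        zp[i] += hi
        zm[i] -= hi
        fp = fitness(SocialState(*zp), params)
        fm_ = fitness(SocialState(*zm), params)
        if math.isnan(fp) or math.isnan(fm_):
            raise InfeasibleStateError("numeric gradient stepped outside feasibility")
        out[i] = (fp - fm_) / (2.0 * hi)
    return out


# ---------------------------------------------------------------------------
# optima


def optimal_n(params: LifeHistoryParams, n_hi: float | None = None) -> float:
    """Producer-equivalents maximising per-capita output g(n)/n.

    Solves ``n*g'(n) = g(n)`` beyond the inflection by bracketing + Brent.
    Invariant to the production scale A (it cancels).
    """

    def h(n: float) -> float:
        return n * production_g_prime(n, params) - production_g(n, params)

    lo = params.n0
    if h(lo) <= 0:
        # inflection already past the average=marginal point; bracket below
        lo_candidates = np.linspace(1e-3, params.n0, 64)
        vals = [h(c) for c in lo_candidates]
        pos = [c for c, v in zip(lo_candidates, vals) if v > 0]
        if not pos:
            raise OptimizationError("no n with positive marginal-average gap found")
        lo = pos[-1]
    hi = n_hi or lo * 1.5
    for _ in range(200):
        if h(hi) < 0:
            break
        hi *= 1.5
    else:
        raise OptimizationError("could not bracket the optimal-n condition")
    return float(brentq(h, lo, hi, xtol=1e-10))


def classify(
    state: SocialState,
    params: LifeHistoryParams,
    atol: float = 1e-6,
) -> OptimumClass:
    """Active-set classification of a (near-)stationary state.

    A bound counts as active when the state sits within ``atol`` of it and
    the inward derivative does not favour moving off the bound.
    """
    out = _eval_fast(state.N, state.p, state.x, params)
    if out is None:
        return OptimumClass.UNCLASSIFIED
    pi, _, dp, dx, _, _, _ = out
    gtol = 1e-6 * (1.0 + abs(pi))
    p_lower = abs(state.p - 1.0 / state.N) <= atol and dp <= gtol
    x_upper = abs(state.x - params.x_max) <= atol and dx >= -gtol
    if p_lower and x_upper:
        return OptimumClass.DOUBLE_CORNER
    if p_lower:
        return OptimumClass.SINGLE_REPRODUCTIVE
    if x_upper:
        return OptimumClass.STAGE_RESTRICTED
    return OptimumClass.UNCLASSIFIED


@dataclass(frozen=True)
class FitnessOptimum:
    state: SocialState
    opt_class: OptimumClass
    pi: float
    converged: bool
    message: str
    n_iter: int


def maximize_fitness(
    params: LifeHistoryParams,
    initial: SocialState | None = None,
    N_max: float = 1e4,
    maxiter: int = 2000,
    tol: float = 1e-12,
) -> FitnessOptimum:
    """Box-constrained maximisation of pi over (N, p, x) via SLSQP.

    The coupled bound ``p >= 1/N`` and feasibility ``g(n) >= N*s`` enter as
    inequality constraints; in the infeasible region the objective becomes a
    penalty on the energy deficit whose gradient points back toward
    feasibility, so iterates cannot stall there.  Deterministic given the
    initial state and options.
    """
    params_ = params
    if initial is None:
        initial = SocialState(N=1.0, p=1.0, x=0.3)
    initial.validate(params_.t)
    d0 = derived(initial, params_)
    if not d0.feasible:
        raise InfeasibleStateError(f"initial state {initial} has m <= 0")
    scale = max(1.0, abs(d0.pi))
    m_scale = max(1.0, params_.s)

    def _m_and_grad(z: np.ndarray):
        N, p, x = z[0], z[1], max(z[2], _X_FLOOR)
        n = producer_equivalents(N, p, x, params_.t)
        g = production_g(n, params_)
        gp = production_g_prime(n, params_)
        u, v = g - N * params_.s, N * p
        m = u / v
        c = 1.0 - p * (params_.t + x)
        dm = np.array([
            (gp * c - params_.s) / v - u * p / v**2,
            -N * (params_.t + x) * gp / v - u * N / v**2,
            -N * p * gp / v,
        ])
        return m, dm

    def neg_pi(z: np.ndarray) -> float:
        out = _eval_fast(z[0], z[1], max(z[2], _X_FLOOR), params_)
        if out is None:
            m, _ = _m_and_grad(z)
            return -m / m_scale
        return -out[0] / scale

    def neg_grad(z: np.ndarray) -> np.ndarray:
        out = _eval_fast(z[0], z[1], max(z[2], _X_FLOOR), params_)
        if out is None:
            _, dm = _m_and_grad(z)
            return -dm / m_scale
        return -np.array(out[1:4]) / scale

    def c_skew(z):
        return z[0] * z[1] - 1.0

    def c_skew_jac(z):
        return np.array([z[1], z[0], 0.0])

    def c_surplus(z):
        n = producer_equivalents(z[0], z[1], z[2], params_.t)
        return production_g(n, params_) - z[0] * params_.s

    def c_surplus_jac(z):
        n = producer_equivalents(z[0], z[1], z[2], params_.t)
        gp = production_g_prime(n, params_)
        return np.array([
            gp * (1.0 - z[1] * (params_.t + z[2])) - params_.s,
            -gp * z[0] * (params_.t + z[2]),
            -gp * z[0] * z[1],
        ])

    res = minimize(
        neg_pi,
        initial.as_array(),
        jac=neg_grad,
        method="SLSQP",
        bounds=[(1.0, N_max), (1e-9, 1.0), (_X_FLOOR, params_.x_max)],
        constraints=[
            {"type": "ineq", "fun": c_skew, "jac": c_skew_jac},
            {"type": "ineq", "fun": c_surplus, "jac": c_surplus_jac},
        ],
        options={"maxiter": maxiter, "ftol": tol},
    )
    N, p, x = res.x
    N = min(max(N, 1.0), N_max)
    p = min(max(p, 1.0 / N), 1.0)
    x = min(max(x, _X_FLOOR), params_.x_max)
    state = SocialState(N=N, p=p, x=x)
    pi = fitness(state, params_)
    # SLSQP's own status can report a line-search failure at numerical
    # resolution; accept the point if it satisfies first-order conditions.
    converged = bool(res.success)
    if not converged and not math.isnan(pi):
        converged = projected_gradient_norm(state, params_, N_max) <= 1e-6 * (1 + abs(pi))
    return FitnessOptimum(
        state=state,
        opt_class=classify(state, params_),
        pi=pi,
        converged=converged,
        message=str(res.message),
        n_iter=int(res.nit),
    )


def projected_gradient_norm(
    state: SocialState, params: LifeHistoryParams, N_max: float = 1e4,
    atol: float = 1e-9,
) -> float:
    """Norm of the fitness gradient with outward components at active bounds removed.

    Zero (to tolerance) at any constrained stationary point; used as the
    first-order optimality measure by both the optimizer and the
    gradient-flow integrator.
    """
    g = gradient(state, params).as_array()
    N, p, x = state.N, state.p, state.x
    if N <= 1.0 + atol and g[0] < 0:
        g[0] = 0.0
    if N >= N_max - atol and g[0] > 0:
        g[0] = 0.0
    if x <= _X_FLOOR + atol and g[2] < 0:
        g[2] = 0.0
    if x >= params.x_max - atol and g[2] > 0:
        g[2] = 0.0
    if p >= 1.0 - atol and g[1] > 0:
        g[1] = 0.0
    if p - 1.0 / N <= atol * max(1.0, 1.0 / N):
        normal = np.array([1.0 / (N * N), 1.0, 0.0])
        normal /= np.linalg.norm(normal)
        comp = float(g @ normal)
        if comp < 0:
            g = g - comp * normal
    return float(np.linalg.norm(g))


# ---------------------------------------------------------------------------
# the x/p mutual-exclusion theorem


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of a randomized search for joint interior optima of x and p."""

    seed: int
    n_draws: int
    n_x_stationary: int
    n_p_stationary: int
    counterexamples: tuple
    passed: bool


def _interior_root(fun, lo: float, hi: float, n_scan: int = 64):
    """Root of a scalar function inside (lo, hi), if a sign change exists."""
    grid = np.linspace(lo, hi, n_scan)
    prev_g, prev_v = None, None
    for gpt in grid:
        v = fun(gpt)
        if v is None:
            prev_g, prev_v = None, None
            continue
        if prev_v is not None and prev_v * v < 0:
            return brentq(lambda u: fun(u), prev_g, gpt, xtol=1e-12)
        prev_g, prev_v = gpt, v
    return None


def mutual_exclusion_check(
    n_draws: int = 1000,
    seed: int = 0,
    margin: float = 1e-9,
) -> ExclusionReport:
    """Randomised validation that x and p cannot both be interior-stationary.

    For each random parameter set (t > 0) and feasible state, the check finds
    an interior x with dpi/dx = 0 at fixed (N, p) and verifies dpi/dp < 0
    there; symmetrically it finds interior-stationary p and verifies
    dpi/dx > 0.  Returns all counterexamples (expected: none).
    """
    from .scenarios import random_params  # local import to avoid a cycle

    draws = random_params(seed=seed, n_draws=n_draws)
    n_x_stat = n_p_stat = 0
    bad = []
    for par, st in draws:
        lo_x = 0.01 * par.x_max

        def dpi_dx_at(x, _par=par, _st=st):
            out = _eval_fast(_st.N, _st.p, x, _par)
            return None if out is None else out[3]

        x_star = _interior_root(dpi_dx_at, lo_x, par.x_max * 0.999)
        if x_star is not None:
            n_x_stat += 1
            out = _eval_fast(st.N, st.p, x_star, par)
            if out is not None:
                pi_scale = 1.0 + abs(out[0])
                if not out[2] < margin * pi_scale:
                    bad.append(("x-stationary", par, replace(st, x=x_star), out[2]))

        def dpi_dp_at(p, _par=par, _st=st):
            out = _eval_fast(_st.N, p, _st.x, _par)
            return None if out is None else out[2]

        p_star = _interior_root(dpi_dp_at, 1.0 / st.N + 1e-9, 1.0 - 1e-9)
        if p_star is not None:
            n_p_stat += 1
            out = _eval_fast(st.N, p_star, st.x, par)
            if out is not None:
                pi_scale = 1.0 + abs(out[0])
                if not out[3] > -margin * pi_scale:
                    bad.append(("p-stationary", par, replace(st, p=p_star), out[3]))
    return ExclusionReport(
        seed=seed,
        n_draws=n_draws,
        n_x_stationary=n_x_stat,
        n_p_stationary=n_p_stat,
        counterexamples=tuple(bad),
        passed=not bad,
    )
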