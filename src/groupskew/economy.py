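"""Group economy with increasing-then-diminishing returns and density feedback.

A single representative group of a hypothetical social species contains ``n``
full-time producers and ``R`` reproductive females.  Producers jointly generate
energy output

    Y(n, D) = D**(-gamma) * (a2 * n**2 - a3 * n**3),

which first rises faster than linearly in ``n`` (increasing returns from
cooperation) and eventually collapses (crowding, coordination costs).  Output
is scaled down by conspecific population density ``D`` through the factor
``D**-gamma``.  Every member eats ``s`` energy per year, leaving the surplus

    S = Y - s * (n + R)

for reproduction.  A reproductive female first covers her own maintenance
ration ``s`` and the fixed cost ``c0`` of being reproductive; additional
births then cost ``c1`` each plus a quadratic congestion term ``c2 * B**2``,
so average cost per birth is U-shaped and a female enjoys economies of scale
up to an efficient brood size.  Births per reproductive are the positive root
of the quadratic budget identity

    S / R - s = c0 + c1 * B + c2 * B**2.

Groups can be ranked either by total surviving births or by the per-capita
birth rate.  Subtracting the adult death rate from the best attainable
per-capita rate gives the population growth rate at each density; the density
at which growth crosses zero is the population equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import bisect


class NoFeasibleGroupError(RuntimeError):
    """Raised when no (n, R) configuration attains positive births."""


class BracketingError(RuntimeError):
    """Raised when the growth rate does not change sign over a density bracket."""


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class EconomyParams:
    """World parameters of the group economy.

    a2, a3
        Quadratic and cubic production coefficients (energy).  Output per
        group is ``a2*n**2 - a3*n**3`` at unit density.
    gamma
        Density exponent; output scales as ``D**-gamma``.
    s
        Per-member subsistence need (energy/year).
    death_rate
        Adult mortality hazard (1/year).
    """

    a2: float = 2.0
    a3: float = 0.03
    gamma: float = 0.7
    s: float = 20.0
    death_rate: float = 0.4

    def __post_init__(self) -> None:
        if not self.a2 > 0:
            raise ValueError(f"a2 must be > 0, got {self.a2}")
        if not self.a3 > 0:
            raise ValueError(f"a3 must be > 0, got {self.a3}")
        if not self.gamma >= 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not self.s > 0:
            raise ValueError(f"s must be > 0, got {self.s}")
        if not 0 < self.death_rate < 1:
            raise ValueError(f"death_rate must be in (0, 1), got {self.death_rate}")


@dataclass(frozen=True)
class BirthCostCurve:
    """Quadratic total cost of B births: ``C(B) = c0 + c1*B + c2*B**2``.

    The fixed cost c0 is spread over more births as fertility rises while the
    quadratic term eventually dominates, so average cost per birth is U-shaped
    with an efficient brood size at ``sqrt((c0 + s)/c2)`` once the
    reproductive's own ration is folded in.
    """

    c0: float = 20.0
    c1: float = 3.0
    c2: float = 0.1

    def __post_init__(self) -> None:
        if self.c0 < 0 or self.c1 < 0:
            raise ValueError("c0 and c1 must be non-negative")
        if not self.c2 > 0:
            raise ValueError(f"c2 must be > 0, got {self.c2}")

    def total_cost(self, B):
        return self.c0 + self.c1 * B + self.c2 * B**2


class Objective(Enum):
    TOTAL_BIRTHS = "total"
    PER_CAPITA_RATE = "per-capita"


class PerCapitaConvention(Enum):
    """Denominator used for the per-capita birth rate.

    MEMBERS divides total births by current members ``n + R``;
    MEMBERS_PLUS_OFFSPRING also counts the newborns in the denominator.
    """

    MEMBERS = "members"
    MEMBERS_PLUS_OFFSPRING = "members-plus-offspring"


@dataclass(frozen=True)
class GroupConfig:
    """An integer choice of producers ``n`` and reproductives ``R``."""

    n: int
    R: int

    def __post_init__(self) -> None:
        if self.n < 1 or self.R < 1:
            raise ValueError("need n >= 1 and R >= 1")

    @property
    def size(self) -> int:
        return self.n + self.R


@dataclass(frozen=True)
class GroupOutcome:
    """Computed energetics and demography of one group configuration."""

    Y: float
    S: float
    B_per: float
    B_total: float
    rate_pc: float
    feasible: bool


# ---------------------------------------------------------------------------
# elementary operations


def total_output(n, D, params: EconomyParams | None = None):
    """Total group output ``D**-gamma * (a2*n**2 - a3*n**3)``.

    Accepts scalar or array ``n``.  May be negative for very large ``n``
    (production has collapsed); the raw value is returned.
    """
    params = params or EconomyParams()
    n = np.asarray(n, dtype=float)
    if np.any(np.asarray(D) <= 0):
        raise ValueError(f"density must be positive, got {D}")
    out = float(D) ** (-params.gamma) * (params.a2 * n**2 - params.a3 * n**3)
    return out if out.ndim else float(out)


def surplus(n, R, D, params: EconomyParams | None = None):
    """Group surplus ``Y - s*(n + R)``; negative values mark infeasibility."""
    params = params or EconomyParams()
    n = np.asarray(n, dtype=float)
    R = np.asarray(R, dtype=float)
    out = total_output(n, D, params) - params.s * (n + R)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def births_per_reproductive(S, R, cost: BirthCostCurve | None = None, s: float = 20.0):
    """Surviving births per reproductive from surplus S split equally among R.

    Each reproductive's ration is ``S/R - s`` (she eats ``s`` on top of the
    group subsistence already deducted from S), which must cover
    ``c0 + c1*B + c2*B**2``.  Returns the positive root of the quadratic, or
    0.0 when no strictly positive real root exists (infeasible, not an error).
    """
    cost = cost or BirthCostCurve()
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    const = cost.c0 + s - S / R
    disc = cost.c1**2 - 4.0 * cost.c2 * const
    with np.errstate(invalid="ignore"):
        root = (-cost.c1 + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * cost.c2)
    out = np.where((disc > 0) & (root > 0), root, 0.0)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def _rate_pc(B_total, n, R, convention: PerCapitaConvention):
    if convention is PerCapitaConvention.MEMBERS:
        return B_total / (n + R)
    return B_total / (n + R + B_total)


def evaluate_group(
    config: GroupConfig,
    D: float,
    params: EconomyParams | None = None,
    cost: BirthCostCurve | None = None,
    convention: PerCapitaConvention = PerCapitaConvention.MEMBERS,
) -> GroupOutcome:
    """Evaluate output, surplus, births and the per-capita rate of one config."""
    params = params or EconomyParams()
    cost = cost or BirthCostCurve()
    Y = total_output(config.n, D, params)
    S = Y - params.s * (config.n + config.R)
    B_per = births_per_reproductive(S, config.R, cost, params.s)
    B_total = config.R * B_per
    rate = _rate_pc(B_total, config.n, config.R, convention)
    return GroupOutcome(Y=Y, S=S, B_per=B_per, B_total=B_total, rate_pc=rate,
                        feasible=B_total > 0)


def _scan(D, params, cost, convention, n_max, R_max):
    """Vectorised evaluation of every (n, R) on the search grid."""
    n = np.arange(1, n_max + 1, dtype=float)
    R = np.arange(1, R_max + 1, dtype=float)
    nn, RR = np.meshgrid(n, R, indexing="ij")
    Y = total_output(nn, D, params)
    S = Y - params.s * (nn + RR)
    B_per = births_per_reproductive(S, RR, cost, params.s)
    B_total = RR * B_per
    rate = _rate_pc(B_total, nn, RR, convention)
    return nn, RR, Y, S, B_per, B_total, rate


def optimize_group(
    D: float,
    objective: Objective,
    params: EconomyParams | None = None,
    cost: BirthCostCurve | None = None,
    convention: PerCapitaConvention = PerCapitaConvention.MEMBERS,
    n_max: int = 200,
    R_max: int = 10,
) -> tuple[GroupConfig, GroupOutcome]:
    """Exhaustive integer search for the best (n, R) at density D.

    Ties are broken toward the smallest n, then the smallest R, so results
    are reproducible.  Raises :class:`NoFeasibleGroupError` when every
    configuration yields zero births.
    """
    params = params or EconomyParams()
    cost = cost or BirthCostCurve()
    nn, RR, Y, S, B_per, B_total, rate = _scan(D, params, cost, convention, n_max, R_max)
    feasible = B_total > 0
    if not feasible.any():
        raise NoFeasibleGroupError(f"no configuration with positive births at D={D}")
    value = B_total if objective is Objective.TOTAL_BIRTHS else rate
    best = np.max(np.where(feasible, value, -np.inf))
    ties = np.argwhere(feasible & (value == best))
    i, j = min(map(tuple, ties))  # smallest n index, then smallest R index
    config = GroupConfig(n=int(nn[i, j]), R=int(RR[i, j]))
    outcome = GroupOutcome(
        Y=float(Y[i, j]), S=float(S[i, j]), B_per=float(B_per[i, j]),
        B_total=float(B_total[i, j]), rate_pc=float(rate[i, j]), feasible=True,
    )
    return config, outcome


def viable_producer_range(
    D: float,
    params: EconomyParams | None = None,
    cost: BirthCostCurve | None = None,
    n_max: int = 200,
) -> tuple[int, int] | None:
    """Smallest and largest producer count sustaining a single reproductive.

    A producer count is viable when a group with R = 1 attains strictly
    positive births.  Returns ``None`` when no count qualifies.
    """
    params = params or EconomyParams()
    cost = cost or BirthCostCurve()
    n = np.arange(1, n_max + 1, dtype=float)
    S = surplus(n, 1.0, D, params)
    B = births_per_reproductive(S, 1.0, cost, params.s)
    viable = np.flatnonzero(B > 0)
    if viable.size == 0:
        return None
    return int(n[viable[0]]), int(n[viable[-1]])


def growth_rate(
    D: float,
    objective: Objective,
    params: EconomyParams | None = None,
    cost: BirthCostCurve | None = None,
    convention: PerCapitaConvention = PerCapitaConvention.MEMBERS,
    n_max: int = 200,
    R_max: int = 10,
) -> float:
    """Per-capita birth rate of the objective-optimal group minus the death rate."""
    params = params or EconomyParams()
    _, outcome = optimize_group(D, objective, params, cost, convention, n_max, R_max)
    return outcome.rate_pc - params.death_rate


def equilibrium_density(
    objective: Objective,
    params: EconomyParams | None = None,
    cost: BirthCostCurve | None = None,
    convention: PerCapitaConvention = PerCapitaConvention.MEMBERS,
    bracket: tuple[float, float] = (0.5, 5.0),
    xtol: float = 1e-6,
) -> float:
    """Density at which the population growth rate crosses zero (bisection).

    Densities at which no group is feasible contribute a growth rate of
    ``-death_rate`` (zero births), which keeps the growth curve defined on the
    whole bracket.  Raises :class:`BracketingError` without a sign change.
    """
    params = params or EconomyParams()
    cost = cost or BirthCostCurve()

    def growth(D: float) -> float:
        try:
            return growth_rate(D, objective, params, cost, convention)
        except NoFeasibleGroupError:
            return -params.death_rate

    lo, hi = bracket
    glo, ghi = growth(lo), growth(hi)
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    if glo * ghi > 0:
        raise BracketingError(
            f"growth rate does not change sign on [{lo}, {hi}]: ({glo:.4g}, {ghi:.4g})"
        )
    return float(bisect(growth, lo, hi, xtol=xtol))


DENSITY_SWEEP_COLUMNS = [
    "D", "objective", "n", "R", "Y", "S", "B_total", "rate_pc", "growth", "feasible",
]


def density_sweep(
    D_grid: Sequence[float] | Iterable[float],
    params: EconomyParams | None = None,
    cost: BirthCostCurve | None = None,
    convention: PerCapitaConvention = PerCapitaConvention.MEMBERS,
    n_max: int = 200,
    R_max: int = 10,
) -> pd.DataFrame:
    """Best configuration under each objective at every density in the grid.

    Rows where no configuration is feasible are flagged (``feasible=False``)
    with NaN for the configuration columns and growth ``-death_rate``.
    """
    params = params or EconomyParams()
    cost = cost or BirthCostCurve()
    rows = []
    for D in D_grid:
        for objective in Objective:
            try:
                config, outcome = optimize_group(
                    D, objective, params, cost, convention, n_max, R_max
                )
                rows.append(dict(
                    D=float(D), objective=objective.value, n=config.n, R=config.R,
                    Y=outcome.Y, S=outcome.S, B_total=outcome.B_total,
                    rate_pc=outcome.rate_pc,
                    growth=outcome.rate_pc - params.death_rate, feasible=True,
                ))
            except NoFeasibleGroupError:
                rows.append(dict(
                    D=float(D), objective=objective.value, n=np.nan, R=np.nan,
                    Y=np.nan, S=np.nan, B_total=0.0, rate_pc=0.0,
                    growth=-params.death_rate, feasible=False,
                ))
    return pd.DataFrame(rows, columns=DENSITY_SWEEP_COLUMNS)


GROUP_SCAN_COLUMNS = ["n", "R", "Y", "S", "B_per", "B_total", "rate_pc"]


def group_scan(
    D: float,
    params: EconomyParams | None = None,
    cost: BirthCostCurve | None = None,
    convention: PerCapitaConvention = PerCapitaConvention.MEMBERS,
    n_max: int = 200,
    R_max: int = 10,
) -> pd.DataFrame:
    """Full (n, R) table at one density, for export and plotting."""
    params = params or EconomyParams()
    cost = cost or BirthCostCurve()
    nn, RR, Y, S, B_per, B_total, rate = _scan(D, params, cost, convention, n_max, R_max)
    return pd.DataFrame({
        "n": nn.ravel().astype(int), "R": RR.ravel().astype(int),
        "Y": Y.ravel(), "S": S.ravel(), "B_per": B_per.ravel(),
        "B_total": B_total.ravel(), "rate_pc": rate.ravel(),
    }, columns=GROUP_SCAN_COLUMNS)
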