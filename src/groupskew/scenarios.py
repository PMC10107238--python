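"""Packaged parameter presets, production-curve calibration and random draws.

The group-economy preset carries the canonical parameter values of the numerical model
(cubic production, subsistence 20, quadratic birth costs, death rate 0.4).
The life-history presets share one calibrated production curve and differ
only in the food intensity ``beta`` of reproduction: food-intensive
(beta = 0.995), time-intensive (beta = 0.25) and intermediate (beta = 0.99).
The production curve itself is under-determined (only the target optimal
producer number n* = 21.47 is pinned down), so :func:`calibrate_g` solves
the inflection ``n0`` from the target n* at a chosen steepness ``q`` and
scales ``A`` to leave a comfortable energy surplus at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq

from .economy import BirthCostCurve, EconomyParams
from .lifehistory import LifeHistoryParams, SocialState, optimal_n, producer_equivalents, production_g


class CalibrationError(RuntimeError):
    """Raised when no production curve satisfies the calibration targets."""


@dataclass(frozen=True)
class Preset:
    """A named, self-contained parameter bundle."""

    name: str
    economy: EconomyParams | None = None
    cost: BirthCostCurve | None = None
    lifehistory: LifeHistoryParams | None = None
    start: SocialState | None = None

    def to_dict(self) -> dict:
        out: dict = {"name": self.name}
        for key in ("economy", "cost", "lifehistory", "start"):
            val = getattr(self, key)
            if val is not None:
                out[key] = asdict(val)
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "Preset":
        return cls(
            name=d["name"],
            economy=EconomyParams(**d["economy"]) if "economy" in d else None,
            cost=BirthCostCurve(**d["cost"]) if "cost" in d else None,
            lifehistory=LifeHistoryParams(**d["lifehistory"]) if "lifehistory" in d else None,
            start=SocialState(**d["start"]) if "start" in d else None,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "Preset":
        return cls.from_dict(yaml.safe_load(text))


def _load_preset_file(name: str) -> dict:
    text = resources.files("groupskew.presets").joinpath(name).read_text()
    return yaml.safe_load(text)


def baseline_economy_preset() -> Preset:
    """The group-economy world with its canonical parameter values."""
    raw = _load_preset_file("economy.yaml")
    return Preset(
        name=raw["name"],
        economy=EconomyParams(**raw["economy"]),
        cost=BirthCostCurve(**raw["cost"]),
    )


def calibrate_g(
    target_n_star: float = 21.47,
    q: float = 1.3,
    s: float = 100.0,
    margin: float = 25.0,
    t: float = 0.2,
) -> tuple[float, float]:
    """Solve (A, n0) so the production optimum lands on ``target_n_star``.

    ``n0`` is found by root-solving optimal_n(q, n0) = target (A cancels from
    the average=marginal condition, so it is solved at A = 1).  ``A`` is then
    scaled so that a reference group with one full-time-equivalent
    reproductive (N = target + 1) produces ``margin`` times its subsistence
    at the optimum; margins <= 1 leave no reproductive surplus and raise
    :class:`CalibrationError`.  The default margin also leaves a solitary
    female (about half a producer-equivalent) viable, so evolutionary
    trajectories can start from the ancestral solitary state.
    """
    if target_n_star <= 0:
        raise CalibrationError("target n* must be positive")
    if q <= 1:
        raise CalibrationError("q must exceed 1")

    def gap(n0: float) -> float:
        par = LifeHistoryParams(t=t, s=s, beta=0.5, A=1.0, q=q, n0=n0)
        return optimal_n(par) - target_n_star

    lo, hi = 1e-2, 10.0
    for _ in range(60):
        if gap(hi) > 0:
            break
        hi *= 1.5
    else:
        raise CalibrationError("could not bracket n0 for the requested n*")
    if gap(lo) >= 0:
        raise CalibrationError("target n* too small for this steepness q")
    n0 = float(brentq(gap, lo, hi, xtol=1e-10))

    unit = LifeHistoryParams(t=t, s=s, beta=0.5, A=1.0, q=q, n0=n0)
    g_unit = production_g(target_n_star, unit)
    N_ref = target_n_star + 1.0
    A = margin * s * N_ref / g_unit
    if margin <= 1.0:
        raise CalibrationError(
            f"margin {margin} leaves no surplus (need g(n*) > N*s at the optimum)"
        )
    return A, n0


LIFEHISTORY_BETAS = {
    "food-intensive": 0.995,
    "time-intensive": 0.25,
    "intermediate": 0.99,
}

SOLITARY_START = SocialState(N=1.0, p=1.0, x=0.3)


def lifehistory_presets(
    q: float | None = None,
    margin: float | None = None,
) -> dict[str, Preset]:
    """Three life-history presets sharing one calibrated production curve.

    All share t = 0.2, s = 100, alpha = 1 and the calibrated (A, q, n0); the
    solitary starting state is (N=1, p=1, x=0.3).
    """
    raw = _load_preset_file("lifehistory.yaml")
    q = q if q is not None else raw["q"]
    margin = margin if margin is not None else raw["margin"]
    t, s = raw["t"], raw["s"]
    A, n0 = calibrate_g(target_n_star=raw["target_n_star"], q=q, s=s, margin=margin, t=t)
    start = SocialState(**raw["start"])
    out = {}
    for name, beta in LIFEHISTORY_BETAS.items():
        par = LifeHistoryParams(t=t, s=s, beta=beta, alpha=1.0, A=A, q=q, n0=n0)
        out[name] = Preset(name=name, lifehistory=par, start=start)
    return out


def random_params(
    seed: int,
    n_draws: int,
) -> list[tuple[LifeHistoryParams, SocialState]]:
    """Seeded stream of valid parameter sets with feasible states.

    Draws keep t strictly positive (lower bound 0.01) because the p-derivative
    degenerates at t = 0, where any proportion of reproductives is optimal.
    The production scale A is solved per-draw so the sampled state carries a
    strictly positive reproductive surplus.
    """
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_draws:
        t = rng.uniform(0.01, 0.5)
        s = rng.uniform(10.0, 200.0)
        beta = rng.uniform(0.05, 0.95)
        alpha = rng.uniform(0.5, 2.0)
        q = rng.uniform(1.05, 2.0)
        n0 = rng.uniform(5.0, 40.0)
        N = rng.uniform(1.0, 60.0)
        p = rng.uniform(1.0 / N, 1.0)
        x = rng.uniform(0.05 * (1 - t), 0.95 * (1 - t))
        n = producer_equivalents(N, p, x, t)
        if n <= 0.05:
            continue
        unit = LifeHistoryParams(t=t, s=s, beta=beta, alpha=alpha, A=1.0, q=q, n0=n0)
        g_unit = production_g(n, unit)
        if g_unit <= 0:
            continue
        surplus_factor = rng.uniform(1.2, 4.0)
        A = surplus_factor * N * s / g_unit
        par = LifeHistoryParams(t=t, s=s, beta=beta, alpha=alpha, A=A, q=q, n0=n0)
        state = SocialState(N=N, p=p, x=x)
        state.validate(t)
        out.append((par, state))
    return out


def random_feasible_states(
    params: LifeHistoryParams,
    n_draws: int,
    seed: int,
    N_hi: float = 60.0,
) -> list[SocialState]:
    """Seeded feasible starting states for a fixed parameter set."""
    rng = np.random.default_rng(seed)
    out: list[SocialState] = []
    attempts = 0
    while len(out) < n_draws:
        attempts += 1
        if attempts > 10000 * n_draws:
            raise RuntimeError("could not sample enough feasible states")
        N = rng.uniform(1.0, N_hi)
        p = rng.uniform(1.0 / N, 1.0)
        x = rng.uniform(0.02, params.x_max - 0.02)
        n = producer_equivalents(N, p, x, params.t)
        if n <= 0:
            continue
        if production_g(n, params) - N * params.s <= 0:
            continue
        out.append(SocialState(N=N, p=p, x=x))
    return out


def list_presets() -> list[str]:
    return ["baseline-economy"] + list(LIFEHISTORY_BETAS)


def get_preset(name: str) -> Preset:
    if name == "baseline-economy":
        return baseline_economy_preset()
    presets = lifehistory_presets()
    if name in presets:
        return presets[name]
    raise KeyError(f"unknown preset {name!r}; choose from {list_presets()}")
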