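"""Four-panel summary figures for the group economy and the fitness landscape."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from . import economy as econ
from . import trajectory as traj
from .economy import Objective, PerCapitaConvention
from .scenarios import Preset, lifehistory_presets
from .trajectory import NPolicy, TrajectoryConfig


def economy_figure(
    preset: Preset,
    out: str | Path,
    densities: tuple[float, float] = (1.0, 1.9),
    D_grid: np.ndarray | None = None,
) -> Path:
    """Production, birth costs, group births and density-dependent growth.

    Panels: (a) output vs producers at two densities with the consumption
    line; (b) average cost per birth; (c) total and per-capita births by
    producer count with the best reproductive count; (d) growth rate vs
    density for both objectives with equilibrium dots.
    """
    params, cost = preset.economy, preset.cost
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    n = np.arange(0, 71)

    ax = axes[0, 0]
    for D in densities:
        ax.plot(n, econ.total_output(n, D, params), label=f"output, D={D:g}")
    ax.plot(n, params.s * (n + 1), "k--", label="consumption (R=1)")
    ax.set_xlabel("producers n")
    ax.set_ylabel("energy / year")
    ax.legend(fontsize=8)
    ax.set_title("(a) output and consumption")

    ax = axes[0, 1]
    B = np.linspace(0.5, 60, 200)
    ax.plot(B, cost.total_cost(B) / B)
    ax.set_xlabel("births B")
    ax.set_ylabel("average cost per birth")
    ax.set_title("(b) U-shaped cost per birth")

    ax = axes[1, 0]
    scan = econ.group_scan(densities[0], params, cost)
    best = scan.loc[scan.groupby("n")["B_total"].idxmax()]
    best = best[best.B_total > 0]
    ax.plot(best.n, best.B_total, "--", label="total births")
    ax2 = ax.twinx()
    ax2.plot(best.n, best.rate_pc, "-", color="C1", label="per-capita rate")
    ax.step(best.n, best.R, ":", color="gray", label="best R")
    ax.set_xlabel("producers n")
    ax.set_ylabel("births / year")
    ax2.set_ylabel("per-capita rate (1/y)")
    ax.legend(fontsize=8, loc="upper left")
    ax.set_title(f"(c) births by group size, D={densities[0]:g}")

    ax = axes[1, 1]
    D_grid = D_grid if D_grid is not None else np.linspace(1.0, 1.75, 40)
    sweep = econ.density_sweep(D_grid, params, cost)
    for objective, style in ((Objective.PER_CAPITA_RATE, "-"), (Objective.TOTAL_BIRTHS, "--")):
        sub = sweep[sweep.objective == objective.value]
        ax.plot(sub.D, sub.growth, style, label=objective.value)
        try:
            d_eq = econ.equilibrium_density(objective, params, cost)
            ax.plot([d_eq], [0.0], "o", color="k", ms=4)
        except econ.BracketingError:
            pass
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("density D")
    ax.set_ylabel("growth rate (1/y)")
    ax.legend(fontsize=8)
    ax.set_title("(d) growth vs density")

    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def landscape_figure(
    out: str | Path,
    presets: dict[str, Preset] | None = None,
    n_grid: int = 61,
) -> Path:
    """Isoquant panels with gradient-flow trajectories for the three presets.

    Panel (a): the 3D trajectory of the food-intensive lineage; panels
    (b)-(d): (p, x) isoquants, the plane trajectory from the solitary start
    and a dot at the optimum for each preset.
    """
    presets = presets or lifehistory_presets()
    cfg = TrajectoryConfig(step_init=1e-3, step_max=5e-3, record_stride=1, max_steps=60000)
    fig = plt.figure(figsize=(10, 8))

    ax3 = fig.add_subplot(2, 2, 1, projection="3d")
    food = presets["food-intensive"]
    t3 = traj.ascend(food.lifehistory, food.start)
    pts = np.array([[q.state.N, q.state.p, q.state.x] for q in t3.points])
    ax3.plot(pts[:, 1], pts[:, 2], pts[:, 0], "k-", lw=2)
    ax3.scatter(*[[v] for v in (t3.endpoint.p, t3.endpoint.x, t3.endpoint.N)], color="k", s=25)
    ax3.set_xlabel("p")
    ax3.set_ylabel("x")
    ax3.set_zlabel("N")
    ax3.set_title("(a) 3D trajectory, food-intensive")

    for i, name in enumerate(["food-intensive", "time-intensive", "intermediate"], start=2):
        pr = presets[name]
        par = pr.lifehistory
        ax = fig.add_subplot(2, 2, i)
        field = traj.isoquant_field(par, NPolicy.FIXED_OPTIMAL_N, n_points=n_grid)
        P, X = np.meshgrid(field.p_grid, field.x_grid, indexing="ij")
        vals = np.where(field.feasible, field.values, np.nan)
        ax.contourf(P, X, vals, levels=20, cmap="Greys")
        ax.contour(P, X, vals, levels=12, colors="k", linewidths=0.4)
        ptr = traj.ascend_plane(par, (pr.start.p, pr.start.x), NPolicy.FIXED_OPTIMAL_N, cfg)
        path = np.array([[p, x] for (_, p, x, _) in ptr.points])
        ax.plot(path[:, 0], path[:, 1], "k-", lw=2)
        ax.plot([ptr.endpoint[0]], [ptr.endpoint[1]], "ko", ms=6)
        ax.set_xlabel("p")
        ax.set_ylabel("x")
        ax.set_title(f"({'bcd'[i - 2]}) {name} (beta={par.beta:g})")

    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
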