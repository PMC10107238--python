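"""Group-economy model: production, surplus, births, optima and equilibrium."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import groupskew.economy as econ
from groupskew import (
    BirthCostCurve,
    EconomyParams,
    GroupConfig,
    NoFeasibleGroupError,
    Objective,
    PerCapitaConvention,
)


def birth_oracle(S: float, R: int, cost: BirthCostCurve, s: float) -> float:
    """Dense-grid inversion of the birth cost curve (independent of the solver)."""
    avail = S / R - s
    if avail <= cost.c0:
        return 0.0
    grid = np.arange(0.0, 400.0, 1e-4)
    total = cost.c0 + cost.c1 * grid + cost.c2 * grid**2
    return float(np.interp(avail, total, grid))


class TestProductionAndSurplus:
    @pytest.mark.parametrize(
        "n,D,expected",
        [
            (0, 1.0, 0.0),
            (32, 1.0, 2 * 32**2 - 0.03 * 32**3),              # 1064.96
            (32, 1.9, (2 * 32**2 - 0.03 * 32**3) * 1.9**-0.7),
        ],
    )
    def test_total_output_closed_form(self, n, D, expected, econ_params):
        assert econ.total_output(n, D, econ_params) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_density_rejected(self, econ_params):
        with pytest.raises(ValueError):
            econ.total_output(10, 0.0, econ_params)
        with pytest.raises(ValueError):
            econ.total_output(10, -1.0, econ_params)

    @pytest.mark.parametrize(
        "n,R,D,expected",
        [(32, 1, 1.0, 404.96), (16, 1, 1.0, 49.12)],
    )
    def test_surplus_examples(self, n, R, D, expected, econ_params):
        assert econ.surplus(n, R, D, econ_params) == pytest.approx(expected, abs=1e-9)

    def test_surplus_negative_when_output_below_subsistence(self, econ_params):
        # five producers produce far less than six members eat
        assert econ.surplus(5, 1, 1.0, econ_params) < 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EconomyParams(a2=-1.0)
        with pytest.raises(ValueError):
            EconomyParams(death_rate=1.5)
        with pytest.raises(ValueError):
            BirthCostCurve(c2=0.0)


class TestBirthSolver:
    def test_zero_births_when_ration_covers_only_fixed_cost(self, cost_curve):
        # available food S - s = 20 exactly pays the fixed cost: no births
        assert econ.births_per_reproductive(40.0, 1, cost_curve, 20.0) == 0.0

    @pytest.mark.parametrize("S,expected", [(49.12, 2.78), (404.96, 47.25)])
    def test_known_surpluses(self, S, expected, cost_curve):
        got = econ.births_per_reproductive(S, 1, cost_curve, 20.0)
        assert got == pytest.approx(expected, abs=5e-3)
        assert got == pytest.approx(birth_oracle(S, 1, cost_curve, 20.0), abs=1e-3)

    def test_matches_dense_grid_inversion(self, cost_curve):
        for R in (1, 2, 3):
            for S in np.linspace(0.0, 2000.0, 161):
                got = econ.births_per_reproductive(S, R, cost_curve, 20.0)
                want = birth_oracle(float(S), R, cost_curve, 20.0)
                assert abs(got - want) < 1e-3, (S, R)

    @given(S=st.floats(0.0, 3000.0), R=st.integers(1, 5))
    def test_budget_identity_and_nonnegativity(self, S, R):
        cost, s = BirthCostCurve(), 20.0
        B = econ.births_per_reproductive(S, R, cost, s)
        assert B >= 0.0
        if B > 0:
            # the positive root exhausts the reproductive's ration exactly
            assert cost.total_cost(B) == pytest.approx(S / R - s, rel=1e-9, abs=1e-9)

    def test_energy_conservation_of_feasible_outcomes(self, econ_params, cost_curve):
        for n, R in [(20, 1), (33, 2), (39, 3), (50, 1)]:
            out = econ.evaluate_group(GroupConfig(n, R), 1.0, econ_params, cost_curve)
            if not out.feasible:
                continue
            used = econ_params.s * (n + R) + R * (
                econ_params.s + cost_curve.total_cost(out.B_per)
            )
            assert used == pytest.approx(out.Y, rel=1e-12)


class TestEvaluateGroup:
    def test_fifteen_producers_cannot_sustain_a_reproductive(self, econ_params, cost_curve):
        out = econ.evaluate_group(GroupConfig(15, 1), 1.0, econ_params, cost_curve)
        assert not out.feasible and out.B_total == 0.0

    def test_per_capita_conventions(self, econ_params, cost_curve):
        cfg = GroupConfig(32, 1)
        members = econ.evaluate_group(cfg, 1.0, econ_params, cost_curve,
                                      PerCapitaConvention.MEMBERS)
        brood = econ.evaluate_group(cfg, 1.0, econ_params, cost_curve,
                                    PerCapitaConvention.MEMBERS_PLUS_OFFSPRING)
        assert members.rate_pc == pytest.approx(members.B_total / 33)
        assert brood.rate_pc < members.rate_pc


def brute_force_optimum(D, objective, params, cost, convention, n_max=200, R_max=10):
    """Independent enumerator, written from the defining formulas."""
    best, best_val = None, -np.inf
    for n in range(1, n_max + 1):
        for R in range(1, R_max + 1):
            Y = D**-params.gamma * (params.a2 * n**2 - params.a3 * n**3)
            S = Y - params.s * (n + R)
            avail = S / R - params.s
            c = cost.c0 - avail
            disc = cost.c1**2 - 4 * cost.c2 * c
            B = (-cost.c1 + np.sqrt(disc)) / (2 * cost.c2) if disc > 0 else 0.0
            B = max(B, 0.0)
            total = R * B
            if total <= 0:
                continue
            if convention is PerCapitaConvention.MEMBERS:
                rate = total / (n + R)
            else:
                rate = total / (n + R + total)
            val = total if objective is Objective.TOTAL_BIRTHS else rate
            if val > best_val:
                best, best_val = (n, R), val
    return best, best_val


class TestOptimizeGroup:
    @pytest.mark.parametrize("D", [1.0, 1.3])
    @pytest.mark.parametrize("objective", list(Objective))
    @pytest.mark.parametrize("convention", list(PerCapitaConvention))
    def test_matches_independent_enumerator(self, D, objective, convention,
                                            econ_params, cost_curve):
        config, outcome = econ.optimize_group(D, objective, econ_params, cost_curve,
                                              convention)
        want, want_val = brute_force_optimum(D, objective, econ_params, cost_curve,
                                             convention)
        assert (config.n, config.R) == want
        got_val = outcome.B_total if objective is Objective.TOTAL_BIRTHS else outcome.rate_pc
        assert got_val == pytest.approx(want_val, rel=1e-12)

    def test_total_optimum_is_larger_group_than_per_capita_optimum(self, econ_params,
                                                                   cost_curve):
        tot, _ = econ.optimize_group(1.0, Objective.TOTAL_BIRTHS, econ_params, cost_curve)
        pc, _ = econ.optimize_group(1.0, Objective.PER_CAPITA_RATE, econ_params, cost_curve)
        assert tot.size > pc.size
        assert 30 <= pc.n <= 35          # per-capita optimum in the low thirties
        assert 37 <= tot.n <= 41         # total-births optimum near 39

    def test_optimal_value_strictly_decreases_with_density(self, econ_params, cost_curve):
        vals = [
            econ.optimize_group(D, Objective.PER_CAPITA_RATE, econ_params, cost_curve)[1].rate_pc
            for D in np.linspace(1.0, 1.6, 7)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_no_feasible_group_at_extreme_density(self, econ_params, cost_curve):
        with pytest.raises(NoFeasibleGroupError):
            econ.optimize_group(3.0, Objective.TOTAL_BIRTHS, econ_params, cost_curve)

    def test_dominance_of_per_capita_objective(self, econ_params, cost_curve):
        for D in np.linspace(1.0, 1.6, 5):
            _, pc = econ.optimize_group(D, Objective.PER_CAPITA_RATE, econ_params, cost_curve)
            _, tb = econ.optimize_group(D, Objective.TOTAL_BIRTHS, econ_params, cost_curve)
            assert pc.rate_pc >= tb.rate_pc


class TestViableRange:
    def test_monotone_shrinking_with_density(self, econ_params, cost_curve):
        ranges = [econ.viable_producer_range(D, econ_params, cost_curve)
                  for D in (1.0, 1.15, 1.3, 1.45)]
        assert all(r is not None for r in ranges)
        for (lo0, hi0), (lo1, hi1) in zip(ranges, ranges[1:]):
            assert lo1 >= lo0 and hi1 <= hi0   # nested intervals

    def test_empty_beyond_crowding_limit(self, econ_params, cost_curve):
        assert econ.viable_producer_range(2.5, econ_params, cost_curve) is None

    def test_monotone_surplus_and_births_in_density(self, econ_params, cost_curve):
        Ds = np.linspace(1.0, 1.6, 7)
        S = [econ.surplus(32, 1, D, econ_params) for D in Ds]
        B = [econ.births_per_reproductive(s, 1, cost_curve, econ_params.s) for s in S]
        assert all(b <= a for a, b in zip(S, S[1:]))
        assert all(b <= a for a, b in zip(B, B[1:]))


class TestGrowthAndEquilibrium:
    def test_growth_positive_at_unit_density(self, econ_params, cost_curve):
        assert econ.growth_rate(1.0, Objective.PER_CAPITA_RATE, econ_params, cost_curve) > 0

    def test_growth_non_increasing_in_density(self, econ_params, cost_curve):
        g = [econ.growth_rate(D, Objective.PER_CAPITA_RATE, econ_params, cost_curve)
             for D in np.linspace(1.0, 1.6, 7)]
        assert all(b <= a for a, b in zip(g, g[1:]))

    def test_equilibrium_is_a_root_and_objectives_are_ordered(self, econ_params, cost_curve):
        d_pc = econ.equilibrium_density(Objective.PER_CAPITA_RATE, econ_params, cost_curve)
        d_tb = econ.equilibrium_density(Objective.TOTAL_BIRTHS, econ_params, cost_curve)
        assert abs(econ.growth_rate(d_pc, Objective.PER_CAPITA_RATE,
                                    econ_params, cost_curve)) < 1e-4
        assert d_pc > d_tb
        # total-births groups decline at the per-capita equilibrium density
        assert econ.growth_rate(d_pc, Objective.TOTAL_BIRTHS, econ_params, cost_curve) < 0

    def test_bracketing_failure_signalled(self, econ_params, cost_curve):
        with pytest.raises(econ.BracketingError):
            econ.equilibrium_density(Objective.PER_CAPITA_RATE, econ_params, cost_curve,
                                     bracket=(2.5, 5.0))


class TestDensitySweep:
    def test_consistency_with_optimize_group(self, econ_params, cost_curve):
        table = econ.density_sweep([1.0], econ_params, cost_curve)
        assert len(table) == 2
        row = table[table.objective == Objective.PER_CAPITA_RATE.value].iloc[0]
        config, outcome = econ.optimize_group(1.0, Objective.PER_CAPITA_RATE,
                                              econ_params, cost_curve)
        assert (row.n, row.R) == (config.n, config.R)
        assert row.rate_pc == pytest.approx(outcome.rate_pc)
        assert row.growth == pytest.approx(outcome.rate_pc - econ_params.death_rate)

    def test_empty_grid_gives_empty_table(self, econ_params, cost_curve):
        table = econ.density_sweep([], econ_params, cost_curve)
        assert table.empty and list(table.columns) == econ.DENSITY_SWEEP_COLUMNS

    def test_infeasible_rows_flagged(self, econ_params, cost_curve):
        table = econ.density_sweep([1.0, 2.5], econ_params, cost_curve)
        bad = table[table.D == 2.5]
        assert (~bad.feasible).all()
        assert (bad.growth == -econ_params.death_rate).all()
        assert bad.n.isna().all()

    def test_group_scan_schema(self, econ_params, cost_curve):
        scan = econ.group_scan(1.0, econ_params, cost_curve, n_max=40, R_max=3)
        assert list(scan.columns) == econ.GROUP_SCAN_COLUMNS
        assert len(scan) == 40 * 3
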