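"""Convex lighting optimizer: KKT solution vs. independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

from greenlight.optimizer import LightingPlan, OptimizationInput, objective_cost, solve
from greenlight.phytomodel import (
    GREEN_TOWERS_LETTUCE,
    LightResponseParams,
    etr_from_ppfd,
    ppfd_from_etr,
)

A, K = GREEN_TOWERS_LETTUCE.a, GREEN_TOWERS_LETTUCE.k


def make_input(prices, sun_ppfd, dpi_target, etr_cap=86.21, step_seconds=900.0,
               credit=0.0):
    return OptimizationInput(
        prices=np.asarray(prices, float),
        sun_ppfd=np.asarray(sun_ppfd, float),
        step_seconds=step_seconds,
        etr_cap=etr_cap,
        dpi_target=dpi_target,
        credit_etr_sum=credit,
    )


def grid_search(inp, grid_step=0.5):
    """Exhaustive enumeration oracle on a coarse ETR grid (small T only)."""
    T = inp.n_steps
    axes = [np.arange(0.0, inp.etr_cap + 1e-9, grid_step)] * T
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=1)  # (n_points, T)
    required = inp.required_etr_sum - inp.sun_etr.sum()
    feasible = X.sum(axis=1) >= required - 1e-9
    X = X[feasible]
    total = X + inp.sun_etr
    supp_ppfd = -np.log1p(-total / A) / K - inp.sun_ppfd
    obj = supp_ppfd @ inp.prices
    best = np.argmin(obj)
    return X[best], float(obj[best])


def slsqp_solve(inp):
    """Independent NLP route for the same program."""
    required = inp.required_etr_sum - inp.sun_etr.sum()

    def f(x):
        total = x + inp.sun_etr
        return float(inp.prices @ (-np.log1p(-total / A) / K - inp.sun_ppfd))

    res = minimize(
        f,
        x0=np.full(inp.n_steps, min(required / inp.n_steps, inp.etr_cap) * 0.9 + 1e-3),
        bounds=[(0.0, inp.etr_cap)] * inp.n_steps,
        constraints=[{"type": "ineq", "fun": lambda x: x.sum() - required}],
        method="SLSQP",
        options={"maxiter": 300, "ftol": 1e-12},
    )
    return res.x, float(res.fun)


def dpi_of_plan(inp, plan):
    total = plan.x_etr + inp.sun_etr
    return (total.sum() + inp.credit_etr_sum) * inp.step_seconds * 1e-6


class TestSolveStructure:
    def test_requirement_met_by_credit_gives_zero_plan(self):
        inp = make_input([10.0] * 4, [0.0] * 4, dpi_target=3.0,
                         credit=3e6 / 900 + 1.0)
        plan = solve(inp)
        np.testing.assert_allclose(plan.x_etr, 0.0, atol=1e-12)
        assert plan.objective_value == 0.0
        assert plan.feasible

    def test_single_step_binding_constraint(self):
        # required ETR-sum of 40 over a single dark step: x must be 40 exactly
        inp = make_input([10.0], [0.0], dpi_target=40 * 900 * 1e-6)
        plan = solve(inp)
        assert plan.x_etr[0] == pytest.approx(40.0, rel=1e-9)

    def test_equal_prices_equal_sun_gives_symmetric_plan(self):
        inp = make_input([5.0] * 4, [100.0] * 4, dpi_target=140 * 900 * 1e-6)
        plan = solve(inp)
        assert plan.feasible
        assert np.ptp(plan.x_etr) < 1e-6  # all steps identical by symmetry
        assert dpi_of_plan(inp, plan) == pytest.approx(inp.dpi_target, rel=1e-9)

    def test_load_concentrates_on_free_step(self):
        # one zero-price step and a small requirement: all load goes there
        inp = make_input([1.0, 1.0, 1.0, 0.0], [0.0] * 4,
                         dpi_target=30 * 900 * 1e-6)
        plan = solve(inp)
        np.testing.assert_allclose(plan.x_etr[:3], 0.0, atol=1e-9)
        assert plan.x_etr[3] == pytest.approx(30.0, rel=1e-9)

    def test_infeasible_returns_capped_plan_with_shortfall(self):
        inp = make_input([1.0] * 2, [0.0] * 2, dpi_target=3.0, etr_cap=10.0)
        plan = solve(inp)
        assert not plan.feasible
        np.testing.assert_allclose(plan.x_etr, 10.0)
        assert plan.shortfall == pytest.approx(3e6 / 900 - 20.0, rel=1e-9)

    def test_feasibility_flag_is_exact(self):
        required = 2 * 10.0  # exactly reachable at the cap
        inp = make_input([1.0] * 2, [0.0] * 2,
                         dpi_target=required * 900 * 1e-6, etr_cap=10.0)
        assert solve(inp).feasible

    def test_near_saturating_sun_respects_log_domain(self):
        inp = make_input([1.0] * 4, [5000.0] * 3 + [0.0], dpi_target=6.0,
                         etr_cap=86.21)
        plan = solve(inp)
        assert np.all(plan.x_etr + inp.sun_etr < A)
        assert np.all(plan.x_ppfd >= -1e-9)


class TestGlobalOptimality:
    def test_matches_grid_search_on_random_small_instances(self, rng):
        # exhaustive enumeration oracle, 50 random T=4 instances
        for _ in range(50):
            inp = make_input(
                prices=rng.uniform(0.5, 3.0, 4),
                sun_ppfd=rng.uniform(0, 200, 4),
                dpi_target=rng.uniform(0.5, 1.0) * 4 * 10 * 900 * 1e-6,
                etr_cap=10.0,
            )
            plan = solve(inp)
            _, grid_obj = grid_search(inp, grid_step=0.5)
            # never worse than any grid point; and within grid resolution
            assert plan.objective_value <= grid_obj + 1e-8
            max_marginal = 1.0 / (K * (A - inp.sun_etr.max() - inp.etr_cap))
            slack = 4 * 0.5 * inp.prices.max() * max_marginal
            assert grid_obj - plan.objective_value <= slack

    def test_matches_slsqp_on_larger_instance(self, rng):
        inp = make_input(
            prices=rng.uniform(5, 20, 16),
            sun_ppfd=rng.uniform(0, 300, 16),
            dpi_target=1.0,
            etr_cap=86.21,
        )
        plan = solve(inp)
        _, ref_obj = slsqp_solve(inp)
        assert plan.objective_value == pytest.approx(ref_obj, rel=1e-5)

    def test_kkt_stationarity_at_optimum(self, rng):
        # interior requirement: ~60% of the 8-step LED capacity
        inp = make_input(rng.uniform(5, 20, 8), rng.uniform(0, 100, 8),
                         dpi_target=0.6 * 8 * 86.21 * 900e-6)
        plan = solve(inp)
        marg = inp.prices / (K * (A - inp.sun_etr - plan.x_etr))
        interior = (plan.x_etr > 1e-6) & (plan.x_etr < inp.etr_cap - 1e-6)
        assert interior.any()
        assert np.ptp(marg[interior]) / marg[interior].mean() < 1e-6

    def test_objective_monotone_in_requirement_and_sun(self, rng):
        prices = rng.uniform(5, 20, 8)
        sun = rng.uniform(0, 150, 8)
        cap_dpi = 8 * 86.21 * 900e-6  # feasible range upper end
        targets = [f * cap_dpi for f in (0.2, 0.4, 0.6, 0.8)]
        objs = [
            solve(make_input(prices, sun, dpi_target=d)).objective_value
            for d in targets
        ]
        assert all(a <= b + 1e-9 for a, b in zip(objs, objs[1:]))
        mid = 0.5 * cap_dpi
        brighter = solve(make_input(prices, sun + 50, dpi_target=mid)).objective_value
        assert brighter <= solve(make_input(prices, sun, dpi_target=mid)).objective_value + 1e-9

    def test_constraint_binds_under_equal_positive_prices(self, rng):
        inp = make_input([13.19] * 64, rng.uniform(0, 100, 64), dpi_target=3.0)
        plan = solve(inp)
        assert dpi_of_plan(inp, plan) == pytest.approx(3.0, rel=1e-6)


class TestObjective:
    def test_zero_supplemental_costs_nothing(self):
        inp = make_input([10.0] * 8, np.linspace(0, 400, 8), dpi_target=0.0)
        plan = LightingPlan(
            x_etr=np.zeros(8), x_ppfd=np.zeros(8), objective_value=0.0
        )
        assert objective_cost(plan, inp) == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_prices(self, rng):
        sun = rng.uniform(0, 200, 8)
        prices = rng.uniform(1, 10, 8)
        inp1 = make_input(prices, sun, dpi_target=2.0)
        inp2 = make_input(2 * prices, sun, dpi_target=2.0)
        plan = solve(inp1)
        assert objective_cost(plan, inp2) == pytest.approx(
            2 * objective_cost(plan, inp1), rel=1e-12
        )

    def test_equals_price_weighted_supplemental_ppfd(self, rng):
        inp = make_input(rng.uniform(1, 10, 8), rng.uniform(0, 200, 8),
                         dpi_target=2.0)
        plan = solve(inp)
        direct = float(inp.prices @ plan.x_ppfd)
        assert objective_cost(plan, inp) == pytest.approx(direct, rel=1e-9)

    def test_saturated_plan_rejected(self):
        inp = make_input([1.0], [0.0], dpi_target=0.0)
        plan = LightingPlan(np.array([121.0]), np.array([0.0]), 0.0)
        with pytest.raises(ValueError):
            objective_cost(plan, inp)
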