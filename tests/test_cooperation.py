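"""Cover solvers, the symbiosis program, and the cooperation arithmetic."""

import itertools
import math

import numpy as np
import pytest

from coopbarrier.cooperation import (
    Assignment,
    CoverInstance,
    ILPInstance,
    InfeasibleError,
    cover_to_ilp,
    exact_cover,
    fig2_benchmark,
    ga_cover,
    gen_cover_instance,
    greedy_cover,
    ilp_solve,
    jacob_monod_nreg,
    lp_relax,
    min_cell_types,
    resource_feasible,
    symbiosis_condition,
)
from conftest import random_cover_instance


def enumerate_min_cover(inst: CoverInstance, target=None) -> int:
    """Oracle: scan all 2^n subfamilies for the smallest feasible one."""
    target = inst.universe() if target is None else frozenset(target)
    best = None
    for picks in itertools.product((0, 1), repeat=inst.n_subsets):
        covered = frozenset().union(
            *(s for s, p in zip(inst.family, picks) if p), frozenset()
        )
        if target <= covered:
            size = sum(picks)
            if best is None or size < best:
                best = size
    return best


def enumerate_min_ilp(inst: ILPInstance) -> float:
    """Oracle: exhaustive 0/1 enumeration of the symbiosis program."""
    best = math.inf
    for u in itertools.product((0, 1), repeat=inst.n_genotypes):
        u = np.array(u, dtype=float)
        if (inst.a @ u >= inst.h - 1e-9).all():
            best = min(best, float(inst.r @ u))
    return best


class TestGreedy:
    def test_demo_trace(self, demo_cover):
        sol = greedy_cover(demo_cover)
        assert sol.selected == frozenset({1, 2, 3}) and sol.size == 3

    def test_universe_set_single_step(self):
        inst = CoverInstance(4, [frozenset({1, 2}), frozenset({1, 2, 3, 4})])
        assert greedy_cover(inst).size == 1

    def test_empty_target(self, demo_cover):
        sol = greedy_cover(demo_cover, target=frozenset())
        assert sol.selected == frozenset() and sol.size == 0

    def test_uncoverable_target_names_elements(self):
        inst = CoverInstance(3, [frozenset({1})])  # warns: 2,3 uncovered
        with pytest.raises(InfeasibleError, match=r"\[2, 3\]"):
            greedy_cover(inst)


class TestExact:
    def test_demo_optimum_beats_greedy(self, demo_cover):
        sol = exact_cover(demo_cover)
        assert sol.selected == frozenset({2, 3}) and sol.size == 2
        assert greedy_cover(demo_cover).size == 3  # greedy suboptimality gap

    def test_disjoint_partition_forced(self):
        inst = CoverInstance(6, [frozenset({1, 2}), frozenset({3, 4}), frozenset({5, 6})])
        assert exact_cover(inst, target={1, 5}).size == 2

    def test_lexicographic_tie_break(self):
        inst = CoverInstance(2, [frozenset({1, 2}), frozenset({1, 2})])
        assert exact_cover(inst).selected == frozenset({1})

    def test_refuses_large_family(self):
        inst = CoverInstance(2, [frozenset({1, 2})] * 25)
        with pytest.raises(ValueError, match="n=25"):
            exact_cover(inst)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle(self, seed):
        inst = random_cover_instance(np.random.default_rng(seed))
        assert exact_cover(inst).size == enumerate_min_cover(inst)


class TestGA:
    def test_seeded_greedy_never_degrades(self, demo_cover):
        greedy = greedy_cover(demo_cover)
        sol = ga_cover(
            demo_cover, generations=1, pop_size=5, seed=0,
            seed_individuals=[greedy.selected],
        )
        assert sol.size <= greedy.size

    def test_reaches_optimum_on_demo(self, demo_cover):
        sol = ga_cover(demo_cover, generations=1000, pop_size=50, seed=1)
        assert sol.size == 2

    def test_seed_reproducible(self, demo_cover):
        a = ga_cover(demo_cover, generations=20, pop_size=10, seed=7)
        b = ga_cover(demo_cover, generations=20, pop_size=10, seed=7)
        assert a.selected == b.selected

    def test_solution_always_feasible(self):
        for seed in range(5):
            inst = random_cover_instance(np.random.default_rng(100 + seed))
            sol = ga_cover(inst, generations=30, pop_size=10, seed=seed)
            assert sol.feasible_for(inst.universe())


class TestSolverOrdering:
    def test_exact_le_greedy_le_log_bound_and_ga(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            inst = random_cover_instance(rng)
            opt = exact_cover(inst).size
            grd = greedy_cover(inst).size
            ga = ga_cover(inst, generations=60, pop_size=16, seed=rng).size
            assert opt <= grd <= (1 + math.log(inst.universe_size)) * opt
            assert ga >= opt


class TestILP:
    def test_identity_forced(self):
        inst = ILPInstance(a=np.eye(2), r=[1, 1], h=[1, 1])
        sol = ilp_solve(inst)
        assert np.array_equal(sol.u, [1, 1]) and sol.objective == 2

    def test_zero_demand(self):
        inst = ILPInstance(a=np.eye(3), r=[1, 2, 3], h=[0, 0, 0])
        sol = ilp_solve(inst)
        assert sol.objective == 0 and not sol.u.any()

    def test_cover_reduction_matches_exact(self, demo_cover):
        assert ilp_solve(cover_to_ilp(demo_cover)).objective == 2

    def test_infeasible_lists_demands(self):
        inst = ILPInstance(a=[[1.0], [0.5]], r=[1], h=[0.5, 2.0])
        with pytest.raises(InfeasibleError, match=r"\[2\]"):
            ilp_solve(inst)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(2, 6)), int(rng.integers(2, 7))
        a = rng.uniform(0, 1, size=(m, n))
        h = a.sum(axis=1) * rng.uniform(0.1, 0.9, size=m)
        inst = ILPInstance(a=a, r=rng.uniform(0.5, 2.0, size=n), h=h)
        assert ilp_solve(inst).objective == pytest.approx(enumerate_min_ilp(inst))

    @pytest.mark.parametrize("seed", range(30))
    def test_setcover_ilp_equivalence(self, seed):
        inst = random_cover_instance(np.random.default_rng(1000 + seed))
        assert ilp_solve(cover_to_ilp(inst)).objective == exact_cover(inst).size


class TestLPRelaxation:
    def test_identity_relaxation_tight(self):
        inst = ILPInstance(a=np.eye(2), r=[1, 1], h=[1, 1])
        assert lp_relax(inst).objective == pytest.approx(2.0)

    def test_cyclic_gap(self, cyclic_ilp):
        lp = lp_relax(cyclic_ilp)
        assert lp.objective == pytest.approx(1.5)
        assert np.allclose(lp.u, 0.5, atol=1e-6)
        assert ilp_solve(cyclic_ilp).objective == pytest.approx(2.0)

    def test_cost_homogeneity(self, cyclic_ilp):
        scaled = ILPInstance(a=cyclic_ilp.a, r=cyclic_ilp.r * 3.0, h=cyclic_ilp.h)
        assert lp_relax(scaled).objective == pytest.approx(3 * 1.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_lp_lower_bounds_ilp(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(2, 7)), int(rng.integers(2, 9))
        a = rng.uniform(0, 1, size=(m, n))
        h = a.sum(axis=1) * rng.uniform(0.1, 0.9, size=m)
        inst = ILPInstance(a=a, r=rng.uniform(0.5, 2.0, size=n), h=h)
        assert lp_relax(inst).objective <= ilp_solve(inst).objective + 1e-8


class TestResourceCap:
    def test_strict_inequality(self):
        a = Assignment([1, 1], "boolean", objective=2.0)
        assert resource_feasible(a, 3.0)
        assert not resource_feasible(a, 2.0)

    def test_extinction_gap_between_greedy_and_exact(self, demo_cover):
        # a cap between the greedy cost (3) and the optimal cost (2):
        # the greedy colony starves while the optimal community survives
        greedy = greedy_cover(demo_cover)
        exact = exact_cover(demo_cover)
        c_res = 2.5
        assert not resource_feasible(
            Assignment(np.zeros(3), "boolean", greedy.cost), c_res
        )
        assert resource_feasible(
            Assignment(np.zeros(3), "boolean", exact.cost), c_res
        )


class TestCooperationArithmetic:
    def test_symbiosis_condition(self):
        assert symbiosis_condition(10, 2, 100, 1.0)
        assert not symbiosis_condition(50, 2, 100, 1.0)  # strict boundary
        # (n-1)/n grows with n, so the condition only gets easier
        held = [symbiosis_condition(30, n, 100, 1.0) for n in range(2, 10)]
        assert held == sorted(held)

    def test_jacob_monod(self):
        est = jacob_monod_nreg(100, 10, 2.0)
        assert est.n_reg == 20.0 and est.advantageous
        est1 = jacob_monod_nreg(100, 1, 2.0)
        assert est1.n_reg == 200.0 and not est1.advantageous
        assert not jacob_monod_nreg(100, 2, 2.0).advantageous  # n == C_reg strict

    @pytest.mark.parametrize(
        "total, cap, expected", [(600, 100, 6), (1, 100, 1), (601, 100, 7)]
    )
    def test_min_cell_types(self, total, cap, expected):
        assert min_cell_types(total, cap) == expected


class TestBenchmarkFamily:
    def test_generated_instance_covers_universe(self):
        inst = gen_cover_instance(50, 12, seed=3)
        assert frozenset().union(*inst.family) == inst.universe()
        assert all(inst.family)

    def test_benchmark_ordering_smoke(self):
        res = fig2_benchmark(60, 15, reps=3, seed=5, ga_configs=((60, 16),))
        assert set(res["rows"][0]) >= {"greedy", "best_ga"}
        assert 0.0 <= res["best_ga_le_greedy_fraction"] <= 1.0
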