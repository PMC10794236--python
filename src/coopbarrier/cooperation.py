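"""Cooperation models: set cover, symbiosis ILP, and its LP relaxation.

Division of labor among n organisms facing M ecological constraints is
modeled as a Set Cover Problem: organism k can satisfy the constraint
subset E_k, and a community is a subfamily J whose union covers the
constraints, minimal |J| being the cheapest community.  Jacob-Monod
sensing regulation — each organism covers the constraints left
unsatisfied by the others — is the classical greedy approximation, with
the (1 + ln M) guarantee and the well-known suboptimality gap that a
genetic algorithm (or exact search) can close.

The general symbiosis problem is an integer linear program: activate
genotypes u_l in {0,1} producing quantities a_il of gene product i at
resource cost r_l, meeting demands h_i at minimum total cost F_targ,
optionally under a hard resource cap F_targ < C_res.  Relaxing u_l to
real concentrations in [0,1] — the multicellularity transition — turns
the NP-hard program into a polynomial-time linear program whose optimum
lower-bounds the integer one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

__all__ = [
    "CoverInstance", "CoverSolution", "ILPInstance", "Assignment",
    "InfeasibleError", "greedy_cover", "exact_cover", "ga_cover",
    "ilp_solve", "lp_relax", "resource_feasible", "symbiosis_condition",
    "jacob_monod_nreg", "min_cell_types", "gen_cover_instance",
    "cover_to_ilp", "fig2_benchmark",
]


class InfeasibleError(ValueError):
    """Raised when no selection of subsets / genotypes meets the demands."""


# ---------------------------------------------------------------------------
# domain types

@dataclass
class CoverInstance:
    """Universe {1..M} of constraints and a family of n covering subsets.

    Elements are 1-based.  Costs default to 1 (minimize community size).
    """

    universe_size: int
    family: list[frozenset[int]]
    costs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.universe_size < 1:
            raise ValueError("universe must be nonempty")
        if not self.family:
            raise ValueError("subset family must be nonempty")
        self.family = [frozenset(s) for s in self.family]
        for k, s in enumerate(self.family):
            if not s:
                raise ValueError(f"subset {k + 1} is empty")
            if any(e < 1 or e > self.universe_size for e in s):
                raise ValueError(f"subset {k + 1} has elements outside 1..{self.universe_size}")
        if self.costs is None:
            self.costs = np.ones(len(self.family))
        self.costs = np.asarray(self.costs, dtype=float)
        if self.costs.shape != (len(self.family),) or not (self.costs > 0).all():
            raise ValueError("one positive cost per subset required")
        uncov = self.universe() - frozenset().union(*self.family)
        if uncov:
            warnings.warn(
                f"family does not cover the universe; uncovered elements {sorted(uncov)}",
                stacklevel=2,
            )

    @property
    def n_subsets(self) -> int:
        return len(self.family)

    def universe(self) -> frozenset[int]:
        return frozenset(range(1, self.universe_size + 1))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CoverInstance)
            and self.universe_size == other.universe_size
            and self.family == other.family
            and np.allclose(self.costs, other.costs)
        )


@dataclass
class CoverSolution:
    """A selected subfamily J (1-based subset indices) and what it covers."""

    selected: frozenset[int]
    covered: frozenset[int]
    cost: float

    @property
    def size(self) -> int:
        return len(self.selected)

    def feasible_for(self, target: frozenset[int]) -> bool:
        return target <= self.covered


@dataclass
class ILPInstance:
    """Symbiosis program: min r.u s.t. a u >= h, u in {0,1}^n (or [0,1]^n)."""

    a: np.ndarray
    r: np.ndarray
    h: np.ndarray
    c_res: float | None = None

    def __post_init__(self):
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
        self.r = np.asarray(self.r, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        m, n = self.a.shape
        if self.r.shape != (n,) or self.h.shape != (m,):
            raise ValueError("dimension mismatch between a, r, h")
        if (self.a < 0).any():
            raise ValueError("product quantities a_il must be nonnegative")
        if (self.r <= 0).any():
            raise ValueError("resource costs r_l must be positive")
        if (self.h < 0).any():
            raise ValueError("demands h_i must be nonnegative")

    @property
    def n_products(self) -> int:
        return int(self.a.shape[0])

    @property
    def n_genotypes(self) -> int:
        return int(self.a.shape[1])


@dataclass
class Assignment:
    """Activation vector u with its objective F_targ = r.u."""

    u: np.ndarray
    mode: Literal["boolean", "real"]
    objective: float

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.mode == "boolean" and not np.isin(self.u, (0.0, 1.0)).all():
            raise ValueError("boolean assignment must be 0/1")
        if (self.u < -1e-9).any() or (self.u > 1 + 1e-9).any():
            raise ValueError("activations must lie in [0,1]")


# ---------------------------------------------------------------------------
# set-cover solvers

def _as_target(inst: CoverInstance, target: Iterable[int] | None) -> frozenset[int]:
    t = inst.universe() if target is None else frozenset(target)
    if any(e < 1 or e > inst.universe_size for e in t):
        raise ValueError("target contains elements outside the universe")
    return t


def _check_coverable(inst: CoverInstance, target: frozenset[int]) -> None:
    uncoverable = target - frozenset().union(*inst.family)
    if uncoverable:
        raise InfeasibleError(
            f"elements {sorted(uncoverable)} are covered by no subset"
        )


def greedy_cover(inst: CoverInstance, target: Iterable[int] | None = None) -> CoverSolution:
    """Jacob-Monod greedy cover: repeatedly take the subset covering the
    most still-uncovered target elements (ties to the lowest index).

    Guarantees |J| <= (1 + ln M) * optimum.
    """
    target = _as_target(inst, target)
    _check_coverable(inst, target)
    uncovered = set(target)
    selected: set[int] = set()
    covered: set[int] = set()
    while uncovered:
        best_k, best_gain = -1, 0
        for k, s in enumerate(inst.family):
            gain = len(uncovered & s)
            if gain > best_gain:
                best_k, best_gain = k, gain
        sel = inst.family[best_k]
        selected.add(best_k + 1)
        covered |= sel
        uncovered -= sel
    return CoverSolution(
        selected=frozenset(selected),
        covered=frozenset(covered),
        cost=float(inst.costs[[k - 1 for k in selected]].sum()) if selected else 0.0,
    )


def exact_cover(inst: CoverInstance, target: Iterable[int] | None = None) -> CoverSolution:
    """Minimum-size cover by iterative-deepening search (n <= 24).

    Ties are broken toward the lexicographically smallest index set J.
    """
    target = _as_target(inst, target)
    n = inst.n_subsets
    if n > 24:
        raise ValueError(f"exact search refused for n={n} > 24 subsets")
    _check_coverable(inst, target)
    if not target:
        return CoverSolution(frozenset(), frozenset(), 0.0)

    # bitmask encoding of subset coverage restricted to the target
    elems = sorted(target)
    pos = {e: i for i, e in enumerate(elems)}
    masks = []
    for s in inst.family:
        m = 0
        for e in s & target:
            m |= 1 << pos[e]
        masks.append(m)
    full = (1 << len(elems)) - 1
    max_gain = max(bin(m).count("1") for m in masks)

    def dfs(start: int, uncovered: int, picks: list[int], depth: int) -> list[int] | None:
        if uncovered == 0:
            return picks
        if depth == 0:
            return None
        # bound: remaining picks cannot cover what is left
        if bin(uncovered).count("1") > depth * max_gain:
            return None
        for k in range(start, n):
            if masks[k] & uncovered:
                got = dfs(k + 1, uncovered & ~masks[k], picks + [k], depth - 1)
                if got is not None:
                    return got
        return None

    for size in range(1, n + 1):
        got = dfs(0, full, [], size)
        if got is not None:
            selected = frozenset(k + 1 for k in got)
            covered = frozenset().union(*(inst.family[k] for k in got))
            return CoverSolution(
                selected=selected,
                covered=covered,
                cost=float(inst.costs[list(got)].sum()),
            )
    raise InfeasibleError("no cover found")  # unreachable after _check_coverable


def _repair_and_prune(
    bits: np.ndarray,
    masks: list[int],
    full: int,
    costs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Make an individual feasible by greedy additions, then drop redundant sets."""
    n = bits.size
    covered = 0
    for k in range(n):
        if bits[k]:
            covered |= masks[k]
    # greedy repair
    while covered != full:
        best_k, best_score = -1, -1.0
        for k in range(n):
            if bits[k]:
                continue
            gain = bin(masks[k] & ~covered).count("1")
            if gain == 0:
                continue
            score = gain / costs[k]
            if score > best_score:
                best_k, best_score = k, score
        if best_k < 0:
            raise InfeasibleError("individual cannot be repaired: target not coverable")
        bits[best_k] = 1
        covered |= masks[best_k]
    # redundancy elimination in random order
    order = rng.permutation(np.flatnonzero(bits))
    for k in order:
        without = 0
        for j in range(n):
            if bits[j] and j != k:
                without |= masks[j]
        if without == full:
            bits[k] = 0
    return bits


def ga_cover(
    inst: CoverInstance,
    target: Iterable[int] | None = None,
    pop_size: int = 50,
    generations: int = 200,
    mutation_rate: float | None = None,
    seed: int | np.random.Generator = 0,
    crossover_rate: float = 0.9,
    seed_individuals: Sequence[Iterable[int]] | None = None,
) -> CoverSolution:
    """Genetic-algorithm cover: bit vectors over subsets, tournament
    selection (size 2), uniform crossover, per-bit mutation, greedy
    repair plus redundancy pruning, elitism of one.

    ``seed_individuals`` injects known solutions (e.g. the greedy one)
    into the initial population.  Returns the best feasible individual
    ever seen; with elitism this is never worse than the final
    population's worst feasible member.
    """
    target = _as_target(inst, target)
    _check_coverable(inst, target)
    n = inst.n_subsets
    if pop_size < 2 or generations < 1:
        raise ValueError("need pop_size >= 2 and generations >= 1")
    if mutation_rate is None:
        mutation_rate = 1.0 / n
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation rate must lie in [0,1]")
    if not target:
        return CoverSolution(frozenset(), frozenset(), 0.0)
    rng = np.random.default_rng(seed)

    elems = sorted(target)
    pos = {e: i for i, e in enumerate(elems)}
    masks = []
    for s in inst.family:
        m = 0
        for e in s & target:
            m |= 1 << pos[e]
        masks.append(m)
    full = (1 << len(elems)) - 1
    costs = inst.costs

    def cost_of(bits: np.ndarray) -> float:
        return float(costs[bits.astype(bool)].sum())

    pop = (rng.random((pop_size, n)) < 0.5).astype(np.int8)
    if seed_individuals:
        for row, sel in enumerate(seed_individuals[: pop_size]):
            pop[row] = 0
            for k in sel:
                pop[row][k - 1] = 1
    for row in range(pop_size):
        pop[row] = _repair_and_prune(pop[row], masks, full, costs, rng)
    fitness = np.array([cost_of(ind) for ind in pop])
    best_idx = int(np.argmin(fitness))
    best_bits, best_cost = pop[best_idx].copy(), float(fitness[best_idx])

    for _ in range(generations):
        children = np.empty_like(pop)
        # elitism: carry the best-ever individual
        children[0] = best_bits
        for row in range(1, pop_size):
            i, j = rng.integers(0, pop_size, size=2)
            pa = pop[i] if fitness[i] <= fitness[j] else pop[j]
            i, j = rng.integers(0, pop_size, size=2)
            pb = pop[i] if fitness[i] <= fitness[j] else pop[j]
            if rng.random() < crossover_rate:
                take = rng.random(n) < 0.5
                child = np.where(take, pa, pb).astype(np.int8)
            else:
                child = pa.copy()
            flip = rng.random(n) < mutation_rate
            child[flip] ^= 1
            children[row] = _repair_and_prune(child, masks, full, costs, rng)
        pop = children
        fitness = np.array([cost_of(ind) for ind in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_cost:
            best_bits, best_cost = pop[gen_best].copy(), float(fitness[gen_best])

    selected = frozenset(int(k) + 1 for k in np.flatnonzero(best_bits))
    covered = frozenset().union(*(inst.family[k - 1] for k in selected)) if selected else frozenset()
    return CoverSolution(selected=selected, covered=covered, cost=best_cost)


# ---------------------------------------------------------------------------
# ILP and LP relaxation

def ilp_solve(inst: ILPInstance) -> Assignment:
    """Exact Boolean program: min r.u s.t. a u >= h, u in {0,1}^n."""
    # demands no activation pattern can meet (a >= 0, so u = 1 is maximal)
    short = np.flatnonzero(inst.a.sum(axis=1) < inst.h)
    if short.size:
        raise InfeasibleError(
            f"demands {sorted((short + 1).tolist())} exceed total producible quantity"
        )
    res = milp(
        c=inst.r,
        constraints=LinearConstraint(inst.a, lb=inst.h, ub=np.inf),
        integrality=np.ones(inst.n_genotypes),
        bounds=Bounds(0, 1),
    )
    if not res.success:
        raise InfeasibleError(f"integer program infeasible: {res.message}")
    u = np.round(res.x)
    return Assignment(u=u, mode="boolean", objective=float(inst.r @ u))


def lp_relax(inst: ILPInstance) -> Assignment:
    """Real-valued relaxation: u in [0,1]^n (cell-type concentrations).

    The optimum never exceeds the integer optimum.
    """
    res = linprog(
        c=inst.r,
        A_ub=-inst.a,
        b_ub=-inst.h,
        bounds=[(0.0, 1.0)] * inst.n_genotypes,
        method="highs",
    )
    if not res.success:
        raise InfeasibleError(f"linear program infeasible: {res.message}")
    return Assignment(u=np.clip(res.x, 0.0, 1.0), mode="real", objective=float(res.fun))


def resource_feasible(assign: Assignment, c_res: float) -> bool:
    """Survival under the resource cap: F_targ(u) < C_res (strict)."""
    return assign.objective < c_res


def cover_to_ilp(inst: CoverInstance, c_res: float | None = None) -> ILPInstance:
    """Encode a set-cover instance as the 0/1 ILP with unit costs and demands."""
    a = np.zeros((inst.universe_size, inst.n_subsets))
    for k, s in enumerate(inst.family):
        for e in s:
            a[e - 1, k] = 1.0
    return ILPInstance(a=a, r=inst.costs.copy(), h=np.ones(inst.universe_size), c_res=c_res)


# ---------------------------------------------------------------------------
# symbiosis / regulation arithmetic

def symbiosis_condition(n_reg: float, n: int, m: int, c_max: float) -> bool:
    """Symbiosis pays when N_reg < C_max^-1 (n-1) M / n (strict)."""
    if n_reg <= 0 or n < 2 or m < 1 or c_max <= 0:
        raise ValueError("all arguments must be positive, with n >= 2")
    return n_reg < (m * (n - 1)) / (c_max * n)


class JacobMonodEstimate(NamedTuple):
    n_reg: float
    advantageous: bool


def jacob_monod_nreg(m: int, n: int, c_reg: float) -> JacobMonodEstimate:
    """Regulatory gene demand of greedy sensing regulation: N_reg = C_reg M / n.

    The colony transition is computationally profitable iff n > C_reg
    (strict), since one regulatory gene then coordinates several products.
    """
    if m < 1 or n < 1:
        raise ValueError("M and n must be >= 1")
    if c_reg <= 1:
        raise ValueError("C_reg must exceed 1")
    return JacobMonodEstimate(n_reg=c_reg * m / n, advantageous=n > c_reg)


def min_cell_types(total_constraints: int, per_cell_capacity: int) -> int:
    """Distinct cell types needed to divide M constraints among cells of
    the given capacity: ceil(M / capacity)."""
    if total_constraints < 1 or per_cell_capacity < 1:
        raise ValueError("both arguments must be >= 1")
    return math.ceil(total_constraints / per_cell_capacity)


# ---------------------------------------------------------------------------
# benchmark instance family

def gen_cover_instance(
    universe_size: int,
    n_subsets: int,
    seed: int | np.random.Generator = 0,
    mean_subset_size: float | None = None,
) -> CoverInstance:
    """Seeded random cover instance: subset sizes geometric (mean ~2M/n by
    default), elements uniform, every element then patched into at least
    one subset so the family covers the universe."""
    if universe_size < 1 or n_subsets < 1:
        raise ValueError("need at least one element and one subset")
    rng = np.random.default_rng(seed)
    if mean_subset_size is None:
        mean_subset_size = max(2.0, 2.0 * universe_size / n_subsets)
    p = min(1.0, 1.0 / mean_subset_size)
    sets: list[set[int]] = []
    for _ in range(n_subsets):
        size = int(np.clip(rng.geometric(p), 1, universe_size))
        sets.append(set(rng.choice(universe_size, size=size, replace=False) + 1))
    covered = set().union(*sets)
    for e in range(1, universe_size + 1):
        if e not in covered:
            sets[int(rng.integers(n_subsets))].add(e)
    return CoverInstance(universe_size, [frozenset(s) for s in sets])


def fig2_benchmark(
    universe_size: int = 200,
    n_subsets: int = 50,
    reps: int = 20,
    seed: int = 0,
    ga_configs: Sequence[tuple[int, int]] = ((200, 30), (200, 50), (500, 50)),
) -> dict:
    """Greedy-vs-genetic resource benchmark on the seeded instance family.

    ``ga_configs`` are (generations, population) pairs, echoing the
    steps-by-population labeling of genetic-algorithm runs.  Returns per
    replicate the greedy cover size and each configuration's GA size,
    plus the fraction of replicates where the best GA matches or beats
    greedy (the efficient-resource-utilization ordering).
    """
    root = np.random.default_rng(seed)
    rows = []
    wins = 0
    for rep, child in enumerate(root.spawn(reps)):
        inst_rng, *ga_rngs = child.spawn(1 + len(ga_configs))
        inst = gen_cover_instance(universe_size, n_subsets, inst_rng)
        greedy_size = greedy_cover(inst).size
        ga_sizes = []
        for (gens, pop), ga_rng in zip(ga_configs, ga_rngs):
            sol = ga_cover(inst, generations=gens, pop_size=pop, seed=ga_rng)
            ga_sizes.append(sol.size)
        best_ga = min(ga_sizes)
        wins += best_ga <= greedy_size
        rows.append({"rep": rep, "greedy": greedy_size,
                     **{f"ga_{g}x{p}": s for (g, p), s in zip(ga_configs, ga_sizes)},
                     "best_ga": best_ga})
    return {
        "rows": rows,
        "ga_configs": list(map(list, ga_configs)),
        "best_ga_le_greedy_fraction": wins / reps,
    }
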