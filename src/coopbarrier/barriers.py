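"""Adaptivity-barrier quantities and the satisfiability phase transition.

The adaptivity barrier bounds how many environmental constraints M a
genome of N genes can satisfy simultaneously: a well-adapted genotype
exists (with non-vanishing probability) only while

    M < C_max N,   C_max = ln2 / |ln P+|,

where P+ is the maximal probability that a single random constraint is
satisfied (to tolerance delta) by some genotype.  Closed forms:

* fixed-K clauses:      P+ = 1 - 2^-K,  C_max -> 2^K ln2 for large K;
* Poisson clause sizes: C_max ~ exp(K/2) ln2 (randomized redundancy
  lowers the barrier);
* Gaussian threshold traits: C_max = ln2 / |ln Q(h_bar)| with Q the
  standard normal upper tail and h_bar = h/(sqrt(N) r).

The module also measures the empirical satisfiability curve of random
K-SAT against the constraint density alpha = M/N, using either
exhaustive genotype enumeration or a DPLL solver (unit propagation,
pure-literal elimination, first-unassigned branching).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

from coopbarrier.landscapes import SIGMOIDS, Genotype, KSATInstance, gen_ksat

__all__ = [
    "BarrierEstimate", "SatCurve", "KSATClauseFamily", "SLPTraitFamily",
    "cmax_from_p", "cmax_ksat_exact", "cmax_ksat_asymptotic", "cmax_poisson",
    "cmax_slp", "p_plus_mc", "barrier_check", "gene_deficit", "sat_curve",
    "dpll_satisfiable", "exhaustive_satisfiable",
]

_LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# closed-form barrier constants

def cmax_from_p(p_plus: float) -> float:
    """Barrier constant C_max = ln2 / |ln P+| for P+ in (0,1)."""
    if not 0.0 < p_plus < 1.0:
        raise ValueError(f"P+ must lie strictly in (0,1), got {p_plus}")
    return _LN2 / abs(math.log(p_plus))


def cmax_ksat_exact(k: int) -> float:
    """Exact K-SAT barrier: ln2/|ln(1 - 2^-K)|.

    A fixed genotype satisfies a uniformly random K-clause unless all K
    literals disagree, so P+ = 1 - 2^-K.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    return cmax_from_p(1.0 - 2.0 ** (-k))


def cmax_ksat_asymptotic(k: int) -> float:
    """Large-K form of the K-SAT barrier: 2^K ln2."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return (2.0 ** k) * _LN2


def cmax_poisson(k: float) -> float:
    """Barrier for Poisson-distributed clause sizes with mean K: exp(K/2) ln2."""
    if k <= 0:
        raise ValueError("mean clause size K must be positive")
    return math.exp(k / 2.0) * _LN2


def cmax_slp(hbar: float) -> float:
    """Barrier for Gaussian-threshold traits: ln2/|ln Q(h_bar)|.

    Q is the standard normal upper tail; h_bar = h/(sqrt(N) r) the
    normalized threshold.  Decreasing in h_bar; equals 1 at h_bar = 0.
    """
    if not math.isfinite(hbar):
        raise ValueError("normalized threshold must be finite")
    q = float(norm.sf(hbar))
    if q <= 0.0:
        raise ValueError(
            f"Gaussian tail underflows at h_bar={hbar}: barrier is effectively zero"
        )
    if q >= 1.0:
        raise ValueError(f"Gaussian tail saturates at h_bar={hbar}")
    return _LN2 / abs(math.log(q))


def barrier_check(m: int, n: int, c_max: float) -> str:
    """Classify (M, N) against the barrier M < C_max N (strict).

    Returns ``'below_barrier'`` when adaptation is feasible and
    ``'above_barrier'`` when a well-adapted genotype is exponentially
    unlikely.
    """
    if m < 1 or n < 1:
        raise ValueError("M and N must be >= 1")
    if c_max <= 0:
        raise ValueError("C_max must be positive")
    return "below_barrier" if m < c_max * n else "above_barrier"


def gene_deficit(m_total: int, n_genes: int, alpha: float = 1.0) -> float:
    """Extra genes needed to adapt to ``m_total`` constraints at density alpha.

    At the barrier M = alpha N the genome must reach M_total/alpha genes,
    so the deficit is M_total/alpha - N (negative means headroom).
    """
    if m_total < 1 or n_genes < 1:
        raise ValueError("constraint and gene counts must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return m_total / alpha - n_genes


# ---------------------------------------------------------------------------
# Monte-Carlo estimation of P+

@dataclass
class BarrierEstimate:
    """P+ estimate with the barrier constant it implies."""

    p_plus: float
    c_max: float
    delta: float
    method: Literal["closed_form", "enumeration", "monte_carlo"]
    stderr: float = 0.0


@dataclass
class KSATClauseFamily:
    """Random K-clause constraints over N genes (fixed or Poisson size)."""

    n_genes: int
    k: int
    k_dist: Literal["fixed", "poisson"] = "fixed"

    def batch_traits(self, rng: np.random.Generator, s: Genotype, n_draws: int) -> np.ndarray:
        bits = s.bits
        out = np.empty(n_draws)
        # vectorized per fixed size; Poisson sizes grouped by value
        if self.k_dist == "fixed":
            sizes = np.full(n_draws, self.k)
        else:
            sizes = np.clip(rng.poisson(self.k, size=n_draws), 1, self.n_genes)
        for size in np.unique(sizes):
            rows = np.flatnonzero(sizes == size)
            # distinct indices per clause via argsort of uniforms
            order = np.argsort(rng.random((rows.size, self.n_genes)), axis=1)
            idx = order[:, :size]
            pol = rng.choice((-1, 1), size=(rows.size, size))
            lit_sat = np.where(pol == 1, bits[idx] == 1, bits[idx] == 0)
            out[rows] = lit_sat.any(axis=1).astype(float)
        return out


@dataclass
class SLPTraitFamily:
    """Random Gaussian-threshold trait constraints f = sigma(w.s - h)."""

    n_genes: int
    r: float
    h: float
    sigmoid: str = "heaviside"

    def batch_traits(self, rng: np.random.Generator, s: Genotype, n_draws: int) -> np.ndarray:
        W = rng.normal(0.0, self.r, size=(n_draws, self.n_genes))
        z = W @ s.bits.astype(float) - self.h
        return SIGMOIDS[self.sigmoid](z)


def p_plus_mc(
    model_family,
    delta: float = 0.0,
    n_genotypes: int = 64,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> BarrierEstimate:
    """Monte-Carlo estimate of P+ = max_s Pr[f(s) > 1 - delta].

    Scans genotypes exhaustively when 2^N <= ``n_genotypes`` (N <= 20),
    otherwise a uniform random sample of size ``n_genotypes``; for each
    scanned genotype the satisfaction probability over ``n_draws`` fresh
    random constraints is estimated, and the maximum taken.  The strict
    inequality f > 1 - delta follows the barrier definition.
    """
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must lie in [0, 1)")
    if n_draws < 1:
        raise ValueError("need at least one constraint draw")
    if n_genotypes < 1:
        raise ValueError("need at least one genotype")
    rng = np.random.default_rng(seed)
    n = model_family.n_genes
    if n <= 20 and 2 ** n <= n_genotypes:
        genotypes = [
            Genotype([(code >> i) & 1 for i in range(n)]) for code in range(2 ** n)
        ]
    else:
        genotypes = [Genotype.random(n, rng) for _ in range(n_genotypes)]
    best = -1.0
    for s in genotypes:
        f = model_family.batch_traits(rng, s, n_draws)
        # exact satisfaction f = 1 always counts; at delta = 0 a Boolean
        # constraint value of 1 would otherwise fail the strict inequality
        frac = float(np.mean((f > 1.0 - delta) | (f >= 1.0)))
        if frac > best:
            best = frac
    stderr = math.sqrt(best * (1.0 - best) / n_draws)
    if 0.0 < best < 1.0:
        c_max = cmax_from_p(best)
    elif best >= 1.0:
        c_max = math.inf
    else:
        c_max = 0.0
    return BarrierEstimate(
        p_plus=best, c_max=c_max, delta=delta, method="monte_carlo", stderr=stderr
    )


# ---------------------------------------------------------------------------
# satisfiability solvers

def _to_signed_clauses(inst: KSATInstance) -> list[tuple[int, ...]]:
    """Clauses as tuples of signed 1-based literals (DIMACS style)."""
    return [
        tuple((i + 1) * pol for i, pol in c.literals) for c in inst.clauses
    ]


def dpll_satisfiable(inst: KSATInstance) -> bool:
    """DPLL: unit propagation, pure-literal elimination, first-unassigned branching."""
    clauses = _to_signed_clauses(inst)

    def solve(clauses: list[tuple[int, ...]], assignment: dict[int, bool]) -> bool:
        # unit propagation + pure literal to fixpoint
        while True:
            unit = None
            for c in clauses:
                if len(c) == 0:
                    return False
                if len(c) == 1:
                    unit = c[0]
                    break
            if unit is not None:
                clauses = _assign(clauses, unit)
                if clauses is None:
                    return False
                continue
            lits = {lit for c in clauses for lit in c}
            pure = next((lit for lit in lits if -lit not in lits), None)
            if pure is not None:
                clauses = _assign(clauses, pure)
                if clauses is None:
                    return False
                continue
            break
        if not clauses:
            return True
        # branch on the first variable appearing in the remaining clauses
        var = abs(clauses[0][0])
        for lit in (var, -var):
            reduced = _assign(clauses, lit)
            if reduced is not None and solve(reduced, assignment):
                return True
        return False

    def _assign(clauses: list[tuple[int, ...]], lit: int):
        out = []
        for c in clauses:
            if lit in c:
                continue
            if -lit in c:
                c = tuple(x for x in c if x != -lit)
                if not c:
                    return None
            out.append(c)
        return out

    return solve(clauses, {})


def exhaustive_satisfiable(inst: KSATInstance, chunk: int = 1 << 16) -> bool:
    """Decide satisfiability by scanning all 2^N genotypes (N <= 25)."""
    n = inst.n_genes
    if n > 25:
        raise ValueError(
            f"exhaustive scan refused for N={n} > 25; use the DPLL solver"
        )
    if not inst.clauses:
        return True
    shifts = np.arange(n, dtype=np.uint32)
    total = 1 << n
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.uint32)
        bits = ((codes[:, None] >> shifts) & 1).astype(np.int8)
        alive = np.ones(codes.size, dtype=bool)
        for c in inst.clauses:
            idx = np.fromiter((i for i, _ in c.literals), dtype=np.int64)
            pol = np.fromiter((p for _, p in c.literals), dtype=np.int64)
            sat = np.where(pol == 1, bits[:, idx] == 1, bits[:, idx] == 0).any(axis=1)
            alive &= sat
            if not alive.any():
                break
        if alive.any():
            return True
    return False


# ---------------------------------------------------------------------------
# phase-transition curve

@dataclass
class SatCurve:
    """Empirical satisfiability fraction against constraint density alpha = M/N."""

    alphas: np.ndarray
    p_sat: np.ndarray
    reps: int
    n_genes: int
    k: int
    seed: int
    solver: str = "dpll"

    def __post_init__(self):
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.p_sat = np.asarray(self.p_sat, dtype=float)
        if np.any(np.diff(self.alphas) <= 0):
            raise ValueError("alphas must be strictly increasing")
        if np.any((self.p_sat < 0) | (self.p_sat > 1)):
            raise ValueError("p_sat must lie in [0,1]")

    def crossing_alpha(self, level: float = 0.5) -> float:
        """First grid alpha where p_sat drops below ``level`` (nan if never)."""
        below = np.flatnonzero(self.p_sat < level)
        return float(self.alphas[below[0]]) if below.size else math.nan


def sat_curve(
    n_genes: int,
    k: int,
    alphas: Sequence[float],
    reps: int,
    seed: int = 0,
    solver: Literal["exhaustive", "dpll"] = "dpll",
) -> SatCurve:
    """Fraction of satisfiable random K-SAT instances at each density alpha.

    For each alpha, M = round(alpha * N) clauses are generated per
    instance; an instance counts as satisfiable when some genotype
    satisfies all M clauses.
    """
    alphas = np.asarray(sorted(alphas), dtype=float)
    if np.any(alphas <= 0):
        raise ValueError("alphas must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if solver == "exhaustive" and n_genes > 25:
        raise ValueError("exhaustive solver refused for N > 25; use solver='dpll'")
    if solver not in ("exhaustive", "dpll"):
        raise ValueError(f"unknown solver {solver!r}")
    decide = exhaustive_satisfiable if solver == "exhaustive" else dpll_satisfiable
    root = np.random.default_rng(seed)
    # one independent child stream per (alpha, rep) so grid edits do not
    # reshuffle other points
    p_sat = np.empty(alphas.size)
    for a_i, alpha in enumerate(alphas):
        m = max(1, round(alpha * n_genes))
        sat = 0
        for child in root.spawn(reps):
            inst = gen_ksat(n_genes, m, k, "fixed", child)
            if decide(inst):
                sat += 1
        p_sat[a_i] = sat / reps
    return SatCurve(
        alphas=alphas, p_sat=p_sat, reps=reps, n_genes=n_genes, k=k,
        seed=seed if isinstance(seed, int) else -1, solver=solver,
    )
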