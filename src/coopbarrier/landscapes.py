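"""Combinatorial genotype-fitness landscapes.

A genotype is a Boolean string s in {0,1}^N where s_i = 1 means gene i
is expressed.  Fitness is a weighted sum F(s) = sum_k b_k f_k(s) over M
environmental constraints.  Two constraint families are provided:

* K-SAT clauses — each constraint is an OR over K genes, satisfied by
  the correct expression (or non-expression) of the genes involved; with
  unit weights the fitness is the number of satisfied constraints.
* Threshold perceptrons — gene-trait maps f_j = sigma(sum_i w_ji s_i - h_j)
  with Gaussian random regulation weights; positive weights are
  activators, negative weights repressors, h_j a robustness threshold.
  Single-layer (SLP) and feed-forward multi-layer (MLP) variants.

Gene indices are 1-based in file formats and error messages (the DIMACS
convention) and 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "Genotype", "Clause", "KSATInstance", "SLPModel", "MLPModel",
    "SIGMOIDS", "gen_ksat", "eval_clause", "ksat_fitness", "gen_slp",
    "slp_traits", "mlp_traits", "normalized_threshold",
]


# ---------------------------------------------------------------------------
# sigmoid families

def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _heaviside(z: np.ndarray) -> np.ndarray:
    # z == 0 resolves to 1 (>= convention)
    return np.where(np.asarray(z, dtype=float) >= 0.0, 1.0, 0.0)


SIGMOIDS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "logistic": _logistic,
    "heaviside": _heaviside,
}


# ---------------------------------------------------------------------------
# domain types

class Genotype:
    """Boolean gene-expression string s in {0,1}^N."""

    __slots__ = ("bits",)

    def __init__(self, bits: Sequence[int]):
        arr = np.asarray(bits, dtype=np.int8)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("genotype must be a non-empty 1-D bit sequence")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("genotype entries must be 0 or 1")
        self.bits = arr

    def __len__(self) -> int:
        return int(self.bits.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genotype) and np.array_equal(self.bits, other.bits)

    def __repr__(self) -> str:
        return f"Genotype({''.join(map(str, self.bits.tolist()))})"

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        """Parse '1011' or '1,0,1,1' into a genotype."""
        s = s.strip()
        parts = s.split(",") if "," in s else list(s)
        return cls([int(p) for p in parts])

    @classmethod
    def random(cls, n: int, rng: np.random.Generator) -> "Genotype":
        return cls(rng.integers(0, 2, size=n))


@dataclass(frozen=True)
class Clause:
    """Disjunction of K literals: (gene index, polarity) pairs.

    Indices are 0-based here; polarity +1 means the literal is satisfied
    by s_i = 1, polarity -1 by s_i = 0.
    """

    literals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        idx = [i for i, _ in self.literals]
        if len(set(idx)) != len(idx):
            raise ValueError("clause gene indices must be distinct")
        if any(i < 0 for i in idx):
            raise ValueError("negative gene index in clause")
        if any(p not in (-1, 1) for _, p in self.literals):
            raise ValueError("polarity must be +1 or -1")

    def __len__(self) -> int:
        return len(self.literals)


@dataclass
class KSATInstance:
    """M weighted clauses over N Boolean genes: a combinatorial landscape."""

    n_genes: int
    clauses: list[Clause]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.ones(len(self.clauses))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.clauses),):
            raise ValueError("one weight per clause required")
        if len(self.clauses) and not (self.weights > 0).all():
            raise ValueError("clause weights must be positive")
        for c in self.clauses:
            if any(i >= self.n_genes for i, _ in c.literals):
                raise ValueError("clause index exceeds gene count")

    @property
    def n_clauses(self) -> int:
        return len(self.clauses)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KSATInstance)
            and self.n_genes == other.n_genes
            and self.clauses == other.clauses
            and np.allclose(self.weights, other.weights)
        )


@dataclass
class SLPModel:
    """Single-layer gene-trait map f_j = sigma(W s - h)_j.

    W is M x N; row j holds the regulation weights of trait j; h the
    trait thresholds; r records the weight standard deviation used at
    generation time (for the normalized threshold h / (sqrt(N) r)).
    """

    W: np.ndarray
    h: np.ndarray
    r: float
    sigmoid: str = "logistic"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be an M x N matrix")
        if self.h.shape != (self.W.shape[0],):
            raise ValueError("one threshold per trait required")
        if not np.isfinite(self.W).all():
            raise ValueError("W must be finite")
        if self.sigmoid not in SIGMOIDS:
            raise ValueError(f"unknown sigmoid {self.sigmoid!r}")

    @property
    def n_traits(self) -> int:
        return int(self.W.shape[0])

    @property
    def n_genes(self) -> int:
        return int(self.W.shape[1])


@dataclass
class MLPModel:
    """Feed-forward cascade of (weight matrix, threshold vector) layers.

    Each layer computes sigma(W x - h); genes in one layer depend on the
    genes of the previous layer, mimicking cascade regulation (maternal
    factors -> gap genes -> Hox genes -> realizators).
    """

    layers: list[tuple[np.ndarray, np.ndarray]]
    sigmoid: str = "logistic"

    def __post_init__(self):
        if not self.layers:
            raise ValueError("at least one layer required")
        fixed = []
        prev_out = None
        for W, h in self.layers:
            W = np.asarray(W, dtype=float)
            h = np.asarray(h, dtype=float)
            if W.ndim != 2 or h.shape != (W.shape[0],):
                raise ValueError("layer shapes inconsistent")
            if prev_out is not None and W.shape[1] != prev_out:
                raise ValueError(
                    f"layer input dim {W.shape[1]} != previous output {prev_out}"
                )
            prev_out = W.shape[0]
            fixed.append((W, h))
        self.layers = fixed
        if self.sigmoid not in SIGMOIDS:
            raise ValueError(f"unknown sigmoid {self.sigmoid!r}")

    @property
    def n_genes(self) -> int:
        return int(self.layers[0][0].shape[1])

    @property
    def n_traits(self) -> int:
        return int(self.layers[-1][0].shape[0])


# ---------------------------------------------------------------------------
# generators

def gen_ksat(
    n_genes: int,
    n_clauses: int,
    k: int,
    k_dist: Literal["fixed", "poisson"] = "fixed",
    seed: int | np.random.Generator = 0,
) -> KSATInstance:
    """Generate a random K-SAT landscape: M clauses over N genes.

    With ``k_dist='fixed'`` each clause has exactly K distinct genes;
    with ``'poisson'`` the per-clause size is Poisson with mean K,
    truncated to [1, N].  Gene indices are drawn uniformly without
    replacement and polarities uniformly.  Weights default to 1 so that
    fitness counts satisfied constraints.
    """
    if n_genes < 1 or n_clauses < 0 or k < 1:
        raise ValueError("require N >= 1, M >= 0, K >= 1")
    if k_dist == "fixed" and k > n_genes:
        raise ValueError(f"fixed clause size K={k} exceeds gene count N={n_genes}")
    if k_dist not in ("fixed", "poisson"):
        raise ValueError(f"unknown k_dist {k_dist!r}")
    rng = np.random.default_rng(seed)
    clauses = []
    for _ in range(n_clauses):
        if k_dist == "fixed":
            size = k
        else:
            size = int(np.clip(rng.poisson(k), 1, n_genes))
        idx = rng.choice(n_genes, size=size, replace=False)
        pol = rng.choice((-1, 1), size=size)
        clauses.append(Clause(tuple(zip(idx.tolist(), pol.tolist()))))
    return KSATInstance(n_genes, clauses)


def gen_slp(
    n_genes: int,
    n_traits: int,
    r: float,
    h: float,
    seed: int | np.random.Generator = 0,
    sigmoid: str = "logistic",
) -> SLPModel:
    """Random gene regulation: W entries i.i.d. Normal(0, r^2), common threshold h."""
    if n_genes < 1 or n_traits < 1:
        raise ValueError("require N, M >= 1")
    if r <= 0:
        raise ValueError("weight standard deviation r must be positive")
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, r, size=(n_traits, n_genes))
    return SLPModel(W=W, h=np.full(n_traits, float(h)), r=float(r), sigmoid=sigmoid)


# ---------------------------------------------------------------------------
# evaluation

def eval_clause(clause: Clause, s: Genotype) -> int:
    """1 iff at least one literal agrees with the genotype."""
    bits = s.bits
    for i, pol in clause.literals:
        if i >= bits.size:
            raise IndexError(f"clause refers to gene {i + 1} beyond genotype length {bits.size}")
        if (pol == 1 and bits[i] == 1) or (pol == -1 and bits[i] == 0):
            return 1
    return 0


def ksat_fitness(inst: KSATInstance, s: Genotype) -> float:
    """Weighted count of satisfied constraints, F(s) = sum_k b_k f_k(s)."""
    if len(s) != inst.n_genes:
        raise ValueError(
            f"genotype length {len(s)} != instance gene count {inst.n_genes}"
        )
    return float(
        sum(b * eval_clause(c, s) for c, b in zip(inst.clauses, inst.weights))
    )


def slp_traits(model: SLPModel, s: Genotype) -> np.ndarray:
    """Trait vector f_j = sigma(sum_i w_ji s_i - h_j)."""
    if len(s) != model.n_genes:
        raise ValueError(
            f"genotype length {len(s)} != model gene count {model.n_genes}"
        )
    z = model.W @ s.bits.astype(float) - model.h
    return SIGMOIDS[model.sigmoid](z)


def mlp_traits(model: MLPModel, s: Genotype) -> np.ndarray:
    """Feed-forward composition of per-layer affine map + sigmoid.

    A one-layer model reproduces :func:`slp_traits` exactly.
    """
    if len(s) != model.n_genes:
        raise ValueError(
            f"genotype length {len(s)} != model input dim {model.n_genes}"
        )
    x = s.bits.astype(float)
    sig = SIGMOIDS[model.sigmoid]
    for W, h in model.layers:
        x = sig(W @ x - h)
    return x


def normalized_threshold(h: float, n_genes: int, r: float) -> float:
    """h_bar = h / (sqrt(N) r): trait sensitivity under Gaussian regulation."""
    if n_genes < 1:
        raise ValueError("N must be >= 1")
    if r <= 0:
        raise ValueError("r must be positive")
    return float(h) / (np.sqrt(n_genes) * r)
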