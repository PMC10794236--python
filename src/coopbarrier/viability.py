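"""Homeostasis viability under random stress and replicating-chain survival.

An organism's metabolism is a kinetic system dv/dt = g(v, xi, s) on a
nonnegative domain, where xi is a random environmental stress and s the
gene-expression string gating the reactions.  The organism is viable
when its output concentrations clear thresholds, v_i > h_i for i in I;
the viability probability P_v(s) = Pr[v_i(xi, s) > h_i for all i in I]
is its fitness, estimated here by Monte Carlo over stress draws.

Across a chain of replications the log survival probability is
approximately -sum_t P_out(t) with P_out = 1 - F the per-step exit
probability.  With a static genome P_out is constant and survival
decays to zero; when rare innovations grow the regulatory network
(size N_reg), the exit probability falls as exp(-c0 N_reg^gamma) — the
complement of the asymptotic viability 1 - exp(-c0 N_reg^gamma) — and
indefinite survival becomes possible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from coopbarrier.landscapes import Genotype

__all__ = [
    "StressSpec", "KineticModel", "GRNState", "ChainStep", "ChainTrajectory",
    "ChainResult", "ViabilityEstimate", "homeostasis_viability_mc", "p_out",
    "log_viability", "asymptotic_viability", "simulate_chain",
    "michaelis_menten_chain", "linear_relaxation_model",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stress distributions

@dataclass(frozen=True)
class StressSpec:
    """Named stress distribution: the measure rho from which xi is drawn."""

    name: str  # normal | lognormal | uniform
    params: tuple[float, ...]
    size: int = 1

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        if self.name == "normal":
            mu, sigma = self.params
            return rng.normal(mu, sigma, size=self.size)
        if self.name == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size=self.size)
        if self.name == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size=self.size)
        raise ValueError(f"unknown stress distribution {self.name!r}")


# ---------------------------------------------------------------------------
# kinetic models

@dataclass
class KineticModel:
    """Kinetic system dv/dt = g(v, xi, s) with homeostasis thresholds.

    ``rates(v, xi, s)`` returns dv/dt; ``thresholds`` and
    ``viability_idx`` (0-based, the index set I) define the homeostasis
    domain v_i > h_i; ``domain_bound`` is an upper concentration bound
    (leaving it counts as non-viable); ``v0`` the initial state.
    """

    n_species: int
    rates: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    thresholds: np.ndarray
    viability_idx: tuple[int, ...]
    stress: StressSpec
    v0: np.ndarray = field(default=None)  # type: ignore[assignment]
    domain_bound: float | None = None

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (len(self.viability_idx),):
            raise ValueError("one threshold per monitored species required")
        if (self.thresholds < 0).any():
            raise ValueError("thresholds must be nonnegative")
        if any(i < 0 or i >= self.n_species for i in self.viability_idx):
            raise ValueError("viability index outside species range")
        if self.v0 is None:
            self.v0 = np.zeros(self.n_species)
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.v0.shape != (self.n_species,):
            raise ValueError("initial state dimension mismatch")


def michaelis_menten_chain(
    n_stages: int,
    vmax: float = 2.0,
    km: float = 1.0,
    decay: float = 1.0,
    stress: StressSpec | None = None,
    thresholds: Sequence[float] | None = None,
) -> KineticModel:
    """Gated Michaelis-Menten chain: substrate -> v_1 -> ... -> v_L.

    Stage i converts species i-1 into species i at rate
    s_i * vmax * v_{i-1} / (km + v_{i-1}) and species decay linearly;
    the chain input is the stress draw xi (clipped at 0), so an
    unexpressed gene blocks everything downstream.  Viability requires
    the terminal product to clear its threshold (default 0.1).
    """
    if n_stages < 1:
        raise ValueError("chain needs at least one stage")
    if stress is None:
        stress = StressSpec("normal", (2.0, 0.5))
    if thresholds is None:
        thresholds = [0.1]

    def rates(v: np.ndarray, xi: np.ndarray, s: np.ndarray) -> np.ndarray:
        dv = np.empty(n_stages)
        upstream = max(float(xi[0]), 0.0)
        for i in range(n_stages):
            gate = float(s[i]) if i < len(s) else 0.0
            dv[i] = gate * vmax * upstream / (km + upstream) - decay * v[i]
            upstream = max(float(v[i]), 0.0)
        return dv

    return KineticModel(
        n_species=n_stages,
        rates=rates,
        thresholds=np.asarray(thresholds, dtype=float),
        viability_idx=(n_stages - 1,),
        stress=stress,
    )


def linear_relaxation_model(
    mu: float = 2.0, sigma: float = 1.0, threshold: float = 1.0
) -> KineticModel:
    """One-species relaxation dv/dt = xi - v with Gaussian stress.

    The steady state is v* = xi, so for large t_end the viability
    probability is the Gaussian tail Pr[xi > h].
    """

    def rates(v: np.ndarray, xi: np.ndarray, s: np.ndarray) -> np.ndarray:
        return xi - v

    return KineticModel(
        n_species=1,
        rates=rates,
        thresholds=np.array([threshold]),
        viability_idx=(0,),
        stress=StressSpec("normal", (mu, sigma)),
    )


@dataclass
class ViabilityEstimate:
    """Monte-Carlo probability estimate with its binomial standard error."""

    estimate: float
    stderr: float
    n_samples: int


def homeostasis_viability_mc(
    model: KineticModel,
    s: Genotype | Sequence[int],
    n_samples: int,
    t_end: float = 20.0,
    seed: int | np.random.Generator = 0,
    pathwise: bool = False,
    rtol: float = 1e-6,
) -> ViabilityEstimate:
    """Monte-Carlo estimate of P_v(s) = Pr[v_i(xi, s) > h_i for all i in I].

    Integrates the kinetics to ``t_end`` for each stress draw xi ~ rho
    and checks the thresholds there (a steady-state proxy); with
    ``pathwise=True`` the minimum over the trajectory after a burn-in of
    t_end/2 must clear the thresholds instead.  Trajectories leaving the
    concentration domain count as non-viable and are logged.
    """
    if n_samples < 1:
        raise ValueError("need at least one stress sample")
    bits = s.bits if isinstance(s, Genotype) else np.asarray(s, dtype=np.int8)
    rng = np.random.default_rng(seed)
    idx = np.asarray(model.viability_idx, dtype=int)
    viable = 0
    clipped = False
    for _ in range(n_samples):
        xi = model.stress.sample(rng)
        sol = solve_ivp(
            lambda t, v: model.rates(np.maximum(v, 0.0), xi, bits),
            (0.0, t_end),
            model.v0,
            rtol=rtol,
            atol=1e-9,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"kinetic integration failed: {sol.message}")
        traj = sol.y
        if (traj < -1e-6).any():
            clipped = True
        traj = np.maximum(traj, 0.0)
        if model.domain_bound is not None and (traj > model.domain_bound).any():
            logger.info("trajectory left the domain; sample counted non-viable")
            continue
        if pathwise:
            burn = sol.t >= t_end / 2.0
            vals = traj[np.ix_(idx, np.flatnonzero(burn))].min(axis=1)
        else:
            vals = traj[idx, -1]
        if (vals > model.thresholds).all():
            viable += 1
    if clipped:
        logger.warning("negative concentrations clipped to 0 during integration")
    p = viable / n_samples
    return ViabilityEstimate(
        estimate=p,
        stderr=math.sqrt(p * (1.0 - p) / n_samples),
        n_samples=n_samples,
    )


# ---------------------------------------------------------------------------
# replicating-chain survival

def p_out(fitness: float) -> float:
    """Per-replication exit probability P_out = 1 - F for F in [0,1]."""
    if not 0.0 <= fitness <= 1.0:
        raise ValueError(f"fitness must lie in [0,1], got {fitness}")
    return 1.0 - fitness


def asymptotic_viability(n_reg: int, c0: float = 1.0, gamma: float = 0.5) -> float:
    """Long-run viability of a regulatory network of size N_reg:
    P_v = 1 - exp(-c0 N_reg^gamma), strictly increasing in N_reg."""
    if n_reg < 1:
        raise ValueError("network size must be >= 1")
    if c0 <= 0 or gamma <= 0:
        raise ValueError("c0 and gamma must be positive")
    return 1.0 - math.exp(-c0 * float(n_reg) ** gamma)


@dataclass
class GRNState:
    """Gene-regulatory-network state along a chain: size plus parameters."""

    n_reg: int
    genotype: Genotype | None = None
    w: np.ndarray | None = None

    def __post_init__(self):
        if self.n_reg < 1:
            raise ValueError("network size must be >= 1")


@dataclass(frozen=True)
class ChainStep:
    t: int
    n_reg: int
    p_out: float


@dataclass
class ChainTrajectory:
    """One replication chain: per-step network size and exit probability."""

    steps: list[ChainStep]
    innovation_rate: float

    @property
    def n_rep(self) -> int:
        return len(self.steps)

    @property
    def p_outs(self) -> np.ndarray:
        return np.array([st.p_out for st in self.steps])


@dataclass
class ChainResult:
    """Chain survival estimate with a sample trajectory."""

    estimate: float
    stderr: float
    n_runs: int
    trajectory: ChainTrajectory


def log_viability(chain: ChainTrajectory) -> float:
    """Small-exit-probability approximation log P_v,T ~ -sum_t P_out(t).

    Valid when every P_out is small; warns above 0.2.
    """
    if chain.n_rep == 0:
        warnings.warn("empty chain: log viability taken as 0", stacklevel=2)
        return 0.0
    p = chain.p_outs
    if (p > 0.2).any():
        warnings.warn(
            "some P_out exceed 0.2; the linearized log-viability is inaccurate",
            stacklevel=2,
        )
    return float(-p.sum())


def _default_pout_rule(c0: float = 1.0, gamma: float = 0.5) -> Callable[[GRNState], float]:
    def rule(state: GRNState) -> float:
        return math.exp(-c0 * float(state.n_reg) ** gamma)

    return rule


def _default_growth(state: GRNState) -> GRNState:
    return replace(state, n_reg=state.n_reg + 1)


def simulate_chain(
    init: GRNState,
    innovation_rate: float,
    n_rep: int,
    growth_rule: Callable[[GRNState], GRNState] | None = None,
    pout_rule: Callable[[GRNState], float] | None = None,
    n_runs: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ChainResult:
    """Monte-Carlo survival of a replicating chain with a growing network.

    Per run and step: the organism survives with probability
    1 - P_out(state); then, with probability ``innovation_rate``, an
    innovation grows the network (default: N_reg += 1).  The default
    exit rule P_out = exp(-c0 N_reg^gamma) is the complement of
    :func:`asymptotic_viability`.  Returns the fraction of runs
    surviving all ``n_rep`` steps and the (fully evaluated) trajectory
    of the first run as a sample.
    """
    if n_rep < 1 or n_runs < 1:
        raise ValueError("n_rep and n_runs must be >= 1")
    if not 0.0 <= innovation_rate <= 1.0:
        raise ValueError("innovation rate must lie in [0,1]")
    growth_rule = growth_rule or _default_growth
    pout_rule = pout_rule or _default_pout_rule()
    rng = np.random.default_rng(seed)

    # every run consumes exactly two uniforms per step (survival, then
    # innovation) so that runs at different innovation rates couple
    # monotonely under common random numbers
    sample_steps: list[ChainStep] | None = None
    survived = 0
    for run in range(n_runs):
        state = init
        alive = True
        steps: list[ChainStep] = []
        record = run == 0
        for t in range(n_rep):
            q = float(pout_rule(state))
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"exit probability {q} outside [0,1] at step {t}")
            if record:
                steps.append(ChainStep(t=t, n_reg=state.n_reg, p_out=q))
            if rng.random() < q:
                alive = False
            if rng.random() < innovation_rate:
                state = growth_rule(state)
        if alive:
            survived += 1
        if record:
            sample_steps = steps
    p = survived / n_runs
    return ChainResult(
        estimate=p,
        stderr=math.sqrt(p * (1.0 - p) / n_runs),
        n_runs=n_runs,
        trajectory=ChainTrajectory(steps=sample_steps or [], innovation_rate=innovation_rate),
    )
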