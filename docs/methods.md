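# Methods

## Fitness landscapes

Genotypes are Boolean strings s ∈ {0,1}^N; s_i = 1 means gene i is
expressed.  Fitness is F(s) = Σ_k b_k f_k(s) over M environmental
constraints.  Weights b_k default to 1 so F counts satisfied
constraints; a uniform 1/M normalization is a one-line rescale of the
weights vector if relative fitness is wanted.

**K-SAT constraints.**  `gen_ksat` draws, per clause, K distinct gene
indices uniformly without replacement and independent uniform
polarities.  With `k_dist="poisson"` the per-clause size is Poisson with
mean K, truncated to [1, N] (truncation is the only choice that keeps a
clause well-defined; the mean shifts negligibly for K ≪ N).  Gene
indices are 1-based in DIMACS files and messages, 0-based in memory.

**Threshold gene–trait maps.**  `gen_slp` draws regulation weights
w_ji i.i.d. Normal(0, r²) — random gene regulation — with a common
trait threshold h.  Two sigmoid families are built in: the logistic
1/(1+e^(−z)) (traits as survival probabilities in (0,1)) and the hard
threshold (Heaviside; traits as Boolean functions), selectable per
model because the closed-form barrier constants correspond to the hard-
threshold limit while graded responses want the logistic.  The
degenerate argument z = 0 in the hard threshold resolves to 1 (the "≥"
convention).  Multi-layer models are feed-forward cascades of
affine-plus-sigmoid layers; a one-layer cascade reproduces the
single-layer map exactly.

## Barrier quantities

C_max = ln 2/|ln P₊,δ|.  The specializations implemented: fixed-K
clauses (P₊ = 1 − 2⁻ᴷ), the large-K asymptote 2ᴷ ln 2, the Poisson-size
asymptote e^{K/2} ln 2, and the Gaussian-threshold form
ln 2/|ln Q(h̄)| with h̄ = h/(√N r).  As printed, the last form lacks an
absolute value; since ln Q < 0 we take |ln Q| so that C_max > 0,
consistent with the general definition.  Q is evaluated with the
standard-normal survival function; underflow (h̄ large) raises a domain
error rather than returning 0.

**Monte-Carlo P₊.**  The definition takes a max over constraints and
genotypes of a probability over random regulation.  The estimator scans
genotypes (exhaustively when 2^N fits the scan budget, else a uniform
sample) and, for each, estimates the satisfaction fraction over fresh
constraint draws, returning the maximum with its binomial standard
error.  Because the estimator is a max of noisy binomials it carries a
positive bias of order one standard error per scanned genotype decade;
calibration checks therefore scan few genotypes and use many draws.
Satisfaction uses f > 1 − δ, with exact satisfaction f = 1 always
counting — otherwise a Boolean constraint could never satisfy the
strict inequality at δ = 0.

**Satisfiability curve.**  For each density α, M = round(α·N) clauses
per instance.  Two deciders, cross-checked on random instances: an
exhaustive vectorized scan of all 2^N genotypes (N ≤ 25) and a DPLL
solver (unit propagation, pure-literal elimination, branching on the
first variable of the first open clause).  The empirical 0.5-crossing
is only asserted to lie below the first-moment bound 2ᴷ ln 2; the true
satisfiability threshold is not pinned to literature values.

## Cooperation models

**Greedy cover** selects the subset covering the most still-uncovered
target elements; ties break to the lowest subset index for determinism.
This is the algorithmic content of Jacob–Monod sensing regulation: each
organism satisfies constraints the others left unsatisfied.  The
standard (1 + ln M) approximation guarantee is asserted in tests.

**Exact cover** is iterative-deepening depth-first search over subset
indices in increasing order with a coverage-bound prune, so the first
solution found at the minimal depth is also the lexicographically
smallest; refused above n = 24 subsets.

**Genetic-algorithm cover** uses bit-vector encoding over subsets,
tournament selection of size 2, uniform crossover (rate 0.9), per-bit
flip mutation (default rate 1/n), elitism of one, and — the piece that
makes small populations competitive — a repair operator that adds sets
greedily (gain per cost) until feasible and then removes redundant sets
in random order.  All operators are parameters of `ga_cover`;
`seed_individuals` can inject the greedy solution.  Solution quality is
invariant under subset relabeling except through seed-dependent tie
behavior (documented, not asserted).

**ILP / LP.**  The symbiosis program min r·u s.t. a u ≥ h is solved
exactly over u ∈ {0,1}^n with `scipy.optimize.milp` (HiGHS
branch-and-bound); an exhaustive 0/1 enumeration serves as an
independent oracle in tests up to n ≈ 16, and the 0/1-matrix special
case is cross-checked against `exact_cover`.  The relaxation u ∈ [0,1]^n
uses `scipy.optimize.linprog` (HiGHS); constraint residuals are within
solver tolerance (~1e−9) and the LP optimum is verified never to exceed
the ILP optimum.  Infeasibility is reported with the demands that no
activation pattern can meet.  The resource cap F_targ < C_res is strict,
as is the symbiosis condition N_reg < C_max⁻¹(n−1)M/n and the colony
advantage n > C_reg.

**Benchmark family.**  The greedy-vs-genetic comparison runs on a
seeded random family: n subsets with geometric sizes (mean 2M/n),
elements uniform, every uncovered element patched into a random subset.
Default scale 200 elements × 50 subsets, 20 replicates, GA
configurations (150 generations × 30) and (200 × 50).  Results are a
scaled analog of the qualitative greedy-vs-genetic ordering, not a
replication of any particular published benchmark run.

## Viability

**Homeostasis Monte Carlo.**  A kinetic model dv/dt = g(v, ξ, s) is
integrated per stress draw ξ ~ ρ with an adaptive explicit scheme
(`solve_ivp`, rtol 1e−6); viability means v_i > h_i for all monitored
species at t_end (a steady-state proxy; a pathwise-minimum variant over
the second half of the trajectory is available via `pathwise=True`).
Negative concentrations are clipped to 0 inside the rate evaluation and
logged; trajectories exceeding the optional domain bound count as
non-viable.  The default model is a gated Michaelis–Menten chain —
stage i converts species i−1 at rate s_i·V_max·v_{i−1}/(K_m + v_{i−1})
with linear decay, fed by the stress draw — so an unexpressed gene
blocks everything downstream.  Defaults: V_max = 2, K_m = 1, decay 1,
stress Normal(2, 0.5) on the influx, terminal threshold 0.1; chosen so
that a fully expressed chain is viable with probability near 1 and a
blocked chain is not, which is the regime of interest.  A one-species
linear model dv/dt = ξ − v provides a closed-form calibration target
(the Gaussian tail Pr[ξ > h]).

**Replicating chain.**  Per replication step the organism exits
homeostasis with probability P_out(state) and, independently with
probability `innovation_rate`, an innovation grows the network by one
unit (innovations are rare multi-mutation events; unit granularity is
the simplest choice).  The default exit rule P_out = exp(−c₀ N_reg^γ)
is the complement of the asymptotic viability 1 − exp(−c₀ N_reg^γ);
c₀ = 1 and γ = 0.5 are free configuration constants (they depend on
kinetic details that are not modeled).  Exactly two uniforms are
consumed per step regardless of outcome, so runs at different
innovation rates couple monotonely under common random numbers — the
survival-monotone-in-innovation property is tested that way.  The
log-viability approximation log P ≈ −Σ P_out is used (and tested) only
in the regime where all P_out ≤ 0.05; a warning fires above 0.2.
Whether P_out should be wired to the instantaneous combinatorial
fitness or to the network-size law is left to the caller: `pout_rule`
accepts any state-to-probability function and both wirings are one
lambda away.

## Problem sizes and randomness

Default experiment sizes: satisfiability transition at N = 20 with 100
instances per density; cover comparisons on 200 random instances with
M ≤ 12, n ≤ 8 (where the enumeration oracle is exact) plus the
200 × 50 benchmark; 10⁴ chain runs; 10³–2×10⁴ Monte-Carlo draws
elsewhere.  These sizes put every stochastic check within three
standard errors of its closed-form target while keeping a full run in
minutes on one core.  Every stochastic entry point takes a seed
(integer or `numpy` Generator); sub-streams are derived by
`SeedSequence` spawning so adding one draw site does not reshuffle the
others, and the CLI echoes auto-generated seeds in its output.

## Limitations

Synthetic constraint families are exchangeable and unstructured: no
epistatic modularity, no correlated regulation, no real GRN topology,
and the kinetic default is a single unbranched chain.  Passing tests
therefore certify the algorithmic claims (barrier locations, solver
orderings, relaxation gaps, survival laws) on the stated random
ensembles, not the behavior of any real metabolic or regulatory
network.  The exact cover/ILP solvers are exponential by design and
refuse large instances rather than degrade silently; the DPLL solver
has no clause learning and is intended for the N ≲ 100 instances the
experiments use.
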