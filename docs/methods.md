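# Methods

## Model and assumptions

The package treats a metabolic network as a stoichiometric matrix `S` over
non-boundary metabolites with box bounds `lb ≤ v ≤ ub` on reaction fluxes.
All analyses assume **metabolic and isotopic steady state**: `S·v = 0` and
time-invariant isotopologue fractions.  Flux units are carried as metadata
only (`μmol·h⁻¹·million-cells⁻¹` by convention); no conversion is performed.

Reversible reactions are split into forward and reverse fluxes through a
turnover variable `t_i ≥ 0` (`v_f = t + max(v,0)`, `v_r = t − min(v,0)`).
Turnover affects labeling (bidirectional exchange mixes pools) but not mass
balance, so it appears in the labeling simulation and in the decision
vector, while the parsimony objective penalizes only net fluxes `|v_i|`.
Penalizing `t` as well would doubly suppress the exchange needed to fit
labeling data; the choice is recorded as configurable in principle but the
shipped objective always excludes `t`.

## Label propagation

Carbon routing is declared per reaction as letter-mapped equations
(`glc[abcdef] -> gap[cba] + gap[def]`).  Reactions may carry several
equally weighted mapping variants; this is how symmetric metabolites
(succinate/fumarate-style scrambling) are expressed.  Reverse mappings of
reversible reactions are the inverses of the forward ones.

The simulator uses the EMU decomposition: walking backwards from the
measured fragments it collects the minimal set of metabolite carbon subsets
whose mass distributions determine the measurements.  Within one EMU size
the steady-state balances are **linear** once all smaller sizes are solved
(condensations contribute convolutions of smaller-size solutions), so the
per-size systems are solved exactly by LU factorization in increasing size
order.  This replaces a generic nonlinear root-finder with a direct method;
the fixed point is identical.  An EMU whose total flux-weighted inflow is
zero has undefined labeling; this is reported as an error naming the EMU
rather than regularized (during global search such points simply score the
failure penalty).

Metabolite pools too large to reach isotopic steady state within the
experiment (glycogen, external media pools, fatty acids) are accommodated
by a virtual dilution reaction: a net-zero flux variable `d` that injects
unlabeled (m0) material and drains the pool at the same rate, so the
effective distribution is the produced one mixed with m0 in ratio
production : d.  Because `d` enters the parsimony objective, the second
stage finds solutions needing the minimum correction.

A brute-force positional-isotopomer solver (one unknown per isotopomer,
2ⁿ per n-carbon metabolite; fixed-point iteration with an `fsolve` polish)
serves as an independent oracle.  It shares only the atom-transition
parser with the EMU path and is guarded to ~2¹⁶ unknowns.  Both methods
assume statistical independence of substrate labeling in condensations,
the standard assumption of isotopomer balancing.

Natural ¹³C abundance is assumed to be already corrected in the input
measurements; unlabeled inputs are pure m0.  Carbon indices are 1-based.

## Objectives and weights

The fit objective is the variance-weighted sum of squared residuals
`X = Σ_j ((E_j − Y_j)/σ_j)²`; σ_j must be strictly positive (no clamping
floor is applied — an input with σ = 0 is rejected).  The tolerance `T`
bounding the stage-2 region is the upper χ² quantile at the chosen
confidence (default 0.95) with 1 degree of freedom, giving `T = 3.84`.

Expression weights follow `w_i = 1 + max(Th − ge_i, 0)`.  GPR rules are
evaluated with AND → min (a complex is limited by its scarcest subunit) and
OR → max (isoenzymes add capacity).  Reactions without annotation get
weight 1.  The default threshold `Th` is the maximum expression among genes
mapped to the network, which maximizes the information extracted from the
expression data; any percentile can be requested instead.

## Optimization

The decision vector stacks the free fluxes — null-space coordinates of `S`,
chosen by QR column pivoting so each coordinate *is* one reaction's flux,
with box bounds from flux-variability analysis — and the turnover
variables (default upper bound: the larger of |lb|, |ub| of the reaction).

Both stages use a self-adaptive differential evolution (rand/1/bin with
jDE-style per-individual F/CR adaptation) on a ring of islands with
migration of the island best.  Default settings are 7 islands × 60
individuals with migration every 400 generations; the tests and the
acceptance script use desk-scale budgets (2 islands × 16–20, migration
every 50, ≤ 300 generations), which are ample for the bundled fixtures
(decision dimension ≤ 3).  Termination is max-generations or a
500-generation stall (100 at desk scale); the firing criterion is recorded
in the result.  The evolutionary best is refined by a bounded Nelder–Mead
polish.  Every stochastic operation takes an explicit seed (default 1) and
runs are bit-reproducible given (seed, settings).

Initial populations sample free fluxes with a hit-and-run walk over the
flux polytope, started from the mean of the FVA vertex solutions (interior
by convexity).  Directions are drawn from the null space of the
equality-constrained rows (`lb_j = ub_j`, e.g. measured exchange rates), as
unconstrained directions would almost surely violate those equalities.
Turnover variables are sampled uniformly within bounds.

The stage-2 χ² constraint is enforced by an exterior penalty
`ρ·max(0, X − X_opt − T)` with ρ = 10⁴ by default, escalating tenfold on
violation at restart (up to 3 restarts, warm-started from the best point
so far; the stage-1 solution is injected into the initial population and is
always feasible).  Solutions violating the constraint by more than 10⁻⁶
are flagged non-converged.  Inside the search, steady-state vectors outside
the flux bounds score a graded penalty (10⁶·(1+violation)) and failed
labeling simulations a large finite penalty (10¹²).

Confidence intervals solve the same constrained problem with `±v_i` as
objective, independently per reaction and warm-started from the stage-1
(and, where available, stage-2) solutions.  Reported intervals are **inner
approximations** — best feasible points found — because evolutionary search
cannot certify outer bounds; convergence flags and achieved-SSR
certificates are attached to every bound.

The linear problems (FVA, pFBA, GIMME) are solved exactly as LPs over split
forward/reverse variables with HiGHS; `Σ w_i|v_i|` is linear in the split
variables, and degenerate optima are resolved to an arbitrary optimal
vertex (the objective value, not the vertex, is the contract).

## Synthetic fixtures: what they do and do not show

The five seeded fixtures emulate the canonical situations of the method:
condensation of labeled precursors, label-indistinguishable parallel
routes, an unforced futile cycle, reversible exchange with an unlabeled
pool (turnover identifiability), and an oxidative-vs-rearrangement route
split to a pentose probed by a 50% [1,2-¹³C₂] hexose tracer.  Measurement
standard deviations default to 0.01, a typical GC-MS isotopologue
precision; measurements are noise-free by default (seeded Gaussian noise
optional), and the route split in the pentose fixture is 40:60
oxidative:non-oxidative.

These toys have ≤ 12 metabolites, ≤ 6 carbons and ≤ 3 decision dimensions.
Passing tests therefore demonstrate correctness of the balance equations,
the decomposition, the two-stage logic and the interval geometry — not
performance or identifiability on genome-scale networks, where the
nonconvex landscape is far harder and evolutionary budgets dominate the
cost.  Real-data concerns deliberately out of scope: natural-abundance
correction, measurement-fragment overlap, non-stationary labeling, and
expression normalization (a normalized table is taken as input).

## Numerical choices

- Null space via SVD with singular-value cutoff 10⁻¹⁰·σ_max.
- Steady-state feasibility contract of every returned flux vector:
  `‖S·v‖∞ ≤ 10⁻⁶·max(1, ‖v‖∞)` and bounds respected to 10⁻⁶.
- EMU transitions with flux below 10⁻¹² are dropped from the balance of a
  given evaluation (they would otherwise create spurious structural
  singularities at vertices with inactive reverse fluxes).
- Isotopologue vectors are renormalized after each linear solve and must
  sum to 1 within 10⁻⁹.
- Oracle agreement tolerance: 10⁻⁸ per fraction.
- LP/FVA ties broken by the solver; determined fluxes may return
  vmin > vmax by ≤ solver tolerance and are swapped.

## Known limitations

- No gradient-based fitting (EMU adjoints); global search only, so
  confidence intervals are exploratory at small budgets.
- No tandem-MS fragments, no ¹⁵N/²H tracers, no time-course (non-stationary)
  analysis, no thermodynamic (ΔG) constraint generation, no loopless FVA.
- The island model runs serially in one process; no cluster parallelism.
- SBML reading requires carbon counts derivable from metabolite formulas.
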