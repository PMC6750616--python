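"""Global optimization of the 13C MFA and parsimonious-stage problems.

The decision vector stacks the free fluxes (null-space coordinates, bounded
by their flux-variability intervals) and the turnover variables of
reversible reactions.  Both stages are solved with a self-adaptive
differential evolution (jDE-style per-individual F/CR adaptation) run on an
island topology with ring migration, followed by a bounded Nelder-Mead
polish of the best individual.  The chi2-tolerance constraint of the second
stage is enforced by an exterior penalty whose coefficient escalates
tenfold on violation at restart.

Failed labeling simulations (singular EMU balances) score a large finite
penalty; steady-state vectors outside the flux bounds score a graded
penalty so the search is pulled back onto the polytope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg
from scipy.optimize import minimize

from .emu import (
    EMUSystem,
    PoolDilution,
    SingularLabelingError,
    TracerSpec,
    decompose_to_emu,
    simulate_labeling,
)
from .atommap import AtomTransition, validate_transitions
from .network import (
    FluxVector,
    MetabolicNetwork,
    NullSpaceParameterization,
    flux_variability,
    null_space,
)
from .objectives import (
    LabelingMeasurement,
    ToleranceConfig,
    ssr_objective,
    weighted_flux_sum,
)

__all__ = [
    "ProblemSpec",
    "OptimizerSettings",
    "OptimizationResult",
    "parse_fragment",
    "sample_initial_population",
    "fit_13c_mfa",
    "fit_p13cmfa",
]

SIM_FAILURE_PENALTY = 1e12
BOUND_PENALTY = 1e6


def parse_fragment(net: MetabolicNetwork, frag_id: str) -> tuple[str, tuple[int, ...]]:
    """Fragment id dialect: ``"met"`` (all carbons) or ``"met@1,2,3"``."""
    if "@" in frag_id:
        mid, atoms_s = frag_id.split("@", 1)
        atoms = tuple(sorted(int(a) for a in atoms_s.split(",")))
    else:
        mid, atoms = frag_id, ()
    if mid not in net.met_index:
        raise ValueError(f"fragment {frag_id!r}: unknown metabolite {mid!r}")
    if not atoms:
        atoms = tuple(range(1, net.metabolite(mid).n_carbons + 1))
    return mid, atoms


@dataclass
class OptimizerSettings:
    """Island-model SADE settings (defaults mirror desk-scale usage of
    7 islands x 60 individuals with migration every 400 generations)."""

    n_islands: int = 7
    pop_size: int = 60
    migration_every: int = 400
    max_generations: int = 2000
    stall_generations: int = 500
    seed: int = 1
    penalty_rho: float = 1e4
    polish: bool = True

    def __post_init__(self) -> None:
        for name in (
            "n_islands",
            "pop_size",
            "migration_every",
            "max_generations",
            "stall_generations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class OptimizationResult:
    objective: float
    ssr: float
    x: np.ndarray
    flux: FluxVector
    trace: list[float]
    settings: OptimizerSettings
    converged: bool
    termination: str
    n_evaluations: int
    constraint_violation: float = 0.0

    @property
    def X_opt(self) -> float:
        return self.ssr


class ProblemSpec:
    """A fully assembled 13C MFA problem.

    Bundles the network, atom transitions, tracer, measurements and the
    decision-vector parameterization (free fluxes + turnover variables).
    """

    def __init__(
        self,
        net: MetabolicNetwork,
        transitions: list[AtomTransition],
        tracers: list[TracerSpec],
        measurements: list[LabelingMeasurement],
        weights: np.ndarray | None = None,
        tolerance: ToleranceConfig | None = None,
        dilutions: list[PoolDilution] | None = None,
        turnover_ub: float | None = None,
    ):
        self.net = net
        self.transitions = transitions
        self.tracers = tracers
        self.measurements = measurements
        self.weights = None if weights is None else np.asarray(weights, float)
        self.tolerance = tolerance or ToleranceConfig()
        self.dilutions = list(dilutions or [])
        validate_transitions(net, transitions)

        frag_ids = sorted({m.fragment_id for m in measurements})
        targets = {f: parse_fragment(net, f) for f in frag_ids}
        tracer_mets = {t.metabolite for t in tracers}
        self.emu_system: EMUSystem = decompose_to_emu(
            net, transitions, targets, extra_inputs=tracer_mets
        )

        self.parameterization: NullSpaceParameterization = null_space(net)
        p = self.parameterization
        fva = {
            fr.reaction_id: fr
            for fr in flux_variability(net, p.free_flux_ids)
        }
        self.free_bounds = np.array(
            [[fva[rid].vmin, fva[rid].vmax] for rid in p.free_flux_ids]
        ).reshape(-1, 2)
        self.reversible_ids = net.reversible_ids()
        if turnover_ub is None:
            caps = [
                max(abs(net.reaction(rid).lb), abs(net.reaction(rid).ub))
                for rid in self.reversible_ids
            ]
        else:
            caps = [turnover_ub] * len(self.reversible_ids)
        self.turnover_bounds = np.array([[0.0, c] for c in caps]).reshape(-1, 2)
        self.bounds = np.vstack([self.free_bounds, self.turnover_bounds])
        self.n_free = len(p.free_flux_ids)
        self.dim = self.bounds.shape[0]
        self._rev_idx = [net.rxn_index[rid] for rid in self.reversible_ids]

    # -- decision-vector plumbing -------------------------------------------------

    def decode(self, x: np.ndarray) -> FluxVector:
        """Map a decision vector to a steady-state FluxVector."""
        x = np.asarray(x, dtype=float)
        f, tvars = x[: self.n_free], x[self.n_free :]
        p = self.parameterization
        v = p.basis @ f if self.n_free else np.zeros(len(self.net.reactions))
        t = np.zeros_like(v)
        t[self._rev_idx] = np.maximum(tvars, 0.0)
        return FluxVector(p.reaction_ids, v, t)

    def encode(self, flux: FluxVector) -> np.ndarray:
        """Free coordinates + turnover values of a flux vector."""
        fidx = [self.net.rxn_index[rid] for rid in self.parameterization.free_flux_ids]
        return np.concatenate([flux.v[fidx], flux.t[self._rev_idx]])

    def bound_violation(self, flux: FluxVector) -> float:
        lb, ub = self.net.lb, self.net.ub
        return float(
            np.sum(np.maximum(lb - flux.v, 0.0)) + np.sum(np.maximum(flux.v - ub, 0.0))
        )

    def simulate(self, flux: FluxVector):
        return simulate_labeling(
            self.emu_system, flux, self.tracers, self.dilutions
        )

    def ssr(self, x: np.ndarray) -> tuple[float, FluxVector]:
        """Penalized SSR at a decision vector (penalties >= 1e6 flag
        infeasibility or simulation failure)."""
        flux = self.decode(x)
        viol = self.bound_violation(flux)
        if viol > 1e-9:
            return BOUND_PENALTY * (1.0 + viol), flux
        try:
            sim = self.simulate(flux)
        except SingularLabelingError:
            return SIM_FAILURE_PENALTY, flux
        return ssr_objective(sim, self.measurements), flux

    def parsimony(self, flux: FluxVector) -> float:
        return weighted_flux_sum(flux, self.weights)


# -- sampling -------------------------------------------------------------------


def _interior_point(spec: ProblemSpec) -> np.ndarray:
    """Average of the FVA vertices of the free fluxes: feasible by convexity
    and interior along every undetermined direction."""
    from scipy.optimize import linprog

    net = spec.net
    n = len(net.reactions)
    pts = []
    for rid in spec.parameterization.free_flux_ids:
        j = net.rxn_index[rid]
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = linprog(
                c,
                A_eq=net.S if net.S.size else None,
                b_eq=np.zeros(net.S.shape[0]) if net.S.size else None,
                bounds=list(zip(net.lb, net.ub)),
                method="highs",
            )
            if res.success:
                pts.append(res.x)
    if not pts:
        raise RuntimeError("could not find a feasible interior point")
    v0 = np.mean(pts, axis=0)
    fidx = [net.rxn_index[r] for r in spec.parameterization.free_flux_ids]
    return v0[fidx]


def sample_free_fluxes(
    spec: ProblemSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Hit-and-run walk over the free-flux polytope {f : lb <= N f <= ub}."""
    d = spec.n_free
    if d == 0:
        return np.zeros((n, 0))
    N = spec.parameterization.basis
    lb, ub = spec.net.lb, spec.net.ub
    f = _interior_point(spec)
    # directions must respect equality rows (lb_j == ub_j): sample from the
    # null space of those rows of N, else every step interval is degenerate
    eq_rows = (ub - lb) < 1e-9
    if eq_rows.any():
        E = N[eq_rows, :]
        Q = scipy.linalg.null_space(E)
        if Q.shape[1] == 0:
            return np.tile(f, (n, 1))
    else:
        Q = np.eye(d)
    samples = []
    burn, thin = 20, 3
    step = 0
    attempts = 0
    max_attempts = 200 * (burn + thin * n)
    while len(samples) < n:
        attempts += 1
        if attempts > max_attempts:  # point-like polytope in practice
            return np.tile(f, (n, 1))
        u = Q @ rng.standard_normal(Q.shape[1])
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            continue
        u /= nu
        w = N @ u
        base = N @ f
        tlo, thi = -np.inf, np.inf
        for j in range(w.size):
            if abs(w[j]) < 1e-12:
                continue
            a = (lb[j] - base[j]) / w[j]
            b = (ub[j] - base[j]) / w[j]
            lo, hi = min(a, b), max(a, b)
            tlo, thi = max(tlo, lo), min(thi, hi)
        if not np.isfinite(tlo) or not np.isfinite(thi) or thi - tlo < 1e-12:
            continue
        f = f + u * rng.uniform(tlo, thi)
        step += 1
        if step > burn and step % thin == 0:
            samples.append(f.copy())
    return np.array(samples[:n])


def sample_initial_population(
    spec: ProblemSpec, n: int, seed: int
) -> np.ndarray:
    """n decision vectors: free fluxes from a hit-and-run polytope walk,
    turnover variables uniform within bounds.  Deterministic given seed."""
    rng = np.random.default_rng(seed)
    free = sample_free_fluxes(spec, n, rng)
    k = spec.dim - spec.n_free
    if k:
        t = rng.uniform(
            spec.turnover_bounds[:, 0], spec.turnover_bounds[:, 1], size=(n, k)
        )
        return np.hstack([free, t])
    return free


# -- SADE islands ---------------------------------------------------------------


def _sade_islands(
    objective,
    bounds: np.ndarray,
    settings: OptimizerSettings,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float], str, int]:
    """Self-adaptive DE (rand/1/bin, jDE F/CR adaptation) on a ring of islands."""
    rng = np.random.default_rng(settings.seed)
    d = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    if d == 0:
        x = np.zeros(0)
        fx = objective(x)
        return x, fx, [fx], "zero-dimensional", 1

    n_isl, npop = settings.n_islands, max(settings.pop_size, 5)
    pops, fits, Fs, CRs = [], [], [], []
    total = n_isl * npop
    if init is not None and len(init):
        seedpop = np.clip(np.asarray(init, float), lo, hi)
    else:
        seedpop = np.empty((0, d))
    extra = total - len(seedpop)
    if extra > 0:
        rand = rng.uniform(lo, hi, size=(extra, d))
        allpop = np.vstack([seedpop, rand])
    else:
        allpop = seedpop[:total]
    n_eval = 0
    for i in range(n_isl):
        pop = allpop[i * npop : (i + 1) * npop].copy()
        fit = np.array([objective(x) for x in pop])
        n_eval += npop
        pops.append(pop)
        fits.append(fit)
        Fs.append(rng.uniform(0.4, 0.9, npop))
        CRs.append(rng.uniform(0.1, 0.9, npop))

    best_idx = int(np.argmin([f.min() for f in fits]))
    best_x = pops[best_idx][int(np.argmin(fits[best_idx]))].copy()
    best_f = float(min(f.min() for f in fits))
    trace = [best_f]
    stall = 0
    termination = "max_generations"
    for gen in range(1, settings.max_generations + 1):
        for k in range(n_isl):
            pop, fit = pops[k], fits[k]
            for i in range(npop):
                F, CR = Fs[k][i], CRs[k][i]
                if rng.random() < 0.1:
                    F = Fs[k][i] = 0.1 + 0.9 * rng.random()
                if rng.random() < 0.1:
                    CR = CRs[k][i] = rng.random()
                r = rng.choice(npop, 3, replace=False)
                while i in r:
                    r = rng.choice(npop, 3, replace=False)
                mutant = pop[r[0]] + F * (pop[r[1]] - pop[r[2]])
                cross = rng.random(d) < CR
                cross[rng.integers(d)] = True
                trial = np.where(cross, mutant, pop[i])
                trial = np.clip(trial, lo, hi)
                ft = objective(trial)
                n_eval += 1
                if ft <= fit[i]:
                    pop[i], fit[i] = trial, ft
        gen_best = float(min(f.min() for f in fits))
        if gen_best < best_f - 1e-12:
            best_f = gen_best
            k = int(np.argmin([f.min() for f in fits]))
            best_x = pops[k][int(np.argmin(fits[k]))].copy()
            stall = 0
        else:
            stall += 1
        trace.append(best_f)
        if stall >= settings.stall_generations:
            termination = "stall"
            break
        if n_isl > 1 and gen % settings.migration_every == 0:
            for k in range(n_isl):
                src = pops[k][int(np.argmin(fits[k]))].copy()
                src_f = float(fits[k].min())
                nxt = (k + 1) % n_isl
                worst = int(np.argmax(fits[nxt]))
                if src_f < fits[nxt][worst]:
                    pops[nxt][worst] = src
                    fits[nxt][worst] = src_f
    return best_x, best_f, trace, termination, n_eval


def _polish(objective, x0: np.ndarray, bounds: np.ndarray) -> tuple[np.ndarray, float, int]:
    d = x0.size
    if d == 0:
        return x0, objective(x0), 1
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=list(map(tuple, bounds)),
        options={"maxfev": 400 * d, "xatol": 1e-10, "fatol": 1e-12},
    )
    return res.x, float(res.fun), int(res.nfev)


def _run(
    objective, spec: ProblemSpec, settings: OptimizerSettings,
    extra_seeds: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float], str, int]:
    n_init = settings.n_islands * max(settings.pop_size, 5)
    try:
        init = sample_initial_population(spec, n_init, settings.seed)
    except RuntimeError:
        init = None
    if extra_seeds is not None and init is not None and len(extra_seeds):
        init = np.vstack([np.asarray(extra_seeds, float).reshape(-1, spec.dim), init])
    x, fx, trace, term, n_eval = _sade_islands(objective, spec.bounds, settings, init)
    if settings.polish:
        xp, fp, ne = _polish(objective, x, spec.bounds)
        n_eval += ne
        if fp <= fx:
            x, fx = xp, fp
            trace.append(fp)
    return x, fx, trace, term, n_eval


def fit_13c_mfa(
    spec: ProblemSpec, settings: OptimizerSettings | None = None
) -> OptimizationResult:
    """Stage 1: minimize the 13C MFA sum-of-squared-residuals objective."""
    settings = settings or OptimizerSettings()

    def objective(x: np.ndarray) -> float:
        ssr, _ = spec.ssr(x)
        return ssr

    x, fx, trace, term, n_eval = _run(objective, spec, settings)
    ssr, flux = spec.ssr(x)
    return OptimizationResult(
        objective=fx,
        ssr=ssr,
        x=x,
        flux=flux,
        trace=trace,
        settings=settings,
        converged=ssr < BOUND_PENALTY,
        termination=term,
        n_evaluations=n_eval,
    )


def fit_p13cmfa(
    spec: ProblemSpec,
    X_opt: float,
    settings: OptimizerSettings | None = None,
    warm_start: np.ndarray | None = None,
    max_restarts: int = 3,
) -> OptimizationResult:
    """Stage 2: minimize the weighted flux sum inside the chi2-tolerance
    region SSR <= X_opt + T (exterior penalty, rho escalates on restart)."""
    settings = settings or OptimizerSettings()
    bound = X_opt + spec.tolerance.T
    rho = settings.penalty_rho

    best = None
    for attempt in range(max_restarts):
        rho_now = rho * (10.0**attempt)

        def objective(x: np.ndarray, _rho=rho_now) -> float:
            ssr, flux = spec.ssr(x)
            if ssr >= BOUND_PENALTY:
                return ssr
            return spec.parsimony(flux) + _rho * max(0.0, ssr - bound)

        seeds = warm_start
        if best is not None:
            seeds = best.x.reshape(1, -1)
        run_settings = replace(settings, seed=settings.seed + attempt)
        x, fx, trace, term, n_eval = _run(objective, spec, run_settings, seeds)
        ssr, flux = spec.ssr(x)
        viol = max(0.0, ssr - bound)
        result = OptimizationResult(
            objective=spec.parsimony(flux),
            ssr=ssr,
            x=x,
            flux=flux,
            trace=trace,
            settings=run_settings,
            converged=viol <= 1e-6,
            termination=term,
            n_evaluations=n_eval,
            constraint_violation=viol,
        )
        if best is None or (
            result.converged and (not best.converged or result.objective < best.objective)
        ):
            best = result
        if result.converged:
            break
    return best
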