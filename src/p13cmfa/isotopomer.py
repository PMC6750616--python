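"""Full positional-isotopomer steady-state solver.

Independent reference for the EMU simulator: one unknown per positional
isotopomer (2**n per n-carbon metabolite), balance equations built from the
same atom transitions, solved by fixed-point iteration with an ``fsolve``
polish.  Condensations assume statistical independence of the substrates'
isotopomer distributions, as in the EMU framework.

For each producing reaction instance the contribution to a product
isotopomer pattern factorizes over substrate occurrences; each factor is a
marginal probability expressed as a precomputed 0/1 consistency matrix
applied to the substrate's isotopomer vector.

Only tractable for toy networks (guarded at ~2**16 total isotopomers).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import fsolve

from .atommap import AtomTransition
from .emu import PoolDilution, TracerSpec, IsotopologueVector
from .emu import _production_instances
from .network import FluxVector, MetabolicNetwork

__all__ = ["brute_force_isotopomer", "fragment_mass_distribution"]

_MAX_ISOTOPOMERS = 2**16


def _consistency_matrix(
    n_prod: int, n_sub: int, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """M[p, iso] = 1 iff substrate isotopomer ``iso`` carries, at each mapped
    1-based position, the bit that product pattern ``p`` requires."""
    M = np.ones((2**n_prod, 2**n_sub))
    for p in range(2**n_prod):
        for iso in range(2**n_sub):
            for spos, ppos in pairs:
                if ((iso >> (spos - 1)) & 1) != ((p >> (ppos - 1)) & 1):
                    M[p, iso] = 0.0
                    break
    return M


def brute_force_isotopomer(
    net: MetabolicNetwork,
    transitions: list[AtomTransition],
    flux: FluxVector,
    tracers: list[TracerSpec],
    dilutions: list[PoolDilution] | None = None,
    extra_inputs: set[str] | frozenset[str] = frozenset(),
    tol: float = 1e-13,
    max_iter: int = 10000,
) -> dict[str, np.ndarray]:
    """Steady-state positional-isotopomer distributions of all internal
    carbon-carrying metabolites.

    Returns metabolite id -> vector of length ``2**n_carbons`` (bit i set
    means carbon i+1 is 13C).
    """
    inputs = {m.id for m in net.metabolites if m.is_boundary} | set(extra_inputs)
    tracer_by_met = {t.metabolite: t for t in tracers}
    dil_by_met = {d.metabolite: d.reaction_id for d in (dilutions or [])}
    carbon_mets = [
        m for m in net.metabolites if m.n_carbons > 0 and m.id not in inputs
    ]
    if sum(2**m.n_carbons for m in carbon_mets) > _MAX_ISOTOPOMERS:
        raise ValueError("isotopomer system too large for the brute-force oracle")

    n_carb = {m.id: m.n_carbons for m in net.metabolites}
    known: dict[str, np.ndarray] = {}
    for m in net.metabolites:
        if m.id in inputs and m.n_carbons > 0:
            spec = tracer_by_met.get(m.id)
            if spec is None:
                d = np.zeros(2**m.n_carbons)
                d[0] = 1.0
            else:
                d = spec.isotopomer_distribution(m.n_carbons)
            known[m.id] = d

    vf, vr = flux.vf, flux.vr
    ridx = {rid: i for i, rid in enumerate(flux.reaction_ids)}

    # per metabolite: (flux, [(sub_id, consistency matrix), ...]) per producer
    producers: dict[str, list[tuple[float, list[tuple[str, np.ndarray]]]]] = {
        m.id: [] for m in carbon_mets
    }
    for tr, direction in _production_instances(net, transitions):
        f = tr.weight * (
            vf[ridx[tr.reaction_id]] if direction == "f" else vr[ridx[tr.reaction_id]]
        )
        if f <= 1e-12:
            continue
        for occ, (mid, _) in enumerate(tr.products):
            if mid not in producers:
                continue
            nC = n_carb[mid]
            maps: dict[int, list[tuple[int, int]]] = {}
            for a in range(1, nC + 1):
                si, spos = tr.source_of(occ, a)
                maps.setdefault(si, []).append((spos, a))
            factors = [
                (
                    tr.substrates[si][0],
                    _consistency_matrix(nC, n_carb[tr.substrates[si][0]], pairs),
                )
                for si, pairs in maps.items()
            ]
            producers[mid].append((f, factors))

    order = [m.id for m in carbon_mets]
    state = {
        m.id: np.full(2**m.n_carbons, 1.0 / 2**m.n_carbons) for m in carbon_mets
    }

    def inflow(mid: str, pool: dict[str, np.ndarray]) -> tuple[np.ndarray, float]:
        acc = np.zeros(2 ** n_carb[mid])
        total = 0.0
        for f, factors in producers[mid]:
            total += f
            term = np.full(acc.size, f)
            for sub, M in factors:
                x = known[sub] if sub in known else pool[sub]
                term = term * (M @ x)
            acc += term
        d = 0.0
        if mid in dil_by_met:
            d = max(float(flux.v[ridx[dil_by_met[mid]]]), 0.0)
            acc[0] += d
        if total + d <= 1e-12:
            raise ValueError(f"metabolite {mid} has zero inflow in the oracle")
        return acc, total + d

    converged = False
    for _ in range(max_iter):
        delta = 0.0
        for mid in order:
            acc, D = inflow(mid, state)
            new = acc / D
            delta = max(delta, float(np.max(np.abs(new - state[mid]))))
            state[mid] = new
        if delta < tol:
            converged = True
            break

    if not converged:
        sizes = [2 ** n_carb[mid] for mid in order]
        offsets = np.cumsum([0] + sizes)

        def unpack(x: np.ndarray) -> dict[str, np.ndarray]:
            return {mid: x[offsets[i] : offsets[i + 1]] for i, mid in enumerate(order)}

        def residual(x: np.ndarray) -> np.ndarray:
            pool = unpack(x)
            res = np.empty_like(x)
            for i, mid in enumerate(order):
                acc, D = inflow(mid, pool)
                res[offsets[i] : offsets[i + 1]] = D * pool[mid] - acc
            return res

        x0 = np.concatenate([state[mid] for mid in order])
        sol, info, ier, _msg = fsolve(residual, x0, full_output=True, xtol=1e-13)
        if ier == 1 and np.max(np.abs(info["fvec"])) < 1e-9:
            state = unpack(sol)
    return {mid: np.asarray(state[mid]) for mid in order} | {
        mid: known[mid] for mid in known
    }


def fragment_mass_distribution(
    iso: np.ndarray, n_carbons: int, atoms: tuple[int, ...] | None = None
) -> IsotopologueVector:
    """Marginalize a positional-isotopomer vector to a fragment's mass
    distribution (atoms are 1-based; default: the whole molecule)."""
    if atoms is None:
        atoms = tuple(range(1, n_carbons + 1))
    out = np.zeros(len(atoms) + 1)
    for i, prob in enumerate(iso):
        mass = sum((i >> (a - 1)) & 1 for a in atoms)
        out[mass] += prob
    return IsotopologueVector("fragment", out)
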