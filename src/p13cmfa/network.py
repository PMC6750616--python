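"""Constraint-based metabolic network core.

Stoichiometric network representation, forward/reverse splitting of
reversible reactions via turnover variables, null-space parameterization of
the steady-state flux space, flux variability analysis and weighted
flux-minimization linear programs (pFBA / GIMME).

All linear programs are solved over split forward/reverse variables so that
the absolute-value objective ``sum w_i |v_i|`` is exactly linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxVector",
    "NullSpaceParameterization",
    "FluxRange",
    "build_network",
    "split_reversible",
    "null_space",
    "flux_from_free",
    "flux_variability",
    "minimize_weighted_flux_lp",
    "InfeasibleNetworkError",
]

#: default unit label carried as metadata only (no conversion is performed)
FLUX_UNITS = "umol/h/million-cells"


class InfeasibleNetworkError(RuntimeError):
    """Raised when the constraint set {S.v = 0, lb <= v <= ub} is empty."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    n_carbons: int = 0
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise ValueError(f"metabolite {self.id}: n_carbons must be >= 0")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float = 0.0
    ub: float = 1000.0
    gpr: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"reaction {self.id}: lb ({self.lb}) > ub ({self.ub})")

    @property
    def reversible(self) -> bool:
        return self.lb < 0


class MetabolicNetwork:
    """Stoichiometric model: metabolites, reactions and balance matrix S.

    Rows of ``S`` correspond to non-boundary metabolites only; boundary
    metabolites (external pools) are excluded from mass balance.
    """

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction]):
        ids = [m.id for m in metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite id(s): {dup}")
        rids = [r.id for r in reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ValueError(f"duplicate reaction id(s): {dup}")
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self.rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        known = set(self.met_index)
        for r in reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValueError(
                    f"reaction {r.id} references unknown metabolite(s): {sorted(missing)}"
                )
        self.balanced = [m for m in self.metabolites if not m.is_boundary]
        self._bal_index = {m.id: i for i, m in enumerate(self.balanced)}
        S = np.zeros((len(self.balanced), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coef in r.stoichiometry.items():
                i = self._bal_index.get(mid)
                if i is not None:
                    S[i, j] += coef
        self.S = S

    @property
    def lb(self) -> np.ndarray:
        return np.array([r.lb for r in self.reactions], dtype=float)

    @property
    def ub(self) -> np.ndarray:
        return np.array([r.ub for r in self.reactions], dtype=float)

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.rxn_index[rid]]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self.met_index[mid]]

    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.reversible]

    def copy(self) -> "MetabolicNetwork":
        mets = [Metabolite(**vars(m)) for m in self.metabolites]
        rxns = [
            Reaction(r.id, dict(r.stoichiometry), r.lb, r.ub, r.gpr)
            for r in self.reactions
        ]
        return MetabolicNetwork(mets, rxns)


def build_network(
    metabolites: list[Metabolite], reactions: list[Reaction]
) -> MetabolicNetwork:
    """Assemble a validated :class:`MetabolicNetwork`."""
    return MetabolicNetwork(metabolites, reactions)


@dataclass
class FluxVector:
    """Net fluxes plus turnover variables on reversible reactions.

    ``t`` stores one non-negative turnover flux per reaction (zero and
    ignored for irreversible ones).  Forward and reverse fluxes follow
    ``vf = t + max(v, 0)`` and ``vr = t - min(v, 0)``.
    """

    reaction_ids: list[str]
    v: np.ndarray
    t: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.t is None:
            self.t = np.zeros_like(self.v)
        self.t = np.asarray(self.t, dtype=float)
        if self.v.shape != self.t.shape or len(self.reaction_ids) != self.v.size:
            raise ValueError("flux vector dimension mismatch")
        if np.any(self.t < -1e-12):
            raise ValueError("negative turnover flux")
        self._idx = {rid: i for i, rid in enumerate(self.reaction_ids)}

    @property
    def vf(self) -> np.ndarray:
        return self.t + np.maximum(self.v, 0.0)

    @property
    def vr(self) -> np.ndarray:
        return self.t - np.minimum(self.v, 0.0)

    def __getitem__(self, rid: str) -> float:
        return float(self.v[self._idx[rid]])

    def turnover(self, rid: str) -> float:
        return float(self.t[self._idx[rid]])

    def as_dict(self) -> dict[str, float]:
        return {rid: float(x) for rid, x in zip(self.reaction_ids, self.v)}


def split_reversible(
    net: MetabolicNetwork, flux: FluxVector
) -> tuple[np.ndarray, np.ndarray]:
    """Forward/reverse flux assignment ``vf = t + max(v,0)``, ``vr = t - min(v,0)``."""
    if np.any(flux.t < 0):
        raise ValueError("negative turnover flux")
    return flux.vf, flux.vr


@dataclass
class NullSpaceParameterization:
    """Basis N with S.N = 0 such that the rows of the chosen free fluxes are I.

    Any steady-state flux vector is the product of N with the free-flux
    vector, and conversely the free coordinates of a flux vector are just
    its values on ``free_flux_ids``.
    """

    basis: np.ndarray
    free_flux_ids: list[str]
    reaction_ids: list[str]

    @property
    def dim(self) -> int:
        return self.basis.shape[1]


def null_space(net: MetabolicNetwork, rtol: float = 1e-10) -> NullSpaceParameterization:
    """Null space of S via SVD (singular-value cutoff ``rtol * sigma_max``).

    The raw kernel basis is re-expressed so that each basis column carries a
    unit entry on one "free" reaction; free reactions are picked by QR with
    column pivoting for numerical stability.
    """
    S = net.S
    rids = [r.id for r in net.reactions]
    if S.shape[1] == 0:
        return NullSpaceParameterization(np.zeros((0, 0)), [], rids)
    if S.shape[0] == 0:
        K = np.eye(S.shape[1])
    else:
        K = scipy.linalg.null_space(S, rcond=rtol)
    d = K.shape[1]
    if d == 0:
        return NullSpaceParameterization(np.zeros((len(rids), 0)), [], rids)
    # pick d maximally independent rows of K as free fluxes
    _, _, piv = scipy.linalg.qr(K.T, pivoting=True)
    free_idx = sorted(piv[:d])
    N = K @ np.linalg.inv(K[free_idx, :])
    N[free_idx, :] = np.eye(d)  # exact identity on free rows
    return NullSpaceParameterization(N, [rids[i] for i in free_idx], rids)


def flux_from_free(
    p: NullSpaceParameterization, free: np.ndarray, t: np.ndarray | None = None
) -> FluxVector:
    """Map free-flux values to a full steady-state :class:`FluxVector`."""
    free = np.atleast_1d(np.asarray(free, dtype=float))
    if free.size != p.dim:
        raise ValueError(f"expected {p.dim} free fluxes, got {free.size}")
    v = p.basis @ free if p.dim else np.zeros(len(p.reaction_ids))
    return FluxVector(p.reaction_ids, v, t)


@dataclass
class FluxRange:
    reaction_id: str
    vmin: float
    vmax: float


def _split_bounds(net: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Upper bounds of the forward / reverse split variables."""
    ub_f = np.maximum(net.ub, 0.0)
    ub_r = np.maximum(-net.lb, 0.0)
    return ub_f, ub_r


def _lp(net: MetabolicNetwork, c: np.ndarray) -> np.ndarray:
    """min c.v over the steady-state polytope; returns v or raises."""
    n = len(net.reactions)
    res = linprog(
        c,
        A_eq=net.S if net.S.size else None,
        b_eq=np.zeros(net.S.shape[0]) if net.S.size else None,
        bounds=list(zip(net.lb, net.ub)),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleNetworkError("constraint set {S.v=0, lb<=v<=ub} is infeasible")
    if not res.success:
        raise RuntimeError(f"LP failed: {res.message}")
    return res.x[:n]


def flux_variability(
    net: MetabolicNetwork, reactions: list[str] | None = None
) -> list[FluxRange]:
    """Flux spectrum: per-reaction min and max of v_i over {S.v=0, lb<=v<=ub}."""
    rids = reactions if reactions is not None else [r.id for r in net.reactions]
    n = len(net.reactions)
    out = []
    for rid in rids:
        j = net.rxn_index[rid]
        c = np.zeros(n)
        c[j] = 1.0
        vmin = _lp(net, c)[j]
        c[j] = -1.0
        vmax = _lp(net, c)[j]
        if vmin > vmax:  # numerical jitter on determined fluxes
            vmin, vmax = vmax, vmin
        out.append(FluxRange(rid, float(vmin), float(vmax)))
    return out


def minimize_weighted_flux_lp(
    net: MetabolicNetwork, w: np.ndarray | None = None
) -> tuple[FluxVector, float]:
    """argmin sum_i w_i |v_i| over {S.v=0, lb<=v<=ub} (pFBA when w is uniform).

    Solved as an LP over split variables v = vf - vr with vf, vr >= 0.
    Returns the optimal flux vector and the objective value.
    """
    n = len(net.reactions)
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if w.size != n:
        raise ValueError("weight vector dimension mismatch")
    if np.any(w < 0):
        raise ValueError("minimization weights must be non-negative")
    ub_f, ub_r = _split_bounds(net)
    # variables: [vf (n), vr (n)]
    c = np.concatenate([w, w])
    A_eq = np.hstack([net.S, -net.S]) if net.S.size else None
    b_eq = np.zeros(net.S.shape[0]) if net.S.size else None
    lo_f = np.maximum(net.lb, 0.0)  # irreversible with lb>0 forces forward flux
    lo_r = np.maximum(-net.ub, 0.0)
    bounds = list(zip(lo_f, ub_f)) + list(zip(lo_r, ub_r))
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleNetworkError("constraint set {S.v=0, lb<=v<=ub} is infeasible")
    if not res.success:
        raise RuntimeError(f"LP failed: {res.message}")
    vf, vr = res.x[:n], res.x[n:]
    v = vf - vr
    obj = float(np.sum(w * np.abs(v)))
    return FluxVector([r.id for r in net.reactions], v), obj
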