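"""Elementary Metabolite Unit (EMU) decomposition and label simulation.

An EMU is a specific subset of a metabolite's carbon atoms.  The minimal set
of EMUs needed to simulate the measured fragments is found by walking the
carbon-transition network backwards from the target fragments.  At isotopic
steady state the mass-isotopologue distributions of all EMUs of one size
satisfy a flux-weighted *linear* balance system once all smaller sizes are
known (condensations enter as convolutions of smaller-size solutions), so
the systems are solved sequentially in increasing size order.

Large metabolite pools that have not reached isotopic steady state are
accommodated by a virtual dilution reaction that replaces labeled
isotopologues with unlabeled ones at a minimizable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atommap import AtomTransition, group_variants
from .network import FluxVector, MetabolicNetwork

__all__ = [
    "EMU",
    "EMUTransition",
    "EMUSystem",
    "TracerSpec",
    "IsotopologueVector",
    "PoolDilution",
    "decompose_to_emu",
    "simulate_labeling",
    "add_pool_dilution",
    "SingularLabelingError",
]

DILUTION_PREFIX = "dilution_"


class SingularLabelingError(RuntimeError):
    """An EMU has zero total inflow: its steady-state labeling is undefined."""

    def __init__(self, emu: "EMU"):
        self.emu = emu
        super().__init__(f"EMU {emu} has zero dilution-corrected inflow")


@dataclass(frozen=True, order=True)
class EMU:
    metabolite: str
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.atoms or list(self.atoms) != sorted(set(self.atoms)):
            raise ValueError("EMU atoms must be a non-empty sorted set of indices")
        if self.atoms[0] < 1:
            raise ValueError("carbon indices are 1-based")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:
        return f"{self.metabolite}{{{','.join(map(str, self.atoms))}}}"


@dataclass(frozen=True)
class EMUTransition:
    """Flux-carrying transition: ``sources -> target``.

    ``len(sources) > 1`` marks a condensation (source sizes sum to the
    target size).  ``direction`` selects the forward or reverse flux of the
    carrying reaction; ``weight`` is the variant share for reactions with
    alternative (symmetric) carbon mappings.
    """

    target: EMU
    sources: tuple[EMU, ...]
    reaction_id: str
    direction: str = "f"  # "f" -> vf, "r" -> vr
    weight: float = 1.0

    @property
    def condensation(self) -> bool:
        return len(self.sources) > 1


@dataclass
class TracerSpec:
    """Labeling pattern of an input substrate.

    ``patterns`` maps isotopomer bit-strings (carbon 1 first, '1' = 13C) to
    molar fractions summing to one.
    """

    metabolite: str
    patterns: list[tuple[str, float]]

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.patterns)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"tracer fractions for {self.metabolite} sum to {total}")
        lengths = {len(p) for p, _ in self.patterns}
        if len(lengths) > 1:
            raise ValueError("inconsistent tracer pattern lengths")
        if any(set(p) - {"0", "1"} for p, _ in self.patterns):
            raise ValueError("tracer patterns must be 0/1 strings")

    def emu_distribution(self, emu: EMU) -> np.ndarray:
        """Mass distribution of one of this substrate's EMUs."""
        out = np.zeros(emu.size + 1)
        for pattern, frac in self.patterns:
            mass = sum(pattern[a - 1] == "1" for a in emu.atoms)
            out[mass] += frac
        return out

    def isotopomer_distribution(self, n_carbons: int) -> np.ndarray:
        """Joint positional-isotopomer distribution (length 2**n)."""
        out = np.zeros(2**n_carbons)
        for pattern, frac in self.patterns:
            idx = sum((1 << (i)) for i, ch in enumerate(pattern) if ch == "1")
            out[idx] += frac
        return out


@dataclass
class IsotopologueVector:
    id: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)

    def __getitem__(self, i: int) -> float:
        return float(self.fractions[i])


@dataclass
class PoolDilution:
    """Virtual reaction replacing labeled by unlabeled isotopologues."""

    metabolite: str
    reaction_id: str


@dataclass
class EMUSystem:
    """Size-ordered EMU variables, transitions and input distributions."""

    targets: dict[str, EMU]  # fragment id -> EMU
    emus_by_size: dict[int, list[EMU]]
    transitions: list[EMUTransition]
    input_emus: set[EMU]
    input_metabolites: set[str]

    @property
    def sizes(self) -> list[int]:
        return sorted(self.emus_by_size)

    def all_emus(self) -> list[EMU]:
        return [e for s in self.sizes for e in self.emus_by_size[s]]


def _production_instances(
    net: MetabolicNetwork, transitions: list[AtomTransition]
) -> list[tuple[AtomTransition, str]]:
    """All unidirectional mapping instances: (variant, direction)."""
    out = []
    for rid, variants in group_variants(transitions).items():
        rxn = net.reaction(rid)
        for tr in variants:
            out.append((tr, "f"))
            if rxn.reversible:
                out.append((tr.reverse(), "r"))
    return out


def decompose_to_emu(
    net: MetabolicNetwork,
    transitions: list[AtomTransition],
    target_fragments: dict[str, tuple[str, tuple[int, ...]]],
    extra_inputs: set[str] | frozenset[str] = frozenset(),
) -> EMUSystem:
    """Minimal EMU system reachable backwards from the target fragments.

    Label inputs are boundary metabolites plus ``extra_inputs`` (typically
    tracer substrates); recursion stops there.  Raises if an internal
    metabolite on a backward path has no producing transition.
    """
    inputs = {m.id for m in net.metabolites if m.is_boundary} | set(extra_inputs)
    instances = _production_instances(net, transitions)
    targets = {}
    for frag_id, (mid, atoms) in target_fragments.items():
        met = net.metabolite(mid)
        atoms = tuple(sorted(atoms)) if atoms else tuple(range(1, met.n_carbons + 1))
        if atoms[-1] > met.n_carbons:
            raise ValueError(f"fragment {frag_id}: atom index beyond {mid} carbons")
        targets[frag_id] = EMU(mid, atoms)

    emus: set[EMU] = set()
    etrans: set[EMUTransition] = set()
    input_emus: set[EMU] = set()
    stack = [e for e in targets.values()]
    while stack:
        emu = stack.pop()
        if emu in emus or emu in input_emus:
            continue
        if emu.metabolite in inputs:
            input_emus.add(emu)
            continue
        emus.add(emu)
        produced = False
        for tr, direction in instances:
            for occ, (mid, _letters) in enumerate(tr.products):
                if mid != emu.metabolite:
                    continue
                produced = True
                groups: dict[int, list[int]] = {}
                for a in emu.atoms:
                    si, spos = tr.source_of(occ, a)
                    groups.setdefault(si, []).append(spos)
                sources = tuple(
                    sorted(
                        EMU(tr.substrates[si][0], tuple(sorted(pos)))
                        for si, pos in groups.items()
                    )
                )
                etrans.add(
                    EMUTransition(emu, sources, tr.reaction_id, direction, tr.weight)
                )
                stack.extend(sources)
        if not produced:
            raise ValueError(
                f"metabolite {emu.metabolite} is not an input and has no producing "
                "atom transition"
            )
    by_size: dict[int, list[EMU]] = {}
    for e in sorted(emus):
        by_size.setdefault(e.size, []).append(e)
    return EMUSystem(targets, by_size, sorted(etrans, key=str), input_emus, inputs)


def _input_distribution(
    emu: EMU, tracer_by_met: dict[str, TracerSpec]
) -> np.ndarray:
    spec = tracer_by_met.get(emu.metabolite)
    if spec is None:  # unlabeled input: pure m0
        out = np.zeros(emu.size + 1)
        out[0] = 1.0
        return out
    return spec.emu_distribution(emu)


def simulate_labeling(
    sys: EMUSystem,
    flux: FluxVector,
    tracers: list[TracerSpec],
    dilutions: list[PoolDilution] | None = None,
) -> dict[str, IsotopologueVector]:
    """Steady-state mass-isotopologue distributions of the target fragments.

    Solves, in increasing EMU size, the flux-weighted linear balance system
    of each size; condensations contribute convolutions of already-solved
    smaller-size distributions.
    """
    tracer_by_met = {t.metabolite: t for t in tracers}
    dil_by_met = {d.metabolite: d.reaction_id for d in (dilutions or [])}
    vf, vr = flux.vf, flux.vr
    ridx = {rid: i for i, rid in enumerate(flux.reaction_ids)}

    def trans_flux(tr: EMUTransition) -> float:
        j = ridx[tr.reaction_id]
        base = vf[j] if tr.direction == "f" else vr[j]
        return tr.weight * base

    solved: dict[EMU, np.ndarray] = {}
    for emu in sys.input_emus:
        solved[emu] = _input_distribution(emu, tracer_by_met)

    by_target: dict[EMU, list[EMUTransition]] = {}
    for tr in sys.transitions:
        by_target.setdefault(tr.target, []).append(tr)

    for size in sys.sizes:
        unknowns = sys.emus_by_size[size]
        index = {e: i for i, e in enumerate(unknowns)}
        n = len(unknowns)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for e in unknowns:
            i = index[e]
            inflow = 0.0
            for tr in by_target.get(e, []):
                f = trans_flux(tr)
                if f <= 1e-12:
                    continue
                inflow += f
                if tr.condensation:
                    dist = solved[tr.sources[0]]
                    for src in tr.sources[1:]:
                        dist = np.convolve(dist, solved[src])
                    B[i] += f * dist
                else:
                    src = tr.sources[0]
                    if src in index:
                        A[i, index[src]] -= f
                    else:
                        B[i] += f * solved[src]
            d = 0.0
            if e.metabolite in dil_by_met:
                d = max(float(flux.v[ridx[dil_by_met[e.metabolite]]]), 0.0)
                B[i, 0] += d  # unlabeled inflow from the large pool
            if inflow + d <= 1e-12:
                raise SingularLabelingError(e)
            A[i, i] += inflow + d
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as err:
            raise SingularLabelingError(unknowns[0]) from err
        for e in unknowns:
            x = X[index[e]]
            total = x.sum()
            if not np.isfinite(total) or total <= 0:
                raise SingularLabelingError(e)
            solved[e] = x / total

    out = {}
    for frag_id, emu in sys.targets.items():
        dist = solved[emu] if emu not in sys.input_emus else solved[emu]
        out[frag_id] = IsotopologueVector(frag_id, dist.copy())
    return out


def add_pool_dilution(
    net: MetabolicNetwork, metabolite: str, ub: float = 1000.0
) -> tuple[MetabolicNetwork, PoolDilution]:
    """Add a virtual dilution reaction for a large metabolite pool.

    The reaction carries a non-negative flux d; in the labeling balance it
    injects unlabeled (m0) metabolite at rate d and drains the pool at the
    same rate, so the effective distribution is the produced distribution
    mixed with m0 in ratio production:d.  Mass balance is untouched (the
    reaction is net-zero in S).
    """
    if metabolite not in net.met_index:
        raise ValueError(f"unknown metabolite {metabolite!r}")
    rid = DILUTION_PREFIX + metabolite
    if rid in net.rxn_index:
        raise ValueError(f"metabolite {metabolite} already has a dilution reaction")
    from .network import Reaction  # local import to avoid cycle at module load

    new = net.copy()
    new_rxns = new.reactions + [Reaction(rid, {}, 0.0, ub)]
    out = MetabolicNetwork(new.metabolites, new_rxns)
    return out, PoolDilution(metabolite, rid)
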