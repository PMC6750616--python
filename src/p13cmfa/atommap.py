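"""Carbon atom-transition rules.

Transitions are written as letter-mapped equations, one row per rule, e.g.::

    glc[abcdef] -> gap[cba] + gap[def]

Each letter names one carbon; the multiset of letters must balance between
the two sides and no letter may repeat within a side.  A reaction may carry
several rules (e.g. two equally weighted variants for symmetric metabolites
such as succinate or fumarate); the variants of a reaction share its flux in
equal parts.  For reversible reactions the reverse mapping is the inverse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .network import MetabolicNetwork

__all__ = ["AtomTransition", "parse_transition_equation", "validate_transitions"]

_TERM = re.compile(r"^\s*([A-Za-z0-9_\-]+)\s*\[([A-Za-z]*)\]\s*$")


@dataclass
class AtomTransition:
    """One carbon-mapping variant of a reaction.

    ``substrates`` and ``products`` are occurrence lists ``(metabolite_id,
    letters)``; letters are positional, carbon 1 first.  ``weight`` is the
    share of the reaction flux carried by this variant (1/n_variants).
    """

    reaction_id: str
    substrates: list[tuple[str, str]]
    products: list[tuple[str, str]]
    weight: float = 1.0

    def source_of(self, occ: int, carbon: int) -> tuple[int, int]:
        """Substrate (occurrence index, 1-based carbon) feeding product
        occurrence ``occ`` at 1-based position ``carbon``."""
        letter = self.products[occ][1][carbon - 1]
        for si, (_, letters) in enumerate(self.substrates):
            pos = letters.find(letter)
            if pos >= 0:
                return si, pos + 1
        raise KeyError(f"{self.reaction_id}: no substrate carries carbon '{letter}'")

    def reverse(self) -> "AtomTransition":
        return AtomTransition(
            self.reaction_id, list(self.products), list(self.substrates), self.weight
        )


def _parse_side(side: str, eq: str) -> list[tuple[str, str]]:
    out = []
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        m = _TERM.match(term)
        if not m:
            raise ValueError(f"cannot parse atom-transition term {term!r} in {eq!r}")
        out.append((m.group(1), m.group(2)))
    return out


def parse_transition_equation(reaction_id: str, equation: str) -> AtomTransition:
    """Parse ``"A[ab] + B[c] -> C[abc]"`` into an :class:`AtomTransition`."""
    if "->" not in equation:
        raise ValueError(f"transition equation missing '->': {equation!r}")
    left, right = equation.split("->", 1)
    subs = _parse_side(left, equation)
    prods = _parse_side(right, equation)
    for side, name in ((subs, "substrate"), (prods, "product")):
        letters = "".join(l for _, l in side)
        if len(set(letters)) != len(letters):
            raise ValueError(f"{reaction_id}: repeated carbon letter on {name} side")
    lsub = sorted("".join(l for _, l in subs))
    lprod = sorted("".join(l for _, l in prods))
    if lsub != lprod:
        raise ValueError(
            f"{reaction_id}: carbon letters unbalanced "
            f"({''.join(lsub)!r} vs {''.join(lprod)!r})"
        )
    return AtomTransition(reaction_id, subs, prods)


def group_variants(transitions: list[AtomTransition]) -> dict[str, list[AtomTransition]]:
    """Group transitions by reaction and set equal variant weights."""
    by_rxn: dict[str, list[AtomTransition]] = {}
    for tr in transitions:
        by_rxn.setdefault(tr.reaction_id, []).append(tr)
    for rid, var in by_rxn.items():
        for tr in var:
            tr.weight = 1.0 / len(var)
    return by_rxn


def validate_transitions(
    net: MetabolicNetwork, transitions: list[AtomTransition]
) -> None:
    """Check transitions against the network's metabolites and carbon counts.

    Every mapped metabolite must exist, every occurrence's letter count must
    equal the metabolite's ``n_carbons``, and the occurrences must be
    consistent with the reaction stoichiometry (|coefficient| occurrences on
    the matching side, allowing the sides to be written swapped relative to
    the stoichiometric convention for reversible reactions).
    """
    for tr in transitions:
        if tr.reaction_id not in net.rxn_index:
            raise ValueError(f"transition for unknown reaction {tr.reaction_id!r}")
        rxn = net.reaction(tr.reaction_id)
        counts: dict[str, int] = {}
        for mid, letters in tr.substrates + tr.products:
            if mid not in net.met_index:
                raise ValueError(f"{tr.reaction_id}: unknown metabolite {mid!r}")
            met = net.metabolite(mid)
            if len(letters) != met.n_carbons:
                raise ValueError(
                    f"{tr.reaction_id}: {mid} has {met.n_carbons} carbons but the "
                    f"transition maps {len(letters)}"
                )
            counts[mid] = counts.get(mid, 0) + 1
        for mid, coef in rxn.stoichiometry.items():
            met = net.metabolite(mid)
            if met.n_carbons == 0:
                continue
            expected = int(round(abs(coef)))
            if counts.get(mid, 0) != expected:
                raise ValueError(
                    f"{tr.reaction_id}: metabolite {mid} appears {counts.get(mid, 0)} "
                    f"time(s) in the transition but |stoichiometry| is {expected}"
                )
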