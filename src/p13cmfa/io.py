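"""Readers and writers for the tabular dialects and SBML.

Tabular formats (all plain CSV):

- ``metabolites.csv``: id, name, compartment, n_carbons, boundary
- ``reactions.csv``: id, equation (``"A + 2 B -> C"``), lb, ub, gpr
- ``transitions.csv``: reaction_id, equation (``"glc[abcdef] -> gap[cba] + gap[def]"``)
- ``tracer.csv``: metabolite, pattern (0/1 string, carbon 1 first), fraction
- ``measurements.csv``: fragment_id, m_index, fraction, sd
- ``expression.csv``: gene_id, value

SBML level 3 models (fbc bounds and GPR rules) are read through cobrapy;
carbon counts are taken from metabolite formulas.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .atommap import AtomTransition, parse_transition_equation
from .emu import IsotopologueVector, TracerSpec
from .network import FluxVector, Metabolite, MetabolicNetwork, Reaction, build_network
from .objectives import ExpressionData, LabelingMeasurement

__all__ = [
    "parse_reaction_equation",
    "format_reaction_equation",
    "read_network_csv",
    "write_network_csv",
    "read_transitions_csv",
    "write_transitions_csv",
    "read_tracer_csv",
    "write_tracer_csv",
    "read_measurements_csv",
    "write_measurements_csv",
    "read_expression_csv",
    "write_expression_csv",
    "write_flux_report",
    "read_flux_report",
    "write_labeling_csv",
    "read_sbml_network",
]

_COEF_TERM = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z0-9_\-]+)\s*$")


def parse_reaction_equation(equation: str) -> dict[str, float]:
    """``"A + 2 B -> C"`` to a signed stoichiometry map."""
    if "->" not in equation:
        raise ValueError(f"reaction equation missing '->': {equation!r}")
    left, right = equation.split("->", 1)
    stoich: dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            m = _COEF_TERM.match(term)
            if not m:
                raise ValueError(f"cannot parse term {term!r} in {equation!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            stoich[m.group(2)] = stoich.get(m.group(2), 0.0) + sign * coef

    add(left, -1.0)
    add(right, +1.0)
    return {k: v for k, v in stoich.items() if v != 0.0}


def format_reaction_equation(stoich: dict[str, float]) -> str:
    def side(items):
        parts = []
        for mid, c in items:
            c = abs(c)
            parts.append(mid if c == 1 else f"{c:g} {mid}")
        return " + ".join(parts)

    subs = sorted((m, c) for m, c in stoich.items() if c < 0)
    prods = sorted((m, c) for m, c in stoich.items() if c > 0)
    return f"{side(subs)} -> {side(prods)}"


def read_network_csv(metabolites_path, reactions_path) -> MetabolicNetwork:
    mdf = pd.read_csv(metabolites_path)
    rdf = pd.read_csv(reactions_path)
    mets = [
        Metabolite(
            id=str(row.id),
            name=str(getattr(row, "name_", getattr(row, "name", ""))) or "",
            compartment=str(row.compartment),
            n_carbons=int(row.n_carbons),
            is_boundary=bool(row.boundary),
        )
        for row in mdf.itertuples(index=False)
    ]
    rxns = []
    for row in rdf.itertuples(index=False):
        gpr = "" if pd.isna(row.gpr) else str(row.gpr)
        rxns.append(
            Reaction(
                id=str(row.id),
                stoichiometry=parse_reaction_equation(str(row.equation)),
                lb=float(row.lb),
                ub=float(row.ub),
                gpr=gpr,
            )
        )
    return build_network(mets, rxns)


def write_network_csv(net: MetabolicNetwork, metabolites_path, reactions_path) -> None:
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "n_carbons": m.n_carbons,
                "boundary": m.is_boundary,
            }
            for m in net.metabolites
        ]
    ).to_csv(metabolites_path, index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "equation": format_reaction_equation(r.stoichiometry),
                "lb": r.lb,
                "ub": r.ub,
                "gpr": r.gpr,
            }
            for r in net.reactions
        ]
    ).to_csv(reactions_path, index=False)


def read_transitions_csv(path) -> list[AtomTransition]:
    df = pd.read_csv(path)
    return [
        parse_transition_equation(str(row.reaction_id), str(row.equation))
        for row in df.itertuples(index=False)
    ]


def write_transitions_csv(transitions: list[AtomTransition], path) -> None:
    rows = []
    for tr in transitions:
        eq = (
            " + ".join(f"{m}[{l}]" for m, l in tr.substrates)
            + " -> "
            + " + ".join(f"{m}[{l}]" for m, l in tr.products)
        )
        rows.append({"reaction_id": tr.reaction_id, "equation": eq})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracer_csv(path) -> list[TracerSpec]:
    df = pd.read_csv(path, dtype={"pattern": str})
    specs = []
    for mid, grp in df.groupby("metabolite", sort=True):
        patterns = [
            (str(row.pattern).replace(" ", ""), float(row.fraction))
            for row in grp.itertuples(index=False)
        ]
        specs.append(TracerSpec(str(mid), patterns))
    return specs


def write_tracer_csv(tracers: list[TracerSpec], path) -> None:
    rows = [
        {"metabolite": t.metabolite, "pattern": p, "fraction": f}
        for t in tracers
        for p, f in t.patterns
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_measurements_csv(path) -> list[LabelingMeasurement]:
    df = pd.read_csv(path)
    return [
        LabelingMeasurement(
            str(row.fragment_id), int(row.m_index), float(row.fraction), float(row.sd)
        )
        for row in df.itertuples(index=False)
    ]


def write_measurements_csv(measurements: list[LabelingMeasurement], path) -> None:
    pd.DataFrame(
        [
            {
                "fragment_id": m.fragment_id,
                "m_index": m.m_index,
                "fraction": m.value,
                "sd": m.sd,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)


def read_expression_csv(path) -> ExpressionData:
    df = pd.read_csv(path)
    return ExpressionData(
        {str(row.gene_id): float(row.value) for row in df.itertuples(index=False)}
    )


def write_expression_csv(expr: ExpressionData, path) -> None:
    pd.DataFrame(
        [{"gene_id": g, "value": v} for g, v in sorted(expr.values.items())]
    ).to_csv(path, index=False)


def write_flux_report(
    flux: FluxVector,
    path,
    fva: dict[str, tuple[float, float]] | None = None,
) -> None:
    """CSV with columns reaction_id, v, t, vmin, vmax."""
    rows = []
    for rid in flux.reaction_ids:
        vmin, vmax = (fva or {}).get(rid, (np.nan, np.nan))
        rows.append(
            {
                "reaction_id": rid,
                "v": flux[rid],
                "t": flux.turnover(rid),
                "vmin": vmin,
                "vmax": vmax,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_flux_report(path) -> FluxVector:
    df = pd.read_csv(path)
    return FluxVector(
        [str(r) for r in df["reaction_id"]],
        df["v"].to_numpy(float),
        df["t"].to_numpy(float) if "t" in df else None,
    )


def write_labeling_csv(labeling: dict[str, IsotopologueVector], path) -> None:
    """Wide CSV: fragment, m0..mN (shorter fragments padded with blanks)."""
    nmax = max(v.fractions.size for v in labeling.values())
    rows = []
    for frag, vec in sorted(labeling.items()):
        row: dict[str, object] = {"fragment": frag}
        for i in range(nmax):
            row[f"m{i}"] = vec.fractions[i] if i < vec.fractions.size else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sbml_network(path) -> MetabolicNetwork:
    """Read an SBML L3 (fbc) model via cobrapy.

    Carbon counts come from metabolite formulas; all model metabolites are
    balanced (cobra models open the system through exchange reactions).
    """
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            n_carbons=int((m.elements or {}).get("C", 0)),
            is_boundary=False,
        )
        for m in model.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lb=float(r.lower_bound),
            ub=float(r.upper_bound),
            gpr=str(r.gpr) if r.gpr else "",
        )
        for r in model.reactions
    ]
    return build_network(mets, rxns)
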