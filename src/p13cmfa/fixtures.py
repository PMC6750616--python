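"""Seeded toy fixtures with analytically known flux and labeling solutions.

Each fixture bundles a small network (3-12 metabolites, 1-6 carbons), atom
transitions, a tracer, ground-truth fluxes and measurements generated from
them.  They are the package's synthetic study conditions:

- ``s1fig_condensation``: two mono-carbon precursors condensing into a
  bi-carbon product; 50% m1 inputs give exactly (0.25, 0.50, 0.25).
- ``parallel_routes``: two label-indistinguishable routes between the same
  nodes; the route split is a pure parsimony/expression question.
- ``futile_cycle``: a forced linear throughput plus an unforced cycle whose
  flux labeling cannot see; parsimony must drive it to zero.
- ``reversible_exchange``: a labeled and an unlabeled pool exchanging
  through a reversible reaction; the turnover flux is label-identifiable.
- ``mini_ppp``: an oxidative route (losing carbon 1 as CO2) and a
  rearrangement-style route to a pentose; with a 50% [1,2-13C2] hexose
  tracer the pentose mass distribution pins the route split (truth: 60%
  non-oxidative).

Measurements default to noise-free simulated fractions with sd 0.01, a
typical GC-MS isotopologue precision; ``noise=True`` adds seeded Gaussian
noise of that size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atommap import AtomTransition, parse_transition_equation
from .emu import TracerSpec, decompose_to_emu, simulate_labeling
from .network import FluxVector, Metabolite, MetabolicNetwork, Reaction, build_network
from .objectives import ExpressionData, LabelingMeasurement
from .optimize import parse_fragment

__all__ = ["Fixture", "generate_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "s1fig_condensation",
    "parallel_routes",
    "futile_cycle",
    "reversible_exchange",
    "mini_ppp",
)

DEFAULT_SD = 0.01


@dataclass
class Fixture:
    name: str
    net: MetabolicNetwork
    transitions: list[AtomTransition]
    tracers: list[TracerSpec]
    truth_flux: FluxVector
    measurements: list[LabelingMeasurement]
    fragments: list[str]
    expression: ExpressionData | None
    seed: int
    truth_labeling: dict = field(default_factory=dict)

    def write(self, outdir) -> dict[str, Path]:
        """Write all input files plus ground-truth tables; returns the paths."""
        from . import io as pio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "metabolites": outdir / "metabolites.csv",
            "reactions": outdir / "reactions.csv",
            "transitions": outdir / "transitions.csv",
            "tracer": outdir / "tracer.csv",
            "measurements": outdir / "measurements.csv",
            "truth_flux": outdir / "truth_flux.csv",
            "truth_labeling": outdir / "truth_labeling.csv",
        }
        pio.write_network_csv(self.net, paths["metabolites"], paths["reactions"])
        pio.write_transitions_csv(self.transitions, paths["transitions"])
        pio.write_tracer_csv(self.tracers, paths["tracer"])
        pio.write_measurements_csv(self.measurements, paths["measurements"])
        pio.write_flux_report(self.truth_flux, paths["truth_flux"])
        pio.write_labeling_csv(self.truth_labeling, paths["truth_labeling"])
        if self.expression is not None:
            paths["expression"] = outdir / "expression.csv"
            pio.write_expression_csv(self.expression, paths["expression"])
        return paths


def _tr(rid: str, eq: str) -> AtomTransition:
    return parse_transition_equation(rid, eq)


def _mets(*specs) -> list[Metabolite]:
    return [
        Metabolite(id=i, compartment=c, n_carbons=n, is_boundary=b)
        for i, c, n, b in specs
    ]


def _build_s1fig() -> tuple:
    net = build_network(
        _mets(
            ("Ca_e", "e", 1, True),
            ("Cb_e", "e", 1, True),
            ("Ca", "c", 1, False),
            ("Cb", "c", 1, False),
            ("Cab", "c", 2, False),
            ("Cab_e", "e", 2, True),
        ),
        [
            Reaction("upt_a", {"Ca_e": -1, "Ca": 1}, 1, 1),
            Reaction("upt_b", {"Cb_e": -1, "Cb": 1}, 1, 1),
            Reaction("cond", {"Ca": -1, "Cb": -1, "Cab": 1}, 0, 10),
            Reaction("sink", {"Cab": -1, "Cab_e": 1}, 0, 10),
        ],
    )
    transitions = [
        _tr("upt_a", "Ca_e[a] -> Ca[a]"),
        _tr("upt_b", "Cb_e[a] -> Cb[a]"),
        _tr("cond", "Ca[a] + Cb[b] -> Cab[ab]"),
        _tr("sink", "Cab[ab] -> Cab_e[ab]"),
    ]
    tracers = [
        TracerSpec("Ca_e", [("1", 0.5), ("0", 0.5)]),
        TracerSpec("Cb_e", [("1", 0.5), ("0", 0.5)]),
    ]
    truth = FluxVector(["upt_a", "upt_b", "cond", "sink"], np.ones(4))
    return net, transitions, tracers, truth, ["Cab"], None


def _build_parallel_routes() -> tuple:
    net = build_network(
        _mets(
            ("A_e", "e", 2, True),
            ("A", "c", 2, False),
            ("B", "c", 2, False),
            ("C", "c", 2, False),
            ("B_e", "e", 2, True),
        ),
        [
            Reaction("upt", {"A_e": -1, "A": 1}, 1, 1),
            Reaction("r1", {"A": -1, "B": 1}, 0, 10, gpr="g1"),
            Reaction("r2a", {"A": -1, "C": 1}, 0, 10, gpr="g2"),
            Reaction("r2b", {"C": -1, "B": 1}, 0, 10, gpr="g2"),
            Reaction("exp", {"B": -1, "B_e": 1}, 0, 10),
        ],
    )
    transitions = [
        _tr("upt", "A_e[ab] -> A[ab]"),
        _tr("r1", "A[ab] -> B[ab]"),
        _tr("r2a", "A[ab] -> C[ab]"),
        _tr("r2b", "C[ab] -> B[ab]"),
        _tr("exp", "B[ab] -> B_e[ab]"),
    ]
    tracers = [TracerSpec("A_e", [("11", 0.5), ("00", 0.5)])]
    truth = FluxVector(
        ["upt", "r1", "r2a", "r2b", "exp"], np.array([1.0, 0.5, 0.5, 0.5, 1.0])
    )
    # route 2 (g2) highly expressed, route 1 (g1) low
    expr = ExpressionData({"g1": 1.0, "g2": 10.0})
    return net, transitions, tracers, truth, ["B"], expr


def _build_futile_cycle() -> tuple:
    net = build_network(
        _mets(
            ("A_e", "e", 2, True),
            ("A", "c", 2, False),
            ("B", "c", 2, False),
            ("B_e", "e", 2, True),
        ),
        [
            Reaction("upt", {"A_e": -1, "A": 1}, 1, 1),
            Reaction("fwd", {"A": -1, "B": 1}, 0, 10),
            Reaction("bwd", {"B": -1, "A": 1}, 0, 10),
            Reaction("exp", {"B": -1, "B_e": 1}, 0, 10),
        ],
    )
    transitions = [
        _tr("upt", "A_e[ab] -> A[ab]"),
        _tr("fwd", "A[ab] -> B[ab]"),
        _tr("bwd", "B[ab] -> A[ab]"),
        _tr("exp", "B[ab] -> B_e[ab]"),
    ]
    tracers = [TracerSpec("A_e", [("11", 0.5), ("00", 0.5)])]
    truth = FluxVector(["upt", "fwd", "bwd", "exp"], np.array([1.0, 1.0, 0.0, 1.0]))
    return net, transitions, tracers, truth, ["B"], None


def _build_reversible_exchange() -> tuple:
    net = build_network(
        _mets(
            ("A_e", "e", 1, True),
            ("U_e", "e", 1, True),
            ("A", "c", 1, False),
            ("B", "c", 1, False),
            ("B_e", "e", 1, True),
        ),
        [
            Reaction("upt_a", {"A_e": -1, "A": 1}, 1, 1),
            Reaction("rev", {"A": -1, "B": 1}, -10, 10),
            Reaction("upt_u", {"U_e": -1, "B": 1}, 1, 1),
            Reaction("exp", {"B": -1, "B_e": 1}, 2, 2),
        ],
    )
    transitions = [
        _tr("upt_a", "A_e[a] -> A[a]"),
        _tr("rev", "A[a] -> B[a]"),
        _tr("upt_u", "U_e[a] -> B[a]"),
        _tr("exp", "B[a] -> B_e[a]"),
    ]
    tracers = [TracerSpec("A_e", [("1", 1.0)])]
    t = np.array([0.0, 0.5, 0.0, 0.0])
    truth = FluxVector(
        ["upt_a", "rev", "upt_u", "exp"], np.array([1.0, 1.0, 1.0, 2.0]), t
    )
    return net, transitions, tracers, truth, ["A", "B"], None


def _build_mini_ppp() -> tuple:
    net = build_network(
        _mets(
            ("Hex_e", "e", 6, True),
            ("Hex", "c", 6, False),
            ("Pen", "c", 5, False),
            ("Rib", "c", 5, False),
            ("CO2", "c", 1, False),
            ("Rib_e", "e", 5, True),
            ("CO2_e", "e", 1, True),
        ),
        [
            Reaction("upt", {"Hex_e": -1, "Hex": 1}, 1, 1),
            Reaction("ox", {"Hex": -1, "Pen": 1, "CO2": 1}, 0, 10, gpr="g_ox"),
            Reaction("nonox", {"Hex": -1, "Pen": 1, "CO2": 1}, 0, 10, gpr="g_nonox"),
            Reaction("iso", {"Pen": -1, "Rib": 1}, -10, 10, gpr="g_iso"),
            Reaction("exp_rib", {"Rib": -1, "Rib_e": 1}, 0, 10),
            Reaction("exp_co2", {"CO2": -1, "CO2_e": 1}, 0, 10),
        ],
    )
    transitions = [
        _tr("upt", "Hex_e[abcdef] -> Hex[abcdef]"),
        # oxidative: carbon 1 lost as CO2
        _tr("ox", "Hex[abcdef] -> CO2[a] + Pen[bcdef]"),
        # rearrangement-style route keeping carbons 1-5
        _tr("nonox", "Hex[abcdef] -> Pen[abcde] + CO2[f]"),
        _tr("iso", "Pen[abcde] -> Rib[abcde]"),
        _tr("exp_rib", "Rib[abcde] -> Rib_e[abcde]"),
        _tr("exp_co2", "CO2[a] -> CO2_e[a]"),
    ]
    # 50% [1,2-13C2] hexose
    tracers = [TracerSpec("Hex_e", [("110000", 0.5), ("000000", 0.5)])]
    t = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    truth = FluxVector(
        ["upt", "ox", "nonox", "iso", "exp_rib", "exp_co2"],
        np.array([1.0, 0.4, 0.6, 1.0, 1.0, 1.0]),
        t,
    )
    expr = ExpressionData({"g_ox": 3.0, "g_nonox": 7.0, "g_iso": 7.0})
    return net, transitions, tracers, truth, ["Rib"], expr


_BUILDERS = {
    "s1fig_condensation": _build_s1fig,
    "parallel_routes": _build_parallel_routes,
    "futile_cycle": _build_futile_cycle,
    "reversible_exchange": _build_reversible_exchange,
    "mini_ppp": _build_mini_ppp,
}


def generate_fixture(
    name: str, seed: int = 1, noise: bool = False, sd: float = DEFAULT_SD
) -> Fixture:
    """Build a named fixture with measurements generated from the ground
    truth (noise-free by default; seeded Gaussian noise otherwise)."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    net, transitions, tracers, truth, fragments, expr = _BUILDERS[name]()
    targets = {f: parse_fragment(net, f) for f in fragments}
    tracer_mets = {t.metabolite for t in tracers}
    system = decompose_to_emu(net, transitions, targets, extra_inputs=tracer_mets)
    labeling = simulate_labeling(system, truth, tracers)
    rng = np.random.default_rng(seed)
    measurements = []
    for frag in fragments:
        vec = labeling[frag]
        for m_index, frac in enumerate(vec.fractions):
            value = float(frac)
            if noise:
                value = float(np.clip(value + rng.normal(0.0, sd), 0.0, 1.0))
            measurements.append(LabelingMeasurement(frag, m_index, value, sd))
    return Fixture(
        name=name,
        net=net,
        transitions=transitions,
        tracers=tracers,
        truth_flux=truth,
        measurements=measurements,
        fragments=fragments,
        expression=expr,
        seed=seed,
        truth_labeling=labeling,
    )
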