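"""Objective functions and gene-expression weighting.

The primary 13C MFA objective is the variance-weighted sum of squared
residuals between measured and simulated isotopologue fractions,

    X = sum_j ((E_j - Y_j) / sigma_j)**2 ,

which at the optimum deviates from perturbed optima following a chi2
distribution with one degree of freedom; the parsimonious second stage
minimizes sum_i w_i |v_i| inside the tolerance region X <= X_opt + T.

GIMME-style weights derive from gene expression mapped through GPR rules:
w_i = 1 + max(Th - ge_i, 0) with Th the maximum (or a chosen percentile of)
expression among mapped genes.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .emu import IsotopologueVector
from .network import FluxVector, MetabolicNetwork

__all__ = [
    "LabelingMeasurement",
    "ExpressionData",
    "ToleranceConfig",
    "ssr_objective",
    "weighted_flux_sum",
    "expression_weights",
    "default_threshold",
    "gpr_expression",
    "chi2_tolerance",
]


@dataclass
class LabelingMeasurement:
    """One measured isotopologue fraction with its standard deviation."""

    fragment_id: str
    m_index: int
    value: float
    sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(
                f"{self.fragment_id} m{self.m_index}: fraction {self.value} not in [0,1]"
            )
        if self.sd <= 0:
            raise ValueError(f"{self.fragment_id} m{self.m_index}: sd must be > 0")


@dataclass
class ToleranceConfig:
    confidence: float = 0.95
    df: int = 1

    @property
    def T(self) -> float:
        return chi2_tolerance(self.confidence, self.df)


def ssr_objective(
    simulated: dict[str, IsotopologueVector],
    measured: list[LabelingMeasurement],
) -> float:
    """Sum of squared sigma-scaled residuals over all measurements."""
    x = 0.0
    for m in measured:
        sim = simulated.get(m.fragment_id)
        if sim is None:
            raise KeyError(f"no simulated fragment {m.fragment_id!r}")
        if m.m_index >= sim.fractions.size:
            raise IndexError(
                f"fragment {m.fragment_id} has no isotopologue m{m.m_index}"
            )
        x += ((m.value - sim.fractions[m.m_index]) / m.sd) ** 2
    return float(x)


def weighted_flux_sum(flux: FluxVector, w: np.ndarray | None = None) -> float:
    """Parsimony objective sum_i w_i |v_i| over net fluxes.

    Turnover fluxes are deliberately excluded: penalizing t would doubly
    suppress the exchange flux needed to fit labeling data.
    """
    v = np.abs(flux.v)
    if w is None:
        return float(v.sum())
    w = np.asarray(w, dtype=float)
    if w.size != v.size:
        raise ValueError("weight vector dimension mismatch")
    return float(np.sum(w * v))


class ExpressionData:
    """Gene id -> normalized expression value, mapped to reactions via GPR."""

    def __init__(self, values: dict[str, float]):
        bad = {g: v for g, v in values.items() if not np.isfinite(v)}
        if bad:
            raise ValueError(f"non-finite expression values: {sorted(bad)}")
        self.values = dict(values)

    def reaction_expression(self, net: MetabolicNetwork) -> dict[str, float]:
        """ge_i for every reaction with a (resolvable) GPR rule."""
        out = {}
        for r in net.reactions:
            if r.gpr.strip():
                out[r.id] = gpr_expression(r.gpr, self.values)
        return out

    def mapped_values(self, net: MetabolicNetwork) -> list[float]:
        genes: set[str] = set()
        for r in net.reactions:
            if r.gpr.strip():
                genes |= _gpr_genes(r.gpr)
        return [self.values[g] for g in sorted(genes) if g in self.values]


def _normalize_rule(rule: str) -> str:
    return rule.replace(" AND ", " and ").replace(" OR ", " or ").replace(
        " And ", " and "
    ).replace(" Or ", " or ")


def _gpr_genes(rule: str) -> set[str]:
    tree = ast.parse(_normalize_rule(rule), mode="eval")
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


def _eval_gpr(node: ast.AST, values: dict[str, float]) -> float:
    # AND -> min (complexes limited by the scarcest subunit)
    # OR  -> max (isoenzymes add capacity)
    if isinstance(node, ast.Expression):
        return _eval_gpr(node.body, values)
    if isinstance(node, ast.BoolOp):
        parts = [_eval_gpr(v, values) for v in node.values]
        return min(parts) if isinstance(node.op, ast.And) else max(parts)
    if isinstance(node, ast.Name):
        if node.id not in values:
            raise KeyError(f"unknown gene id {node.id!r} in GPR rule")
        return values[node.id]
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    raise ValueError(f"unsupported GPR syntax: {ast.dump(node)}")


def gpr_expression(rule: str, gene_values: dict[str, float]) -> float:
    """Evaluate a boolean gene-protein-reaction rule over expression values."""
    tree = ast.parse(_normalize_rule(rule), mode="eval")
    return float(_eval_gpr(tree, gene_values))


def default_threshold(
    expr: ExpressionData, net: MetabolicNetwork, percentile: float = 100.0
) -> float:
    """Expression threshold Th: the maximum (default) or a percentile of the
    expression values of genes mapped to the network."""
    vals = expr.mapped_values(net)
    if not vals:
        raise ValueError("no expression values map to the network's GPR rules")
    if percentile >= 100.0:
        return float(max(vals))
    return float(np.percentile(vals, percentile))


def expression_weights(
    expr: ExpressionData, net: MetabolicNetwork, Th: float | None = None
) -> np.ndarray:
    """GIMME-style minimization weights w_i = 1 + max(Th - ge_i, 0).

    Reactions without a GPR annotation get weight 1.
    """
    if Th is None:
        Th = default_threshold(expr, net)
    if not np.isfinite(Th):
        raise ValueError("threshold Th must be finite")
    ge = expr.reaction_expression(net)
    w = np.ones(len(net.reactions))
    for rid, g in ge.items():
        w[net.rxn_index[rid]] = 1.0 + max(Th - g, 0.0)
    return w


def chi2_tolerance(confidence: float = 0.95, df: int = 1) -> float:
    """Primary-objective tolerance T: upper chi2 quantile (3.84 at 95%, 1 df)."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(chi2.ppf(confidence, df))
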