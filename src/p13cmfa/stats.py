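"""Flux-map comparison metrics.

Pearson correlation and Euclidean distance between paired flux maps, plus
the Fisher r-to-z test for the significance of a difference between two
correlation coefficients:

    r' = (1/2) ln((1+r)/(1-r)),   Var(z) = 1/(n-3),
    Z  = (r'_1 - r'_2) / sqrt(1/(n1-3) + 1/(n2-3)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "FluxComparison",
    "ZTestResult",
    "compare_flux_maps",
    "fisher_r_to_z",
    "compare_correlations",
]


@dataclass
class FluxComparison:
    method: str
    r: float
    d: float
    n: int


@dataclass
class ZTestResult:
    z1: float
    z2: float
    Z: float
    p: float


def compare_flux_maps(
    candidate: dict[str, float] | np.ndarray,
    reference: dict[str, float] | np.ndarray,
    method: str = "candidate",
) -> FluxComparison:
    """Pearson r and Euclidean distance over paired net fluxes.

    Dict inputs are paired by reaction id (intersection, sorted); array
    inputs are paired positionally.  Zero-flux pairs are retained.
    """
    if isinstance(candidate, dict) and isinstance(reference, dict):
        ids = sorted(set(candidate) & set(reference))
        if not ids:
            raise ValueError("no shared reaction ids to compare")
        a = np.array([candidate[i] for i in ids], dtype=float)
        b = np.array([reference[i] for i in ids], dtype=float)
    else:
        a = np.asarray(candidate, dtype=float)
        b = np.asarray(reference, dtype=float)
        if a.shape != b.shape:
            raise ValueError("flux maps have different lengths")
    if a.size < 2:
        raise ValueError("need at least 2 paired fluxes")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = float(sps.pearsonr(a, b).statistic)
    d = float(np.linalg.norm(a - b))
    return FluxComparison(method, r, d, a.size)


def fisher_r_to_z(r: float) -> float:
    """Variance-stabilizing transform r' = (1/2) ln((1+r)/(1-r))."""
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return float(0.5 * np.log((1.0 + r) / (1.0 - r)))


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> ZTestResult:
    """Two-sided z-test for the difference between two Pearson correlations."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("sample sizes must exceed 3 (variance is 1/(n-3))")
    z1, z2 = fisher_r_to_z(r1), fisher_r_to_z(r2)
    Z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = float(2.0 * sps.norm.sf(abs(Z)))
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return ZTestResult(z1, z2, float(Z), p)
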