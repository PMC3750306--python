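"""Bistability analysis of the pro-caspase/caspase subsystem.

With free Bax clamped, the caspase pair obeys

    dProcasp/dt = s3 - (a1*Bax + a2*Casp^2)*Procasp - d3*Procasp
    dCasp/dt    = (a1*Bax + a2*Casp^2)*Procasp - d3*Casp

whose total relaxes to S = s3/d3 independently of Bax.  On that total the
steady states are roots of a cubic in Casp; the quadratic auto-activation
term makes the subsystem bistable at low Bax.  The low/unstable pair
coalesces in a saddle-node (fold) at Bax_bif — the free-Bax level above
which apoptosis is the only steady outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .parameters import KineticParameters

__all__ = [
    "Stability",
    "CaspaseSteadyState",
    "BifurcationResult",
    "caspase_steady_states",
    "find_bifurcation",
    "commitment_threshold",
    "bifurcation_diagram",
]

#: Roots closer than this fraction of S are merged (near-fold tie-break).
_MERGE_FRAC = 1e-6


class Stability(str, Enum):
    STABLE = "STABLE"
    UNSTABLE = "UNSTABLE"


@dataclass(frozen=True)
class CaspaseSteadyState:
    """A steady state of the clamped-Bax caspase subsystem.

    ``casp + procasp == s3/d3`` by construction.
    """

    casp: float
    procasp: float
    stability: Stability


@dataclass(frozen=True)
class BifurcationResult:
    """Location of the saddle-node fold in the (Bax, Casp) plane."""

    bax_bif: float
    casp_bif: float


def _residual(casp: float, bax: float, p: KineticParameters) -> float:
    """dCasp/dt restricted to the invariant total Procasp = S - Casp.

    Exact at steady states; its sign-slope classifies their stability.
    """
    S = p.caspase_total
    return (p.a1 * bax + p.a2 * casp**2) * (S - casp) - p.d3 * casp


def _residual_slope(casp: float, bax: float, p: KineticParameters) -> float:
    S = p.caspase_total
    return (
        2 * p.a2 * casp * (S - casp)
        - (p.a1 * bax + p.a2 * casp**2)
        - p.d3
    )


def caspase_steady_states(
    bax_clamped: float, params: KineticParameters
) -> list[CaspaseSteadyState]:
    """All steady states of the caspase pair at a clamped free-Bax level.

    Solves the cubic ``(a1*Bax + a2*C^2)(S - C) = d3*C`` for C in [0, S]
    via companion-matrix roots, merges near-double roots, and labels
    stability from the slope of the reduced residual.  Returns 1–3 states
    sorted by ascending caspase level.
    """
    if not np.isfinite(bax_clamped) or bax_clamped < 0:
        raise ValueError(f"bax_clamped must be nonnegative, got {bax_clamped!r}")
    p = params
    S = p.caspase_total
    # a2*C^3 - a2*S*C^2 + (a1*Bax + d3)*C - a1*Bax*S = 0
    coeffs = [p.a2, -p.a2 * S, p.a1 * bax_clamped + p.d3, -p.a1 * bax_clamped * S]
    roots = np.roots(coeffs)
    real = sorted(
        float(r.real)
        for r in roots
        if abs(r.imag) <= 1e-9 * S and -1e-9 * S <= r.real <= S * (1 + 1e-9)
    )
    merged: list[float] = []
    for r in real:
        if merged and abs(r - merged[-1]) < _MERGE_FRAC * S:
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)
    out = []
    for c in merged:
        c = min(max(c, 0.0), S)
        stab = (
            Stability.STABLE
            if _residual_slope(c, bax_clamped, p) <= 0
            else Stability.UNSTABLE
        )
        out.append(CaspaseSteadyState(casp=c, procasp=S - c, stability=stab))
    return out


def find_bifurcation(
    params: KineticParameters, verify: bool = True
) -> BifurcationResult:
    """Locate the saddle-node of the caspase subsystem in clamped Bax.

    At the fold, the residual and its Casp-derivative vanish together;
    eliminating the Bax term gives the one-variable double-root condition
    ``C*(S - C)^2 = d3*S/(2*a2)`` on (0, S/3), solved by bracketing.  The
    fold Bax follows from the residual.  The root-count change across the
    fold is verified by direct enumeration.
    """
    p = params
    S = p.caspase_total
    target = p.d3 * S / (2 * p.a2)

    def g(c: float) -> float:
        return c * (S - c) ** 2 - target

    lo, hi = 1e-12 * S, S / 3
    if g(lo) > 0 or g(hi) < 0:
        raise ValueError(
            "no saddle-node: the double-root condition has no solution on "
            f"(0, S/3); the caspase subsystem is monostable (d3*S/(2*a2) = {target:g})"
        )
    c_bif = brentq(g, lo, hi, xtol=1e-9, rtol=1e-14)
    bax_bif = (p.d3 * c_bif / (S - c_bif) - p.a2 * c_bif**2) / p.a1
    if bax_bif <= 0:
        raise ValueError(f"fold found at non-physical Bax = {bax_bif:g}")
    if verify:
        below = len(caspase_steady_states(bax_bif * 0.99, p))
        above = len(caspase_steady_states(bax_bif * 1.01, p))
        if not (below == 3 and above == 1):
            raise RuntimeError(
                "root count does not change 3 -> 1 across the computed fold "
                f"(Bax_bif = {bax_bif:g}: {below} roots below, {above} above)"
            )
    return BifurcationResult(bax_bif=bax_bif, casp_bif=c_bif)


def commitment_threshold(params: KineticParameters) -> float:
    """Caspase level of the unstable steady state at Bax = 0 (molecules).

    A trajectory whose caspase level ends above this value after the inputs
    are withdrawn relaxes to the high (apoptotic) branch; the apoptotic
    decision is irreversible past this point.
    """
    states = caspase_steady_states(0.0, params)
    unstable = [s for s in states if s.stability is Stability.UNSTABLE]
    if len(states) < 3 or not unstable:
        raise ValueError(
            "the Bax=0 caspase subsystem is not bistable; no commitment "
            "threshold exists for these parameters"
        )
    return unstable[0].casp


def bifurcation_diagram(
    params: KineticParameters, bax_grid
) -> pd.DataFrame:
    """Steady-state branches over a grid of clamped Bax values.

    Returns a long-format table with columns ``bax``, ``casp_root``,
    ``procasp_root``, ``stability`` — one row per root per grid point.
    """
    rows = []
    for bax in np.asarray(bax_grid, dtype=float):
        for ss in caspase_steady_states(float(bax), params):
            rows.append(
                {
                    "bax": float(bax),
                    "casp_root": ss.casp,
                    "procasp_root": ss.procasp,
                    "stability": ss.stability.value,
                }
            )
    return pd.DataFrame(rows, columns=["bax", "casp_root", "procasp_root", "stability"])
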