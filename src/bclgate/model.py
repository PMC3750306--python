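"""Right-hand side of the 11-species apoptotic-module ODE system.

Species (all in molecules per cell): Bax mRNA; free Bax; free Bcl-xL; the
Bax:Bcl-xL and Bcl-xL:Bad_u complexes; unphosphorylated and phosphorylated
Bad; the Bad_p:Scaffold complex; free Scaffold 14-3-3; pro-caspase;
active caspase.  Internal time unit is seconds; user-facing durations are
hours and are converted at the interface.

Three linear combinations of the state are conserved exactly by the
mass-action structure: the Bcl-xL, Bad, and Scaffold pools.  Bax and the
caspase pair are synthesized and degraded and are not conserved.
"""

from __future__ import annotations

import numpy as np

from .parameters import InputPoint, KineticParameters

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "hill_synthesis_rate",
    "derivatives",
    "conserved_pools",
]

#: Canonical species order used by every state vector, CSV column set, and
#: trajectory in the package.
SPECIES = (
    "Bax_mRNA",
    "Bax",
    "BclxL",
    "cBaxBclxL",
    "cBclxLBadu",
    "Bad_u",
    "Bad_p",
    "cBadpScaffold",
    "Scaffold",
    "Procasp",
    "Casp",
)
N_SPECIES = len(SPECIES)

# Indices, for readers of the RHS below.
(I_MRNA, I_BAX, I_BCLXL, I_CBX, I_CXB, I_BADU, I_BADP, I_CBS, I_SCAF,
 I_PROCASP, I_CASP) = range(N_SPECIES)


def hill_synthesis_rate(p53_killer: float, params: KineticParameters) -> float:
    """Bax-mRNA synthesis rate driven by p53_killer (molecules/s).

    Sigmoidal transcription kinetics with cooperativity 2:
    ``s1 + s2 * p53^2 / (M^2 + p53^2)``; ranges from s1 at zero input to
    s1 + s2 at saturation.
    """
    if not np.isfinite(p53_killer) or p53_killer < 0:
        raise ValueError(f"p53_killer must be nonnegative, got {p53_killer!r}")
    p = params
    return p.s1 + p.s2 * p53_killer**2 / (p.M**2 + p53_killer**2)


def _rhs(t, y, k: tuple, p53: float, akt_p: float) -> list[float]:
    """Mass-action RHS over the full 11-species state.

    ``k`` is the flat parameter tuple (s1..a2); scalar arithmetic is used
    throughout as it is markedly faster than vectorized numpy at n=11.
    """
    (s1, s2, s3, s4, M, d1, d2, d3, b1, b2, b3, u1, u2, u3,
     p1, q1, a1, a2) = k
    mrna, bax, bclxl, cbx, cxb, badu, badp, cbs, scaf, procasp, casp = y

    hill = s1 + s2 * p53 * p53 / (M * M + p53 * p53)
    bind_bx = b1 * bax * bclxl          # Bax + Bcl-xL association
    bind_xb = b2 * bclxl * badu         # Bcl-xL + Bad_u association
    bind_bs = b3 * badp * scaf          # Bad_p + Scaffold association
    phos_free = p1 * akt_p * badu       # Akt_p phosphorylates free Bad_u
    phos_cplx = p1 * akt_p * cxb        # ... and Bad_u inside Bcl-xL:Bad_u
    act = a1 * bax * procasp + a2 * casp * casp * procasp

    return [
        hill - d1 * mrna,
        s4 * mrna + u1 * cbx - bind_bx - d2 * bax,
        # d2*cbx: degradation of the Bax moiety releases Bcl-xL intact
        u2 * cxb + u1 * cbx + phos_cplx - bind_xb - bind_bx + d2 * cbx,
        bind_bx - u1 * cbx - d2 * cbx,
        bind_xb - u2 * cxb - phos_cplx,
        u2 * cxb - bind_xb - phos_free + q1 * badp + q1 * cbs,
        u3 * cbs - bind_bs + phos_free + phos_cplx - q1 * badp,
        bind_bs - u3 * cbs - q1 * cbs,
        u3 * cbs - bind_bs + q1 * cbs,
        s3 - act - d3 * procasp,
        act - d3 * casp,
    ]


def _rhs9(t, y9, k: tuple, p53: float, akt_p: float) -> list[float]:
    """RHS of the caspase-independent 9-species Bcl-2 subsystem.

    The first nine equations never reference the caspase pair, so the
    subsystem can be integrated on its own for steady-state analysis.
    """
    (s1, s2, s3, s4, M, d1, d2, d3, b1, b2, b3, u1, u2, u3,
     p1, q1, a1, a2) = k
    mrna, bax, bclxl, cbx, cxb, badu, badp, cbs, scaf = y9

    hill = s1 + s2 * p53 * p53 / (M * M + p53 * p53)
    bind_bx = b1 * bax * bclxl
    bind_xb = b2 * bclxl * badu
    bind_bs = b3 * badp * scaf
    phos_free = p1 * akt_p * badu
    phos_cplx = p1 * akt_p * cxb

    return [
        hill - d1 * mrna,
        s4 * mrna + u1 * cbx - bind_bx - d2 * bax,
        u2 * cxb + u1 * cbx + phos_cplx - bind_xb - bind_bx + d2 * cbx,
        bind_bx - u1 * cbx - d2 * cbx,
        bind_xb - u2 * cxb - phos_cplx,
        u2 * cxb - bind_xb - phos_free + q1 * badp + q1 * cbs,
        u3 * cbs - bind_bs + phos_free + phos_cplx - q1 * badp,
        bind_bs - u3 * cbs - q1 * cbs,
        u3 * cbs - bind_bs + q1 * cbs,
    ]


def _param_tuple(params: KineticParameters) -> tuple:
    p = params
    return (p.s1, p.s2, p.s3, p.s4, p.M, p.d1, p.d2, p.d3, p.b1, p.b2,
            p.b3, p.u1, p.u2, p.u3, p.p1, p.q1, p.a1, p.a2)


def derivatives(
    state, inputs: InputPoint, params: KineticParameters
) -> np.ndarray:
    """Time derivative of the full state (11 components, molecules/s)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (N_SPECIES,):
        raise ValueError(
            f"state must have {N_SPECIES} components in the order {SPECIES}, "
            f"got shape {y.shape}"
        )
    akt_p = inputs.akt_p(params)
    return np.array(_rhs(0.0, y, _param_tuple(params), inputs.p53_killer, akt_p))


def conserved_pools(state) -> tuple[float, float, float]:
    """Conserved pool totals (BclxL_tot, Bad_tot, Scaffold_tot) of a state.

    Works on full 11-component or bare 9-component state vectors.
    """
    y = np.asarray(state, dtype=float)
    if y.shape not in ((N_SPECIES,), (9,)):
        raise ValueError(f"state must have 9 or {N_SPECIES} components, got {y.shape}")
    bclxl_tot = y[I_BCLXL] + y[I_CBX] + y[I_CXB]
    bad_tot = y[I_BADU] + y[I_BADP] + y[I_CXB] + y[I_CBS]
    scaffold_tot = y[I_SCAF] + y[I_CBS]
    return (bclxl_tot, bad_tot, scaffold_tot)
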