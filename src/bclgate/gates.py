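"""Steady states of the Bcl-2 subsystem, fate and logic-gate classification.

The first nine equations of the module are independent of the caspase pair,
so constant-input steady states of the Bcl-2 subsystem can be computed on
their own and classified: when the steady free-Bax level exceeds the
saddle-node level Bax_bif of the caspase switch, the input is apoptotic;
otherwise the cell survives.  Evaluating the four logic corners of the
(p53_killer, Akt_u) plane gives a truth table, and the truth table a gate
type.  Two evaluation paths exist: direct ODE relaxation, and algebraic
inequalities over seven macro-parameters (lumped parameter clusters that
fully determine the steady state).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import caspase
from .model import _param_tuple, _rhs9
from .parameters import InputPoint, KineticParameters, PoolConfiguration

__all__ = [
    "FateLabel",
    "GateType",
    "MacroParameters",
    "GateClassification",
    "ScanResult",
    "GateBoundaryScan",
    "SteadyStateError",
    "bcl2_steady_state",
    "classify_fate",
    "macro_parameters",
    "algebraic_corner_prediction",
    "classify_gate",
    "input_plane_scan",
    "apoptotic_isoline",
    "gate_boundary",
    "CORNERS",
]

log = logging.getLogger(__name__)

#: Corner order used for truth tables: (p53 logic level, Akt_u logic level).
CORNERS = ((0, 0), (1, 0), (0, 1), (1, 1))

#: Residual norm (molecules/s) below which the subsystem counts as relaxed.
RESIDUAL_TOL = 1e-6

#: Hard cap on relaxation time, hours.
MAX_RELAX_HOURS = 2000.0

# Indices of the six independent unknowns of the reduced steady-state
# system; the remaining three species follow from the conservation laws.
_FREE = np.array([0, 1, 3, 4, 5, 7])  # mRNA, Bax, cBaxBclxL, cBclxLBadu, Bad_u, cBadpScaffold


class SteadyStateError(RuntimeError):
    """Relaxation failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class FateLabel(str, Enum):
    SURVIVAL = "SURVIVAL"
    APOPTOSIS = "APOPTOSIS"


class GateType(str, Enum):
    ALWAYS_SURVIVE = "ALWAYS_SURVIVE"
    AND = "AND"
    OR = "OR"
    P53_ONLY = "P53_ONLY"
    AKT_ONLY = "AKT_ONLY"
    AKT_INTERMEDIATE = "AKT_INTERMEDIATE"
    CONSTITUTIVE = "CONSTITUTIVE"


@dataclass(frozen=True)
class MacroParameters:
    """Lumped parameter clusters governing the steady state.

    m1/m2: minimal/maximal total Bax (molecules) at zero/saturating p53;
    m3–m5: binding affinities (1/molecules) of Bax–Bcl-xL, Bcl-xL–Bad_u and
    Bad_p–Scaffold; m6: maximal phosphorylated-Bad fraction (dimensionless);
    m7: the saddle-node free-Bax level Bax_bif (molecules).
    """

    m1: float
    m2: float
    m3: float
    m4: float
    m5: float
    m6: float
    m7: float


@dataclass(frozen=True)
class GateClassification:
    """Fates at the four logic corners and the resulting gate type."""

    truth_table: dict[tuple[int, int], FateLabel]
    gate_type: GateType
    method: str


def canonical_start(pools: PoolConfiguration) -> np.ndarray:
    """Resting-like initial condition for relaxation (9 species).

    All Bad phosphorylated and scaffold-bound up to scaffold capacity,
    Bcl-xL entirely free, no Bax mRNA or protein.
    """
    y = np.zeros(9)
    cbs = min(pools.bad_tot, pools.scaffold_tot)
    y[2] = pools.bclxl_tot
    y[6] = pools.bad_tot - cbs
    y[7] = cbs
    y[8] = pools.scaffold_tot - cbs
    return y


def _residual_norm(y9, k, p53, akt_p) -> float:
    return float(np.max(np.abs(_rhs9(0.0, y9, k, p53, akt_p))))


def _polish(y9, pools: PoolConfiguration, k, p53, akt_p):
    """Newton-polish a near-steady 9-species state on the reduced system.

    The nine steady-state equations are rank-deficient (three conservation
    laws), so the complexes and free totals are re-expressed through the
    pools and the six independent components are solved for.  Returns the
    polished state or None if the solve fails or leaves the physical region.
    """

    def expand(x):
        mrna, bax, cbx, cxb, badu, cbs = x
        y = np.empty(9)
        y[0], y[1], y[3], y[4], y[5], y[7] = mrna, bax, cbx, cxb, badu, cbs
        y[2] = pools.bclxl_tot - cbx - cxb
        y[6] = pools.bad_tot - badu - cxb - cbs
        y[8] = pools.scaffold_tot - cbs
        return y

    def fun(x):
        return np.asarray(_rhs9(0.0, expand(x), k, p53, akt_p))[_FREE]

    (s1, s2, s3, s4, M, d1, d2, d3, b1, b2, b3, u1, u2, u3,
     p1, q1, a1, a2) = k

    def jac(x):
        _, bax, cbx, cxb, badu, cbs = x
        bclxl = pools.bclxl_tot - cbx - cxb
        badp = pools.bad_tot - badu - cxb - cbs
        scaf = pools.scaffold_tot - cbs
        pa = p1 * akt_p
        # rows: d/dt of (mRNA, Bax, cBaxBclxL, cBclxLBadu, Bad_u, cBadpScaffold)
        # cols: the same six unknowns; the three dependent species enter
        # through the conservation substitutions.
        return np.array([
            [-d1, 0.0, 0.0, 0.0, 0.0, 0.0],
            [s4, -b1 * bclxl - d2, u1 + b1 * bax, b1 * bax, 0.0, 0.0],
            [0.0, b1 * bclxl, -b1 * bax - (u1 + d2), -b1 * bax, 0.0, 0.0],
            [0.0, 0.0, -b2 * badu, -b2 * badu - (u2 + pa), b2 * bclxl, 0.0],
            [0.0, 0.0, b2 * badu, u2 + b2 * badu - q1,
             -b2 * bclxl - pa - q1, 0.0],
            [0.0, 0.0, 0.0, -b3 * scaf, -b3 * scaf,
             -b3 * (scaf + badp) - (u3 + q1)],
        ])

    sol = root(fun, y9[_FREE], jac=jac, method="hybr", tol=1e-14)
    if not sol.success:
        return None
    y = expand(sol.x)
    scale = max(pools.bad_tot, pools.bclxl_tot, pools.scaffold_tot, 1.0)
    if np.min(y) < -1e-9 * scale:
        return None
    return np.clip(y, 0.0, None)


def _relax(
    y9,
    pools: PoolConfiguration,
    k,
    p53: float,
    akt_p: float,
    residual_tol: float,
    max_hours: float,
    polish: bool = True,
):
    """Relax the 9-species subsystem to steady state by chunked integration.

    Implicit (BDF) integration over doubling time spans until the residual
    norm drops below tolerance; once close, an exact Newton polish on the
    reduced system finishes the job.  Raises SteadyStateError at the time
    cap.
    """
    max_seconds = max_hours * 3600.0
    elapsed, span = 0.0, 2e4
    resid = _residual_norm(y9, k, p53, akt_p)
    while resid >= residual_tol:
        if polish and resid < 1e3:
            polished = _polish(y9, pools, k, p53, akt_p)
            if polished is not None:
                r = _residual_norm(polished, k, p53, akt_p)
                if r < residual_tol:
                    return polished, r
        if elapsed >= max_seconds:
            raise SteadyStateError(
                f"no steady state within {max_hours:g} h "
                f"(final residual {resid:.3g} molecules/s)",
                residual=resid,
            )
        sol = solve_ivp(
            _rhs9,
            (0.0, span),
            y9,
            args=(k, p53, akt_p),
            method="BDF",
            rtol=1e-8,
            atol=1e-6,
        )
        if not sol.success:
            raise SteadyStateError(
                f"relaxation integrator failed: {sol.message}", residual=resid
            )
        y9 = sol.y[:, -1]
        elapsed += span
        span = min(span * 2, max(max_seconds - elapsed, 1.0))
        resid = _residual_norm(y9, k, p53, akt_p)
    return np.clip(y9, 0.0, None), resid


def bcl2_steady_state(
    inputs: InputPoint,
    pools: PoolConfiguration,
    params: KineticParameters,
    residual_tol: float = RESIDUAL_TOL,
    max_hours: float = MAX_RELAX_HOURS,
    include_caspases: bool = True,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Constant-input steady state of the Bcl-2 subsystem.

    Relaxes from the canonical resting-like start (or ``start``) until the
    derivative residual falls below ``residual_tol`` molecules/s.  Returns
    the full 11-component state; the caspase pair is reported on the lowest
    steady branch consistent with the steady free-Bax level (pass
    ``include_caspases=False`` for the bare 9-species vector).
    """
    k = _param_tuple(params)
    p53 = inputs.p53_killer
    akt_p = inputs.akt_p(params)
    y0 = canonical_start(pools) if start is None else np.asarray(start, float)[:9]
    y9, resid = _relax(y0, pools, k, p53, akt_p, residual_tol, max_hours)
    log.debug(
        "steady state at (p53=%g, akt_u=%g): free Bax %.4g, residual %.3g",
        p53, inputs.akt_u, y9[1], resid,
    )
    if not include_caspases:
        return y9
    low = caspase.caspase_steady_states(float(y9[1]), params)[0]
    return np.concatenate([y9, [low.procasp, low.casp]])


def classify_fate(
    inputs: InputPoint,
    pools: PoolConfiguration,
    params: KineticParameters,
    bax_bif: float | None = None,
) -> FateLabel:
    """Survive-or-die label of a constant input.

    APOPTOSIS iff the steady-state free Bax reaches the saddle-node level of
    the caspase switch.
    """
    if bax_bif is None:
        bax_bif = caspase.find_bifurcation(params).bax_bif
    y9 = bcl2_steady_state(inputs, pools, params, include_caspases=False)
    return FateLabel.APOPTOSIS if y9[1] >= bax_bif else FateLabel.SURVIVAL


def macro_parameters(params: KineticParameters) -> MacroParameters:
    """The seven macro-parameters in closed form (m7 from the fold)."""
    p = params
    hill_max = p.s1 + p.s2 * p.p53killer_max**2 / (p.M**2 + p.p53killer_max**2)
    return MacroParameters(
        m1=p.s1 * p.s4 / (p.d1 * p.d2),
        m2=hill_max * p.s4 / (p.d1 * p.d2),
        m3=p.b1 / p.u1,
        m4=p.b2 / p.u2,
        m5=p.b3 / p.u3,
        m6=p.p1 * p.akt_tot / (p.q1 + p.p1 * p.akt_tot),
        m7=caspase.find_bifurcation(params).bax_bif,
    )


def algebraic_corner_prediction(
    corner: tuple[int, int],
    pools: PoolConfiguration,
    macro: MacroParameters,
) -> FateLabel:
    """Fate of a logic corner from the macro-parameter inequality.

    Because Bad_u binds Bcl-xL much more tightly than Bax does (m3 << m4),
    free Bax appears only when the combined pro-apoptotic totals exceed the
    restrainer pool: apoptosis iff

        Bax_tot(corner) + Bad_u(corner) > BclxL_tot + m7

    with Bax_tot = m1 (p53 logic-0) or m2 (logic-1), and Bad_u =
    (1 - m6)*Bad_tot (Akt_u logic-0) or Bad_tot (logic-1).
    """
    c1, c2 = corner
    if c1 not in (0, 1) or c2 not in (0, 1):
        raise ValueError(f"corner entries must be 0 or 1, got {corner!r}")
    bax_tot = macro.m2 if c1 else macro.m1
    bad_u = pools.bad_tot if c2 else (1.0 - macro.m6) * pools.bad_tot
    apoptotic = bax_tot + bad_u > pools.bclxl_tot + macro.m7
    return FateLabel.APOPTOSIS if apoptotic else FateLabel.SURVIVAL


def _gate_type(truth: dict[tuple[int, int], FateLabel]) -> GateType:
    apoptotic = frozenset(c for c in CORNERS if truth[c] is FateLabel.APOPTOSIS)
    if not apoptotic:
        return GateType.ALWAYS_SURVIVE
    if (0, 0) in apoptotic:
        return GateType.CONSTITUTIVE
    mapping = {
        frozenset({(1, 1)}): GateType.AND,
        frozenset({(1, 0), (0, 1), (1, 1)}): GateType.OR,
        frozenset({(1, 0), (1, 1)}): GateType.P53_ONLY,
        frozenset({(0, 1), (1, 1)}): GateType.AKT_INTERMEDIATE,
        frozenset({(0, 1)}): GateType.AKT_ONLY,
    }
    if apoptotic in mapping:
        return mapping[apoptotic]
    raise ValueError(f"non-monotone truth table: apoptotic corners {sorted(apoptotic)}")


def classify_gate(
    pools: PoolConfiguration,
    params: KineticParameters,
    method: str = "ode",
) -> GateClassification:
    """Gate type of a pool configuration from its four-corner truth table.

    ``method='ode'`` relaxes the Bcl-2 subsystem at each corner;
    ``method='algebraic'`` evaluates the macro-parameter inequalities.
    """
    if method not in ("ode", "algebraic"):
        raise ValueError(f"method must be 'ode' or 'algebraic', got {method!r}")
    truth: dict[tuple[int, int], FateLabel] = {}
    if method == "algebraic":
        macro = macro_parameters(params)
        for corner in CORNERS:
            truth[corner] = algebraic_corner_prediction(corner, pools, macro)
    else:
        bax_bif = caspase.find_bifurcation(params).bax_bif
        for corner in CORNERS:
            inp = InputPoint.from_corner(corner, params)
            truth[corner] = classify_fate(inp, pools, params, bax_bif=bax_bif)
    return GateClassification(truth_table=truth, gate_type=_gate_type(truth), method=method)


@dataclass(frozen=True)
class ScanResult:
    """Steady-state free Bax over a grid of constant inputs.

    ``bax[i, j]`` is the free-Bax level at ``(p53_killer[i], akt_u[j])``.
    """

    p53_killer: np.ndarray
    akt_u: np.ndarray
    bax: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns p53_killer, akt_u, bax_ss."""
        pp, aa = np.meshgrid(self.p53_killer, self.akt_u, indexing="ij")
        return pd.DataFrame(
            {"p53_killer": pp.ravel(), "akt_u": aa.ravel(), "bax_ss": self.bax.ravel()}
        )


def _steady_bax_grid(
    pools: PoolConfiguration,
    params: KineticParameters,
    p53_values: np.ndarray,
    akt_values: np.ndarray,
) -> np.ndarray:
    """Free-Bax steady states on a grid, warm-starting each cell's Newton
    solve from its neighbour (the subsystem is monostable, so the branch is
    unique and warm starts are safe); relaxation is the fallback."""
    k = _param_tuple(params)
    bax = np.empty((len(p53_values), len(akt_values)))
    prev_row_start: np.ndarray | None = None
    for i, p53 in enumerate(p53_values):
        y = prev_row_start
        for j, akt_u in enumerate(akt_values):
            akt_p = params.akt_tot - akt_u
            y_new = _polish(y, pools, k, p53, akt_p) if y is not None else None
            if y_new is not None and _residual_norm(y_new, k, p53, akt_p) < RESIDUAL_TOL:
                y = y_new
            else:
                y, _ = _relax(
                    y if y is not None else canonical_start(pools),
                    pools, k, p53, akt_p, RESIDUAL_TOL, MAX_RELAX_HOURS,
                )
            if j == 0:
                prev_row_start = y
            bax[i, j] = y[1]
    return bax


def input_plane_scan(
    pools: PoolConfiguration,
    params: KineticParameters,
    grid: int = 81,
) -> ScanResult:
    """Steady-state free Bax over the full admissible input plane.

    The plane is [0, p53killer_max] x [0, akt_tot] sampled on a uniform
    ``grid`` x ``grid`` lattice.  Free Bax is monotone nondecreasing along
    both axes.
    """
    if grid < 2:
        raise ValueError(f"grid must be at least 2 per axis, got {grid}")
    p53_values = np.linspace(0.0, params.p53killer_max, grid)
    akt_values = np.linspace(0.0, params.akt_tot, grid)
    bax = _steady_bax_grid(pools, params, p53_values, akt_values)
    return ScanResult(p53_killer=p53_values, akt_u=akt_values, bax=bax)


def apoptotic_isoline(scan: ScanResult, level: float) -> np.ndarray:
    """Level set of steady free Bax at the given level, as (p53, akt_u) points.

    Crossings are located by linear interpolation along grid rows and
    columns; the points are returned sorted by p53_killer (the isoline is a
    monotone curve for this model).  Empty array when the whole plane lies
    on one side of the level.
    """
    pts: list[tuple[float, float]] = []
    p53v, aktv, bax = scan.p53_killer, scan.akt_u, scan.bax
    for i, p53 in enumerate(p53v):  # sweep Akt_u at fixed p53
        f = bax[i, :] - level
        for j in range(len(aktv) - 1):
            if f[j] == 0.0:
                pts.append((p53, float(aktv[j])))
            elif f[j] * f[j + 1] < 0:
                w = f[j] / (f[j] - f[j + 1])
                pts.append((p53, float(aktv[j] + w * (aktv[j + 1] - aktv[j]))))
    for j, akt_u in enumerate(aktv):  # sweep p53 at fixed Akt_u
        f = bax[:, j] - level
        for i in range(len(p53v) - 1):
            if f[i] * f[i + 1] < 0:
                w = f[i] / (f[i] - f[i + 1])
                pts.append((float(p53v[i] + w * (p53v[i + 1] - p53v[i])), akt_u))
    if not pts:
        return np.empty((0, 2))
    arr = np.array(sorted(set(pts), key=lambda t: (t[0], -t[1])))
    return arr


@dataclass(frozen=True)
class GateBoundaryScan:
    """Gate-type transitions along one varied pool axis.

    ``corner_flips`` holds, per logic corner, the smallest scanned value at
    which the corner's fate differs from its fate at the scan start (None
    if it never flips).  ``boundaries`` maps each gate type to the smallest
    scanned value where it holds.
    """

    varied: str
    values: np.ndarray
    gate_types: list[GateType]
    corner_flips: dict[tuple[int, int], float | None]
    boundaries: dict[GateType, float]


def gate_boundary(
    params: KineticParameters,
    pools: PoolConfiguration,
    varied: str,
    vmin: float,
    vmax: float,
    step: float,
) -> GateBoundaryScan:
    """Scan one pool total and locate the gate-type transitions.

    ``varied`` is ``'bad_tot'`` or ``'bclxl_tot'``; the other pools stay at
    their values in ``pools``.  Each scanned value is classified through the
    ODE path (four corner steady states against Bax_bif), warm-starting
    along the scan.
    """
    if varied not in ("bad_tot", "bclxl_tot"):
        raise ValueError(f"varied must be 'bad_tot' or 'bclxl_tot', got {varied!r}")
    if step <= 0:
        raise ValueError("step must be positive")
    values = np.arange(vmin, vmax + step / 2, step)
    bax_bif = caspase.find_bifurcation(params).bax_bif
    k = _param_tuple(params)

    fates = {c: [] for c in CORNERS}
    warm: dict[tuple[int, int], np.ndarray | None] = {c: None for c in CORNERS}
    for v in values:
        pv = pools.replace(**{varied: float(v)})
        for corner in CORNERS:
            inp = InputPoint.from_corner(corner, params)
            akt_p = params.akt_tot - inp.akt_u
            y = warm[corner]
            # The polish re-imposes the new pool totals through the
            # conservation substitution, so a neighbour guess is safe even
            # though the pools differ; plain relaxation would conserve the
            # old totals, so the fallback restarts from the canonical state.
            y_new = _polish(y, pv, k, inp.p53_killer, akt_p) if y is not None else None
            if y_new is None or _residual_norm(y_new, k, inp.p53_killer, akt_p) >= RESIDUAL_TOL:
                y_new, _ = _relax(
                    canonical_start(pv), pv, k, inp.p53_killer, akt_p,
                    RESIDUAL_TOL, MAX_RELAX_HOURS,
                )
            warm[corner] = y_new
            fates[corner].append(
                FateLabel.APOPTOSIS if y_new[1] >= bax_bif else FateLabel.SURVIVAL
            )

    gate_types = [
        _gate_type({c: fates[c][iv] for c in CORNERS}) for iv in range(len(values))
    ]
    corner_flips: dict[tuple[int, int], float | None] = {}
    for corner in CORNERS:
        seq = fates[corner]
        flip = next(
            (float(values[iv]) for iv in range(len(values)) if seq[iv] is not seq[0]),
            None,
        )
        corner_flips[corner] = flip
    boundaries: dict[GateType, float] = {}
    for iv, gt in enumerate(gate_types):
        boundaries.setdefault(gt, float(values[iv]))
    return GateBoundaryScan(
        varied=varied,
        values=values,
        gate_types=gate_types,
        corner_flips=corner_flips,
        boundaries=boundaries,
    )
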