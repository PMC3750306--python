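"""Transient stimulation of the full module and apoptotic commitment.

A stimulation protocol holds the inputs at a constant level for a finite
window, with zero inputs before and after.  Commitment is decided after the
inputs are withdrawn: if the caspase level has passed the unstable Bax=0
steady state, caspase auto-activation completes the switch without further
stimulus; otherwise the cell relaxes back to the resting state.  Bisection
on the window length yields the minimal committing duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import caspase
from .gates import bcl2_steady_state
from .model import I_CASP, N_SPECIES, SPECIES, _param_tuple, _rhs
from .parameters import InputPoint, KineticParameters, PoolConfiguration

__all__ = [
    "StimulationProtocol",
    "Trajectory",
    "IndeterminateCommitment",
    "simulate",
    "committed_to_apoptosis",
    "minimal_stimulation_duration",
]

log = logging.getLogger(__name__)

SECONDS_PER_HOUR = 3600.0

#: Default relaxation window after stimulus withdrawal, hours.
DEFAULT_POST_HOURS = 500.0

#: Solver contract for the stiff full system.
RTOL = 1e-8
ATOL = 1e-3


class IndeterminateCommitment(RuntimeError):
    """Terminal caspase level too close to the threshold to call a basin."""


@dataclass(frozen=True)
class StimulationProtocol:
    """Piecewise-constant input schedule.

    Inputs are zero outside the stimulation window.  ``pre_hours=None``
    requests analytic equilibration: the simulation starts directly at the
    computed resting steady state instead of a finite burn-in.
    """

    stimulus: InputPoint
    stim_hours: float
    post_hours: float = DEFAULT_POST_HOURS
    pre_hours: float | None = None

    def __post_init__(self) -> None:
        if self.stim_hours < 0 or self.post_hours < 0:
            raise ValueError("phase durations must be nonnegative")
        if self.pre_hours is not None and self.pre_hours < 0:
            raise ValueError("pre_hours must be nonnegative or None")


@dataclass(frozen=True)
class Trajectory:
    """Simulated time course of the full 11-species system.

    ``time_h`` in hours from the start of the stimulation phase (the pre
    phase, if finite, occupies negative times); ``states`` has one row per
    time point in the canonical species order.  ``committed`` is None when
    the terminal point is too close to the commitment threshold to call.
    """

    time_h: np.ndarray
    states: np.ndarray
    protocol: StimulationProtocol
    committed: bool | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_h", self.time_h)
        return df

    @property
    def terminal_state(self) -> np.ndarray:
        return self.states[-1]


def resting_state(
    pools: PoolConfiguration, params: KineticParameters
) -> np.ndarray:
    """Full 11-species resting steady state at zero inputs.

    The Bcl-2 subsystem is relaxed at (0, 0) and the caspase pair is placed
    on the low branch consistent with the resting free-Bax level.
    """
    return bcl2_steady_state(InputPoint(0.0, 0.0), pools, params)


def _integrate_phase(y, hours, k, p53, akt_p, rtol, atol):
    if hours <= 0:
        return np.array([0.0]), y[:, None] if y.ndim == 2 else np.array([y]).T
    sol = solve_ivp(
        _rhs,
        (0.0, hours * SECONDS_PER_HOUR),
        y,
        args=(k, p53, akt_p),
        method="BDF",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integrator failed during a protocol phase: {sol.message}")
    return sol.t / SECONDS_PER_HOUR, sol.y


def simulate(
    protocol: StimulationProtocol,
    pools: PoolConfiguration,
    params: KineticParameters,
    rtol: float = RTOL,
    atol: float = ATOL,
    start: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the full system through the protocol's phases.

    Each phase is integrated with a stiff implicit method and the solver is
    restarted at phase boundaries, so input discontinuities are never
    interpolated across.  ``start`` overrides the computed resting state
    (useful to amortize equilibration across many protocol probes).
    """
    k = _param_tuple(params)
    stim = protocol.stimulus
    akt_p_stim = stim.akt_p(params)
    akt_p_rest = params.akt_tot

    if start is not None:
        y = np.asarray(start, dtype=float)
        if y.shape != (N_SPECIES,):
            raise ValueError(f"start must have {N_SPECIES} components")
    else:
        y = resting_state(pools, params)

    times = []
    states = []
    if protocol.pre_hours is not None and protocol.pre_hours > 0:
        t, ys = _integrate_phase(y, protocol.pre_hours, k, 0.0, akt_p_rest, rtol, atol)
        times.append(t - protocol.pre_hours)
        states.append(ys)
        y = ys[:, -1]

    if protocol.stim_hours > 0:
        t, ys = _integrate_phase(
            y, protocol.stim_hours, k, stim.p53_killer, akt_p_stim, rtol, atol
        )
        times.append(t)
        states.append(ys)
        y = ys[:, -1]

    if protocol.post_hours > 0:
        t, ys = _integrate_phase(y, protocol.post_hours, k, 0.0, akt_p_rest, rtol, atol)
        times.append(t + protocol.stim_hours)
        states.append(ys)

    if not times:
        times, states = [np.array([0.0])], [y[:, None]]

    time_h = np.concatenate(times)
    traj_states = np.concatenate(states, axis=1).T
    traj = Trajectory(time_h=time_h, states=traj_states, protocol=protocol, committed=None)
    try:
        committed = committed_to_apoptosis(traj, params)
    except IndeterminateCommitment:
        committed = None
    return replace(traj, committed=committed)


def committed_to_apoptosis(traj: Trajectory, params: KineticParameters) -> bool:
    """Whether a trajectory has irreversibly switched to apoptosis.

    True iff the terminal caspase level lies above the Bax=0 unstable
    steady state — equivalently, the nearest stable branch at zero input is
    the high one.  A terminal level within 1% of the threshold itself is
    reported as indeterminate rather than guessed.
    """
    threshold = caspase.commitment_threshold(params)
    casp = float(traj.terminal_state[I_CASP])
    if abs(casp - threshold) <= 0.01 * threshold:
        raise IndeterminateCommitment(
            f"terminal caspase level {casp:.6g} is within 1% of the "
            f"commitment threshold {threshold:.6g}; extend the post phase"
        )
    return casp > threshold


def minimal_stimulation_duration(
    stimulus: InputPoint,
    pools: PoolConfiguration,
    params: KineticParameters,
    tol_hours: float = 0.05,
    bracket_hours: float = 48.0,
    post_hours: float = DEFAULT_POST_HOURS,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> float:
    """Minimal stimulus duration that commits the cell, by bisection.

    The resting state is computed once and reused by every probe.  Each
    probe simulates the stimulus for the trial duration followed by the
    post phase; if a terminal point lands too close to the threshold the
    post phase is extended until the basin assignment is unambiguous.
    Errors identify which bracket end fails when no bracket exists.
    """
    if tol_hours <= 0:
        raise ValueError("tol_hours must be positive")
    rest = resting_state(pools, params)
    threshold = caspase.commitment_threshold(params)

    def probe(duration: float) -> bool:
        post = post_hours
        for _ in range(4):
            proto = StimulationProtocol(
                stimulus=stimulus, stim_hours=duration, post_hours=post
            )
            traj = simulate(proto, pools, params, rtol=rtol, atol=atol, start=rest)
            if traj.committed is not None:
                return traj.committed
            post += DEFAULT_POST_HOURS
        # final attempt decides strictly or raises
        return committed_to_apoptosis(traj, params)

    if probe(0.0):
        raise ValueError(
            "the system commits to apoptosis without any stimulation; "
            "no minimal duration exists"
        )
    if not probe(bracket_hours):
        raise ValueError(
            f"a {bracket_hours:g} h stimulus does not commit the system; "
            "no minimal duration within the bracket"
        )
    lo, hi = 0.0, bracket_hours
    while hi - lo > tol_hours:
        mid = 0.5 * (lo + hi)
        if probe(mid):
            hi = mid
        else:
            lo = mid
        log.debug("bisection bracket: (%.4f, %.4f) h", lo, hi)
    result = 0.5 * (lo + hi)
    log.info(
        "minimal stimulation duration %.3f h (threshold Casp = %.1f)",
        result, threshold,
    )
    return result
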