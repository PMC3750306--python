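# Methods

## Model

The package implements a deterministic mass-action ODE model of the
mitochondrial apoptotic decision module with 11 species: Bax mRNA, free
Bax, free Bcl-xL, the Bax:Bcl-xL and Bcl-xL:Bad_u complexes, Bad_u, Bad_p,
the Bad_p:Scaffold complex, free Scaffold 14-3-3, pro-caspase and caspase.
All abundances are molecules per cell; the internal time unit is seconds
and user-facing durations are hours, converted at the interface.

Key assumptions, inherited from the model structure:

- The two inputs, p53_killer and unphosphorylated Akt, are exogenous and
  piecewise-constant; upstream p53/Akt dynamics are out of scope.  The
  total Akt pool is constant, so Akt_p = Akt_tot − Akt_u.
- Bax transcription responds to p53_killer through a Hill term with
  cooperativity 2; caspase activation carries an auto-catalytic
  `a2·Casp²·Procasp` term that makes the caspase pair bistable and the
  death decision irreversible.  Cytochrome-c/apoptosome intermediates are
  collapsed into the single Bax → caspase activation step.
- Three pools are conserved exactly by construction: Bcl-xL (free + both
  complexes), Bad (four forms) and Scaffold (free + complex).  Degradation
  of the Bax moiety of Bax:Bcl-xL releases Bcl-xL intact (the `d2·{Bax:Bcl-xL}`
  source term in the free-Bcl-xL equation).  Akt_p phosphorylates Bad_u
  both free and inside the Bcl-xL:Bad_u complex; dephosphorylation acts on
  Bad_p both free and scaffold-bound.
- The equation for the Bcl-xL:Bad_u complex is
  `b2·BclxL·Bad_u − u2·C − p1·Akt_p·C`; this is the unique form consistent
  with the Bcl-xL and Bad conservation laws given the other equations.
- `p1` is treated as a bimolecular rate (molecules⁻¹·s⁻¹): every `p1` term
  is of the form `p1·Akt_p·X`, and with the default value 3×10⁻¹⁰ the
  closed-form maximal phosphorylated-Bad fraction
  `m6 = p1·Akt_tot/(q1 + p1·Akt_tot)` comes out exactly 2/3, which the
  steady states reproduce.
- The scaffold pool default is `Scaffold_tot = 2×10⁵`, consistent with the
  resting high-Bad steady state holding ≈1.33×10⁵ molecules of
  Bad_p:Scaffold next to ≈0.67×10⁵ free scaffold.

## Caspase switch analysis

The caspase pair at clamped free Bax keeps the invariant total
`S = s3/d3 = 10⁵`; on that total its steady states solve the cubic
`(a1·Bax + a2·C²)(S − C) = d3·C`.  Roots are computed by numpy's
companion-matrix solver, filtered to real values in [0, S], and near-double
roots closer than 10⁻⁶·S are merged so that fold detection is robust.
Stability comes from the slope of the reduced one-variable residual, which
is exact at steady states; the full 2×2 Jacobian gives the same labels and
serves as a cross-check in the tests.

The saddle-node is found from the double-root reduction
`C·(S − C)² = d3·S/(2·a2)` bracketed on (0, S/3), after which the fold Bax
follows from the residual; with the default parameters the fold is at
(Bax, Casp) ≈ (5.10×10³, 1.02×10³).  The computation verifies that the
steady-state count changes 3 → 1 across the fold and fails loudly
otherwise (e.g. when auto-activation is too weak for bistability).  The
commitment threshold is the unstable root at Bax = 0 (≈2.04×10³); above
it, auto-activation completes the switch with no further input.

## Steady states and gate classification

The first nine equations are independent of the caspase pair, so
constant-input steady states are computed on the 9-species subsystem.
Steady states are obtained by relaxation rather than algebraic solving —
the subsystem is monostable, and relaxation selects the physical branch by
construction.  Relaxation runs the BDF integrator over doubling time
spans from the canonical start (all Bad phosphorylated and scaffold-bound
up to capacity, Bcl-xL free, no Bax) until the residual norm of the
derivatives drops below 10⁻⁶ molecules/s, with a hard cap of 2000 h
(non-convergence raises, reporting the final residual).  Once the residual
is moderate, an exact Newton polish finishes the solve: the three
conservation laws are substituted out and the remaining six unknowns are
solved with an analytic Jacobian.  Because the polish re-imposes the pool
totals, it can safely warm-start from a neighbouring solution even when
the pools differ; plain relaxation cannot (it conserves whatever totals
the start carries), so scan fallbacks restart from the canonical state.
Grid scans warm-start each cell from its neighbour, which makes the
81×81 input-plane scan and the 401-point gate-boundary scans desk-scale.
No clipping is applied during integration; nonnegativity is asserted by
tolerance only, so integrator failures are not masked.

Fate classification follows the steady-state convention: an input is
apoptotic iff steady free Bax ≥ Bax_bif.  Gate classification evaluates
the four logic corners — (p53, Akt_u) at 0 or maximal — and maps the truth
table to a gate type: ALWAYS_SURVIVE, AND (only {1,1} kills), OR (any
nonzero corner kills), P53_ONLY / AKT_INTERMEDIATE (exactly one
single-signal corner kills; the latter is the regime between AND and OR
where full Akt dephosphorylation suffices but maximal p53 does not),
CONSTITUTIVE (the resting corner kills), and AKT_ONLY for the degenerate
table where only {0,1} kills.  Non-monotone tables raise.

The algebraic path evaluates the macro-parameter inequality
`Bax_tot + Bad_u > BclxL_tot + m7` with `Bax_tot` = m1 or m2 and
`Bad_u` = (1−m6)·Bad_tot or Bad_tot by corner.  The right-hand side uses
the *total* Bcl-xL pool; the survival corners hold when the inequality
fails.  ODE and algebraic fates agree whenever the inequality margin
exceeds ~10% of the right side; inside that band finite-affinity effects
can flip the outcome, which is why the ODE path is the reference.

The apoptotic isoline is extracted from a scan by linear interpolation of
the level crossing along grid rows and columns (the scan is monotone along
both axes, so the curve is single-valued in each sweep direction).  Gate
boundaries along a pool axis are reported at the scan resolution
(default step 0.005×10⁵ molecules, matching the two-significant-figure
transition levels).

## Transient stimulation

Protocols are piecewise constant: zero inputs, a stimulation window, zero
inputs again.  The pre-phase defaults to analytic equilibration — the
simulation starts at the computed resting steady state (Bcl-2 subsystem
relaxed at zero input, caspase pair on the low branch at the resting free
Bax) — avoiding an arbitrary burn-in duration.  Each phase is integrated
with the BDF method at rtol 10⁻⁸ / atol 10⁻³ molecules, restarting the
solver at the phase boundaries so discontinuities are never stepped
across.

Commitment is decided after input withdrawal: TRUE iff the terminal
caspase level exceeds the Bax = 0 unstable root.  A terminal level within
1% of the threshold is reported as indeterminate rather than guessed; the
bisection driver then extends the post-phase (default 500 h, extended in
500 h steps) until the basin assignment is unambiguous.  Minimal
committing durations are found by bisection between 0 h (must not commit)
and a 48 h bracket (must commit), to a tolerance of 0.05 h; durations are
conventionally reported rounded to 0.1 h.  A note on the numbers: BDF at
these tolerances reproduces the bisection results to well under the
reporting resolution; tightening rtol tenfold moves the minimal durations
by less than 0.05 h.

## Integrator choice

SciPy's BDF method is used throughout (relaxation, protocol phases,
convergence tests).  The system is stiff — binding rates around
3×10⁻³ molecules⁻¹s⁻¹ acting on 10⁵-molecule pools give sub-second
association timescales next to multi-hour degradation timescales — and in
our hands LSODA stalls on the post-transient tail of this system at tight
tolerances, while BDF handles all phases robustly.

## What the defaults represent

The default kinetic parameters are the published set for this module; the
three pool presets (OR: Bad_tot = 2×10⁵, BclxL_tot = 1×10⁵; AND:
Bad_tot = 0.6×10⁵; AND*: BclxL_tot = 2.4×10⁵) are the published gate
configurations.  The fixture generator perturbs rates log-normally around
the defaults (capacities fixed unless requested) and is used only for
property tests — root-finder equivalence, conservation, closed-form
phosphorylation fraction — not for any reported quantity.

## Limitations

- Deterministic ODEs only; no stochastic (Gillespie) simulation, although
  copy numbers in the low-thousands range near the fold would show
  fluctuation effects in single cells.
- One effector (Bax), one restrainer (Bcl-xL), one BH3-only protein (Bad):
  subfamily diversity, direct effector activation by BH3-only proteins,
  and cytochrome-c release dynamics are outside the model.
- Input signals are clamped levels, not dynamic p53/Akt trajectories;
  oscillatory p53 inputs are not modeled.
- Gate boundaries are read off one-dimensional scans; no two-parameter
  continuation in (Bad_tot, BclxL_tot) is attempted.
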