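"""Kinetic parameters, conserved protein pools, and input signals.

The apoptotic decision module is parameterized by 20 kinetic constants and
capacities (synthesis, degradation, binding/unbinding, phosphorylation and
caspase-activation rates), by three conserved protein totals (Bad, Bcl-xL,
Scaffold 14-3-3), and by two exogenous input levels (the killer form of p53
and unphosphorylated Akt).  All abundances are molecules per cell; all rates
are per second.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParameters",
    "PoolConfiguration",
    "InputPoint",
    "POOL_PRESETS",
    "default_parameters",
    "perturbed_parameters",
]

#: Default scaffold (14-3-3) pool, molecules per cell.  Chosen so that the
#: resting high-Bad cell holds ~1.33e5 molecules of Bad_p:Scaffold complex
#: with ~6.7e4 scaffold molecules left free.
DEFAULT_SCAFFOLD_TOT = 2e5


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants and capacities of the apoptotic module.

    Units: synthesis rates ``s1``–``s3`` in molecules/s, ``s4`` in 1/s
    (per-mRNA protein synthesis); ``M`` in molecules (half-saturation of the
    p53-driven Hill term); degradation rates ``d1``–``d3`` in 1/s;
    bimolecular binding rates ``b1``–``b3`` and the per-Akt_p
    phosphorylation rate ``p1`` in 1/(molecule*s); unbinding rates
    ``u1``–``u3`` and dephosphorylation ``q1`` in 1/s; caspase activation
    ``a1`` in 1/(molecule*s) and auto-activation ``a2`` in 1/(molecule^2*s);
    ``akt_tot`` and ``p53killer_max`` in molecules.
    """

    s1: float = 1e-2
    s2: float = 3e-2
    s3: float = 2e1
    s4: float = 2e-1
    M: float = 1e5
    d1: float = 1e-3
    d2: float = 1e-4
    d3: float = 2e-4
    b1: float = 3e-5
    b2: float = 3e-3
    b3: float = 3e-3
    u1: float = 1e-4
    u2: float = 1e-4
    u3: float = 1e-4
    p1: float = 3e-10
    q1: float = 3e-5
    a1: float = 2e-10
    a2: float = 1e-12
    akt_tot: float = 2e5
    p53killer_max: float = 2e5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {f.name!r} must be strictly positive, got {v!r}")

    @property
    def caspase_total(self) -> float:
        """Steady-state pro-caspase + caspase pool, s3/d3 (molecules)."""
        return self.s3 / self.d3

    def replace(self, **changes: float) -> "KineticParameters":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


# Table-symbol aliases accepted in config files (case-sensitive).
PARAMETER_ALIASES = {
    "Akt_tot": "akt_tot",
    "p53killer_max": "p53killer_max",
    "p53killermax": "p53killer_max",
}


@dataclass(frozen=True)
class PoolConfiguration:
    """Conserved totals of the Bcl-2 module proteins (molecules per cell).

    ``bad_tot`` and ``bclxl_tot`` select the logic-gate type; the scaffold
    pool is held at its default in all named presets.
    """

    bad_tot: float
    bclxl_tot: float
    scaffold_tot: float = DEFAULT_SCAFFOLD_TOT

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"pool {f.name!r} must be nonnegative, got {v!r}")

    def replace(self, **changes: float) -> "PoolConfiguration":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: Named pool presets realizing the three gate types: a high Bad level gives
#: gate OR, a low Bad level gate AND, and a high Bcl-xL level (with high
#: Bad) gate AND*.
POOL_PRESETS: dict[str, PoolConfiguration] = {
    "OR": PoolConfiguration(bad_tot=2e5, bclxl_tot=1e5),
    "AND": PoolConfiguration(bad_tot=0.6e5, bclxl_tot=1e5),
    "AND_STAR": PoolConfiguration(bad_tot=2e5, bclxl_tot=2.4e5),
}


@dataclass(frozen=True)
class InputPoint:
    """Constant input signal levels (molecules per cell).

    ``p53_killer`` is the apoptosis-competent phospho-form of p53 driving Bax
    transcription; ``akt_u`` is unphosphorylated Akt, the pro-apoptotic proxy
    for growth-factor withdrawal.  Phosphorylated Akt is the complement
    ``akt_tot - akt_u`` since the total Akt pool is constant.
    """

    p53_killer: float
    akt_u: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.p53_killer) or self.p53_killer < 0:
            raise ValueError(f"p53_killer must be nonnegative, got {self.p53_killer!r}")
        if not np.isfinite(self.akt_u) or self.akt_u < 0:
            raise ValueError(f"akt_u must be nonnegative, got {self.akt_u!r}")

    def akt_p(self, params: KineticParameters) -> float:
        """Phosphorylated Akt level, akt_tot − akt_u."""
        if self.akt_u > params.akt_tot:
            raise ValueError(
                f"akt_u={self.akt_u} exceeds the total Akt pool {params.akt_tot}"
            )
        return params.akt_tot - self.akt_u

    @classmethod
    def from_corner(
        cls, corner: tuple[int, int], params: KineticParameters
    ) -> "InputPoint":
        """Logic-corner encoding: 0 -> 0 molecules; 1 -> the maximal level
        (``p53killer_max`` for p53, ``akt_tot`` for unphosphorylated Akt)."""
        c1, c2 = corner
        if c1 not in (0, 1) or c2 not in (0, 1):
            raise ValueError(f"corner entries must be 0 or 1, got {corner!r}")
        return cls(
            p53_killer=params.p53killer_max if c1 else 0.0,
            akt_u=params.akt_tot if c2 else 0.0,
        )


def default_parameters() -> KineticParameters:
    """The published kinetic parameter set of the module."""
    return KineticParameters()


# Rate fields subject to log-normal perturbation in fixtures; the two
# capacities akt_tot and p53killer_max stay fixed unless asked for.
_RATE_FIELDS = (
    "s1", "s2", "s3", "s4", "M", "d1", "d2", "d3",
    "b1", "b2", "b3", "u1", "u2", "u3", "p1", "q1", "a1", "a2",
)


def perturbed_parameters(
    seed: int,
    log_sd: float,
    base: KineticParameters | None = None,
    perturb_capacities: bool = False,
) -> KineticParameters:
    """Deterministic log-normally perturbed parameter set for property tests.

    Each rate is multiplied by an independent factor exp(N(0, log_sd^2))
    drawn from a generator seeded with ``seed``.
    """
    if log_sd < 0:
        raise ValueError("log_sd must be nonnegative")
    base = base if base is not None else default_parameters()
    rng = np.random.default_rng(seed)
    fields = _RATE_FIELDS + (("akt_tot", "p53killer_max") if perturb_capacities else ())
    factors = np.exp(rng.normal(0.0, log_sd, size=len(fields)))
    return base.replace(
        **{name: getattr(base, name) * f for name, f in zip(fields, factors)}
    )
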