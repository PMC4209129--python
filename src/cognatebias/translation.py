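"""Kinetic model of translation under limitation of a single amino acid.

Translation of one codon is treated as an enzymatic reaction: the
ribosome--mRNA--peptide complex with an empty A-site binds the cognate
aminoacyl-tRNA (rate constant ``k1``), which may dissociate again (``k2``)
or be incorporated irreversibly (``k3``); a stalled complex may abort and
drop off the message (``k4``).  At steady state the flux through one such
branch point is attenuated by the Michaelis-type factor ``S/(S + Km)``
with ``Km = (k4/k3) * (k2 + k3)/k1``, where ``S`` is the concentration of
the limiting amino acid.

Because every position requiring the limiting amino acid attenuates the
flux by the same factor, a message whose product contains ``n`` such
residues produces protein at rate ``kin * M * (S/(S + Km))**n``.  With
``n`` on the order of 15 for an average bacterial protein, translation is
ultrasensitive to the free concentration of the limiting amino acid.

:func:`chain_oracle` provides an independent check: it builds the full
N-step steady-state mass balance (solving the two-species linear balance
of each branch point explicitly) instead of using the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepKinetics",
    "TranslationSpec",
    "km_from_kinetics",
    "vout_single_step",
    "vout_protein",
    "chain_oracle",
]


@dataclass(frozen=True)
class StepKinetics:
    """Rate constants of a single elongation branch point.

    Parameters
    ----------
    k1 : float
        Rate constant of the cognate aa-tRNA entering the A-site
        (1/(concentration*time)).  Must be positive.
    k2 : float
        Rate constant of the aa-tRNA leaving the A-site (1/time).
    k3 : float
        Rate constant of incorporation into the peptide chain (1/time).
        Must be positive.
    k4 : float
        Rate constant of ribosome abort/dissociation (1/time).  ``k4 = 0``
        means a stalled ribosome never drops off, hence no attenuation.
    """

    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v!r}")
        if self.k1 <= 0 or self.k3 <= 0:
            raise ValueError("k1 and k3 must be strictly positive (Km undefined otherwise)")


@dataclass(frozen=True)
class TranslationSpec:
    """Specification of the translation of one protein species.

    Parameters
    ----------
    kin : float
        Translational initiation rate constant (1/time).
    M : float
        Concentration of the specific mRNA.
    N : int
        Protein length in residues.
    limiting_positions : frozenset of int
        1-based chain positions that require the limiting amino acid; its
        cardinality is the cognate count ``n``.
    S : float
        Free concentration of the limiting amino acid.
    Km : float
        Half-maximal concentration of the branch-point attenuation factor.
    """

    kin: float
    M: float
    N: int
    limiting_positions: frozenset = field(default_factory=frozenset)
    S: float = 0.0
    Km: float = 0.0

    def __post_init__(self) -> None:
        if self.kin < 0 or self.M < 0:
            raise ValueError("kin and M must be nonnegative")
        if self.N < 0:
            raise ValueError("N must be nonnegative")
        pos = frozenset(int(i) for i in self.limiting_positions)
        object.__setattr__(self, "limiting_positions", pos)
        if pos and (min(pos) < 1 or max(pos) > self.N):
            raise ValueError("limiting positions must lie within 1..N")
        if self.S < 0 or self.Km < 0:
            raise ValueError("S and Km must be nonnegative")
        if pos and self.S == 0 and self.Km == 0:
            raise ValueError("S and Km cannot both be zero at a limiting step")

    @property
    def n(self) -> int:
        """Number of positions requiring the limiting amino acid."""
        return len(self.limiting_positions)


def km_from_kinetics(step: StepKinetics) -> float:
    """Half-maximal concentration of one branch point.

    ``Km = (k4/k3) * (k2 + k3)/k1``: the amino-acid concentration at which
    the flux through the step is half its unattenuated value.  Zero when
    ``k4 = 0`` (no abort pathway, hence no attenuation).
    """
    return (step.k4 / step.k3) * ((step.k2 + step.k3) / step.k1)


def vout_single_step(vin: float, S: float, Km: float) -> float:
    """Steady-state flux through a single branch point.

    Returns ``vin * S/(S + Km)``; never exceeds ``vin`` and equals
    ``vin/2`` at the half-maximal point ``S = Km``.
    """
    if vin < 0:
        raise ValueError("vin must be nonnegative")
    if S < 0 or Km < 0:
        raise ValueError("S and Km must be nonnegative")
    if S == 0 and Km == 0:
        raise ValueError("S and Km cannot both be zero")
    return vin * S / (S + Km)


def vout_protein(spec: TranslationSpec) -> float:
    """Closed-form steady-state rate of production of the full protein.

    ``kin * M * (S/(S + Km))**n`` with ``n = |limiting_positions|``.  The
    result depends only on how many positions are limiting, not where they
    fall; it reduces to ``kin * M`` when ``n = 0`` or ``Km = 0``.
    """
    base = spec.kin * spec.M
    if spec.n == 0 or spec.Km == 0:
        return base
    return base * (spec.S / (spec.S + spec.Km)) ** spec.n


def chain_oracle(spec: TranslationSpec, step: StepKinetics) -> float:
    """Terminal production flux from the explicit N-step mass balance.

    Walks the elongation chain position by position.  Non-limiting steps
    pass flux unchanged (an unbranched pathway at steady state).  At every
    limiting position the branch-point balance is solved as a 2x2 linear
    system in the complex concentrations (E: empty A-site, I: occupied
    intermediate)::

        v_in + k2*I - (k1*S + k4)*E = 0
        k1*S*E - (k2 + k3)*I        = 0

    and the outgoing flux is ``k3*I``.  The kinetics of ``step`` determine
    the attenuation; ``spec.Km`` is ignored here so the routine remains an
    independent check of :func:`vout_protein`.

    Restricted to ``N <= 200`` — beyond the regime where the direct
    construction is the intended sanity check.
    """
    if spec.N > 200:
        raise ValueError("chain_oracle is intended for N <= 200")
    a = step.k1 * spec.S  # pseudo-first-order binding rate
    if a + step.k4 == 0:
        raise ValueError("degenerate branch point: S = 0 with k4 = 0 has no steady state")
    v = spec.kin * spec.M
    for pos in range(1, spec.N + 1):
        if pos in spec.limiting_positions:
            coeff = np.array([[-(a + step.k4), step.k2], [a, -(step.k2 + step.k3)]])
            rhs = np.array([-v, 0.0])
            _, intermediate = np.linalg.solve(coeff, rhs)
            v = step.k3 * intermediate
    return float(v)
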