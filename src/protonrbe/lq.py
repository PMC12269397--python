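"""Linear-quadratic (LQ) isoeffect arithmetic.

The LQ model summarises fractionation sensitivity of a tissue through a
single parameter, the α/β ratio (Gy).  A schedule of ``n`` fractions of
``d`` Gy each (total dose ``D = n·d``) is mapped onto the biologically
effective dose

    BED = D · (1 + d / (α/β)),

which removes the fractionation dependence: two schedules with equal BED
are isoeffective.  Low α/β (late-responding tissue such as spinal cord,
typically 2-4 Gy) means strong sparing by small fractions.

This module also provides the standard dose combination of the asymptotic
RBE limits used by phenomenological proton-RBE models,

    RBE(d) = [ sqrt((α/β)_x² + 4·d·(α/β)_x·RBE_max + 4·d²·RBE_min²)
               − (α/β)_x ] / (2·d),

where (α/β)_x refers to the reference (photon) radiation, RBE_max is the
RBE in the limit of zero dose per fraction and RBE_min the limit at
infinite dose per fraction.  The RBE_min-squared form is used, as printed
in the Carabe-Fernandez, Wedenberg and McNamara model publications.

All doses are absorbed dose in Gy.  Fraction numbers are positive reals:
isoeffect solving legitimately produces non-integer fraction numbers and
they are never rounded here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LQParams",
    "FractionSchedule",
    "bed",
    "isoeffective_fraction_dose",
    "fractions_for_bed",
    "rbe_from_max_min",
]


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic tissue parameters.

    Parameters
    ----------
    alpha_beta
        The α/β ratio in Gy.  Must be finite and strictly positive.
    """

    alpha_beta: float

    def __post_init__(self) -> None:
        ab = float(self.alpha_beta)
        if not math.isfinite(ab) or ab <= 0.0:
            raise ValueError(f"alpha_beta must be finite and > 0, got {self.alpha_beta!r}")
        object.__setattr__(self, "alpha_beta", ab)


@dataclass(frozen=True)
class FractionSchedule:
    """A fractionation schedule: ``n_fractions`` fractions of ``fraction_dose`` Gy.

    ``n_fractions`` may be non-integer (isoeffect solving produces real
    fraction numbers).  The total dose is derived, never stored.
    """

    n_fractions: float
    fraction_dose: float

    def __post_init__(self) -> None:
        n = float(self.n_fractions)
        d = float(self.fraction_dose)
        if not math.isfinite(n) or n <= 0.0:
            raise ValueError(f"n_fractions must be finite and > 0, got {self.n_fractions!r}")
        if not math.isfinite(d) or d < 0.0:
            raise ValueError(f"fraction_dose must be finite and >= 0, got {self.fraction_dose!r}")
        object.__setattr__(self, "n_fractions", n)
        object.__setattr__(self, "fraction_dose", d)

    @property
    def total_dose(self) -> float:
        return self.n_fractions * self.fraction_dose

    @classmethod
    def from_total(cls, n_fractions: float, total_dose: float) -> "FractionSchedule":
        """Build a schedule from a total dose split into equal fractions."""
        if n_fractions <= 0:
            raise ValueError("n_fractions must be > 0")
        return cls(n_fractions=n_fractions, fraction_dose=total_dose / n_fractions)


def bed(schedule: FractionSchedule, lq: LQParams) -> float:
    """Biologically effective dose of ``schedule``: ``D·(1 + d/(α/β))``.

    Always ≥ the total dose; equals it in the ``d → 0`` limit.
    """
    return schedule.total_dose * (1.0 + schedule.fraction_dose / lq.alpha_beta)


def isoeffective_fraction_dose(bed_target: float, n_fractions: float, lq: LQParams) -> float:
    """Fraction dose ``d`` such that ``n`` fractions of ``d`` deliver ``bed_target``.

    Solves ``n·d·(1 + d/(α/β)) = BED`` for the positive root of the
    quadratic.  Uses the rationalised root

        d = 2c / (1 + sqrt(1 + 4c/(α/β))),   c = BED/n,

    which avoids cancellation when α/β is large and reduces smoothly to
    ``d = c`` in the α/β → ∞ (purely linear) limit.
    """
    if bed_target <= 0.0:
        raise ValueError(f"bed_target must be > 0, got {bed_target!r}")
    if n_fractions <= 0.0:
        raise ValueError(f"n_fractions must be > 0, got {n_fractions!r}")
    c = bed_target / n_fractions
    return 2.0 * c / (1.0 + math.sqrt(1.0 + 4.0 * c / lq.alpha_beta))


def fractions_for_bed(bed_target: float, fraction_dose: float, lq: LQParams) -> float:
    """Number of fractions of ``fraction_dose`` Gy delivering ``bed_target``.

    The result is a positive real and is deliberately not rounded:
    extrapolating an isoeffect to e.g. 1.8 Gy/fraction implies ~50
    fractions and the arithmetic must stay exact.
    """
    if bed_target <= 0.0:
        raise ValueError(f"bed_target must be > 0, got {bed_target!r}")
    if fraction_dose <= 0.0:
        raise ValueError(f"fraction_dose must be > 0, got {fraction_dose!r}")
    return bed_target / (fraction_dose * (1.0 + fraction_dose / lq.alpha_beta))


def rbe_from_max_min(
    fraction_dose: float,
    alpha_beta_x: float,
    rbe_max: float,
    rbe_min: float,
) -> float:
    """RBE at a given proton fraction dose from its zero- and high-dose limits.

    Implements the LQ-based combination (RBE_min squared form)::

        RBE(d) = [sqrt(ab² + 4·d·ab·RBE_max + 4·d²·RBE_min²) − ab] / (2d)

    with ``ab = (α/β)_x`` of the reference radiation, evaluated in the
    rationalised form ``2·(ab·RBE_max + d·RBE_min²) / (sqrt(...) + ab)``
    which is exact (returns ``rbe_max``) at ``d = 0`` instead of 0/0.

    Monotone in ``d``: decreasing from ``rbe_max`` towards ``rbe_min``
    whenever ``rbe_max > rbe_min``; constant when they coincide.
    """
    d = float(fraction_dose)
    ab = float(alpha_beta_x)
    if d < 0.0:
        raise ValueError(f"fraction_dose must be >= 0, got {fraction_dose!r}")
    if ab <= 0.0:
        raise ValueError(f"alpha_beta_x must be > 0, got {alpha_beta_x!r}")
    if d < 1e-9:
        return float(rbe_max)
    root = math.sqrt(ab * ab + 4.0 * d * ab * rbe_max + 4.0 * d * d * rbe_min * rbe_min)
    return 2.0 * (ab * rbe_max + d * rbe_min * rbe_min) / (root + ab)
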