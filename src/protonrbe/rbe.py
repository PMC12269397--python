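"""RBE estimation: ratio estimators, isoeffect extrapolation, reporting.

The relative biological effectiveness (RBE) of protons is the ratio of
the photon dose to the proton dose producing the same effect.  Here the
isoeffect level is fixed at 50% endpoint probability, giving three ratio
estimators:

* RBE            = ED50(photon) / ED50(proton), per schedule;
* RBE_max        = BED50(photon) / BED50(proton) — the zero-fraction-dose
  limit of the RBE, because BED removes the fractionation dependence;
* relative RBE   = ED50(plateau) / ED50(position) — the rise of the RBE
  along the spread-out Bragg peak, in which the photon reference cancels
  (and with it roughly half the uncertainty).

Between the 6-fraction measurement and the zero-dose limit, the RBE at an
arbitrary proton fraction dose d is obtained by LQ isoeffect
extrapolation: solve the (real) fraction number n that delivers the
proton BED50 in fractions of d, then the photon fraction dose that
delivers the photon BED50 in the same n fractions; the RBE at d is the
ratio of the two fraction doses.

SEs of all ratios use the delta method; 90% confidence limits use
Fieller's theorem.  Photon and proton estimates come from different
experiments (historical photon reference) and are treated as independent
by default; a correlation parameter exists for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .datasets import PhotonReference, PositionSummary
from .dose_response import ConfidenceInterval, Estimate, fieller_cl
from .lq import LQParams, fractions_for_bed, isoeffective_fraction_dose

__all__ = [
    "RBEEstimate",
    "rbe_from_ed50",
    "rbe_max",
    "relative_rbe",
    "rbe_at_fraction_dose",
    "interpolate_rbe_se",
    "table2_report",
]


@dataclass(frozen=True)
class RBEEstimate:
    """A ratio-derived RBE quantity with SE and 90% Fieller limits."""

    value: float
    se: float
    cl90: ConfidenceInterval
    kind: str  # ed50_ratio | bed50_ratio | relative_to_plateau | at_fraction_dose
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value <= 0.0:
            raise ValueError("RBE must be positive")


def _ratio_estimate(
    numerator: Estimate | tuple[float, float],
    denominator: Estimate | tuple[float, float],
    kind: str,
    correlation: float = 0.0,
    level: float = 0.90,
    context: dict | None = None,
) -> RBEEstimate:
    a, se_a = float(numerator[0]), float(numerator[1])
    b, se_b = float(denominator[0]), float(denominator[1])
    if b <= 0.0 or a <= 0.0:
        raise ValueError("ratio estimators need strictly positive inputs")
    value = a / b
    cv_a, cv_b = se_a / a, se_b / b
    var_rel = cv_a * cv_a + cv_b * cv_b - 2.0 * correlation * cv_a * cv_b
    se = value * math.sqrt(max(var_rel, 0.0))
    cl = fieller_cl((a, se_a), (b, se_b), correlation=correlation, level=level)
    return RBEEstimate(value=value, se=se, cl90=cl, kind=kind, context=context or {})


def rbe_from_ed50(
    ed50_reference: Estimate | tuple[float, float],
    ed50_test: Estimate | tuple[float, float],
    correlation: float = 0.0,
    **context,
) -> RBEEstimate:
    """RBE as the photon/proton ED50 ratio at a common fractionation."""
    return _ratio_estimate(ed50_reference, ed50_test, "ed50_ratio",
                           correlation=correlation, context=context)


def rbe_max(
    bed50_reference: Estimate | tuple[float, float],
    bed50_test: Estimate | tuple[float, float],
    correlation: float = 0.0,
    **context,
) -> RBEEstimate:
    """Zero-fraction-dose RBE limit as the photon/proton BED50 ratio."""
    return _ratio_estimate(bed50_reference, bed50_test, "bed50_ratio",
                           correlation=correlation, context=context)


def relative_rbe(
    ed50_plateau: Estimate | tuple[float, float],
    ed50_position: Estimate | tuple[float, float],
    correlation: float = 0.0,
    **context,
) -> RBEEstimate:
    """RBE of a position relative to the plateau (photon reference cancels)."""
    return _ratio_estimate(ed50_plateau, ed50_position, "relative_to_plateau",
                           correlation=correlation, context=context)


def rbe_at_fraction_dose(
    d_test: float,
    test: tuple[float, float],
    reference: tuple[float, float],
) -> float:
    """RBE at a given *test* (proton) fraction dose via LQ isoeffect doses.

    ``test`` and ``reference`` are (BED50, α/β) pairs in Gy.  The stated
    fraction dose is the proton one; the photon fraction dose is solved
    at the same (generally non-integer) fraction number:

        n      = BED50_test / (d·(1 + d/αβ_test))
        d_ref  : n·d_ref·(1 + d_ref/αβ_ref) = BED50_ref
        RBE(d) = d_ref / d_test    (= total-dose ratio at equal n)

    As d → 0 this tends to BED50_ref/BED50_test, i.e. to RBE_max.
    """
    if d_test <= 0.0:
        raise ValueError("d_test must be > 0")
    bed50_t, ab_t = test
    bed50_r, ab_r = reference
    n = fractions_for_bed(bed50_t, d_test, LQParams(ab_t))
    d_ref = isoeffective_fraction_dose(bed50_r, n, LQParams(ab_r))
    return d_ref / d_test


def interpolate_rbe_se(
    se_rbe_max: float,
    se_rbe_6fx: float,
    d: float,
    d_6fx: float,
    allow_extrapolation: bool = False,
) -> float:
    """SE of the extrapolated RBE by linear interpolation in fraction dose.

    Interpolates between (0, SE of RBE_max) and (d_6fx, SE of the
    6-fraction RBE).  Requests outside [0, d_6fx] are extrapolations and
    are refused unless explicitly allowed.
    """
    if d_6fx <= 0.0:
        raise ValueError("d_6fx must be > 0")
    if (d < 0.0 or d > d_6fx) and not allow_extrapolation:
        raise ValueError(
            f"d = {d} Gy outside [0, {d_6fx}] Gy: extrapolation of the SE; "
            "pass allow_extrapolation=True to force"
        )
    t = d / d_6fx
    return (1.0 - t) * se_rbe_max + t * se_rbe_6fx


def table2_report(
    positions: Sequence[PositionSummary],
    photon: PhotonReference,
    n_fractions: int = 6,
    correlation: float = 0.0,
) -> pd.DataFrame:
    """Assemble the per-position summary table of all RBE-related estimates.

    One row per proton position (plus a leading photon row): ED50 ± SE
    with RBE, BED50 ± SE with RBE_max, and α/β, each with 90% Fieller
    limits.  Raises if the photon reference is missing.  With an empty
    proton list the photon-only row is returned.
    """
    if photon is None:
        raise ValueError("photon reference is required")
    rows = [
        {
            "study": "photons",
            "let_d": float("nan"),
            "ed50": photon.ed50_6fx.value, "ed50_se": photon.ed50_6fx.se,
            "rbe": float("nan"), "rbe_se": float("nan"),
            "rbe_cl90_lo": float("nan"), "rbe_cl90_hi": float("nan"),
            "bed50": photon.bed50.value, "bed50_se": photon.bed50.se,
            "rbe_max": float("nan"), "rbe_max_se": float("nan"),
            "rbe_max_cl90_lo": float("nan"), "rbe_max_cl90_hi": float("nan"),
            "alpha_beta": photon.alpha_beta.value, "alpha_beta_se": photon.alpha_beta.se,
        }
    ]
    for p in positions:
        r = rbe_from_ed50(photon.ed50_6fx, p.ed50_6fx, correlation=correlation,
                          let_d=p.let_d, n_fractions=n_fractions)
        rm = rbe_max(photon.bed50, p.bed50, correlation=correlation, let_d=p.let_d)
        rows.append(
            {
                "study": f"protons {p.let_d} keV/um",
                "let_d": p.let_d,
                "ed50": p.ed50_6fx.value, "ed50_se": p.ed50_6fx.se,
                "rbe": r.value, "rbe_se": r.se,
                "rbe_cl90_lo": r.cl90.lower, "rbe_cl90_hi": r.cl90.upper,
                "bed50": p.bed50.value, "bed50_se": p.bed50.se,
                "rbe_max": rm.value, "rbe_max_se": rm.se,
                "rbe_max_cl90_lo": rm.cl90.lower, "rbe_max_cl90_hi": rm.cl90.upper,
                "alpha_beta": p.alpha_beta.value, "alpha_beta_se": p.alpha_beta.se,
            }
        )
    return pd.DataFrame(rows)
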