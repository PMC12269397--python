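"""Synthetic per-animal cohorts with the structure the analysis assumes.

Per-animal tolerance data of the spinal-cord experiments are not
published, so every fitting stage is exercised end-to-end on simulated
cohorts that emulate the experimental design: dose groups of 5 animals on
the published dose grids, binary responses drawn from the generalized
(BED) logistic dose-response, log-normal latency times for responders
truncated at the 300-day follow-up horizon, and sporadic exclusions
acting as independent uniform-time censoring.

Ground truth is parametrised as (BED50, α/β, slope-per-BED-Gy); the
per-schedule logistic coefficients follow from the BED algebra, so a
single truth triplet generates consistent 1-, 2- and 6-fraction cohorts.

Randomness is counter-based: each animal owns an RNG seeded by
(seed, position, schedule, dose-level, animal index), so the same seed
reproduces the cohort byte-for-byte and adding groups never perturbs
existing animals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import load_study_summary
from .dose_response import (
    AnimalRecord,
    build_dose_groups,
    ed50,
    fieller_cl,
    fit_generalized,
    fit_logistic,
    bed50_alpha_beta,
    generalized_probability,
)
from .lq import LQParams, isoeffective_fraction_dose

__all__ = [
    "TruthParams",
    "PositionDesign",
    "CohortDesign",
    "default_design",
    "multischedule_design",
    "simulate_cohort",
    "recovery_study",
]

DEFAULT_ANIMALS_PER_GROUP = 5
DEFAULT_N_CONTROLS = 5
DEFAULT_LATENCY_MEDIAN = 150.0  # days
DEFAULT_LATENCY_SIGMA = 0.35  # log-scale SD
DEFAULT_EXCLUSION_RATE = 0.05
DEFAULT_HORIZON = 300.0


@dataclass(frozen=True)
class TruthParams:
    """Generating dose-response truth in the generalized-logistic form.

    ``slope`` is the logit slope per BED-Gy (the b1 of the generalized
    model); b0 = −slope·BED50 and b2 = slope/(α/β) follow.
    """

    bed50: float
    alpha_beta: float
    slope: float

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (-self.slope * self.bed50, self.slope, self.slope / self.alpha_beta)

    def response_probability(self, total_dose: float, n_fractions: int) -> float:
        d = total_dose / n_fractions if total_dose > 0 else 0.0
        b0, b1, b2 = self.coefficients
        return float(generalized_probability(total_dose, d, b0, b1, b2))

    def ed50_for_schedule(self, n_fractions: float) -> float:
        """Total dose with 50% response probability at a given fraction number."""
        d = isoeffective_fraction_dose(self.bed50, n_fractions, LQParams(self.alpha_beta))
        return n_fractions * d

    @classmethod
    def from_ed50(
        cls,
        ed50_value: float,
        alpha_beta: float,
        n_fractions: int = 6,
        slope_total: float = 0.75,
    ) -> "TruthParams":
        """Truth from a schedule-level ED50 and a total-dose logit slope.

        ``slope_total`` (Gy⁻¹, default 0.75: a response rising from ~5% to
        ~95% over ±4 Gy, the steepness typical of the published 6-fraction
        dose grids) is converted to the BED-scale slope via
        dBED/dD = 1 + 2·D/(n·α/β) at the ED50.
        """
        dbed_dd = 1.0 + 2.0 * ed50_value / (n_fractions * alpha_beta)
        slope = slope_total / dbed_dd
        d50 = ed50_value / n_fractions
        bed50 = ed50_value * (1.0 + d50 / alpha_beta)
        return cls(bed50=bed50, alpha_beta=alpha_beta, slope=slope)


@dataclass(frozen=True)
class PositionDesign:
    """Dose grids and generating truth at one irradiation position."""

    position_mm: float
    let_d: float
    dose_levels: dict[int, tuple[float, ...]]  # n_fractions -> total doses (Gy)
    truth: TruthParams

    def __post_init__(self) -> None:
        for n_fx, levels in self.dose_levels.items():
            if n_fx < 1:
                raise ValueError("n_fractions must be >= 1")
            if any(x <= 0 for x in levels):
                raise ValueError("dose levels must be positive")
            if list(levels) != sorted(levels):
                raise ValueError("dose levels must be sorted ascending")


@dataclass(frozen=True)
class CohortDesign:
    """Full experiment design: positions, group size, latency and censoring."""

    positions: tuple[PositionDesign, ...]
    animals_per_group: int = DEFAULT_ANIMALS_PER_GROUP
    n_controls: int = DEFAULT_N_CONTROLS
    latency_median: float = DEFAULT_LATENCY_MEDIAN
    latency_sigma: float = DEFAULT_LATENCY_SIGMA
    exclusion_rate: float = DEFAULT_EXCLUSION_RATE
    horizon: float = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        if self.animals_per_group < 1:
            raise ValueError("animals_per_group must be >= 1")
        if not 0.0 <= self.exclusion_rate <= 1.0:
            raise ValueError("exclusion_rate must lie in [0, 1]")
        if self.horizon <= 0 or self.latency_median <= 0 or self.latency_sigma <= 0:
            raise ValueError("horizon, latency_median and latency_sigma must be > 0")


def default_design(slope_total: float = 0.75) -> CohortDesign:
    """The 6-fraction experiment: 4 SOBP positions, 5 animals per dose level.

    Dose grids are the published ones; the generating truths reproduce
    the published per-position ED50 and α/β.  130 treated animals plus 5
    controls.
    """
    summary = load_study_summary()
    positions = tuple(
        PositionDesign(
            position_mm=p.position_mm,
            let_d=p.let_d,
            dose_levels={6: p.dose_levels_6fx},
            truth=TruthParams.from_ed50(
                p.ed50_6fx.value, p.alpha_beta.value, n_fractions=6, slope_total=slope_total
            ),
        )
        for p in summary.positions
    )
    return CohortDesign(positions=positions)


def multischedule_design(
    bed50: float = 138.0,
    alpha_beta: float = 3.3,
    slope: float = 0.12,
) -> CohortDesign:
    """A 1/2/6-fraction design at one distal position for joint-fit testing.

    The defaults place the 6-fraction ED50 at ~43.3 Gy; the single- and
    split-dose grids bracket the corresponding isoeffective totals.
    """
    truth = TruthParams(bed50=bed50, alpha_beta=alpha_beta, slope=slope)
    pos = PositionDesign(
        position_mm=127.0,
        let_d=5.5,
        dose_levels={
            1: (16.0, 17.5, 19.0, 20.5, 22.0, 23.5),
            2: (23.0, 24.5, 26.0, 27.5, 29.0, 30.5),
            6: (40.0, 41.5, 43.0, 44.5, 46.0, 47.5),
        },
        truth=truth,
    )
    return CohortDesign(positions=(pos,))


def _truncated_lognormal(u: float, median: float, sigma: float, horizon: float) -> float:
    """Inverse-CDF draw from a log-normal conditioned on being <= horizon."""
    mu = math.log(median)
    f_h = stats.norm.cdf((math.log(horizon) - mu) / sigma)
    t = math.exp(mu + sigma * stats.norm.ppf(u * f_h))
    return min(max(t, 1e-6), horizon)


def simulate_cohort(design: CohortDesign, seed: int | Sequence[int]) -> list[AnimalRecord]:
    """Draw one full cohort; deterministic given (design, seed)."""
    base = [int(seed)] if isinstance(seed, (int, np.integer)) else [int(s) for s in seed]
    records: list[AnimalRecord] = []
    for pi, pos in enumerate(design.positions):
        for n_fx in sorted(pos.dose_levels):
            for dose in pos.dose_levels[n_fx]:
                p_resp = pos.truth.response_probability(dose, n_fx)
                # the dose itself (in mGy) keys the stream, so adding or
                # removing other groups never perturbs this one
                dose_key = int(round(dose * 1000))
                for ai in range(design.animals_per_group):
                    rng = np.random.default_rng(base + [pi, n_fx, dose_key, ai])
                    u_excl, t_excl, u_resp, u_lat = rng.random(4)
                    rec = _one_animal(
                        design, f"P{pi}F{n_fx}D{dose_key}A{ai}", pos.position_mm, pos.let_d,
                        n_fx, dose, p_resp, u_excl, t_excl, u_resp, u_lat,
                        cohort=f"{pos.let_d}keV_{n_fx}fx",
                    )
                    records.append(rec)
    # unirradiated controls: response probability from the first position's
    # truth at zero dose (numerically ~0)
    if design.positions and design.n_controls:
        p0 = design.positions[0].truth.response_probability(0.0, 1)
        for ai in range(design.n_controls):
            # fixed stream id for controls, disjoint from any position index
            rng = np.random.default_rng(base + [2**20, 0, 0, ai])
            u_excl, t_excl, u_resp, u_lat = rng.random(4)
            records.append(
                _one_animal(design, f"CTRL{ai}", 0.0, 0.0, 1, 0.0, p0,
                            u_excl, t_excl, u_resp, u_lat, cohort="control")
            )
    return records


def _one_animal(
    design: CohortDesign,
    animal_id: str,
    position_mm: float,
    let_d: float,
    n_fx: int,
    dose: float,
    p_resp: float,
    u_excl: float,
    t_excl: float,
    u_resp: float,
    u_lat: float,
    cohort: str,
) -> AnimalRecord:
    if u_excl < design.exclusion_rate:
        return AnimalRecord(
            animal_id=animal_id, position_mm=position_mm, let_d=let_d,
            n_fractions=n_fx, total_dose=dose, event=False,
            time_days=max(t_excl * design.horizon, 1e-6),
            excluded=True, reason="simulated exclusion", cohort=cohort,
        )
    if u_resp < p_resp:
        t = _truncated_lognormal(u_lat, design.latency_median, design.latency_sigma, design.horizon)
        return AnimalRecord(
            animal_id=animal_id, position_mm=position_mm, let_d=let_d,
            n_fractions=n_fx, total_dose=dose, event=True, time_days=t, cohort=cohort,
        )
    return AnimalRecord(
        animal_id=animal_id, position_mm=position_mm, let_d=let_d,
        n_fractions=n_fx, total_dose=dose, event=False, time_days=design.horizon,
        cohort=cohort,
    )


def recovery_study(
    design: CohortDesign,
    n_replicates: int,
    seed: int,
    level: float = 0.90,
    rate_method: str = "km",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-and-refit validation of the fitting pipeline.

    For each replicate and position: fit the dose-only logistic per
    schedule and record the ED50 with its Fieller interval; when the
    position has ≥2 schedules, also fit the generalized model and record
    BED50 and α/β.  Returns (per-replicate results, summary) where the
    summary reports mean estimate, truth, relative bias, empirical SE and
    Fieller-interval coverage per (position, parameter).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for rep in range(n_replicates):
        records = simulate_cohort(design, seed=[seed, rep])
        for pos in design.positions:
            pos_recs = [r for r in records if r.let_d == pos.let_d and r.total_dose > 0]
            for n_fx in sorted(pos.dose_levels):
                recs = [r for r in pos_recs if r.n_fractions == n_fx]
                groups = build_dose_groups(recs, horizon=design.horizon, method=rate_method)
                try:
                    fit = fit_logistic(groups)
                    est = ed50(fit)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                truth = pos.truth.ed50_for_schedule(n_fx)
                V = fit.covariance
                ci = fieller_cl(
                    (-fit.b0, math.sqrt(V[0, 0])),
                    (fit.b1, math.sqrt(V[1, 1])),
                    correlation=(-V[0, 1]) / math.sqrt(V[0, 0] * V[1, 1]),
                    level=level,
                )
                rows.append({
                    "replicate": rep, "let_d": pos.let_d, "parameter": f"ed50_{n_fx}fx",
                    "estimate": est.value, "se": est.se, "truth": truth,
                    "cl_lo": ci.lower, "cl_hi": ci.upper,
                    "covered": bool(ci.lower <= truth <= ci.upper),
                    "converged": fit.converged,
                })
            if len(pos.dose_levels) >= 2:
                groups = build_dose_groups(pos_recs, horizon=design.horizon, method=rate_method)
                try:
                    gfit = fit_generalized(groups)
                    bed_est, ab_est = bed50_alpha_beta(gfit)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                for name, est, truth in (
                    ("bed50", bed_est, pos.truth.bed50),
                    ("alpha_beta", ab_est, pos.truth.alpha_beta),
                ):
                    lo, hi = est.value - 1.645 * est.se, est.value + 1.645 * est.se
                    rows.append({
                        "replicate": rep, "let_d": pos.let_d, "parameter": name,
                        "estimate": est.value, "se": est.se, "truth": truth,
                        "cl_lo": lo, "cl_hi": hi,
                        "covered": bool(lo <= truth <= hi),
                        "converged": gfit.converged,
                    })
    results = pd.DataFrame(rows)
    if results.empty:
        return results, results
    summary = (
        results.groupby(["let_d", "parameter"])
        .agg(
            mean_estimate=("estimate", "mean"),
            truth=("truth", "first"),
            empirical_se=("estimate", "std"),
            coverage=("covered", "mean"),
            n_fits=("estimate", "size"),
        )
        .reset_index()
    )
    summary["relative_bias"] = summary["mean_estimate"] / summary["truth"] - 1.0
    return results, summary
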