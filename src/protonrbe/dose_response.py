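"""Actuarial preprocessing and maximum-likelihood dose-response fitting.

Quantal (all-or-nothing) radiation tolerance data — here, groups of
animals scored for the binary endpoint "paresis grade 2 within the
follow-up horizon" — are summarised per dose group and fitted with a
logistic dose-response model

    P(D) = exp(b0 + b1·D) / (1 + exp(b0 + b1·D)),          ED50 = −b0/b1,

and, jointly across fractionation schedules, with the generalized
logistic model whose linear predictor is the LQ biologically effective
dose,

    logit P = b0 + b1·D + b2·D·d = b0 + b1·BED,
    BED50 = −b0/b1,   α/β = b1/b2.

Censoring before the horizon is handled actuarially: the response rate of
a group is the complement of the Kaplan-Meier survival of the endpoint at
the horizon, its variance is Greenwood's, and the pair is converted to
*effective* animal and responder counts whose binomial variance matches
the actuarial variance.  These fractional counts enter the Bernoulli
likelihood as real-valued weights — rounding them would discard exactly
the correction they encode.

Ratio uncertainties (ED50, BED50, α/β, RBE) are propagated with the delta
method using the full parameter covariance, and 90% confidence limits for
ratios come from Fieller's theorem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "AnimalRecord",
    "DoseGroup",
    "LogisticFit",
    "GeneralizedFit",
    "ConfidenceInterval",
    "SlopeFit",
    "logistic_probability",
    "generalized_probability",
    "actuarial_rate",
    "effective_sample",
    "build_dose_groups",
    "fit_logistic",
    "fit_generalized",
    "ed50",
    "bed50_alpha_beta",
    "fieller_cl",
    "slope_regression",
]

DEFAULT_HORIZON_DAYS = 300.0
_GRAD_TOL = 1e-8


# ---------------------------------------------------------------------------
# domain types


@dataclass
class AnimalRecord:
    """One animal: dose, schedule, endpoint status and follow-up time."""

    animal_id: str
    position_mm: float
    let_d: float
    n_fractions: int
    total_dose: float
    event: bool
    time_days: float
    excluded: bool = False
    reason: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError(f"time_days must be > 0 ({self.animal_id})")
        if self.total_dose < 0:
            raise ValueError(f"total_dose must be >= 0 ({self.animal_id})")
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be >= 1 ({self.animal_id})")

    @property
    def fraction_dose(self) -> float:
        return self.total_dose / self.n_fractions


@dataclass
class DoseGroup:
    """Per-dose-group summary feeding the binomial likelihood.

    ``n_effective``/``r_effective`` are the fractional counts whose
    binomial variance reproduces ``actuarial_variance``.
    """

    total_dose: float
    fraction_dose: float
    n_treated: int
    actuarial_rate: float
    actuarial_variance: float
    n_effective: float
    r_effective: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.actuarial_rate <= 1.0:
            raise ValueError("actuarial_rate must lie in [0, 1]")
        if self.actuarial_variance < 0.0:
            raise ValueError("actuarial_variance must be >= 0")
        if self.r_effective > self.n_effective + 1e-9:
            raise ValueError("r_effective cannot exceed n_effective")


@dataclass
class LogisticFit:
    """Fitted dose-only logistic model: logit P = b0 + b1·D."""

    b0: float
    b1: float
    covariance: np.ndarray  # 2x2
    log_likelihood: float
    converged: bool
    method: str = "ml"  # "ml" or "firth"
    separation: bool = False


@dataclass
class GeneralizedFit:
    """Fitted BED-logistic model: logit P = b0 + b1·D + b2·D·d."""

    b0: float
    b1: float
    b2: float
    covariance: np.ndarray  # 3x3
    log_likelihood: float
    converged: bool
    method: str = "ml"
    separation: bool = False
    # unconstrained optimum kept for diagnostics when the constrained
    # (log-b2) parametrisation was used
    unconstrained: tuple[float, float, float] | None = None


class ConfidenceInterval(NamedTuple):
    lower: float
    upper: float
    bounded: bool = True


class SlopeFit(NamedTuple):
    slope: float
    intercept: float
    p_value: float
    slope_se: float


class Estimate(NamedTuple):
    """A point estimate with its standard error."""

    value: float
    se: float


# ---------------------------------------------------------------------------
# response models


def logistic_probability(total_dose, b0: float, b1: float):
    """Endpoint probability of the dose-only logistic model."""
    return special.expit(b0 + b1 * np.asarray(total_dose, dtype=float))


def generalized_probability(total_dose, fraction_dose, b0: float, b1: float, b2: float):
    """Endpoint probability of the generalized (BED) logistic model.

    The linear predictor ``b0 + b1·D + b2·D·d`` equals ``b0 + b1·BED``
    with α/β = b1/b2, so the model is a plain logistic in BED.
    """
    D = np.asarray(total_dose, dtype=float)
    d = np.asarray(fraction_dose, dtype=float)
    return special.expit(b0 + b1 * D + b2 * D * d)


# ---------------------------------------------------------------------------
# actuarial machinery


def actuarial_rate(
    records: Sequence[AnimalRecord],
    horizon: float = DEFAULT_HORIZON_DAYS,
    method: str = "km",
    excluded: str = "censor",
) -> tuple[float, float]:
    """Actuarial response rate of a group at the follow-up horizon.

    The rate is ``1 − S(horizon)`` where S is the Kaplan-Meier survival
    of the endpoint; its variance is Greenwood's formula accumulated over
    event times up to the horizon.  With complete follow-up this reduces
    exactly to the crude responder fraction with binomial variance
    ``p(1−p)/n``.

    Parameters
    ----------
    method
        ``"km"`` (product-limit, default) or ``"crude"`` (ignore
        censoring: responder fraction with binomial variance).
    excluded
        ``"censor"`` treats excluded animals as censored at their last
        observation time (default); ``"drop"`` removes them entirely.
    """
    if excluded not in ("censor", "drop"):
        raise ValueError(f"unknown excluded policy {excluded!r}")
    kept = [r for r in records if not (r.excluded and excluded == "drop")]
    if not kept:
        raise ValueError("actuarial_rate needs at least one usable record")

    times = np.array([min(r.time_days, horizon) for r in kept], dtype=float)
    events = np.array(
        [bool(r.event) and not r.excluded and r.time_days <= horizon for r in kept],
        dtype=bool,
    )

    if method == "crude":
        n = len(kept)
        p = events.mean()
        return float(p), float(p * (1.0 - p) / n)
    if method != "km":
        raise ValueError(f"unknown rate method {method!r}")

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = float(kmf.survival_function_at_times(horizon).iloc[0])

    # Greenwood: Var(S) = S² · Σ d_i / (n_i (n_i − d_i)) over event times
    table = kmf.event_table
    acc = 0.0
    for t, row in table.iterrows():
        d_i = float(row["observed"])
        n_i = float(row["at_risk"])
        if d_i > 0 and t <= horizon:
            if n_i - d_i <= 0:
                # all remaining subjects failed: S = 0, variance degenerate
                return 1.0 - surv, 0.0
            acc += d_i / (n_i * (n_i - d_i))
    variance = surv * surv * acc
    return 1.0 - surv, float(variance)


def effective_sample(rate: float, variance: float, n_treated: int) -> tuple[float, float]:
    """Effective animal and responder counts matching an actuarial rate.

    Replaces the observed counts with fractional ones whose binomial
    variance equals the actuarial variance: ``n_eff = p(1−p)/Var``,
    capped at ``n_treated`` (censoring can only lose information).
    Degenerate rates (0 or 1) or zero variance leave the counts at their
    nominal values.
    """
    if variance < 0.0:
        raise ValueError("variance must be >= 0")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if variance == 0.0 or rate in (0.0, 1.0):
        n_eff = float(n_treated)
    else:
        n_eff = min(rate * (1.0 - rate) / variance, float(n_treated))
    return n_eff, n_eff * rate


def build_dose_groups(
    records: Iterable[AnimalRecord],
    horizon: float = DEFAULT_HORIZON_DAYS,
    method: str = "km",
    excluded: str = "censor",
) -> list[DoseGroup]:
    """Group records by (total dose, schedule) and summarise actuarially."""
    by_key: dict[tuple[float, int], list[AnimalRecord]] = {}
    for r in records:
        by_key.setdefault((r.total_dose, r.n_fractions), []).append(r)
    groups = []
    for (dose, n_fx), recs in sorted(by_key.items()):
        usable = [r for r in recs if not (r.excluded and excluded == "drop")]
        if not usable:
            continue
        rate, var = actuarial_rate(recs, horizon=horizon, method=method, excluded=excluded)
        n_eff, r_eff = effective_sample(rate, var, len(usable))
        groups.append(
            DoseGroup(
                total_dose=dose,
                fraction_dose=dose / n_fx,
                n_treated=len(usable),
                actuarial_rate=rate,
                actuarial_variance=var,
                n_effective=n_eff,
                r_effective=r_eff,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# weighted-binomial logistic ML core


def _nll(beta: np.ndarray, X: np.ndarray, n: np.ndarray, r: np.ndarray) -> float:
    eta = X @ beta
    # log(1+e^eta) computed stably; r·log p + (n−r)·log(1−p) = r·eta − n·log(1+e^eta)
    return float(np.sum(n * np.logaddexp(0.0, eta) - r * eta))


def _grad(beta: np.ndarray, X: np.ndarray, n: np.ndarray, r: np.ndarray) -> np.ndarray:
    p = special.expit(X @ beta)
    return X.T @ (n * p - r)


def _information(beta: np.ndarray, X: np.ndarray, n: np.ndarray) -> np.ndarray:
    p = special.expit(X @ beta)
    w = n * p * (1.0 - p)
    return (X * w[:, None]).T @ X


def _logit_linear_init(X: np.ndarray, n: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Weighted least squares on empirical logits (rates clipped away from 0/1)."""
    p = np.clip((r + 0.5) / (n + 1.0), 1e-4, 1.0 - 1e-4)
    z = special.logit(p)
    w = np.maximum(n * p * (1.0 - p), 1e-8)
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
    return beta


def _fit_weighted_logistic(
    X: np.ndarray, n: np.ndarray, r: np.ndarray, n_starts: int = 3
) -> tuple[np.ndarray, np.ndarray, float, bool, bool, str]:
    """Multi-start quasi-Newton ML fit of a weighted-binomial logistic model.

    Returns (beta, covariance, log-likelihood, converged, separation, method).
    Separation (diverging coefficients / singular information) falls back to
    a Firth-type Jeffreys-penalised likelihood, flagged via ``method``.
    """
    init = _logit_linear_init(X, n, r)
    rng = np.random.default_rng(0)  # fixed: perturbed starts, not a stochastic method
    starts = [init]
    for _ in range(n_starts - 1):
        starts.append(init * (1.0 + 0.1 * rng.standard_normal(init.shape)) + 0.1 * rng.standard_normal(init.shape))

    best = None
    for s in starts:
        res = optimize.minimize(
            _nll, s, args=(X, n, r), jac=_grad, method="BFGS",
            options={"gtol": _GRAD_TOL, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    beta = best.x
    gnorm = float(np.linalg.norm(_grad(beta, X, n, r)))

    info = _information(beta, X, n)
    separation = False
    try:
        cond = np.linalg.cond(info)
    except np.linalg.LinAlgError:
        cond = np.inf
    # a perfect fit of all-0/all-1 rates (log-likelihood ~ 0) means the ML
    # optimum lies at infinity and the reported coefficients are arbitrary
    if best.fun < 1e-6 or not np.isfinite(cond) or cond > 1e12 or np.abs(beta).max() > 1e3:
        separation = True

    if separation:
        # Firth-type fallback: penalise with the Jeffreys prior 0.5·log det I(β)
        def pen_nll(b):
            I = _information(b, X, n)
            sign, logdet = np.linalg.slogdet(I + 1e-12 * np.eye(len(b)))
            return _nll(b, X, n, r) - 0.5 * logdet

        res = optimize.minimize(pen_nll, init, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        beta = res.x
        info = _information(beta, X, n)
        cov = np.linalg.pinv(info)
        return beta, cov, -_nll(beta, X, n, r), bool(res.success), True, "firth"

    cov = np.linalg.inv(info)
    # gradient norm scales with the total effective count; judge it relatively
    converged = bool(best.success or gnorm < 1e-6 * max(1.0, float(n.sum())))
    return beta, cov, -best.fun, converged, False, "ml"


def _as_arrays(groups: Sequence[DoseGroup]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    D = np.array([g.total_dose for g in groups], dtype=float)
    d = np.array([g.fraction_dose for g in groups], dtype=float)
    n = np.array([g.n_effective for g in groups], dtype=float)
    r = np.array([g.r_effective for g in groups], dtype=float)
    return D, d, n, r


def fit_logistic(groups: Sequence[DoseGroup]) -> LogisticFit:
    """ML fit of logit P = b0 + b1·D to effective group counts.

    Maximises Σ r_eff·log P + (n_eff − r_eff)·log(1−P); the covariance is
    the inverse observed information at the optimum.
    """
    if len({g.total_dose for g in groups}) < 2:
        raise ValueError("fit_logistic needs >= 2 groups with distinct doses")
    D, _, n, r = _as_arrays(groups)
    X = np.column_stack([np.ones_like(D), D])
    beta, cov, llf, converged, sep, method = _fit_weighted_logistic(X, n, r)
    return LogisticFit(
        b0=float(beta[0]), b1=float(beta[1]), covariance=cov,
        log_likelihood=llf, converged=converged, method=method, separation=sep,
    )


def fit_generalized(groups: Sequence[DoseGroup]) -> GeneralizedFit:
    """Joint ML fit of logit P = b0 + b1·D + b2·D·d across schedules.

    A single global coefficient triplet is shared by all fractionation
    schedules.  Needs groups spanning at least two distinct fraction
    doses, else b2 is unidentifiable.  If the unconstrained optimum has
    b2 ≤ 0, the fit is repeated with b2 = exp(θ) (positivity constraint),
    the covariance mapped back through the Jacobian, and the
    unconstrained coefficients kept for diagnostics.
    """
    schedules = {round(g.total_dose / g.fraction_dose) for g in groups if g.fraction_dose > 0}
    if len(schedules) < 2:
        raise ValueError(
            "fit_generalized needs groups spanning >= 2 fractionation schedules "
            "(b2 is unidentifiable on a single schedule)"
        )
    D, d, n, r = _as_arrays(groups)
    X = np.column_stack([np.ones_like(D), D, D * d])
    beta, cov, llf, converged, sep, method = _fit_weighted_logistic(X, n, r)

    if beta[2] > 0.0:
        return GeneralizedFit(
            b0=float(beta[0]), b1=float(beta[1]), b2=float(beta[2]),
            covariance=cov, log_likelihood=llf, converged=converged,
            method=method, separation=sep,
        )

    # constrained refit with b2 = exp(theta)
    unconstrained = (float(beta[0]), float(beta[1]), float(beta[2]))

    def nll_c(theta):
        b = np.array([theta[0], theta[1], math.exp(theta[2])])
        return _nll(b, X, n, r)

    theta0 = np.array([beta[0], beta[1], math.log(max(abs(beta[2]), 1e-6))])
    res = optimize.minimize(nll_c, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    b2 = math.exp(res.x[2])
    beta_c = np.array([res.x[0], res.x[1], b2])
    info = _information(beta_c, X, n)
    cov_c = np.linalg.pinv(info)
    return GeneralizedFit(
        b0=float(beta_c[0]), b1=float(beta_c[1]), b2=float(b2),
        covariance=cov_c, log_likelihood=-res.fun, converged=bool(res.success),
        method="ml-constrained", separation=sep, unconstrained=unconstrained,
    )


# ---------------------------------------------------------------------------
# derived quantities and uncertainty


def _ratio_delta_var(num: float, den: float, v_nn: float, v_dd: float, v_nd: float) -> float:
    """Delta-method variance of num/den with full covariance."""
    ratio = num / den
    return (v_nn + ratio * ratio * v_dd - 2.0 * ratio * v_nd) / (den * den)


def ed50(fit: LogisticFit) -> Estimate:
    """ED50 = −b0/b1 with delta-method SE using the full 2×2 covariance."""
    if fit.b1 <= 0.0:
        raise ValueError("ED50 undefined for non-increasing response (b1 <= 0)")
    value = -fit.b0 / fit.b1
    V = fit.covariance
    # num = −b0, den = b1: Var(num) = V00, Cov(num, den) = −V01
    var = _ratio_delta_var(-fit.b0, fit.b1, V[0, 0], V[1, 1], -V[0, 1])
    return Estimate(float(value), math.sqrt(max(var, 0.0)))


def bed50_alpha_beta(fit: GeneralizedFit) -> tuple[Estimate, Estimate]:
    """(BED50, α/β) = (−b0/b1, b1/b2) with delta-method SEs (3×3 covariance)."""
    if fit.b1 <= 0.0 or fit.b2 <= 0.0:
        raise ValueError("BED50/α/β require b1 > 0 and b2 > 0")
    V = fit.covariance
    bed50_val = -fit.b0 / fit.b1
    var_bed = _ratio_delta_var(-fit.b0, fit.b1, V[0, 0], V[1, 1], -V[0, 1])
    ab_val = fit.b1 / fit.b2
    var_ab = _ratio_delta_var(fit.b1, fit.b2, V[1, 1], V[2, 2], V[1, 2])
    return (
        Estimate(float(bed50_val), math.sqrt(max(var_bed, 0.0))),
        Estimate(float(ab_val), math.sqrt(max(var_ab, 0.0))),
    )


def fieller_cl(
    numerator: tuple[float, float] | Estimate,
    denominator: tuple[float, float] | Estimate,
    correlation: float = 0.0,
    level: float = 0.90,
) -> ConfidenceInterval:
    """Fieller confidence limits for the ratio of two jointly normal estimates.

    Parameters are (value, se) pairs plus their correlation.  With
    ``g = z²·Var(den)/den² ≥ 1`` the denominator is not significantly
    nonzero and the Fieller set is unbounded; this is signalled through
    ``bounded=False`` with infinite limits, never silently truncated.
    """
    a, se_a = float(numerator[0]), float(numerator[1])
    b, se_b = float(denominator[0]), float(denominator[1])
    if b == 0.0:
        raise ValueError("denominator estimate must be nonzero")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    v11, v22 = se_a * se_a, se_b * se_b
    v12 = correlation * se_a * se_b
    z = stats.norm.ppf(0.5 + level / 2.0)
    g = z * z * v22 / (b * b)
    R = a / b
    if g >= 1.0:
        return ConfidenceInterval(-math.inf, math.inf, bounded=False)
    if v22 > 0.0:
        center = (R - g * v12 / v22) / (1.0 - g)
        inner = v11 - 2.0 * R * v12 + R * R * v22 - g * (v11 - v12 * v12 / v22)
    else:
        center = R
        inner = v11
    half = z / (abs(b) * (1.0 - g)) * math.sqrt(max(inner, 0.0))
    return ConfidenceInterval(center - half, center + half, bounded=True)


def slope_regression(x, y, se_y=None) -> SlopeFit:
    """OLS (or 1/se² weighted) line with a two-sided t-test on the slope."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("slope_regression needs >= 3 points")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope undefined")
    X = sm.add_constant(x)
    if se_y is not None:
        w = 1.0 / np.asarray(se_y, dtype=float) ** 2
        model = sm.WLS(y, X, weights=w)
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    return SlopeFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        slope_se=float(res.bse[1]),
    )
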