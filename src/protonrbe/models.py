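"""Phenomenological variable proton-RBE predictors and model comparison.

The three classic closed-form models — Carabe-Fernandez (CRB), Wedenberg
(WDB) and McNamara (MNM) — express the asymptotic RBE limits as linear
functions of the dose-averaged LET with an (α/β)_x dependence, and
combine them to a dose-dependent RBE through the standard LQ formula
(:func:`protonrbe.lq.rbe_from_max_min`).  Their published coefficients
live in a versioned data file (``data/rbe_models.yaml``): swapping the
file changes predictions without touching code, and user models (e.g. a
constant clinical RBE of 1.1, or an external mechanistic engine) plug in
through :func:`register_model`.

Model ranking against measured RBE values uses the mean and SD of the
signed deviations (predicted − measured), optionally restricted to the
plateau or the spread-out-Bragg-peak (SOBP) region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import yaml

from .lq import rbe_from_max_min

__all__ = [
    "LinearLETForm",
    "RBEModelSpec",
    "PredictionPoint",
    "builtin_models",
    "get_model",
    "available_models",
    "register_model",
    "model_rbe_max_min",
    "predict_rbe",
    "deviation_stats",
    "classify_region",
    "comparison_table",
]

DEFAULT_ALPHA_BETA_X = 2.0  # Gy; reference-radiation alpha/beta used throughout

# LET below this is counted as plateau, at/above as SOBP, when points carry
# no explicit region label (the experiment's plateau position is 1.4 keV/um,
# the SOBP positions 2.7-5.5 keV/um).
PLATEAU_LET_THRESHOLD = 2.0


@dataclass(frozen=True)
class LinearLETForm:
    """``c0 + c1 · f(abx) · LET_d`` with a selectable α/β_x dependence f."""

    c0: float
    c1: float
    abx_form: str = "none"  # none | inverse | scaled_inverse | sqrt
    abx_ref: float = 1.0

    def __call__(self, let_d: float, alpha_beta_x: float) -> float:
        if self.abx_form == "none":
            f = 1.0
        elif self.abx_form == "inverse":
            f = 1.0 / alpha_beta_x
        elif self.abx_form == "scaled_inverse":
            f = self.abx_ref / alpha_beta_x
        elif self.abx_form == "sqrt":
            f = math.sqrt(alpha_beta_x)
        else:
            raise ValueError(f"unknown abx_form {self.abx_form!r}")
        return self.c0 + self.c1 * f * let_d


@dataclass(frozen=True)
class RBEModelSpec:
    """A named predictor of (RBE_max, RBE_min) from (LET_d, α/β_x)."""

    name: str
    citation: str
    max_min: Callable[[float, float], tuple[float, float]]

    def __call__(self, let_d: float, alpha_beta_x: float) -> tuple[float, float]:
        return self.max_min(let_d, alpha_beta_x)


@dataclass
class PredictionPoint:
    """One (model-independent) evaluation point with its measured RBE."""

    let_d: float
    fraction_dose: float
    measured: float
    measured_se: float = float("nan")
    alpha_beta_x: float = DEFAULT_ALPHA_BETA_X
    predicted: dict[str, float] = field(default_factory=dict)
    region: str | None = None  # "plateau" | "sobp"; derived from LET if None


def _forms_spec(name: str, entry: dict) -> RBEModelSpec:
    fm = LinearLETForm(**entry["rbe_max"])
    fn = LinearLETForm(**entry["rbe_min"])

    def max_min(let_d: float, alpha_beta_x: float) -> tuple[float, float]:
        if let_d < 0.0:
            raise ValueError("let_d must be >= 0")
        if alpha_beta_x <= 0.0:
            raise ValueError("alpha_beta_x must be > 0")
        return fm(let_d, alpha_beta_x), fn(let_d, alpha_beta_x)

    return RBEModelSpec(name=name, citation=entry.get("citation", ""), max_min=max_min)


def builtin_models() -> dict[str, RBEModelSpec]:
    """Load the packaged CRB/WDB/MNM coefficient file into model specs."""
    text = resources.files("protonrbe.data").joinpath("rbe_models.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: _forms_spec(name, entry) for name, entry in raw.items()}


_REGISTRY: dict[str, RBEModelSpec] = {}


def _registry() -> dict[str, RBEModelSpec]:
    if not _REGISTRY:
        _REGISTRY.update(builtin_models())
    return _REGISTRY


def available_models() -> list[str]:
    return sorted(_registry())


def get_model(name: str) -> RBEModelSpec:
    try:
        return _registry()[name]
    except KeyError:
        raise KeyError(f"unknown RBE model {name!r}; available: {available_models()}") from None


def register_model(spec: RBEModelSpec) -> None:
    """Add a user model to the registry; duplicate names are refused."""
    reg = _registry()
    if spec.name in reg:
        raise ValueError(f"model {spec.name!r} is already registered")
    # fail fast if the mapping is not callable on (let_d, abx)
    spec.max_min(1.0, DEFAULT_ALPHA_BETA_X)
    reg[spec.name] = spec


def model_rbe_max_min(
    model: RBEModelSpec | str, let_d: float, alpha_beta_x: float = DEFAULT_ALPHA_BETA_X
) -> tuple[float, float]:
    """Asymptotic (RBE_max, RBE_min) of a model at the given LET_d and α/β_x."""
    spec = get_model(model) if isinstance(model, str) else model
    return spec(let_d, alpha_beta_x)


def predict_rbe(
    model: RBEModelSpec | str,
    let_d: float,
    fraction_dose: float,
    alpha_beta_x: float = DEFAULT_ALPHA_BETA_X,
) -> float:
    """Dose-dependent model RBE: max/min limits combined by the LQ formula."""
    m, n = model_rbe_max_min(model, let_d, alpha_beta_x)
    return rbe_from_max_min(fraction_dose, alpha_beta_x, m, n)


def classify_region(let_d: float, threshold: float = PLATEAU_LET_THRESHOLD) -> str:
    return "plateau" if let_d < threshold else "sobp"


def deviation_stats(
    points: Sequence[PredictionPoint],
    model: str,
    region: str | None = None,
) -> tuple[float, float]:
    """Mean and SD of (predicted − measured) RBE over the selected points.

    The mean measures accuracy, the SD the uniformity of the deviations.
    ``region`` may be "plateau" or "sobp" (points without an explicit
    label are classified by LET).  SD uses the sample convention
    (ddof=1); a single point yields SD 0.
    """
    devs = []
    for p in points:
        reg = p.region or classify_region(p.let_d)
        if region is not None and reg != region:
            continue
        if model not in p.predicted:
            raise KeyError(f"point at LET {p.let_d} has no prediction for {model!r}")
        devs.append(p.predicted[model] - p.measured)
    if not devs:
        raise ValueError(f"no prediction points left after region filter {region!r}")
    n = len(devs)
    mean = sum(devs) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in devs) / (n - 1)) if n > 1 else 0.0
    return mean, sd


def comparison_table(
    points: Sequence[PredictionPoint],
    models: Sequence[str] | None = None,
):
    """Evaluate models at every point and return a long-format DataFrame.

    Fills ``point.predicted`` in place and returns one row per
    (model, point) with predicted, measured and deviation.
    """
    import pandas as pd

    names = list(models) if models is not None else available_models()
    rows = []
    for p in points:
        for name in names:
            pred = predict_rbe(name, p.let_d, p.fraction_dose, p.alpha_beta_x)
            p.predicted[name] = pred
            rows.append(
                {
                    "model": name,
                    "let_d": p.let_d,
                    "fraction_dose": p.fraction_dose,
                    "region": p.region or classify_region(p.let_d),
                    "predicted": pred,
                    "measured": p.measured,
                    "measured_se": p.measured_se,
                    "deviation": pred - p.measured,
                }
            )
    return pd.DataFrame(rows)
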