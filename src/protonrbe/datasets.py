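"""Packaged reference summary of the spinal-cord proton tolerance experiment.

Per-animal raw data are not published; what is available are the fitted
group-level summaries — ED50 per position for the 6-fraction schedule,
BED50 and α/β per position from the joint 1/2/6-fraction fit, and the
historical photon reference.  They are shipped as a JSON fixture and are
the deterministic inputs to every ratio-based RBE estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .dose_response import Estimate

__all__ = ["PhotonReference", "PositionSummary", "StudySummary", "load_study_summary"]


@dataclass(frozen=True)
class PhotonReference:
    """Historical photon reference: 6-fraction ED50 plus BED50 and α/β."""

    ed50_6fx: Estimate
    bed50: Estimate
    alpha_beta: Estimate


@dataclass(frozen=True)
class PositionSummary:
    """Fitted summary at one depth position of the spread-out Bragg peak."""

    position_mm: float
    let_d: float
    region: str  # "plateau" or "sobp"
    ed50_6fx: Estimate
    bed50: Estimate
    alpha_beta: Estimate
    dose_levels_6fx: tuple[float, ...] = ()


@dataclass(frozen=True)
class StudySummary:
    photon: PhotonReference
    positions: tuple[PositionSummary, ...]
    horizon_days: float = 300.0

    def position_at_let(self, let_d: float) -> PositionSummary:
        for p in self.positions:
            if abs(p.let_d - let_d) < 1e-9:
                return p
        raise KeyError(f"no position with LET_d = {let_d} keV/µm")

    @property
    def plateau(self) -> PositionSummary:
        return self.positions[0]


def _est(pair) -> Estimate:
    return Estimate(float(pair[0]), float(pair[1]))


def load_study_summary() -> StudySummary:
    """Load the packaged experiment summary (photon reference + 4 LET positions)."""
    text = resources.files("protonrbe.data").joinpath("spinal_cord_summary.json").read_text()
    raw = json.loads(text)
    photon = PhotonReference(
        ed50_6fx=_est(raw["photon"]["ed50_6fx"]),
        bed50=_est(raw["photon"]["bed50"]),
        alpha_beta=_est(raw["photon"]["alpha_beta"]),
    )
    positions = tuple(
        PositionSummary(
            position_mm=float(p["position_mm"]),
            let_d=float(p["let_d"]),
            region=str(p["region"]),
            ed50_6fx=_est(p["ed50_6fx"]),
            bed50=_est(p["bed50"]),
            alpha_beta=_est(p["alpha_beta"]),
            dose_levels_6fx=tuple(float(x) for x in p["dose_levels_6fx"]),
        )
        for p in raw["positions"]
    )
    return StudySummary(photon=photon, positions=positions, horizon_days=float(raw["horizon_days"]))
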