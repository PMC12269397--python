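"""CSV dialects for per-animal and per-group dose-response data.

Two plain-text formats are accepted:

* the per-animal long format (one row per animal) that carries enough
  information for the actuarial machinery, and
* a per-group summary format (treated/responder counts) for data sets
  where only crude rates survive; the actuarial step then degenerates to
  crude binomial rates.

UTF-8, one header row, "." decimal separator.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .dose_response import AnimalRecord, DoseGroup, effective_sample

__all__ = [
    "ANIMAL_COLUMNS",
    "GROUP_COLUMNS",
    "read_animal_csv",
    "write_animal_csv",
    "records_to_frame",
    "frame_to_records",
    "read_group_csv",
]

ANIMAL_COLUMNS = [
    "animal_id",
    "cohort",
    "position_mm",
    "let_kev_um",
    "n_fractions",
    "total_dose_gy",
    "event",
    "time_days",
    "excluded",
    "reason",
]

GROUP_COLUMNS = [
    "position_mm",
    "let_kev_um",
    "n_fractions",
    "total_dose_gy",
    "n_treated",
    "n_responders",
]


def records_to_frame(records: Iterable[AnimalRecord]) -> pd.DataFrame:
    rows = [
        {
            "animal_id": r.animal_id,
            "cohort": r.cohort,
            "position_mm": r.position_mm,
            "let_kev_um": r.let_d,
            "n_fractions": r.n_fractions,
            "total_dose_gy": r.total_dose,
            "event": int(r.event),
            "time_days": r.time_days,
            "excluded": int(r.excluded),
            "reason": r.reason,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ANIMAL_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[AnimalRecord]:
    missing = [c for c in ANIMAL_COLUMNS if c not in frame.columns and c not in ("cohort", "reason")]
    if missing:
        raise ValueError(f"animal table is missing columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                AnimalRecord(
                    animal_id=str(row["animal_id"]),
                    cohort=str(row.get("cohort", "") or ""),
                    position_mm=float(row["position_mm"]),
                    let_d=float(row["let_kev_um"]),
                    n_fractions=int(row["n_fractions"]),
                    total_dose=float(row["total_dose_gy"]),
                    event=bool(int(row["event"])),
                    time_days=float(row["time_days"]),
                    excluded=bool(int(row["excluded"])),
                    reason=str(row.get("reason", "") or ""),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid animal record at data row {i + 1}: {exc}") from exc
    return records


def write_animal_csv(records: Iterable[AnimalRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_animal_csv(path: str | Path) -> list[AnimalRecord]:
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unparseable CSV") from exc
    return frame_to_records(frame)


def read_group_csv(path: str | Path) -> list[tuple[dict, DoseGroup]]:
    """Read per-group summaries; returns (metadata, DoseGroup) pairs.

    Rates are crude (no censoring information survives aggregation), so
    the effective counts equal the observed ones.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unparseable CSV") from exc
    missing = [c for c in GROUP_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"group table is missing columns: {missing}")
    out = []
    for i, row in frame.iterrows():
        n = int(row["n_treated"])
        r = int(row["n_responders"])
        if n < 1 or r < 0 or r > n:
            raise ValueError(f"invalid counts at data row {i + 1}: n={n}, r={r}")
        p = r / n
        var = p * (1.0 - p) / n
        n_eff, r_eff = effective_sample(p, var, n)
        meta = {
            "position_mm": float(row["position_mm"]),
            "let_kev_um": float(row["let_kev_um"]),
            "n_fractions": int(row["n_fractions"]),
        }
        out.append(
            (
                meta,
                DoseGroup(
                    total_dose=float(row["total_dose_gy"]),
                    fraction_dose=float(row["total_dose_gy"]) / int(row["n_fractions"]),
                    n_treated=n,
                    actuarial_rate=p,
                    actuarial_variance=var,
                    n_effective=n_eff,
                    r_effective=r_eff,
                ),
            )
        )
    return out
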