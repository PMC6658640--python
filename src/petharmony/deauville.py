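"""Deauville 5-point scoring of lesion uptake against reference organs.

The hottest lesion is compared to the mediastinal blood pool (DS 2
boundary) and the liver (DS 3/4 boundary); DS 5 is uptake above a
multiple of the liver value (2x by default, 3x is also in circulation).
Equalities resolve to the lower score ("not above reference"), so the
rule is a first-match over L <= M, L <= H, L <= mult*H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .suv import UptakeMeasurement

__all__ = ["DeauvilleResult", "assign_ds", "classify_response", "score_study",
           "scores_table"]


@dataclass
class DeauvilleResult:
    score: int
    metric: str | None = None
    lesion_value: float | None = None
    mediastinum_value: float | None = None
    liver_value: float | None = None
    ds5_multiplier: float = 2.0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError(f"Deauville score must be in 1..5, got {self.score}")
        if self.ds5_multiplier <= 1:
            raise ValueError("ds5_multiplier must be > 1")


def assign_ds(
    lesion: float | None,
    mediastinum: float,
    liver: float,
    multiplier: float = 2.0,
    metric: str | None = None,
) -> DeauvilleResult:
    """Assign a Deauville score from lesion and reference uptake values.

    ``lesion=None`` means no measurable lesion uptake and yields DS 1;
    any measured lesion is compared to the references, so DS 1 is never
    produced by comparison alone. A blood pool hotter than the liver is
    allowed (first-match rules still apply, so H < L <= M scores DS 2)
    but flagged ``mediastinum_exceeds_liver`` since no guideline covers it.
    """
    if mediastinum <= 0 or liver <= 0:
        raise ValueError("reference uptake values must be positive")
    warn = ["mediastinum_exceeds_liver"] if mediastinum > liver else []
    if lesion is None:
        score = 1
    elif lesion <= mediastinum:
        score = 2
    elif lesion <= liver:
        score = 3
    elif lesion <= multiplier * liver:
        score = 4
    else:
        score = 5
    return DeauvilleResult(
        score=score,
        metric=metric,
        lesion_value=lesion,
        mediastinum_value=mediastinum,
        liver_value=liver,
        ds5_multiplier=multiplier,
        warnings=warn,
    )


def classify_response(ds: DeauvilleResult | int, boundary: int = 3) -> str:
    """Dichotomize a score: DS 1..boundary -> responder, else non_responder."""
    score = ds.score if isinstance(ds, DeauvilleResult) else int(ds)
    return "responder" if score <= boundary else "non_responder"


def score_study(
    measurements: dict[str, dict[str, UptakeMeasurement]],
    metric: str = "suv_max",
    multiplier: float = 2.0,
) -> dict[str, DeauvilleResult | None]:
    """Score one study under every reconstruction setting.

    The lesion value is the maximum of the chosen metric over all lesion
    regions (the most intense lesion carries the score). A setting whose
    liver or blood-pool measurement is missing is returned as None.
    """
    out: dict[str, DeauvilleResult | None] = {}
    for profile, per_role in measurements.items():
        liver = per_role.get("liver")
        blood = per_role.get("blood_pool")
        lesion_vals = [
            m.value(metric)
            for role, m in per_role.items()
            if role.startswith("lesion") and m.value(metric) is not None
        ]
        if (
            liver is None or blood is None
            or liver.value(metric) is None or blood.value(metric) is None
        ):
            out[profile] = None
            continue
        lesion = max(lesion_vals) if lesion_vals else None
        out[profile] = assign_ds(
            lesion, blood.value(metric), liver.value(metric),
            multiplier=multiplier, metric=metric,
        )
    return out


def scores_table(
    per_study: dict[str, dict[str, DeauvilleResult | None]],
    boundary: int = 3,
) -> pd.DataFrame:
    """Tidy per-study scoring table (one row per study x setting)."""
    rows = []
    for study_id, per_profile in per_study.items():
        for profile, res in per_profile.items():
            rows.append(
                {
                    "study_id": study_id,
                    "profile": profile,
                    "metric": None if res is None else res.metric,
                    "score": None if res is None else res.score,
                    "response": None if res is None else classify_response(res, boundary),
                    "warnings": "" if res is None else ";".join(res.warnings),
                }
            )
    return pd.DataFrame(rows)
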