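"""Synthetic virtual-patient cohort.

Stands in for an image-derived patient cohort: each virtual patient
carries demographics (sex, age, BMI — metadata only) and a target LV
end-diastolic volume drawn from a truncated normal distribution,
EDV ~ N(117, 30²) mL truncated to [60, 220] mL.  Note that truncation
shifts the distribution's true mean to about 119 mL and shrinks its SD to
about 28 mL; the stated parent parameters are kept as the sampling law.
Sex is assigned by exact count (round(0.6·n) male) rather than Bernoulli
draws so that small cohorts match the 60% male proportion exactly.  The
EDV sets a per-patient geometric scale factor applied to all chamber
reference volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .circulation import CirculationState, HeartModel

__all__ = ["CohortSpec", "VirtualPatient", "generate_cohort", "cohort_manifest"]


@dataclass(frozen=True)
class CohortSpec:
    """Demographic sampling distributions of the virtual cohort."""

    edv_mean: float = 117.0
    edv_sd: float = 30.0
    edv_bounds: tuple[float, float] = (60.0, 220.0)
    male_fraction: float = 0.6
    age_mean: float = 63.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (35.0, 95.0)
    bmi_mean: float = 28.0
    bmi_sd: float = 2.8
    bmi_bounds: tuple[float, float] = (16.0, 45.0)

    def __post_init__(self) -> None:
        if self.edv_sd <= 0 or self.age_sd <= 0 or self.bmi_sd <= 0:
            raise ValueError("standard deviations must be > 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")


@dataclass
class VirtualPatient:
    """One synthetic subject of the in-silico trial."""

    patient_id: str
    sex: str
    age: float
    bmi: float
    edv_target: float
    scale_factor: float
    calibrated_params: Optional[HeartModel] = None
    baseline_state: Optional[CirculationState] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.edv_target <= 0 or self.scale_factor <= 0:
            raise ValueError("edv_target and scale_factor must be > 0")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], n: int
) -> np.ndarray:
    lo, hi = bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_cohort(
    n: int, seed, spec: CohortSpec | None = None
) -> list[VirtualPatient]:
    """Deterministically generate ``n`` virtual patients from a seed.

    The geometric ``scale_factor`` is ``edv_target / 117`` so that the
    default chamber geometry (built for a 117-mL LV) is scaled to each
    patient's target end-diastolic volume.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    edv = _truncated_normal(rng, spec.edv_mean, spec.edv_sd, spec.edv_bounds, n)
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, spec.age_bounds, n)
    bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, spec.bmi_bounds, n)
    n_male = int(round(spec.male_fraction * n))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    width = max(2, len(str(n)))
    return [
        VirtualPatient(
            patient_id=f"P{i + 1:0{width}d}",
            sex=str(sexes[i]),
            age=float(age[i]),
            bmi=float(bmi[i]),
            edv_target=float(edv[i]),
            scale_factor=float(edv[i]) / spec.edv_mean,
        )
        for i in range(n)
    ]


def cohort_manifest(cohort: list[VirtualPatient], seed) -> pd.DataFrame:
    """Tabular cohort manifest (round-trippable as CSV)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "sex": [p.sex for p in cohort],
            "age_y": [p.age for p in cohort],
            "bmi_kg_m2": [p.bmi for p in cohort],
            "edv_target_ml": [p.edv_target for p in cohort],
            "scale_factor": [p.scale_factor for p in cohort],
            "seed": seed,
        }
    )
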