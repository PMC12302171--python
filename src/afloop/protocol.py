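"""The 2x2x2 factorial trial protocol.

Enumerates the eight combinations of heart-rate level (physiological vs
rapid), rhythm regularity (regular vs irregular) and atrial contraction
(effective vs absent), attaches their clinical interpretations (rhythm
control, paced/pharmacologic rate control, untreated AF, ...), and runs
the full cohort-by-scenario grid through the closed-loop model.

Pairing structure: within a patient, the same sampled irregular R-R
sequence is reused across the atrial-contraction arms at the same rate
level, so paired contrasts isolate the factor of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circulation import NotCalibratedError, simulate
from .rhythm import RRDistribution, build_schedule

__all__ = [
    "Scenario",
    "ScenarioResult",
    "enumerate_scenarios",
    "run_scenario",
    "run_factorial",
    "UNTREATED_AF_KEY",
    "RHYTHM_CONTROL_KEY",
]

_RATES = ("physiological", "rapid")
_REGULARITIES = ("regular", "irregular")

# Table-style clinical interpretations of the factorial arms; two rapid
# arms carry none.
_LABELS = {
    ("physiological", "regular", True): "Successfully restored sinus rhythm",
    ("physiological", "regular", False): "Paced rate-controlled AF",
    ("physiological", "irregular", True): "Sinus rhythm with irregularity",
    ("physiological", "irregular", False): "Pharmacologically rate-controlled AF",
    ("rapid", "regular", True): "Exercise",
    ("rapid", "regular", False): "",
    ("rapid", "irregular", True): "",
    ("rapid", "irregular", False): "Rapidly conducted AF",
}

UNTREATED_AF_KEY = "rapid_irregular_no"
RHYTHM_CONTROL_KEY = "physiological_regular_yes"


@dataclass(frozen=True)
class Scenario:
    """One factorial arm."""

    rate: str
    regularity: str
    atrial_contraction: bool
    clinical_label: str = ""

    def __post_init__(self) -> None:
        if self.rate not in _RATES:
            raise ValueError(f"unknown rate level {self.rate!r}")
        if self.regularity not in _REGULARITIES:
            raise ValueError(f"unknown regularity {self.regularity!r}")

    @property
    def key(self) -> str:
        ac = "yes" if self.atrial_contraction else "no"
        return f"{self.rate}_{self.regularity}_{ac}"


@dataclass(frozen=True)
class ScenarioResult:
    """Per-patient endpoint of one factorial cell.

    For regular arms the values come from the final beat; for irregular
    arms they are means over the analysed beats.
    """

    patient_id: str
    scenario: Scenario
    lvef: float
    lvsv: float
    edv: float
    esv: float
    sys_pressure: float
    dia_pressure: float
    n_beats_analyzed: int


def enumerate_scenarios() -> list[Scenario]:
    """All eight factorial arms, in the conventional table order."""
    return [
        Scenario(rate, reg, ac, _LABELS[(rate, reg, ac)])
        for rate in _RATES
        for reg in _REGULARITIES
        for ac in (True, False)
    ]


def _rhythm_seed(master_seed: int, rate: str):
    """Seed of the one irregular R-R sequence used at a rate level.

    One sequence per rate level is shared by the whole cohort and across
    the atrial-contraction arms, so every paired contrast compares
    like-for-like rhythms.
    """
    return np.random.SeedSequence((int(master_seed), _RATES.index(rate)))


def run_scenario(
    patient,
    scenario: Scenario,
    config,
) -> ScenarioResult:
    """Simulate one (patient, scenario) cell and average its endpoint beats."""
    bpm = (
        config.physiological_bpm
        if scenario.rate == "physiological"
        else config.rapid_bpm
    )
    cv = config.rr_cv if scenario.regularity == "irregular" else 0.0
    dist = RRDistribution(mean_bpm=bpm, cv=cv, bounds=tuple(config.rr_bounds))
    seed = _rhythm_seed(config.master_seed, scenario.rate)
    schedule = build_schedule(scenario, dist, config.av_delay_s, seed)
    out = simulate(patient, schedule, scenario, dt=config.dt_s)
    analysed = [out.beats[k] for k in schedule.analysis_beats]
    return ScenarioResult(
        patient_id=patient.patient_id,
        scenario=scenario,
        lvef=float(np.mean([b.ef for b in analysed])),
        lvsv=float(np.mean([b.sv for b in analysed])),
        edv=float(np.mean([b.edv for b in analysed])),
        esv=float(np.mean([b.esv for b in analysed])),
        sys_pressure=float(np.mean([b.sys_p for b in analysed])),
        dia_pressure=float(np.mean([b.dia_p for b in analysed])),
        n_beats_analyzed=len(analysed),
    )


def run_factorial(cohort, config) -> pd.DataFrame:
    """Run every scenario on every calibrated patient.

    Returns a tidy table with one row per (patient, scenario) —
    n_patients x 8 rows — fully deterministic under the master seed.
    Aborts with the list of offenders if any patient is uncalibrated.
    """
    uncalibrated = [
        p.patient_id for p in cohort if getattr(p, "calibrated_params", None) is None
    ]
    if uncalibrated:
        raise NotCalibratedError(
            f"uncalibrated patients in cohort: {uncalibrated}"
        )
    scenarios = enumerate_scenarios()
    rows = []
    for patient in cohort:
        for sc in scenarios:
            r = run_scenario(patient, sc, config)
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "scenario_key": sc.key,
                    "rate": sc.rate,
                    "regularity": sc.regularity,
                    "atrial_contraction": sc.atrial_contraction,
                    "clinical_label": sc.clinical_label,
                    "lvef": r.lvef,
                    "lvsv": r.lvsv,
                    "edv": r.edv,
                    "esv": r.esv,
                    "sys_p": r.sys_pressure,
                    "dia_p": r.dia_pressure,
                    "n_beats_analyzed": r.n_beats_analyzed,
                }
            )
    return pd.DataFrame(rows)
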