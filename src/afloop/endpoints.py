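"""Headline trial endpoints computed from the factorial results table.

Each quantity is the cohort mean of a per-patient (paired) contrast,
matching how the trial reports its effects: stroke-volume changes as
percentages of the within-patient reference, ejection-fraction changes as
absolute percentage points versus untreated AF.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["headline_effects"]

_SR = "physiological_regular_yes"
_AF = "rapid_irregular_no"


def headline_effects(results: pd.DataFrame) -> dict[str, float]:
    """Cohort-mean headline effects of the 2x2x2 factorial trial.

    Expects the tidy per-(patient, scenario) results table produced by
    :func:`afloop.protocol.run_factorial`.
    """
    sv = results.pivot(index="patient_id", columns="scenario_key", values="lvsv")
    ef = results.pivot(index="patient_id", columns="scenario_key", values="lvef")
    if sv.isna().any().any():
        raise ValueError("incomplete factorial results table")

    def sv_drop_vs_sr(key: str) -> float:
        return float((100.0 * (sv[_SR] - sv[key]) / sv[_SR]).mean())

    def ef_gain_vs_af(key: str) -> float:
        return float((ef[key] - ef[_AF]).mean())

    return {
        "rate_sv_drop_pct": sv_drop_vs_sr("rapid_regular_yes"),
        "irregularity_sv_drop_pct": sv_drop_vs_sr("physiological_irregular_yes"),
        "atrial_kick_sv_drop_pct": sv_drop_vs_sr("physiological_regular_no"),
        "rhythm_control_ef_gain_pp": ef_gain_vs_af(_SR),
        "pharm_rate_control_ef_gain_pp": ef_gain_vs_af("physiological_irregular_no"),
        "paced_rate_control_ef_gain_pp": ef_gain_vs_af("physiological_regular_no"),
        "rhythm_control_sv_gain_pct": float(
            (100.0 * (sv[_SR] - sv[_AF]) / sv[_AF]).mean()
        ),
        "sr_with_irregularity_ef_gain_pp": ef_gain_vs_af(
            "physiological_irregular_yes"
        ),
        "baseline_sr_lvef_pct": float(ef[_SR].mean()),
        "untreated_af_lvef_pct": float(ef[_AF].mean()),
    }
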