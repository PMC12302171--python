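"""Per-beat left-ventricular metrics, cohort summaries and paired testing.

The trial endpoint layer: extract EDV/ESV/SV/EF and aortic pressures from
simulated traces, aggregate the patient-by-scenario results table into a
cohort summary (scenario means, percent stroke-volume change and absolute
ejection-fraction change versus untreated AF), and test each management
arm against untreated AF with paired t tests under Bonferroni correction
at alpha = 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BeatMetrics",
    "beat_metrics",
    "paired_t",
    "bonferroni_adjust",
    "summarize_cohort",
    "ALPHA",
]

ALPHA = 0.01


@dataclass(frozen=True)
class BeatMetrics:
    """LV metrics of one cardiac cycle (volumes mL, ef %, pressures mm Hg)."""

    beat_index: int
    edv: float
    esv: float
    sv: float
    ef: float
    sys_p: float
    dia_p: float

    @classmethod
    def from_extrema(
        cls,
        beat_index: int,
        edv: float,
        esv: float,
        sys_p: float,
        dia_p: float,
    ) -> "BeatMetrics":
        sv = edv - esv
        ef = 100.0 * sv / edv if edv > 0 else 0.0
        return cls(beat_index, edv, esv, sv, ef, sys_p, dia_p)


def beat_metrics(
    lv_volume_trace,
    pressure_trace,
    beat_window: tuple[int, int],
    *,
    beat_index: int = 0,
    edv_mode: str = "max",
) -> BeatMetrics:
    """Extract one beat's metrics from sampled LV volume and aortic pressure.

    ``beat_window`` is an index interval [start, stop) spanning one full
    cardiac cycle.  ``edv_mode='max'`` takes the end-diastolic volume as the
    window maximum (appropriate for a generic single-cycle trace);
    ``edv_mode='start'`` takes the value at the window start, which in the
    closed-loop simulation coincides with the instant of ventricular
    activation and attributes diastolic filling to the correct beat in
    irregular rhythms.
    """
    v = np.asarray(lv_volume_trace, dtype=float)
    p = np.asarray(pressure_trace, dtype=float)
    start, stop = beat_window
    if stop <= start or start < 0 or stop > v.size:
        raise ValueError(f"empty or out-of-range beat window {beat_window}")
    if p.shape != v.shape:
        raise ValueError("volume and pressure traces must share shape")
    win = v[start:stop]
    if edv_mode == "max":
        edv = float(win.max())
    elif edv_mode == "start":
        edv = float(v[start])
    else:
        raise ValueError(f"unknown edv_mode {edv_mode!r}")
    esv = float(win.min())
    pwin = p[start:stop]
    return BeatMetrics.from_extrema(
        beat_index, edv, esv, float(pwin.max()), float(pwin.min())
    )


def paired_t(a, b) -> tuple[float, float, float]:
    """Classical paired t test; returns (t, two-sided p, mean of a - b).

    Degenerate conventions: if the paired differences have zero variance,
    p = 1 when they are all zero (identical samples) and p = 0 otherwise
    (a constant nonzero shift, infinitely strong evidence at any n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need 1-d paired samples with n >= 2")
    d = a - b
    mean_diff = float(d.mean())
    if float(d.std(ddof=1)) == 0.0:
        if mean_diff == 0.0:
            return 0.0, 1.0, 0.0
        return math.copysign(math.inf, mean_diff), 0.0, mean_diff
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), mean_diff


def bonferroni_adjust(
    p_values, m: int, *, alpha: float = ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment min(1, m*p) and significance flags at alpha.

    ``m`` is the size of the comparison family and must cover all p-values
    passed in (it may exceed it when the family includes tests reported
    elsewhere).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of p-values {p.size}")
    adjusted = np.minimum(1.0, m * p)
    return adjusted, adjusted < alpha


def summarize_cohort(
    results: pd.DataFrame,
    reference_label: str = "Rapidly conducted AF",
    *,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Cohort summary of the factorial results versus untreated AF.

    ``results`` must hold one row per (patient, scenario) with columns
    ``patient_id``, ``scenario_key``, ``clinical_label``, ``lvsv`` and
    ``lvef``.  For every scenario the summary reports the cohort mean and
    SD of LVSV and LVEF, the per-patient percent LVSV change and absolute
    LVEF change (percentage points) versus the reference scenario — each
    with both the cohort SD and the SEM of the paired differences — and,
    for the labelled management arms, the paired-t p-value against the
    reference with Bonferroni adjustment over that family.
    """
    required = {"patient_id", "scenario_key", "clinical_label", "lvsv", "lvef"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns {sorted(missing)}")

    wide_sv = results.pivot(index="patient_id", columns="scenario_key", values="lvsv")
    wide_ef = results.pivot(index="patient_id", columns="scenario_key", values="lvef")
    if wide_sv.isna().any().any() or wide_ef.isna().any().any():
        raise ValueError("incomplete factorial: missing (patient, scenario) cells")

    labels = (
        results[["scenario_key", "clinical_label"]]
        .drop_duplicates()
        .set_index("scenario_key")["clinical_label"]
        .fillna("")  # unlabeled arms survive CSV round-trips as NaN
    )
    ref_keys = labels.index[labels == reference_label]
    if len(ref_keys) != 1:
        raise ValueError(f"reference scenario {reference_label!r} not found uniquely")
    ref = ref_keys[0]

    # comparison family: the labelled management arms contrasted with the
    # reference in the trial report (everything with a clinical label except
    # the reference itself and the exercise arm, which is not a management
    # strategy)
    family = [
        k
        for k in labels.index
        if labels[k] not in ("", reference_label, "Exercise")
    ]
    m = len(family)

    sv_ref = wide_sv[ref]
    ef_ref = wide_ef[ref]
    rows = []
    raw_p: dict[str, float] = {}
    # deterministic scenario order: as first seen in the results table
    scenario_order = list(dict.fromkeys(results["scenario_key"]))
    for key in scenario_order:
        sv = wide_sv[key]
        ef = wide_ef[key]
        pct_sv = 100.0 * (sv - sv_ref) / sv_ref
        d_ef = ef - ef_ref
        row = {
            "scenario_key": key,
            "clinical_label": labels[key],
            "n_patients": int(sv.size),
            "lvsv_mean_ml": sv.mean(),
            "lvsv_sd_ml": sv.std(ddof=1),
            "lvef_mean_pct": ef.mean(),
            "lvef_sd_pct": ef.std(ddof=1),
            "pct_sv_vs_af_mean": pct_sv.mean(),
            "pct_sv_vs_af_sd": pct_sv.std(ddof=1),
            "pct_sv_vs_af_sem": pct_sv.std(ddof=1) / math.sqrt(pct_sv.size),
            "delta_ef_vs_af_mean_pp": d_ef.mean(),
            "delta_ef_vs_af_sd_pp": d_ef.std(ddof=1),
            "delta_ef_vs_af_sem_pp": d_ef.std(ddof=1) / math.sqrt(d_ef.size),
        }
        if key == ref:
            row["p_raw"] = 1.0
        elif key in family:
            _, p, _ = paired_t(ef.to_numpy(), ef_ref.to_numpy())
            row["p_raw"] = p
            raw_p[key] = p
        else:
            row["p_raw"] = np.nan
        rows.append(row)

    summary = pd.DataFrame(rows)
    adj, sig = bonferroni_adjust([raw_p[k] for k in family], m, alpha=alpha)
    adj_map = dict(zip(family, adj))
    sig_map = dict(zip(family, sig))
    summary["p_adjusted"] = summary["scenario_key"].map(adj_map)
    summary.loc[summary["scenario_key"] == ref, "p_adjusted"] = 1.0
    summary["significant"] = summary["scenario_key"].map(
        lambda k: bool(sig_map.get(k, False))
    )
    summary["bonferroni_m"] = m
    return summary
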