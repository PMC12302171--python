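"""Packaged default parameter values.

These are the package's own reference values for a 117-mL-EDV adult heart
and systemic/pulmonary circulation; they are chosen so that a calibrated
left ventricle operates in the physiologic band (aortic 90–140 / 60–90
mm Hg, LVEF above 50%) at 61 bpm sinus rhythm.  All of them can be
overridden through the run configuration.  Chamber geometric volumes scale
with patient size; vascular properties do not.
"""

from __future__ import annotations

from .cell_dynamics import CalciumParams, TensionParams
from .circulation import ChamberParams, CirculationParams, HeartModel

# reference LV end-diastolic volume (mL) that the default chamber geometry
# corresponds to; per-patient chambers are scaled by edv_target / this value
REFERENCE_EDV_ML = 117.0

AV_DELAY_S = 0.16
DT_S = 1e-3


def ventricular_calcium() -> CalciumParams:
    return CalciumParams(
        chamber_type="ventricular",
        c_dia=0.1,
        c_amp_max=1.05,
        t_peak=0.05,
        tau_decay=0.085,
        rr_half=0.15,
        rr_slope=3.0,
    )


def atrial_calcium() -> CalciumParams:
    # faster transient; much steeper restitution, so the atrial kick fades
    # after short diastolic intervals (irregular rhythm, rapid rates)
    return CalciumParams(
        chamber_type="atrial",
        c_dia=0.1,
        c_amp_max=1.0,
        t_peak=0.035,
        tau_decay=0.075,
        rr_half=0.50,
        rr_slope=6.5,
    )


def ventricular_tension(contraction_enabled: bool = True) -> TensionParams:
    return TensionParams(
        chamber_type="ventricular",
        T_ref=17.5,
        ca50=0.55,
        hill_n=4.0,
        beta_length=14.0,
        k_on=35.0,
        k_off=55.0,
        contraction_enabled=contraction_enabled,
    )


def atrial_tension(contraction_enabled: bool = True) -> TensionParams:
    return TensionParams(
        chamber_type="atrial",
        T_ref=14.5,
        ca50=0.80,
        hill_n=4.0,
        beta_length=3.0,
        k_on=45.0,
        k_off=55.0,
        contraction_enabled=contraction_enabled,
    )


def default_chambers(scale_factor: float = 1.0) -> dict[str, ChamberParams]:
    """Four-chamber parameter set scaled to a patient's heart size."""
    s = scale_factor
    return {
        "LV": ChamberParams(
            chamber_id="LV",
            v_ref=60.0 * s,
            v_wall=130.0 * s,
            k_passive=0.14,
            alpha_passive=4.5,
            tension_params=ventricular_tension(),
            calcium_params=ventricular_calcium(),
        ),
        "RV": ChamberParams(
            chamber_id="RV",
            v_ref=65.0 * s,
            v_wall=45.0 * s,
            k_passive=0.22,
            alpha_passive=4.2,
            tension_params=TensionParams(
                chamber_type="ventricular",
                T_ref=7.5,
                ca50=0.55,
                hill_n=4.0,
                beta_length=14.0,
                k_on=35.0,
                k_off=55.0,
            ),
            calcium_params=ventricular_calcium(),
        ),
        "LA": ChamberParams(
            chamber_id="LA",
            v_ref=26.0 * s,
            v_wall=27.3 * s,
            k_passive=1.5,
            alpha_passive=5.0,
            tension_params=atrial_tension(),
            calcium_params=atrial_calcium(),
        ),
        "RA": ChamberParams(
            chamber_id="RA",
            v_ref=28.0 * s,
            v_wall=22.0 * s,
            k_passive=1.2,
            alpha_passive=5.0,
            tension_params=TensionParams(
                chamber_type="atrial",
                T_ref=9.0,
                ca50=0.80,
                hill_n=4.0,
                beta_length=3.0,
                k_on=45.0,
                k_off=45.0,
            ),
            calcium_params=atrial_calcium(),
        ),
    }


def default_circulation(total_blood_volume: float = 5300.0) -> CirculationParams:
    return CirculationParams(
        r_mitral=0.006,
        r_aortic=0.035,
        r_tricuspid=0.008,
        r_pulmonary=0.018,
        c_sys_art=2.0,
        c_sys_ven=60.0,
        c_pul_art=4.5,
        c_pul_ven=4.0,
        r_sys=1.45,
        r_pul=0.08,
        r_sys_ven_return=0.040,
        r_pul_ven_return=0.012,
        v0_sys_art=450.0,
        v0_sys_ven=2800.0,
        v0_pul_art=100.0,
        v0_pul_ven=350.0,
        total_blood_volume=total_blood_volume,
        av_delay=AV_DELAY_S,
    )


def default_heart_model(
    scale_factor: float = 1.0, total_blood_volume: float = 5300.0
) -> HeartModel:
    return HeartModel(
        chambers=default_chambers(scale_factor),
        circulation=default_circulation(total_blood_volume),
    )
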