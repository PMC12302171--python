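"""Closed-loop lumped-parameter (0D) four-chamber hemodynamics.

Each chamber (LA, LV, RA, RV) is an equivalent thin-walled sphere: fiber
stretch is λ = (V / v_ref)^(1/3), active wall tension follows the reduced
tension model of :mod:`afloop.cell_dynamics`, and cavity pressure is the
sum of an exponential end-diastolic pressure–volume relation and the
Laplace term 2·σ·h/r, which for a sphere of wall volume v_wall reduces to
(2/3)·σ·v_wall/V.  The chambers are connected through four resistive diode
valves into systemic and pulmonary arterial/venous windkessel compartments
(linear compliance, series resistances), closing the loop so that preload
and afterload on every chamber emerge from conservation of a fixed total
blood volume.

Integration is explicit fixed-step Heun (RK2) at dt = 1 ms by default.
Activation events (atrial and ventricular, from a beat schedule) reset the
per-chamber calcium clock; the transient amplitude of each beat is scaled
by calcium restitution in the preceding R-R interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple

import numpy as np
import pandas as pd

from .cell_dynamics import CalciumParams, TensionParams
from .stats import BeatMetrics, beat_metrics

if TYPE_CHECKING:  # pragma: no cover
    from .rhythm import BeatSchedule

__all__ = [
    "ChamberParams",
    "CirculationParams",
    "CirculationState",
    "HeartModel",
    "SimulationOutput",
    "NumericalError",
    "NotCalibratedError",
    "chamber_pressure",
    "build_initial_state",
    "step",
    "simulate_model",
    "simulate",
    "KPA_TO_MMHG",
]

KPA_TO_MMHG = 7.500617
_CHAMBER_ORDER = ("LV", "LA", "RV", "RA")
_VASCULAR_ORDER = ("sys_art", "sys_ven", "pul_art", "pul_ven")


class NumericalError(RuntimeError):
    """Integration produced a non-finite state."""


class NotCalibratedError(RuntimeError):
    """The virtual patient has no calibrated model attached."""


@dataclass(frozen=True)
class ChamberParams:
    """Geometry and material laws of one chamber.

    ``v_ref`` (mL) is the unstressed cavity volume (zero passive pressure),
    ``v_wall`` (mL) the myocardial wall volume, and the passive law is
    P = k_passive · (exp(alpha_passive·(V/v_ref − 1)) − 1), gently negative
    below ``v_ref``.
    """

    chamber_id: str
    v_ref: float
    v_wall: float
    k_passive: float
    alpha_passive: float
    tension_params: TensionParams
    calcium_params: CalciumParams

    def __post_init__(self) -> None:
        if self.chamber_id not in _CHAMBER_ORDER:
            raise ValueError(f"unknown chamber_id {self.chamber_id!r}")
        if self.v_ref <= 0 or self.v_wall <= 0:
            raise ValueError("v_ref and v_wall must be > 0")
        if self.k_passive < 0:
            raise ValueError("k_passive must be >= 0")
        if self.alpha_passive <= 0:
            raise ValueError("alpha_passive must be > 0")


@dataclass(frozen=True)
class CirculationParams:
    """Valves, windkessel compartments and global circulatory constants.

    Resistances in mm Hg·s/mL, compliances in mL/mm Hg, volumes in mL,
    times in s.
    """

    r_mitral: float
    r_aortic: float
    r_tricuspid: float
    r_pulmonary: float
    c_sys_art: float
    c_sys_ven: float
    c_pul_art: float
    c_pul_ven: float
    r_sys: float
    r_pul: float
    r_sys_ven_return: float
    r_pul_ven_return: float
    v0_sys_art: float
    v0_sys_ven: float
    v0_pul_art: float
    v0_pul_ven: float
    total_blood_volume: float
    av_delay: float = 0.16

    def __post_init__(self) -> None:
        for name in (
            "r_mitral", "r_aortic", "r_tricuspid", "r_pulmonary",
            "r_sys", "r_pul", "r_sys_ven_return", "r_pul_ven_return",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("c_sys_art", "c_sys_ven", "c_pul_art", "c_pul_ven"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        v0_sum = (
            self.v0_sys_art + self.v0_sys_ven + self.v0_pul_art + self.v0_pul_ven
        )
        if self.total_blood_volume <= v0_sum:
            raise ValueError(
                "total_blood_volume must exceed the summed unstressed "
                f"vascular volumes ({v0_sum} mL)"
            )
        if self.av_delay < 0:
            raise ValueError("av_delay must be >= 0")


@dataclass(frozen=True)
class HeartModel:
    """One patient's full parameterisation: four chambers plus circulation."""

    chambers: dict[str, ChamberParams]
    circulation: CirculationParams

    def __post_init__(self) -> None:
        if set(self.chambers) != set(_CHAMBER_ORDER):
            raise ValueError(f"chambers must be exactly {_CHAMBER_ORDER}")


@dataclass
class CirculationState:
    """Instantaneous state of the closed loop.

    ``volumes`` holds the four chamber volumes (keys LV/LA/RV/RA) and the
    four vascular compartment volumes (keys sys_art/sys_ven/pul_art/
    pul_ven), all in mL; ``gates`` the four tension activation gates in
    [0, 1]; ``last_activation`` and ``preceding_rr`` the calcium-clock
    bookkeeping per chamber group ('ventricular', 'atrial').
    """

    time: float
    volumes: dict[str, float]
    gates: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in _CHAMBER_ORDER}
    )
    last_activation: dict[str, float | None] = field(
        default_factory=lambda: {"ventricular": None, "atrial": None}
    )
    preceding_rr: dict[str, float] = field(
        default_factory=lambda: {"ventricular": 1.0, "atrial": 1.0}
    )

    def total_volume(self) -> float:
        return float(sum(self.volumes.values()))


def chamber_pressure(volume: float, active_tension: float, params: ChamberParams) -> float:
    """Cavity pressure (mm Hg) from volume (mL) and wall tension (kPa)."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    passive = params.k_passive * math.expm1(
        params.alpha_passive * (volume / params.v_ref - 1.0)
    )
    active = KPA_TO_MMHG * (2.0 / 3.0) * active_tension * params.v_wall / volume
    return passive + active


class _Chamber:
    """Flattened per-chamber constants and mutable calcium-clock state."""

    __slots__ = (
        "v_ref", "k_pass", "alpha", "wall_c", "t_ref",
        "ca50", "inv_beta_term", "beta", "hill_n", "k_on", "k_off",
        "c_dia", "amp_max", "inv_tau_d", "inv_tau_r", "norm",
        "rr_half", "rr_slope",
        "t_act", "amp",
    )

    def __init__(self, p: ChamberParams, enabled: bool):
        tp, cp = p.tension_params, p.calcium_params
        self.v_ref = p.v_ref
        self.k_pass = p.k_passive
        self.alpha = p.alpha_passive
        self.wall_c = KPA_TO_MMHG * (2.0 / 3.0) * p.v_wall
        self.t_ref = tp.T_ref if (enabled and tp.contraction_enabled) else 0.0
        self.ca50 = tp.ca50
        self.beta = tp.beta_length
        self.hill_n = tp.hill_n
        self.k_on = tp.k_on
        self.k_off = tp.k_off
        self.c_dia = cp.c_dia
        self.amp_max = cp.c_amp_max
        self.inv_tau_d = 1.0 / cp.tau_decay
        self.inv_tau_r = 1.0 / cp.tau_rise
        self.norm = cp.peak_norm
        self.rr_half = cp.rr_half
        self.rr_slope = cp.rr_slope
        self.t_act = -1e9
        self.amp = 0.0

    def activate(self, t: float, preceding_rr: float) -> None:
        self.t_act = t
        f = 1.0 / (1.0 + (self.rr_half / preceding_rr) ** self.rr_slope)
        self.amp = self.amp_max * f * self.norm

    def calcium(self, t: float) -> float:
        tsa = t - self.t_act
        if tsa < 0.0 or self.amp == 0.0:
            return self.c_dia
        return self.c_dia + self.amp * (
            math.exp(-tsa * self.inv_tau_d) - math.exp(-tsa * self.inv_tau_r)
        )

    def pressure_and_target(self, t: float, v: float, a: float) -> tuple[float, float]:
        """(cavity pressure mm Hg, gate steady-state target)."""
        ca = self.calcium(t)
        v_eff = max(v, 1e-3 * self.v_ref)  # guard against transient overshoot
        lam = (v_eff / self.v_ref) ** (1.0 / 3.0)
        c50 = self.ca50 * max(0.45, 1.0 - 0.08 * self.beta * (lam - 1.0))
        can = ca ** self.hill_n
        s = can / (can + c50 ** self.hill_n)
        # ascending limb of the length-tension relation (slope > 3 keeps the
        # T/V Laplace term from producing negative volume-stiffness)
        g = min(2.5, max(0.0, 1.0 + self.beta * (lam - 1.0)))
        tension = self.t_ref * a * g
        p = self.k_pass * math.expm1(self.alpha * (v_eff / self.v_ref - 1.0))
        p += tension * self.wall_c / v_eff
        return p, s


def _deriv(t: float, y: tuple, ch: list[_Chamber], c: CirculationParams):
    """Time derivative of (8 volumes, 4 gates); exactly volume-conserving."""
    v_lv, v_la, v_rv, v_ra, v_sa, v_sv, v_pa, v_pv = y[:8]
    a = y[8:]
    p_lv, s_lv = ch[0].pressure_and_target(t, v_lv, a[0])
    p_la, s_la = ch[1].pressure_and_target(t, v_la, a[1])
    p_rv, s_rv = ch[2].pressure_and_target(t, v_rv, a[2])
    p_ra, s_ra = ch[3].pressure_and_target(t, v_ra, a[3])
    p_sa = (v_sa - c.v0_sys_art) / c.c_sys_art
    p_sv = (v_sv - c.v0_sys_ven) / c.c_sys_ven
    p_pa = (v_pa - c.v0_pul_art) / c.c_pul_art
    p_pv = (v_pv - c.v0_pul_ven) / c.c_pul_ven

    q_mv = (p_la - p_lv) / c.r_mitral if p_la > p_lv else 0.0
    q_av = (p_lv - p_sa) / c.r_aortic if p_lv > p_sa else 0.0
    q_sys = (p_sa - p_sv) / c.r_sys
    q_svr = (p_sv - p_ra) / c.r_sys_ven_return
    q_tv = (p_ra - p_rv) / c.r_tricuspid if p_ra > p_rv else 0.0
    q_pv = (p_rv - p_pa) / c.r_pulmonary if p_rv > p_pa else 0.0
    q_pul = (p_pa - p_pv) / c.r_pul
    q_pvr = (p_pv - p_la) / c.r_pul_ven_return

    return (
        q_mv - q_av,          # LV
        q_pvr - q_mv,         # LA
        q_tv - q_pv,          # RV
        q_svr - q_tv,         # RA
        q_av - q_sys,         # sys art
        q_sys - q_svr,        # sys ven
        q_pv - q_pul,         # pul art
        q_pul - q_pvr,        # pul ven
        ch[0].k_on * s_lv * (1.0 - a[0]) - ch[0].k_off * (1.0 - s_lv) * a[0],
        ch[1].k_on * s_la * (1.0 - a[1]) - ch[1].k_off * (1.0 - s_la) * a[1],
        ch[2].k_on * s_rv * (1.0 - a[2]) - ch[2].k_off * (1.0 - s_rv) * a[2],
        ch[3].k_on * s_ra * (1.0 - a[3]) - ch[3].k_off * (1.0 - s_ra) * a[3],
    )


def _heun_step(t: float, y: tuple, dt: float, ch: list[_Chamber], c: CirculationParams):
    k1 = _deriv(t, y, ch, c)
    y1 = tuple(y[i] + dt * k1[i] for i in range(12))
    k2 = _deriv(t + dt, y1, ch, c)
    half = 0.5 * dt
    out = [y[i] + half * (k1[i] + k2[i]) for i in range(12)]
    for i in range(8, 12):  # clamp gates
        if out[i] < 0.0:
            out[i] = 0.0
        elif out[i] > 1.0:
            out[i] = 1.0
    return tuple(out)


def _flows_and_pressures(t: float, y: tuple, ch: list[_Chamber], c: CirculationParams):
    """Diagnostic pressures/flows at one instant (mirrors _deriv)."""
    v_lv, v_la, v_rv, v_ra, v_sa, v_sv, v_pa, v_pv = y[:8]
    a = y[8:]
    p_lv, _ = ch[0].pressure_and_target(t, v_lv, a[0])
    p_la, _ = ch[1].pressure_and_target(t, v_la, a[1])
    p_rv, _ = ch[2].pressure_and_target(t, v_rv, a[2])
    p_ra, _ = ch[3].pressure_and_target(t, v_ra, a[3])
    p_sa = (v_sa - c.v0_sys_art) / c.c_sys_art
    p_sv = (v_sv - c.v0_sys_ven) / c.c_sys_ven
    p_pa = (v_pa - c.v0_pul_art) / c.c_pul_art
    p_pv = (v_pv - c.v0_pul_ven) / c.c_pul_ven
    q_mv = (p_la - p_lv) / c.r_mitral if p_la > p_lv else 0.0
    q_av = (p_lv - p_sa) / c.r_aortic if p_lv > p_sa else 0.0
    q_tv = (p_ra - p_rv) / c.r_tricuspid if p_ra > p_rv else 0.0
    q_pv = (p_rv - p_pa) / c.r_pulmonary if p_rv > p_pa else 0.0
    return {
        "p_lv_mmhg": p_lv, "p_la_mmhg": p_la, "p_rv_mmhg": p_rv, "p_ra_mmhg": p_ra,
        "p_sys_art_mmhg": p_sa, "p_sys_ven_mmhg": p_sv,
        "p_pul_art_mmhg": p_pa, "p_pul_ven_mmhg": p_pv,
        "q_mitral_ml_s": q_mv, "q_aortic_ml_s": q_av,
        "q_tricuspid_ml_s": q_tv, "q_pulmonary_ml_s": q_pv,
    }


def build_initial_state(model: HeartModel, *, mean_rr: float = 1.0) -> CirculationState:
    """A physiologically plausible starting state holding the model's
    total blood volume; the systemic venous reservoir absorbs the slack."""
    circ = model.circulation
    start_p = {"sys_art": 90.0, "pul_art": 14.0, "pul_ven": 9.0}
    volumes: dict[str, float] = {}
    volumes["sys_art"] = circ.v0_sys_art + circ.c_sys_art * start_p["sys_art"]
    volumes["pul_art"] = circ.v0_pul_art + circ.c_pul_art * start_p["pul_art"]
    volumes["pul_ven"] = circ.v0_pul_ven + circ.c_pul_ven * start_p["pul_ven"]
    volumes["LV"] = 1.45 * model.chambers["LV"].v_ref
    volumes["RV"] = 1.45 * model.chambers["RV"].v_ref
    volumes["LA"] = 1.25 * model.chambers["LA"].v_ref
    volumes["RA"] = 1.25 * model.chambers["RA"].v_ref
    assigned = sum(volumes.values())
    v_sv = circ.total_blood_volume - assigned
    if v_sv <= 0:
        raise ValueError("total_blood_volume too small for the requested state")
    volumes["sys_ven"] = v_sv
    return CirculationState(
        time=0.0,
        volumes=volumes,
        preceding_rr={"ventricular": mean_rr, "atrial": mean_rr},
    )


def _state_to_vector(state: CirculationState) -> tuple:
    return tuple(
        [state.volumes[k] for k in _CHAMBER_ORDER]
        + [state.volumes[k] for k in _VASCULAR_ORDER]
        + [state.gates[k] for k in _CHAMBER_ORDER]
    )


def _vector_to_state(t: float, y: tuple, template: CirculationState) -> CirculationState:
    volumes = {k: y[i] for i, k in enumerate(_CHAMBER_ORDER)}
    volumes.update({k: y[4 + i] for i, k in enumerate(_VASCULAR_ORDER)})
    gates = {k: y[8 + i] for i, k in enumerate(_CHAMBER_ORDER)}
    return CirculationState(
        time=t,
        volumes=volumes,
        gates=gates,
        last_activation=dict(template.last_activation),
        preceding_rr=dict(template.preceding_rr),
    )


class SimulationOutput(NamedTuple):
    """Sampled time series, per-beat metrics, and the end-of-run state.

    The final state of a baseline run can seed subsequent scenario runs,
    emulating a patient whose venous reservoirs carry their chronic
    operating point into an acute rhythm change.
    """

    trace: pd.DataFrame
    beats: list[BeatMetrics]
    final_state: CirculationState


def _compiled_chambers(model: HeartModel, atrial_contraction: bool) -> list[_Chamber]:
    return [
        _Chamber(model.chambers["LV"], True),
        _Chamber(model.chambers["LA"], atrial_contraction),
        _Chamber(model.chambers["RV"], True),
        _Chamber(model.chambers["RA"], atrial_contraction),
    ]


def step(
    state: CirculationState,
    model: HeartModel,
    dt: float,
    *,
    atrial_contraction: bool = True,
) -> CirculationState:
    """Advance the closed loop by one explicit step of size ``dt``.

    Activation bookkeeping (``last_activation``, ``preceding_rr``) is taken
    from the state; valves pass flow only down their pressure gradient and
    total blood volume is conserved exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    ch = _compiled_chambers(model, atrial_contraction)
    for group, idxs in (("ventricular", (0, 2)), ("atrial", (1, 3))):
        t_act = state.last_activation[group]
        if t_act is not None:
            for i in idxs:
                ch[i].activate(t_act, state.preceding_rr[group])
    y = _state_to_vector(state)
    y_next = _heun_step(state.time, y, dt, ch, model.circulation)
    if not all(math.isfinite(v) for v in y_next):
        raise NumericalError(f"non-finite state at t={state.time + dt:.4f} s")
    return _vector_to_state(state.time + dt, y_next, state)


def simulate_model(
    model: HeartModel,
    schedule: "BeatSchedule",
    *,
    atrial_contraction: bool = True,
    dt: float = 1e-3,
    record: bool = False,
    initial_state: CirculationState | None = None,
) -> SimulationOutput:
    """Run a beat schedule through the closed loop.

    Returns the sampled time series (always: time, LV volume, LV and aortic
    pressure, total blood volume; with ``record=True``: all compartment
    volumes, pressures, and valve flows), one :class:`BeatMetrics` per
    scheduled beat, and the final circulation state.  Per-beat EDV is the LV volume at the instant of
    ventricular activation; ESV the minimum over that beat's R-R window;
    aortic systolic/diastolic pressures the window extrema.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    circ = model.circulation
    ch = _compiled_chambers(model, atrial_contraction)

    v_times = list(schedule.ventricular_activation_times)
    rr = list(schedule.rr_intervals)
    prec = list(schedule.preceding_intervals)
    events: list[tuple[float, str, float]] = [
        (t, "v", p) for t, p in zip(v_times, prec)
    ]
    if atrial_contraction and schedule.atrial_activation_times is not None:
        events += [
            (t, "a", p) for t, p in zip(schedule.atrial_activation_times, prec)
        ]
    events.sort(key=lambda e: e[0])

    t_end = v_times[-1] + rr[-1]
    n_steps = int(round(t_end / dt))

    if initial_state is None:
        initial_state = build_initial_state(model, mean_rr=schedule.mean_rr)
    y = _state_to_vector(initial_state)

    time = np.empty(n_steps + 1)
    v_lv = np.empty(n_steps + 1)
    p_lv = np.empty(n_steps + 1)
    p_sa = np.empty(n_steps + 1)
    v_tot = np.empty(n_steps + 1)
    full: dict[str, np.ndarray] = {}
    if record:
        keys = [f"v_{k.lower()}_ml" for k in _CHAMBER_ORDER] + [
            f"v_{k}_ml" for k in _VASCULAR_ORDER
        ]
        keys += list(_flows_and_pressures(0.0, y, ch, circ).keys())
        full = {k: np.empty(n_steps + 1) for k in keys}

    def _record(i: int, t: float, yv: tuple) -> None:
        time[i] = t
        v_lv[i] = yv[0]
        v_tot[i] = math.fsum(yv[:8])
        diag = _flows_and_pressures(t, yv, ch, circ)
        p_lv[i] = diag["p_lv_mmhg"]
        p_sa[i] = diag["p_sys_art_mmhg"]
        if record:
            for j, k in enumerate(_CHAMBER_ORDER):
                full[f"v_{k.lower()}_ml"][i] = yv[j]
            for j, k in enumerate(_VASCULAR_ORDER):
                full[f"v_{k}_ml"][i] = yv[4 + j]
            for k, val in diag.items():
                full[k][i] = val

    ev_i = 0
    half = 0.5 * dt
    for i in range(n_steps + 1):
        t = i * dt
        while ev_i < len(events) and events[ev_i][0] <= t + half:
            et, kind, p_rr = events[ev_i]
            idxs = (0, 2) if kind == "v" else (1, 3)
            for j in idxs:
                ch[j].activate(et, p_rr)
            ev_i += 1
        _record(i, t, y)
        if i == n_steps:
            break
        y = _heun_step(t, y, dt, ch, circ)
        if not math.isfinite(y[0]):
            raise NumericalError(f"non-finite LV volume at t={t + dt:.4f} s")

    data = {
        "time_s": time,
        "v_lv_ml": v_lv,
        "p_lv_mmhg": p_lv,
        "p_sys_art_mmhg": p_sa,
        "v_total_ml": v_tot,
    }
    if record:
        for k, arr in full.items():
            if k not in data:
                data[k] = arr
    trace = pd.DataFrame(data)

    metrics: list[BeatMetrics] = []
    for k, (t_k, rr_k) in enumerate(zip(v_times, rr)):
        i0 = int(round(t_k / dt))
        i1 = min(int(round((t_k + rr_k) / dt)) + 1, n_steps + 1)
        metrics.append(
            beat_metrics(v_lv, p_sa, (i0, i1), beat_index=k, edv_mode="start")
        )

    template = initial_state
    final_state = _vector_to_state(n_steps * dt, y, template)
    v_act = [t for t, kind, _ in events if kind == "v" and t <= n_steps * dt]
    a_act = [t for t, kind, _ in events if kind == "a" and t <= n_steps * dt]
    final_state.last_activation = {
        "ventricular": v_act[-1] if v_act else None,
        "atrial": a_act[-1] if a_act else None,
    }
    final_state.preceding_rr = {
        "ventricular": prec[-1] if prec else schedule.mean_rr,
        "atrial": prec[-1] if prec else schedule.mean_rr,
    }
    return SimulationOutput(trace, metrics, final_state)


def simulate(
    patient,
    schedule: "BeatSchedule",
    scenario,
    *,
    dt: float = 1e-3,
    record: bool = False,
) -> SimulationOutput:
    """Simulate one calibrated virtual patient under one trial scenario.

    The run starts from the patient's calibrated baseline circulation
    state when one is attached (the trial protocol), else from the generic
    initial state.
    """
    model = getattr(patient, "calibrated_params", None)
    if model is None:
        raise NotCalibratedError(
            f"patient {getattr(patient, 'patient_id', '?')} is not calibrated"
        )
    state = getattr(patient, "baseline_state", None)
    if state is not None:
        state = CirculationState(
            time=0.0,
            volumes=dict(state.volumes),
            gates=dict(state.gates),
            preceding_rr={"ventricular": schedule.mean_rr, "atrial": schedule.mean_rr},
        )
    return simulate_model(
        model,
        schedule,
        atrial_contraction=scenario.atrial_contraction,
        dt=dt,
        record=record,
        initial_state=state,
    )
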