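"""Chamber-level calcium transients and active tension.

The electromechanical driver of each cardiac chamber is reduced to two
phenomenological pieces:

1. a prescribed intracellular calcium transient — a two-exponential bump
   rising from the diastolic level ``c_dia`` to a peak at ``t_peak`` and
   relaxing with time constant ``tau_decay``.  Beat-to-beat rate dependence
   enters through a *restitution* curve: the transient amplitude is scaled
   by a sigmoidal function of the preceding R-R interval, so short diastolic
   intervals produce weaker transients (the 0D analogue of calcium-handling
   rate dependence in ionic cell models);

2. a reduced Land-style active-tension model — a single activation gate
   driven by Hill-type calcium sensitivity whose half-activation point
   ``ca50`` decreases linearly with fiber stretch.  This carries
   length-dependent activation, and hence the Frank–Starling mechanism,
   into the lumped chamber.

Atrial and ventricular chambers use the same equations with different
parameter sets (the atrial transient is faster and atrial tension weaker).
Setting ``contraction_enabled=False`` on the tension parameters forces the
developed tension to zero everywhere, which is how ineffective atrial
contraction in fibrillation is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CalciumParams",
    "TensionParams",
    "restitution",
    "calcium_transient",
    "active_tension_trace",
    "steady_state_tension",
]

_ATRIAL = "atrial"
_VENTRICULAR = "ventricular"
_CHAMBER_TYPES = (_ATRIAL, _VENTRICULAR)

# floor on the stretch-modulated ca50, as a fraction of the reference value
_CA50_FLOOR = 0.45
# ca50 sensitisation slope as a fraction of beta_length (the tension-scale
# slope); calcium sensitivity varies less steeply with length than peak force
_CA50_SLOPE_RATIO = 0.08
# cap on the ascending-limb tension scale
_LT_CAP = 3.0


@lru_cache(maxsize=64)
def _transient_shape(t_peak: float, tau_decay: float) -> tuple[float, float]:
    """Rise time constant and peak normalisation of the two-exponential bump.

    phi(t) = N * (exp(-t/tau_decay) - exp(-t/tau_rise)) peaks at

        t* = tau_rise * tau_decay / (tau_decay - tau_rise) * ln(tau_decay/tau_rise)

    ``tau_rise`` is solved so that t* equals the requested time to peak
    (which therefore must be strictly below ``tau_decay``); ``N`` scales the
    peak to one.
    """
    if not t_peak < tau_decay:
        raise ValueError(
            f"t_peak ({t_peak}) must be < tau_decay ({tau_decay}) for the "
            "two-exponential transient"
        )

    def peak_time(tau_rise: float) -> float:
        return (
            tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise)
        )

    tau_rise = brentq(
        lambda tr: peak_time(tr) - t_peak,
        1e-9 * tau_decay,
        (1.0 - 1e-9) * tau_decay,
        xtol=1e-12,
    )
    peak_value = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return tau_rise, 1.0 / peak_value


@dataclass(frozen=True)
class CalciumParams:
    """Parameters of the rate-dependent calcium transient of one chamber.

    Units: concentrations in µM, times in s.
    """

    chamber_type: str
    c_dia: float = 0.1
    c_amp_max: float = 1.0
    t_peak: float = 0.06
    tau_decay: float = 0.18
    rr_half: float = 0.35
    rr_slope: float = 3.0

    def __post_init__(self) -> None:
        if self.chamber_type not in _CHAMBER_TYPES:
            raise ValueError(f"unknown chamber_type {self.chamber_type!r}")
        for name in ("c_dia", "c_amp_max", "t_peak", "tau_decay", "rr_half"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rr_slope <= 0:
            raise ValueError("rr_slope must be > 0")
        _transient_shape(self.t_peak, self.tau_decay)  # validates t_peak < tau_decay

    @property
    def tau_rise(self) -> float:
        return _transient_shape(self.t_peak, self.tau_decay)[0]

    @property
    def peak_norm(self) -> float:
        return _transient_shape(self.t_peak, self.tau_decay)[1]


def restitution(preceding_rr, params: CalciumParams):
    """Amplitude restitution factor in (0, 1] for a preceding R-R interval.

    Hill-type sigmoid ``rr^k / (rr^k + rr_half^k)``: monotone non-decreasing
    in the interval, half-maximal at ``rr_half`` and saturating to one for
    long diastolic intervals.
    """
    rr = np.asarray(preceding_rr, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("preceding_rr must be > 0")
    k = params.rr_slope
    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + (params.rr_half / rr) ** k)
    return float(f) if np.isscalar(preceding_rr) else f


def calcium_transient(t_since_activation, preceding_rr: float, params: CalciumParams):
    """Calcium concentration (µM) at times since the last activation.

    The trace starts exactly at ``c_dia``, rises to a single peak at
    ``t_peak`` and decays back with ``tau_decay``; its amplitude is the
    maximal amplitude scaled by the restitution factor of the preceding
    interval.
    """
    t = np.asarray(t_since_activation, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_activation must be >= 0")
    if preceding_rr <= 0:
        raise ValueError("preceding_rr must be > 0")
    amp = params.c_amp_max * restitution(preceding_rr, params) * params.peak_norm
    phi = np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    ca = params.c_dia + amp * phi
    return float(ca) if np.isscalar(t_since_activation) else ca


@dataclass(frozen=True)
class TensionParams:
    """Reduced active-tension model parameters for one chamber.

    ``T_ref`` (kPa) is the tension at full activation; ``ca50`` (µM) the
    half-activation calcium at unit stretch; ``beta_length`` the slope with
    which stretch lowers ``ca50`` (length-dependent activation); ``k_on`` /
    ``k_off`` (1/s) the first-order activation/relaxation rates of the
    single gating variable.
    """

    chamber_type: str
    T_ref: float = 40.0
    ca50: float = 0.55
    hill_n: float = 4.0
    beta_length: float = 1.5
    k_on: float = 35.0
    k_off: float = 20.0
    contraction_enabled: bool = True

    def __post_init__(self) -> None:
        if self.chamber_type not in _CHAMBER_TYPES:
            raise ValueError(f"unknown chamber_type {self.chamber_type!r}")
        if self.T_ref < 0:
            raise ValueError("T_ref must be >= 0")
        if self.ca50 <= 0:
            raise ValueError("ca50 must be > 0")
        if self.hill_n < 1:
            raise ValueError("hill_n must be >= 1")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("k_on and k_off must be > 0")


def effective_ca50(params: TensionParams, stretch) -> np.ndarray | float:
    """Stretch-modulated half-activation calcium (floored at 20% of ca50)."""
    lam = np.asarray(stretch, dtype=float)
    slope = _CA50_SLOPE_RATIO * params.beta_length
    scale = np.maximum(_CA50_FLOOR, 1.0 - slope * (lam - 1.0))
    out = params.ca50 * scale
    return float(out) if np.isscalar(stretch) else out


def _gate_target(calcium, stretch, params: TensionParams):
    ca50 = effective_ca50(params, stretch)
    can = np.power(np.asarray(calcium, dtype=float), params.hill_n)
    return can / (can + np.power(ca50, params.hill_n))


def length_tension_scale(params: TensionParams, stretch):
    """Ascending-limb tension scaling: linear in stretch, clipped to [0, cap].

    The slope must exceed ~3 for a spherical chamber to have positive
    volume-stiffness during contraction (tension enters pressure as T/V and
    V ~ stretch cubed); with the default slope tension vanishes near
    stretch 0.75 and saturates at 2.5x reference.
    """
    lam = np.asarray(stretch, dtype=float)
    g = np.clip(1.0 + params.beta_length * (lam - 1.0), 0.0, _LT_CAP)
    return float(g) if np.isscalar(stretch) else g


def steady_state_tension(calcium: float, stretch: float, params: TensionParams) -> float:
    """Closed-form steady-state tension at fixed calcium and stretch (kPa)."""
    if not params.contraction_enabled:
        return 0.0
    s = float(_gate_target(calcium, stretch, params))
    a = params.k_on * s / (params.k_on * s + params.k_off * (1.0 - s))
    return params.T_ref * a * float(length_tension_scale(params, stretch))


def active_tension_trace(
    calcium_trace,
    stretch_trace,
    params: TensionParams,
    dt: float,
) -> np.ndarray:
    """Integrate the activation gate along sampled calcium/stretch traces.

    Both traces must share length and sampling interval ``dt``; stretch must
    lie in (0.6, 1.6).  Returns the developed tension (kPa), which is
    non-negative everywhere and identically zero when contraction is
    disabled.
    """
    ca = np.asarray(calcium_trace, dtype=float)
    lam = np.asarray(stretch_trace, dtype=float)
    if ca.shape != lam.shape:
        raise ValueError(
            f"calcium trace shape {ca.shape} != stretch trace shape {lam.shape}"
        )
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if np.any((lam <= 0.6) | (lam >= 1.6)):
        raise ValueError("stretch values must lie in (0.6, 1.6)")
    if not params.contraction_enabled:
        return np.zeros_like(ca)

    s = np.atleast_1d(_gate_target(ca, lam, params))
    g = np.atleast_1d(length_tension_scale(params, lam))
    a = 0.0
    tension = np.empty_like(ca)
    for i in range(ca.size):
        si = s[i]
        da = params.k_on * si * (1.0 - a) - params.k_off * (1.0 - si) * a
        a = min(1.0, max(0.0, a + dt * da))
        tension.flat[i] = params.T_ref * a * g[i]
    return tension
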