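"""Calcium-transient shape, restitution, and active-tension properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afloop.cell_dynamics import (
    CalciumParams,
    TensionParams,
    active_tension_trace,
    calcium_transient,
    effective_ca50,
    restitution,
    steady_state_tension,
)
from afloop.defaults import (
    atrial_calcium,
    atrial_tension,
    ventricular_calcium,
    ventricular_tension,
)

ALL_CALCIUM = [ventricular_calcium(), atrial_calcium()]
ALL_TENSION = [ventricular_tension(), atrial_tension()]


class TestCalciumTransient:
    @pytest.mark.parametrize("params", ALL_CALCIUM, ids=["ventricular", "atrial"])
    @pytest.mark.parametrize("rr", [0.4, 0.8, 1.5])
    def test_starts_at_diastolic_level(self, params, rr):
        assert calcium_transient(0.0, rr, params) == pytest.approx(params.c_dia)

    @pytest.mark.parametrize("params", ALL_CALCIUM, ids=["ventricular", "atrial"])
    def test_returns_to_baseline_after_decay(self, params):
        t = params.t_peak + 8.0 * params.tau_decay
        ca = calcium_transient(t, 1.0, params)
        assert abs(ca - params.c_dia) < 0.02 * params.c_dia

    @pytest.mark.parametrize("params", ALL_CALCIUM, ids=["ventricular", "atrial"])
    def test_single_peak_at_t_peak(self, params):
        t = np.linspace(0.0, 1.0, 4001)
        ca = calcium_transient(t, 1.0, params)
        i_peak = int(np.argmax(ca))
        assert t[i_peak] == pytest.approx(params.t_peak, abs=2e-3)
        # single-peaked: non-decreasing before, non-increasing after
        assert np.all(np.diff(ca[: i_peak + 1]) >= -1e-12)
        assert np.all(np.diff(ca[i_peak:]) <= 1e-12)

    def test_amplitude_monotone_in_preceding_interval(self):
        # dense-grid oracle for the restitution monotonicity
        params = ventricular_calcium()
        rr = np.linspace(0.05, 5.0, 800)
        f = restitution(rr, params)
        assert np.all(np.diff(f) >= 0)
        amp_short = calcium_transient(params.t_peak, 0.5, params)
        amp_long = calcium_transient(params.t_peak, 1.2, params)
        assert amp_short < amp_long

    @pytest.mark.parametrize("params", ALL_CALCIUM, ids=["ventricular", "atrial"])
    def test_restitution_range_and_saturation(self, params):
        rr = np.geomspace(1e-3, 100.0, 500)
        f = restitution(rr, params)
        assert np.all(f > 0) and np.all(f <= 1.0)
        assert abs(restitution(1e6, params) - 1.0) < 1e-3

    def test_input_domain_errors(self):
        params = ventricular_calcium()
        with pytest.raises(ValueError):
            calcium_transient(-0.1, 1.0, params)
        with pytest.raises(ValueError):
            calcium_transient(0.1, 0.0, params)
        with pytest.raises(ValueError):
            restitution(-1.0, params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CalciumParams(chamber_type="ventricular", tau_decay=-0.1)
        with pytest.raises(ValueError):
            CalciumParams(chamber_type="ventricular", t_peak=0.3, tau_decay=0.2)
        with pytest.raises(ValueError):
            CalciumParams(chamber_type="sinoatrial")


class TestActiveTension:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        data=st.data(),
        n=st.integers(min_value=2, max_value=50),
    )
    def test_disabled_contraction_is_identically_zero(self, data, n):
        ca = np.array(
            data.draw(
                st.lists(
                    st.floats(min_value=0.0, max_value=5.0),
                    min_size=n,
                    max_size=n,
                )
            )
        )
        lam = np.array(
            data.draw(
                st.lists(
                    st.floats(min_value=0.61, max_value=1.59),
                    min_size=n,
                    max_size=n,
                )
            )
        )
        params = TensionParams(chamber_type="atrial", contraction_enabled=False)
        assert np.all(active_tension_trace(ca, lam, params, 1e-3) == 0.0)
        assert steady_state_tension(2.0, 1.2, params) == 0.0

    @pytest.mark.parametrize("params", ALL_TENSION, ids=["ventricular", "atrial"])
    def test_steady_tension_monotone_in_calcium(self, params):
        ca = np.linspace(0.05, 3.0, 60)
        t = [steady_state_tension(c, 1.1, params) for c in ca]
        assert np.all(np.diff(t) >= -1e-12)
        assert min(t) >= 0.0

    def test_length_dependent_activation(self):
        # closed-form steady-state evaluation at two stretches
        params = ventricular_tension()
        ca = ventricular_calcium()
        peak_ca = ca.c_dia + ca.c_amp_max
        assert steady_state_tension(peak_ca, 1.1, params) > steady_state_tension(
            peak_ca, 1.0, params
        )
        assert effective_ca50(params, 1.1) < effective_ca50(params, 1.0)

    def test_trace_peak_follows_length_dependence(self):
        params = ventricular_tension()
        cp = ventricular_calcium()
        t = np.arange(0.0, 0.8, 1e-3)
        ca = calcium_transient(t, 1.0, cp)
        high = active_tension_trace(ca, np.full_like(t, 1.1), params, 1e-3)
        low = active_tension_trace(ca, np.full_like(t, 1.0), params, 1e-3)
        assert high.max() > low.max()
        assert np.all(high >= 0.0) and np.all(low >= 0.0)

    def test_diastolic_calcium_develops_negligible_tension(self):
        params = ventricular_tension()
        cp = ventricular_calcium()
        t = np.arange(0.0, 1.0, 1e-3)
        ca = np.full_like(t, cp.c_dia)
        tension = active_tension_trace(ca, np.full_like(t, 1.0), params, 1e-3)
        assert tension.max() < 0.01 * params.T_ref

    def test_shape_mismatch_and_domain_errors(self):
        params = ventricular_tension()
        with pytest.raises(ValueError):
            active_tension_trace(np.ones(5), np.ones(4), params, 1e-3)
        with pytest.raises(ValueError):
            active_tension_trace(np.ones(5), np.full(5, 1.7), params, 1e-3)
        with pytest.raises(ValueError):
            active_tension_trace(np.ones(5), np.ones(5), params, 0.0)

    def test_atrial_and_ventricular_parameter_sets_differ(self):
        vc, ac = ventricular_calcium(), atrial_calcium()
        vt, at = ventricular_tension(), atrial_tension()
        # atrial transient is faster and atrial tension weaker
        assert ac.t_peak < vc.t_peak
        assert ac.tau_decay < vc.tau_decay
        assert at.T_ref < vt.T_ref
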