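import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pleiopace.core import (
    APMetrics,
    CellModel,
    GatingParameters,
    IntegrationError,
    ParameterError,
    SimulationResult,
    StepStimulus,
    ap_metrics,
    boltzmann_gate,
    detect_spikes,
    integrate_cell,
)


# ---------------------------------------------------------------------------
# Boltzmann gating
# ---------------------------------------------------------------------------

class TestBoltzmannGate:
    def test_midpoint_is_half(self):
        g = GatingParameters(v_half=-40.0, slope=6.0)
        assert boltzmann_gate(-40.0, g, "activation") == pytest.approx(0.5)
        assert boltzmann_gate(-40.0, g, "inactivation") == pytest.approx(0.5)

    def test_saturation(self):
        g = GatingParameters(v_half=-40.0, slope=6.0)
        assert boltzmann_gate(500.0, g, "activation") == pytest.approx(1.0)
        assert boltzmann_gate(500.0, g, "inactivation") == pytest.approx(0.0)

    def test_threequarter_point(self):
        # closed form: x(v_half + k·ln 3) = 1/(1+1/3) = 3/4
        g = GatingParameters(v_half=-40.0, slope=6.0)
        v = -40.0 + 6.0 * math.log(3.0)
        assert boltzmann_gate(v, g, "activation") == pytest.approx(0.75)

    @given(st.floats(-120, 40), st.floats(-15, 15))
    @settings(max_examples=50, deadline=None)
    def test_offset_shifts_halfpoint_exactly(self, v, off):
        base = GatingParameters(v_half=-35.0, slope=7.5)
        shifted = GatingParameters(v_half=-35.0, slope=7.5, v_off=off)
        assert boltzmann_gate(v, shifted, "activation") == pytest.approx(
            boltzmann_gate(v - off, base, "activation"), abs=1e-12)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ParameterError):
            GatingParameters(v_half=-40.0, slope=-2.0)

    @given(st.floats(-200, 200))
    @settings(max_examples=50, deadline=None)
    def test_range_bounds(self, v):
        g = GatingParameters(v_half=-40.0, slope=4.0)
        for kind in ("activation", "inactivation"):
            assert 0.0 <= boltzmann_gate(v, g, kind) <= 1.0


# ---------------------------------------------------------------------------
# integration engine
# ---------------------------------------------------------------------------

def _leak_cell(g=0.02, e_leak=-70.0, cm=0.2, v0=0.0):
    def rhs(t, y, p, istim):
        return np.array([(-p[0] * (y[0] - p[1]) + istim[0]) / p[2]])

    return CellModel(
        name="leak", kind="neuron", n_comp=1, state_names=("v",),
        param_index={"leak.gbar": 0, "leak.e_rev": 1, "cm": 2},
        params=np.array([g, e_leak, cm]), y0=np.array([v0]), rhs=rhs,
    )


class TestIntegrateCell:
    def test_rc_relaxation_matches_analytic(self):
        g, el, cm, v0 = 0.02, -70.0, 0.2, 0.0
        model = _leak_cell(g, el, cm, v0)
        res = integrate_cell(model, None, 60.0, dt_record=0.5)
        expected = el + (v0 - el) * np.exp(-res.t * g / cm)
        assert np.max(np.abs(res.v - expected)) < 0.1 * 0.001 * abs(el - v0)

    def test_zero_conductance_holds_voltage(self):
        model = _leak_cell(g=0.0, v0=-55.0)
        res = integrate_cell(model, None, 100.0)
        assert np.all(res.v == -55.0)

    def test_bit_reproducible(self, san_mouse):
        r1 = integrate_cell(san_mouse, None, 1500.0, dt_record=0.5)
        r2 = integrate_cell(san_mouse, None, 1500.0, dt_record=0.5)
        assert np.array_equal(r1.y, r2.y)

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            integrate_cell(_leak_cell(), None, 0.0)

    def test_stimulus_depolarizes_leak_cell(self):
        model = _leak_cell(v0=-70.0)
        stim = StepStimulus(0.4, 10.0, 60.0)
        res = integrate_cell(model, stim, 100.0, dt_record=0.1)
        # steady state under current: E + I/g = -70 + 20 mV
        i_mid = np.searchsorted(res.t, 59.0)
        assert res.v[i_mid] == pytest.approx(-50.0, abs=0.5)

    def test_gate_and_concentration_bounds_on_accepted_run(self, san_mouse):
        res = integrate_cell(san_mouse, None, 2000.0, dt_record=0.5)
        gates = res.y[:, list(san_mouse.gate_states)]
        assert gates.min() >= 0.0 and gates.max() <= 1.0
        concs = res.y[:, list(san_mouse.conc_states)]
        assert concs.min() > 0.0


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def _brute_force_crossings(t, v, threshold, refractory):
    times = []
    last = -np.inf
    for i in range(len(v) - 1):
        if v[i] < threshold <= v[i + 1]:
            frac = (threshold - v[i]) / (v[i + 1] - v[i])
            tc = t[i] + frac * (t[i + 1] - t[i])
            if tc - last >= refractory:
                times.append(tc)
                last = tc
    return np.array(times)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        t = np.linspace(0, 1000, 2001)
        v = np.full_like(t, -70.0)
        assert len(detect_spikes(t=t, v=v, threshold=-20.0)) == 0

    def test_three_crossings(self):
        t = np.linspace(0, 300, 3001)
        v = -70 + 60 * (np.sin(2 * np.pi * t / 100.0) > 0.9)
        spikes = detect_spikes(t=t, v=v, threshold=-20.0, refractory=2.0)
        assert len(spikes) == 3

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 200.0, 0.5)
        v = rng.normal(-45.0, 30.0, size=len(t))
        got = detect_spikes(t=t, v=v, threshold=-20.0, refractory=2.0)
        want = _brute_force_crossings(t, v, -20.0, 2.0)
        assert np.allclose(got, want)


# ---------------------------------------------------------------------------
# AP shape metrics
# ---------------------------------------------------------------------------

def _fake_result(t, v):
    return SimpleNamespace(t=np.asarray(t), v=np.asarray(v))


class TestApMetrics:
    def _triangle_train(self, dt=0.05, n_ap=3, period=100.0, base=-80.0,
                        peak=20.0, rise=2.0, fall=6.0):
        t = np.arange(0.0, n_ap * period + 50.0, dt)
        v = np.full_like(t, base)
        for k in range(n_ap):
            t0 = 20.0 + k * period
            up = (t >= t0) & (t < t0 + rise)
            dn = (t >= t0 + rise) & (t < t0 + rise + fall)
            v[up] = base + (peak - base) * (t[up] - t0) / rise
            v[dn] = peak - (peak - base) * (t[dn] - t0 - rise) / fall
        return t, v

    def test_triangular_ap_amplitude_and_width(self):
        t, v = self._triangle_train()
        m = ap_metrics(t=t, v=v)
        assert m.has_ap and m.n_ap == 3
        assert m.peak == pytest.approx(20.0, abs=0.1)
        assert m.mdp == pytest.approx(-80.0, abs=0.1)
        assert m.amplitude == pytest.approx(100.0, abs=0.2)
        # triangle: half level crossed at rise/2 and rise + fall/2
        assert m.half_width == pytest.approx(1.0 + 3.0, rel=0.02)

    def test_cycle_length_from_two_aps(self):
        t, v = self._triangle_train(n_ap=2, period=210.0)
        m = ap_metrics(t=t, v=v)
        assert m.cycle_length == pytest.approx(210.0, abs=0.5)

    def test_no_ap_marker_not_exception(self):
        t = np.linspace(0, 500, 501)
        m = ap_metrics(t=t, v=np.full_like(t, -65.0))
        assert isinstance(m, APMetrics) and not m.has_ap
        assert math.isnan(m.amplitude)

    def test_grid_refinement_invariance(self):
        coarse = self._triangle_train(dt=0.1)
        fine = self._triangle_train(dt=0.01)
        mc = ap_metrics(t=coarse[0], v=coarse[1])
        mf = ap_metrics(t=fine[0], v=fine[1])
        assert mc.half_width == pytest.approx(mf.half_width, rel=0.03)
        assert mc.apd90 == pytest.approx(mf.apd90, rel=0.03)
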