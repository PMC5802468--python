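import numpy as np
import pytest

from pleiopace.tissue import (
    CableConfig,
    PropagationResult,
    TissueConfig,
    TissueError,
    conduction_velocity,
    detect_exit_block,
    diffusion_step,
    simulate_cable,
)


class TestCableConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            CableConfig(n_cells=5)
        with pytest.raises(ValueError):
            CableConfig(diffusion=-1.0)
        with pytest.raises(ValueError):
            CableConfig(clamp_fraction=1.5)


class TestCablePropagation:
    def test_zero_diffusion_means_no_propagation(self, san_rabbit):
        # quiescent-cell chain: without coupling the unclamped cells stay
        # silent within the observation window
        quiet = san_rabbit.with_params({"b.e_rev": -60.0, "hcn.gbar": 0.0,
                                        "cal13.gbar": 0.002,
                                        "cat.gbar": 0.002})
        cfg = CableConfig(n_cells=20, diffusion=0.0, v_pre=-78.0,
                          duration=400.0)
        res = simulate_cable(cfg, quiet)
        n_clamp = int(res.clamped.sum())
        assert np.all(np.isnan(res.activation_times[n_clamp:]))

    def test_activation_affine_in_position(self, san_rabbit):
        quiet = san_rabbit.with_params({"b.e_rev": -60.0, "hcn.gbar": 0.0,
                                        "cal13.gbar": 0.002,
                                        "cat.gbar": 0.002})
        cfg = CableConfig(n_cells=60, v_pre=-78.0, duration=600.0)
        res = simulate_cable(cfg, quiet)
        act, pos = res.activation_times, res.positions
        sel = slice(20, 45)
        coef = np.polyfit(act[sel], pos[sel], 1)
        pred = np.polyval(coef, act[sel])
        ss_res = np.sum((pos[sel] - pred) ** 2)
        ss_tot = np.sum((pos[sel] - pos[sel].mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.99

    def test_velocity_robust_to_clamp_fraction(self, san_rabbit):
        quiet = san_rabbit.with_params({"b.e_rev": -60.0, "hcn.gbar": 0.0,
                                        "cal13.gbar": 0.002,
                                        "cat.gbar": 0.002})
        cvs = []
        for frac in (0.18, 0.2, 0.22):
            cfg = CableConfig(n_cells=60, v_pre=-78.0, duration=600.0,
                              clamp_fraction=frac)
            res = simulate_cable(cfg, quiet)
            cvs.append(conduction_velocity(res, cell_range=(25, 42)))
        assert max(cvs) / min(cvs) - 1.0 < 0.05


def _synthetic_prop(v, positions, clamped=None):
    n = len(positions)
    return PropagationResult(
        t=np.arange(10.0), v_probes=np.zeros((10, 1)), probe_labels=("p",),
        positions=np.asarray(positions, float),
        activation_times=np.asarray(v, float),
        clamped=np.zeros(n, bool) if clamped is None else clamped,
    )


class TestConductionVelocity:
    def test_exact_on_linear_activation(self):
        pos = np.arange(30) * 70.0
        act = pos / 120.0   # v = 120 µm/ms
        res = _synthetic_prop(act, pos)
        assert conduction_velocity(res, cell_range=(2, 28)) == pytest.approx(120.0)

    def test_reversed_wave_gives_negative_equal_speed(self):
        pos = np.arange(30) * 70.0
        act = (pos[-1] - pos) / 120.0
        res = _synthetic_prop(act, pos)
        v = conduction_velocity(res, cell_range=(2, 28))
        assert v == pytest.approx(-120.0)

    def test_mixed_propagation_rejected(self):
        pos = np.arange(30) * 70.0
        act = np.abs(pos - pos[15]) / 100.0   # collision pattern
        res = _synthetic_prop(act, pos)
        with pytest.raises(TissueError):
            conduction_velocity(res, cell_range=(2, 28))

    def test_too_few_points_rejected(self):
        pos = np.arange(30) * 70.0
        act = np.full(30, np.nan)
        act[:3] = [0.0, 1.0, 2.0]
        with pytest.raises(TissueError):
            conduction_velocity(_synthetic_prop(act, pos))


class TestDiffusionStep:
    def test_no_flux_conserves_total_charge(self, rng):
        V = rng.normal(-60.0, 20.0, size=(40, 40))
        d = np.where(rng.random((40, 40)) < 0.3, 0.2, 1.0) * 1.2e-3
        dfx = np.zeros_like(V)
        dfy = np.zeros_like(V)
        dfx[:, :-1] = 0.5 * (d[:, :-1] + d[:, 1:])
        dfy[:-1, :] = 0.5 * (d[:-1, :] + d[1:, :])
        out = diffusion_step(V, dfx, dfy, 0.125, 0.04)
        assert np.sum(out) == pytest.approx(np.sum(V), rel=1e-13)

    def test_uniform_field_is_fixed_point(self):
        V = np.full((20, 20), -70.0)
        dfx = np.full((20, 20), 1e-3)
        dfy = np.full((20, 20), 1e-3)
        out = diffusion_step(V, dfx, dfy, 0.1, 0.04)
        assert np.array_equal(out, V)


class TestDetectExitBlock:
    def _prop(self, san_times, atrial_times, t_end=5000.0):
        return PropagationResult(
            t=np.arange(0.0, t_end, 1.0),
            v_probes=np.zeros((int(t_end), 1)), probe_labels=("p",),
            san_cycles=np.asarray(san_times, float),
            atrial_activations=np.asarray(atrial_times, float),
        )

    def test_one_to_one_conduction_gives_no_events(self):
        san = np.arange(600.0, 4000.0, 400.0)
        atr = san + 30.0
        rep = detect_exit_block(self._prop(san, atr))
        assert rep.events == ()
        assert np.allclose(rep.intervals, 400.0)

    def test_three_to_two_pattern_flags_every_third(self):
        san = np.arange(600.0, 4000.0, 300.0)
        atr = np.array([t + 25.0 for i, t in enumerate(san) if i % 3 != 2])
        rep = detect_exit_block(self._prop(san, atr), window=150.0)
        expected = [t for i, t in enumerate(san)
                    if i % 3 == 2 and t + 150.0 <= 4999.0]
        assert list(rep.events) == pytest.approx(expected)

    def test_brute_force_event_count(self, rng):
        san = np.sort(rng.uniform(600, 4500, size=12))
        atr = san[rng.random(12) < 0.6] + 20.0
        rep = detect_exit_block(self._prop(san, atr), window=100.0)
        brute = sum(1 for tc in san
                    if tc + 100.0 <= 4999.0
                    and not np.any((atr >= tc) & (atr <= tc + 100.0)))
        assert len(rep.events) == brute

    def test_silencing_flag(self):
        rep = detect_exit_block(self._prop([], []))
        assert rep.silenced


class TestTissueConfigValidation:
    def test_radius_must_fit(self):
        with pytest.raises(ValueError):
            TissueConfig(san_radius_cm=2.0)

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError):
            TissueConfig(dt=5.0)
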