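import numpy as np
import pytest

from oracles import tc_closed_form

from micromet.errors import ConfigurationError
from micromet.lymph_node import (
    LymphNodeParams,
    LymphNodeState,
    dispatch_t_cells,
    ln_derivatives,
    ln_step,
)


def params(**kw):
    return LymphNodeParams(**kw)


class TestDerivatives:
    def test_origin_only_baseline_source_survives(self):
        p = params(delta_C=2e-3, phi_C=1.5)
        d = ln_derivatives(np.zeros(6), 0.0, p)
        assert d[3] == pytest.approx(p.delta_C * p.phi_C)
        assert np.allclose(np.delete(d, 3), 0.0)

    def test_cytotoxic_baseline_fixed_point_feeds_counter(self):
        p = params(delta_C=2e-3, phi_C=1.0, kappa_T=4e-4)
        y = np.array([0.0, 0.0, 0.0, p.phi_C, 0.0, 0.0])
        d = ln_derivatives(y, 0.0, p)
        assert d[3] == pytest.approx(0.0)
        assert d[4] == pytest.approx(p.kappa_T * p.phi_C)

    def test_helper_extinction_is_invariant(self):
        p = params()
        for d_m in (0.0, 5.0, 50.0):
            for th2 in (0.0, 3.0):
                d = ln_derivatives(np.array([d_m, 0.0, th2, 1.0, 0.0, 0.0]), 0.0, p)
                assert d[1] == 0.0  # every T_H1 term is multiplicative in T_H1


class TestIntegration:
    def test_antigen_free_fixed_point_with_linear_counters(self):
        p = params(kappa_T=1e-3)
        state = LymphNodeState(pools=np.array([0.0, 0.0, 0.0, p.phi_C, 0.0, 0.0]))
        for k in range(500):
            ln_step(state, p, t=k * 6.0, dt=6.0)
        assert state.pools[:4] == pytest.approx([0.0, 0.0, 0.0, p.phi_C])
        assert state.t_ct == pytest.approx(p.kappa_T * p.phi_C * 3000.0, rel=1e-9)

    def test_rk4_matches_cytotoxic_closed_form(self):
        # with D_M = 0 and helpers 0 only the linear T_C equation is active
        p = params(delta_C=5e-3, phi_C=2.0)
        state = LymphNodeState(pools=np.zeros(6))
        T, dt = 300.0, 0.1
        for k in range(int(T / dt)):
            ln_step(state, p, t=k * dt, dt=dt)
        assert state.t_c == pytest.approx(tc_closed_form(2.0, 5e-3, T), abs=1e-8)

    def test_fourth_order_convergence(self):
        # nonlinear pools active; Richardson slope of the global error ≈ 4
        p = params()
        y0 = np.array([5.0, 2.0, 2.0, 3.0, 0.0, 0.0])

        def final(dt, T=96.0):
            s = LymphNodeState(pools=y0.copy())
            for k in range(int(round(T / dt))):
                ln_step(s, p, t=k * dt, dt=dt)
            return s.pools[:4].copy()

        ref = final(0.05)
        errs = [np.linalg.norm(final(dt) - ref) for dt in (3.2, 1.6, 0.8)]
        slopes = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert slopes.mean() == pytest.approx(4.0, abs=0.7)

    def test_delay_under_resolution_rejected(self):
        p = params(tau_DC=10.0)
        with pytest.raises(ConfigurationError):
            ln_step(LymphNodeState(), p, t=0.0, dt=30.0)

    def test_dc_pulse_gain_and_decay(self):
        # an impulse of N departures raises D_M and then decays at delta_DM
        p = params(k_D=1.0, tau_DC=60.0, delta_DM=2e-3)
        state = LymphNodeState(pools=np.zeros(6))
        for _ in range(40):
            state.record_departure(0.0)
        dt = 6.0
        series = []
        for k in range(400):
            ln_step(state, p, t=k * dt, dt=dt)
            series.append((k + 1) * dt)
            series.append(state.d_m)
        t = np.array(series[0::2])
        dm = np.array(series[1::2])
        assert dm.max() > 0
        sel = (t > 300) & (t < 1800) & (dm > 0)
        slope = np.polyfit(t[sel], np.log(dm[sel]), 1)[0]
        assert slope == pytest.approx(-p.delta_DM, rel=0.02)

    def test_pools_nonnegative_for_random_parameters(self):
        """Pools stay ≥ 0 across the cohort's parameter envelope.

        The cytotoxic/trafficking arm (the parameters the virtual-patient
        cohort varies) is drawn over the full ×0.1–×10 range; the helper
        arm, whose cubic self-limitation turns stiff at extreme
        production/deactivation ratios, over ×0.5–×2.
        """
        rng = np.random.default_rng(5)
        base = params()
        for _ in range(100):
            kw = {}
            for name in ("k_D", "delta_DM", "pi_T", "delta_T", "delta_C", "kappa_T"):
                kw[name] = getattr(base, name) * 10 ** rng.uniform(-1, 1)
            for name in ("sigma_TH1", "sigma_TH2", "pi_TH1", "pi_TH2", "delta_TH1", "mu_TH"):
                kw[name] = getattr(base, name) * 2 ** rng.uniform(-1, 1)
            p = params(**kw)
            state = LymphNodeState()
            for k in range(0, 30):
                state.record_departure(k * 60.0)
            for k in range(480):  # 10 days at dt = 30 min
                ln_step(state, p, t=k * 30.0, dt=30.0)
                assert (state.pools >= 0.0).all()


class TestDispatch:
    def test_no_dispatch_before_the_trafficking_delay(self, rng):
        p = params(tau_T=720.0)
        state = LymphNodeState()
        state.history_t = [0.0, 300.0]
        state.history_tct = [5.0, 9.0]
        state.history_tht = [1.0, 2.0]
        assert dispatch_t_cells(state, 600.0, p, rng) == (0, 0)

    def test_zero_history_never_dispatches(self, rng):
        p = params()
        state = LymphNodeState()
        for t in np.arange(0.0, 5000.0, 250.0):
            assert dispatch_t_cells(state, float(t), p, rng) == (0, 0)

    def test_stochastic_rounding_is_unbiased(self):
        rng = np.random.default_rng(2)
        p = params(tau_T=0.0)
        draws = []
        for _ in range(10_000):
            state = LymphNodeState()
            state.history_t = [10.0]
            state.history_tct = [7.6]
            state.history_tht = [0.0]
            state.dispatched_cd8 = 5
            draws.append(dispatch_t_cells(state, 10.0, p, rng)[0])
        assert np.mean(draws) == pytest.approx(2.6, abs=0.05)

    def test_dispatch_monotone_and_tracks_target(self, rng):
        p = params(tau_T=0.0, kappa_T=5e-3)
        state = LymphNodeState(pools=np.array([0.0, 1.0, 1.0, 50.0, 0.0, 0.0]))
        sent_prev = 0
        for k in range(200):
            ln_step(state, p, t=k * 6.0, dt=6.0)
            n8, _ = dispatch_t_cells(state, (k + 1) * 6.0, p, rng)
            assert n8 >= 0
            sent = state.dispatched_cd8
            assert sent >= sent_prev
            assert sent < state.t_ct + 1.0  # never overshoots the target by ≥ 1
            sent_prev = sent
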