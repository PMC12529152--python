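"""Cultivation kinetics: rate laws, events, integration and recovery."""

import numpy as np
import pandas as pd
import pytest

from evtwin import cultivation as cult
from evtwin.cultivation import (COLLECT_PARAMS, GROWTH_PARAMS, CultureState,
                                KineticParams, PhaseSchedule,
                                fit_kinetic_params, glucose_rate,
                                particles_from_product, product_from_particles,
                                simulate_cultivation, specific_death_rate,
                                specific_growth_rate)


class TestRateLaws:
    def test_growth_rate_saturates_at_mu_max(self):
        assert specific_growth_rate(1e9, 0.0, GROWTH_PARAMS) == pytest.approx(
            0.039, rel=1e-6)

    def test_growth_rate_half_saturation(self):
        # Glc = K_Glc, no lactate -> mu_max/2
        mu = specific_growth_rate(GROWTH_PARAMS.K_glc, 0.0, GROWTH_PARAMS)
        assert mu == pytest.approx(GROWTH_PARAMS.mu_max / 2)

    def test_growth_rate_lactate_inhibition_half_point(self):
        mu = specific_growth_rate(1e9, GROWTH_PARAMS.K_i_lac, GROWTH_PARAMS)
        assert mu == pytest.approx(GROWTH_PARAMS.mu_max / 2, rel=1e-6)

    def test_growth_rate_zero_glucose(self):
        assert specific_growth_rate(0.0, 0.0, GROWTH_PARAMS) == 0.0

    def test_growth_rate_rejects_negative(self):
        with pytest.raises(ValueError):
            specific_growth_rate(-1.0, 0.0, GROWTH_PARAMS)

    def test_death_rate_at_exchange_equals_lag_max(self):
        # no lactate, t = 0 after media exchange: only the stress term
        assert specific_death_rate(0.0, 0.0, COLLECT_PARAMS) == pytest.approx(0.04)

    def test_death_rate_mixed_half_points(self):
        # Lac = K_DLac and t = K_Mlag: each term at half its maximum
        mu_d = specific_death_rate(45.8, 160.0, COLLECT_PARAMS)
        assert mu_d == pytest.approx(0.004 / 2 + 0.04 / 2)

    def test_death_rate_limit_is_k_d(self):
        mu_d = specific_death_rate(1e12, 1e12, COLLECT_PARAMS)
        assert mu_d == pytest.approx(COLLECT_PARAMS.k_d, rel=1e-6)

    def test_death_rate_lag_term_decays_monotonically(self):
        ts = np.linspace(0, 500, 50)
        vals = [specific_death_rate(0.0, t, COLLECT_PARAMS) for t in ts]
        assert np.all(np.diff(vals) < 0)

    def test_glucose_rate_zero_vcd(self):
        s = CultureState(vcd=0.0, glc=10.0, lac=0.0)
        assert glucose_rate(s, 0.02, 0.01, GROWTH_PARAMS) == 0.0

    def test_glucose_rate_maintenance_only(self):
        # mu = mu_d in the growth phase: only maintenance remains
        s = CultureState(vcd=0.5, glc=10.0, lac=0.0)
        r = glucose_rate(s, 0.02, 0.02, GROWTH_PARAMS)
        assert r == pytest.approx(-GROWTH_PARAMS.m_glc * 0.5)

    def test_glucose_rate_collect_hand_value(self):
        # (0.01/0.031 + 0.07 + 5.3e-13/1.0e-12) * 0.3, by hand
        s = CultureState(vcd=0.3, glc=10.0, lac=0.0)
        expected = -(0.01 / 0.031 + 0.07 + 5.3e-13 / 1.0e-12) * 0.3
        assert glucose_rate(s, 0.02, 0.01, COLLECT_PARAMS) == pytest.approx(expected)


class TestParticleConversion:
    def test_zero(self):
        assert particles_from_product(0.0) == 0.0

    def test_avogadro_bridge(self):
        # 1.908e-8 mmol/L -> 1.149e10 particles/mL
        assert particles_from_product(1.908e-8) == pytest.approx(1.149e10,
                                                                 rel=1e-3)

    def test_round_trip(self):
        p = 3.7e-9
        assert product_from_particles(particles_from_product(p)) == \
            pytest.approx(p, rel=1e-14)


class TestParamValidation:
    def test_growth_phase_rejects_product_params(self):
        with pytest.raises(ValueError):
            GROWTH_PARAMS.replace(q_product=1e-13)

    def test_collect_phase_requires_product_params(self):
        with pytest.raises(ValueError):
            KineticParams(mu_max=0.03, k_d=0.004, K_glc=1, K_i_lac=43,
                          K_d_lac=45.8, m_glc=0.07, Y_x_glc=0.03,
                          Y_lac_glc=2.0, phase="collect")


class TestSimulation:
    def test_zero_vcd_gives_constant_trajectory(self, collect_schedule):
        init = CultureState(vcd=0.0, glc=20.0, lac=5.0, p=0.0)
        traj = simulate_cultivation(init, collect_schedule,
                                    {"collect": COLLECT_PARAMS})
        for col, val in (("vcd_e6_per_ml", 0.0), ("glc_mM", 20.0),
                         ("lac_mM", 5.0), ("product_mM", 0.0)):
            assert np.allclose(traj[col], val, atol=1e-9)

    def test_constant_vcd_product_closed_form(self, collect_schedule):
        # growth and death switched off: P = 1000*q*VCD*t exactly
        p = COLLECT_PARAMS.replace(mu_max=0.0, k_d=0.0, k_lag_max=0.0,
                                   m_glc=0.0)
        init = CultureState(vcd=0.3, glc=100.0)
        traj = simulate_cultivation(init, collect_schedule, {"collect": p})
        p_end = traj["product_mM"].iloc[-1]
        assert p_end == pytest.approx(1e3 * 5.3e-13 * 0.3 * 120, rel=1e-8)
        assert traj["particles_per_ml"].iloc[-1] == pytest.approx(1.149e10,
                                                                  rel=1e-3)

    def test_product_nondecreasing_in_collect(self, collect_schedule,
                                              collect_init):
        traj = simulate_cultivation(collect_init, collect_schedule,
                                    {"collect": COLLECT_PARAMS},
                                    t_out=np.linspace(0, 120, 60))
        assert np.all(np.diff(traj["product_mM"]) >= -1e-15)

    def test_adaptive_matches_fixed_step_euler(self, growth_schedule,
                                               growth_init):
        traj = simulate_cultivation(growth_init, growth_schedule,
                                    {"growth": GROWTH_PARAMS})
        # brute-force explicit Euler oracle at a step small enough that the
        # oracle's own first-order error stays below the 0.1% band
        dt = 0.002
        y = growth_init.as_array()
        t = 0.0
        euler = {0.0: y.copy()}
        for _ in range(int(120 / dt)):
            y = y + dt * cult._rhs(t, y, GROWTH_PARAMS)
            t += dt
            euler[round(t, 6)] = y.copy()
        for _, row in traj.iterrows():
            ref = euler[round(row.time_h, 6)]
            sim = row[["vcd_e6_per_ml", "glc_mM", "lac_mM",
                       "product_mM"]].to_numpy(dtype=float)
            assert np.allclose(sim[:3], ref[:3], rtol=1e-3)

    def test_feed_event_adds_glucose_bolus(self):
        sched = PhaseSchedule(growth_span_h=120, collect_span_h=0,
                              feed_time_h=72, feed_glc_bolus_mM=10.0)
        init = CultureState(vcd=0.02, glc=25.0)
        t_out = np.array([71.9, 72.0, 120.0])
        traj = simulate_cultivation(init, sched, {"growth": GROWTH_PARAMS},
                                    t_out=t_out)
        pre = traj.loc[traj.time_h == 71.9, "glc_mM"].item()
        post = traj.loc[traj.time_h == 72.0, "glc_mM"].item()
        assert post == pytest.approx(pre + 10.0, abs=0.05)

    def test_media_exchange_resets_lactate_and_product(self):
        sched = PhaseSchedule(growth_span_h=120, collect_span_h=120,
                              feed_time_h=None, exchange_glc_mM=25.0)
        init = CultureState(vcd=0.02, glc=25.0)
        traj = simulate_cultivation(init, sched,
                                    {"growth": GROWTH_PARAMS,
                                     "collect": COLLECT_PARAMS},
                                    t_out=np.array([120.0, 120.5, 240.0]))
        post = traj.loc[traj.time_h == 120.5]
        assert post["lac_mM"].item() < 1.0          # reset, then re-forming
        assert post["glc_mM"].item() > 20.0          # fresh medium
        pre = traj.loc[traj.time_h == 120.0]
        assert pre["phase"].item() == "growth"

    def test_lag_clock_restarts_at_exchange(self):
        """Death right after the exchange reflects the full stress term."""
        sched = PhaseSchedule(growth_span_h=48, collect_span_h=48,
                              feed_time_h=None)
        init = CultureState(vcd=0.3, glc=25.0)
        p_nolag = COLLECT_PARAMS.replace(k_lag_max=1e-12)
        t_out = np.array([48.0, 50.0])
        hi = simulate_cultivation(init, sched, {"growth": GROWTH_PARAMS,
                                                "collect": COLLECT_PARAMS},
                                  t_out=t_out)
        lo = simulate_cultivation(init, sched, {"growth": GROWTH_PARAMS,
                                                "collect": p_nolag},
                                  t_out=t_out)
        # the stress term kills cells immediately after the exchange
        assert hi["vcd_e6_per_ml"].iloc[-1] < lo["vcd_e6_per_ml"].iloc[-1]

    def test_yield_sanity_in_exponential_limit(self):
        """With q = 0 and m_Glc = 0, dVCD/(-dGlc) equals Y_XGlc."""
        p = GROWTH_PARAMS.replace(m_glc=0.0, k_d=0.0, K_i_lac=1e9)
        sched = PhaseSchedule(growth_span_h=12, collect_span_h=0,
                              feed_time_h=None)
        init = CultureState(vcd=0.05, glc=500.0)     # far from limitation
        traj = simulate_cultivation(init, sched, {"growth": p},
                                    t_out=np.array([0.0, 12.0]))
        dv = traj["vcd_e6_per_ml"].iloc[-1] - traj["vcd_e6_per_ml"].iloc[0]
        dg = traj["glc_mM"].iloc[0] - traj["glc_mM"].iloc[-1]
        assert dv / dg == pytest.approx(p.Y_x_glc, rel=0.02)


class TestFitting:
    def test_fixed_point_returns_init(self, growth_schedule, growth_init):
        data = simulate_cultivation(growth_init, growth_schedule,
                                    {"growth": GROWTH_PARAMS})
        fr = fit_kinetic_params(data, ["growth.mu_max"],
                                {"growth": GROWTH_PARAMS}, growth_schedule,
                                growth_init)
        assert fr.estimates["growth.mu_max"] == pytest.approx(0.039, rel=1e-6)
        assert fr.cost < 1e-15

    @pytest.mark.parametrize("free,pert,tol", [
        ("growth.mu_max", 1.3, 0.01),
        ("growth.Y_x_glc", 0.7, 0.02),
        ("growth.Y_lac_glc", 1.3, 0.02),
    ])
    def test_noiseless_growth_recovery(self, growth_schedule, growth_init,
                                       free, pert, tol):
        params = {"growth": GROWTH_PARAMS}
        data = simulate_cultivation(growth_init, growth_schedule, params)
        pname = free.split(".")[1]
        true = getattr(GROWTH_PARAMS, pname)
        fr = fit_kinetic_params(data, [free], params, growth_schedule,
                                growth_init, x0={free: true * pert})
        assert fr.estimates[free] == pytest.approx(true, rel=tol)

    @pytest.mark.parametrize("free,pert,tol", [
        ("collect.q_product", 2.0, 0.02),
        ("collect.k_lag_max", 0.7, 0.02),
    ])
    def test_noiseless_collect_recovery(self, collect_schedule, collect_init,
                                        free, pert, tol):
        params = {"collect": COLLECT_PARAMS}
        data = simulate_cultivation(collect_init, collect_schedule, params,
                                    t_out=np.linspace(0, 120, 13))
        pname = free.split(".")[1]
        true = getattr(COLLECT_PARAMS, pname)
        fr = fit_kinetic_params(data, [free], params, collect_schedule,
                                collect_init, x0={free: true * pert})
        assert fr.estimates[free] == pytest.approx(true, rel=tol)

    def test_noisy_recovery_median_within_15pct(self, growth_schedule,
                                                growth_init):
        """10% multiplicative noise: median mu_max error over 20 seeds."""
        from evtwin.synthetic import NoiseSpec, gen_cultivation_dataset
        params = {"growth": GROWTH_PARAMS}
        noise = {c: NoiseSpec(c, 0.10) for c in
                 ("vcd_e6_per_ml", "glc_mM", "lac_mM")}
        errs = []
        for seed in range(20):
            data, _ = gen_cultivation_dataset(params, growth_schedule,
                                              growth_init, noise=noise,
                                              seed=seed)
            fr = fit_kinetic_params(data, ["growth.mu_max"], params,
                                    growth_schedule, growth_init,
                                    x0={"growth.mu_max": 0.039 * 1.3})
            errs.append(abs(fr.estimates["growth.mu_max"] - 0.039) / 0.039)
        assert np.median(errs) < 0.15

    def test_descent_property(self, growth_schedule, growth_init):
        """Objective at the estimate never exceeds the objective at start."""
        params = {"growth": GROWTH_PARAMS}
        data = simulate_cultivation(growth_init, growth_schedule, params)
        start = {"growth.mu_max": 0.05}
        fr = fit_kinetic_params(data, ["growth.mu_max"], params,
                                growth_schedule, growth_init, x0=start)
        sim0 = simulate_cultivation(
            growth_init, growth_schedule,
            {"growth": GROWTH_PARAMS.replace(mu_max=0.05)},
            t_out=data["time_h"].to_numpy())
        assert fr.cost <= 1e-12 or fr.cost < np.sum(
            (sim0[["vcd_e6_per_ml"]].to_numpy()
             - data[["vcd_e6_per_ml"]].to_numpy()) ** 2)

    def test_uninformative_request_rejected(self, growth_schedule,
                                            growth_init):
        data = simulate_cultivation(growth_init, growth_schedule,
                                    {"growth": GROWTH_PARAMS})
        with pytest.raises(ValueError, match="no collect-phase data"):
            fit_kinetic_params(
                data, ["collect.q_product"],
                {"growth": GROWTH_PARAMS, "collect": COLLECT_PARAMS},
                growth_schedule, growth_init)
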