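"""Column model: isotherm, conservation, moments, fractionation, calibration."""

import numpy as np
import pandas as pd
import pytest

from evtwin.chromatography import (ColumnSystem, ComponentTransport,
                                   IsothermParams, MethodProgram, MethodStep,
                                   apply_frit_capture, estimate_fluid_dynamics,
                                   fit_isotherm, fractionate, langmuir_eq,
                                   simulate_chromatography)
from conftest import aex_program, mmsec_program


def pulse_program(flow=0.5, t_inj_min=0.2, conc=None, mod=100.0, wash_cv=3.0,
                  volume_ml=1.0):
    conc = conc or {"tracer": 1.0}
    return MethodProgram([
        MethodStep("load", t_inj_min * flow / volume_ml, flow, inlet=conc,
                   mod_start_mM=mod),
        MethodStep("wash", wash_cv, flow, mod_start_mM=mod),
    ])


class TestLangmuir:
    ISO = IsothermParams(q_max=[1.0, 1.0], K0=[2.0, 1.0], beta=[0.0, 0.0],
                         k_kin=[1.0, 1.0])

    def test_henry_limit(self):
        c = np.array([1e-9, 0.0])
        q = langmuir_eq(c, self.ISO, 100.0)
        assert q[0] / c[0] == pytest.approx(2.0, rel=1e-6)

    def test_single_component_saturation(self):
        iso = IsothermParams(q_max=[3.0], K0=[2.0], beta=[0.0], k_kin=[1.0])
        q = langmuir_eq(np.array([1e9]), iso, 100.0)
        assert q[0] == pytest.approx(3.0, rel=1e-6)

    def test_two_component_hand_value(self):
        # q_max=(1,1), K=(2,1), c=(1,1): q = (2/4, 1/4)
        q = langmuir_eq(np.array([1.0, 1.0]), self.ISO, 100.0)
        assert q == pytest.approx([0.5, 0.25])

    def test_bounded_by_q_max(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = rng.uniform(0, 100, size=2)
            q = langmuir_eq(c, self.ISO, 50.0)
            assert np.all(q <= self.ISO.q_max + 1e-12)

    def test_zero_modifier_with_beta_raises(self):
        iso = IsothermParams(q_max=[1.0], K0=[1.0], beta=[2.0], k_kin=[1.0])
        with pytest.raises(ValueError):
            langmuir_eq(np.array([1.0]), iso, 0.0)

    def test_modifier_weakens_binding(self):
        iso = IsothermParams(q_max=[1.0], K0=[50.0], beta=[2.0], k_kin=[1.0])
        k_lo = iso.equilibrium_constant(50.0)
        k_hi = iso.equilibrium_constant(500.0)
        assert k_hi < k_lo


class TestTracerPhysics:
    def test_mass_conservation_and_dead_time(self, tracer_system):
        geom = tracer_system.geometry
        flow, t_inj = 0.5, 0.2
        res = simulate_chromatography(tracer_system,
                                      pulse_program(flow, t_inj), n_cells=100)
        assert res.mass_balance_error("tracer") < 0.005
        est = estimate_fluid_dynamics(res.chromatogram, geom, flow, "tracer",
                                      injection_duration_min=t_inj)
        t0_expected = 0.75 * geom.volume_ml / flow
        assert est["dead_time_min"] == pytest.approx(t0_expected, rel=0.01)

    def test_moment_recovery_of_transport_parameters(self, tracer_system):
        est = _tracer_estimate(tracer_system, flow=0.5)
        assert est["eps_tot"] == pytest.approx(0.75, rel=0.02)
        assert est["D_ax"] == pytest.approx(0.1, rel=0.02)

    def test_eps_estimate_flow_independent(self, tracer_system):
        e1 = _tracer_estimate(tracer_system, flow=0.4)["eps_tot"]
        e2 = _tracer_estimate(tracer_system, flow=0.8)["eps_tot"]
        assert e1 == pytest.approx(e2, rel=0.01)

    def test_size_exclusion_elution_order(self, one_ml_column):
        tr = ComponentTransport(names=["big", "small"], eps_tot=[0.4, 0.7],
                                eps_s=[0.0, 0.0], D_ax=[0.05, 0.05],
                                k_eff=[0.0, 0.0])
        iso = IsothermParams(q_max=[0, 0], K0=[0, 0], beta=[0, 0],
                             k_kin=[0, 0])
        sys_ = ColumnSystem(one_ml_column, tr, iso)
        res = simulate_chromatography(
            sys_, pulse_program(conc={"big": 1.0, "small": 1.0}), n_cells=80)
        ch = res.chromatogram
        t_big = ch.loc[ch["big"].idxmax(), "time_min"]
        t_small = ch.loc[ch["small"].idxmax(), "time_min"]
        assert t_big < t_small

    def test_plug_flow_limit_variance_collapses(self, one_ml_column):
        def variance(d_ax):
            tr = ComponentTransport(names=["t"], eps_tot=[0.7], eps_s=[0.0],
                                    D_ax=[d_ax], k_eff=[0.0])
            iso = IsothermParams(q_max=[0], K0=[0], beta=[0], k_kin=[0])
            res = simulate_chromatography(
                ColumnSystem(one_ml_column, tr, iso),
                pulse_program(conc={"t": 1.0}), n_cells=200)
            est = estimate_fluid_dynamics(res.chromatogram, one_ml_column,
                                          0.5, "t", injection_duration_min=0.2)
            return est["variance_min2"]

        assert variance(0.02) < variance(0.2) / 3


def _tracer_estimate(system, flow):
    t_inj = 0.2
    res = simulate_chromatography(system, pulse_program(flow, t_inj),
                                  n_cells=300)
    return estimate_fluid_dynamics(res.chromatogram, system.geometry, flow,
                                   "tracer", injection_duration_min=t_inj)


class TestProgramValidation:
    def test_unknown_step_kind_rejected(self):
        with pytest.raises(ValueError):
            MethodStep("elute", 1.0, 1.0)

    def test_decreasing_gradient_rejected(self):
        with pytest.raises(ValueError):
            MethodStep("gradient", 5.0, 1.0, mod_start_mM=500.0,
                       mod_end_mM=100.0)

    def test_empty_program_rejected(self):
        with pytest.raises(ValueError):
            MethodProgram([])


class TestGradientElution:
    def test_modifier_advects_to_outlet(self, aex_system):
        res = simulate_chromatography(aex_system, aex_program(feed_cv=1.0),
                                      n_cells=30)
        mod = res.chromatogram["modifier_mM"].to_numpy()
        assert mod[0] == pytest.approx(50.0, abs=1.0)
        assert mod.max() > 900.0

    def test_mass_conservation_binding_components(self, aex_system):
        res = simulate_chromatography(aex_system, aex_program(feed_cv=2.0),
                                      n_cells=30)
        for nm in ("ev", "protein", "dna"):
            assert res.mass_balance_error(nm) < 0.005

    def test_higher_beta_elutes_earlier(self, one_ml_column):
        """Stronger salt sensitivity moves elution earlier in the gradient."""
        peaks = []
        for beta in (2.0, 3.0, 4.0):
            k0 = 5e-11 * 50.0 ** beta       # same Henry coefficient at 50 mM
            tr = ComponentTransport(names=["p"], eps_tot=[0.5], eps_s=[0.4],
                                    D_ax=[0.06], k_eff=[0.01])
            iso = IsothermParams(q_max=[1e12], K0=[k0], beta=[beta],
                                 k_kin=[3.0])
            sys_ = ColumnSystem(one_ml_column, tr, iso)
            prog = MethodProgram([
                MethodStep("load", 1.0, 1.0, inlet={"p": 1e9},
                           mod_start_mM=50.0),
                MethodStep("wash", 2.0, 1.0, mod_start_mM=50.0),
                MethodStep("gradient", 15.0, 1.0, mod_start_mM=50.0,
                           mod_end_mM=1000.0),
                MethodStep("cip", 3.0, 1.0, mod_start_mM=1000.0),
            ])
            res = simulate_chromatography(sys_, prog, n_cells=30)
            ch = res.chromatogram
            grad_t0 = 3.0 * sys_.geometry.volume_ml / 1.0
            in_grad = ch[ch["time_min"] > grad_t0]
            peaks.append(in_grad.loc[in_grad["p"].idxmax(), "time_min"])
        assert peaks[0] > peaks[1] > peaks[2]

    def test_step_elution_matches_steep_gradient(self, aex_system):
        """A step to the final salt and a very steep gradient converge."""
        def pool_recovery(program):
            res = simulate_chromatography(aex_system, program, n_cells=30)
            ch = res.chromatogram
            t = ch["time_min"].to_numpy()
            # everything eluting after the wash (5 CV) counts as pool
            mask = t > 5.0 * aex_system.geometry.volume_ml
            out = np.trapezoid(ch["ev"].to_numpy()[mask]
                               * ch["flow_ml_min"].to_numpy()[mask], t[mask])
            return out / res.injected["ev"]

        base = [MethodStep("load", 1.0, 1.0, inlet={"ev": 1e10},
                           mod_start_mM=50.0),
                MethodStep("wash", 4.0, 1.0, mod_start_mM=50.0)]
        step = MethodProgram(base + [
            MethodStep("step", 10.0, 1.0, mod_start_mM=1000.0)])
        steep = MethodProgram(base + [
            MethodStep("gradient", 0.2, 1.0, mod_start_mM=50.0,
                       mod_end_mM=1000.0),
            MethodStep("step", 9.8, 1.0, mod_start_mM=1000.0)])
        assert pool_recovery(step) == pytest.approx(pool_recovery(steep),
                                                    rel=0.01)

    def test_grid_convergence_of_pool_recovery(self, aex_system):
        def recovery(n_cells):
            res = simulate_chromatography(aex_system, aex_program(feed_cv=2.0),
                                          n_cells=n_cells)
            ch = res.chromatogram
            t = ch["time_min"].to_numpy()
            mask = t > 11.0      # gradient region
            out = np.trapezoid(ch["ev"].to_numpy()[mask]
                               * ch["flow_ml_min"].to_numpy()[mask], t[mask])
            return out / res.injected["ev"]

        assert recovery(30) == pytest.approx(recovery(60), abs=0.01)


class TestFritCapture:
    def test_saturation_arithmetic(self):
        captured, passed = apply_frit_capture([2e10, 2e10, 2e10], 3e10)
        assert captured == pytest.approx(3e10)
        assert passed.sum() == pytest.approx(3e10)
        assert passed[0] == 0.0                     # first-come-first-served

    def test_load_below_capacity_all_captured(self):
        captured, passed = apply_frit_capture([1e10], 3e10)
        assert captured == pytest.approx(1e10)
        assert np.all(passed == 0.0)

    def test_recovery_monotone_in_load(self, mmsec_system):
        """Proportional frit loss shrinks as the load grows."""
        recoveries = []
        for feed_cv in (1.0, 2.0, 3.0):
            res = simulate_chromatography(
                mmsec_system, mmsec_program(feed_cv=feed_cv), n_cells=30,
                frit_capacity=1.2e10, frit_components=("ev",))
            recoveries.append(res.eluted["ev"]
                              / (res.injected["ev"]
                                 + res.frit_captured["ev"]))
        assert recoveries[0] < recoveries[1] < recoveries[2]


class TestFractionate:
    def test_constant_outlet_amount(self):
        t = np.linspace(0, 10, 201)
        chrom = pd.DataFrame({"time_min": t, "flow_ml_min": 1.0,
                              "modifier_mM": 0.0, "x": 2.0})
        frac = fractionate(chrom, 1.5)
        assert np.allclose(frac["x_amount"], 2.0 * 1.5)
        assert np.allclose(frac["x_conc"], 2.0)

    def test_mass_closure(self, aex_system):
        res = simulate_chromatography(aex_system, aex_program(feed_cv=1.0),
                                      n_cells=30)
        frac = fractionate(res.chromatogram, 1.5)
        for nm in ("ev", "protein", "dna"):
            total = frac[f"{nm}_amount"].sum()
            # all fractions together recover the eluted mass (minus the
            # partial fraction at the very end of the run)
            assert total == pytest.approx(res.eluted[nm], rel=0.001)

    def test_empty_chromatogram_all_zero(self):
        t = np.linspace(0, 5, 50)
        chrom = pd.DataFrame({"time_min": t, "flow_ml_min": 1.0,
                              "modifier_mM": 0.0, "x": 0.0})
        frac = fractionate(chrom, 1.0)
        assert np.allclose(frac["x_amount"], 0.0)


@pytest.fixture(scope="module")
def small_world(one_ml_column):
    tr = ComponentTransport(names=["p"], eps_tot=[0.5], eps_s=[0.4],
                            D_ax=[0.06], k_eff=[0.01])
    iso = IsothermParams(q_max=[1e4], K0=[5e-3 * 50.0 ** 2.0],
                         beta=[2.0], k_kin=[3.0])
    sys_ = ColumnSystem(one_ml_column, tr, iso)
    prog = MethodProgram([
        MethodStep("load", 1.0, 1.0, inlet={"p": 100.0},
                   mod_start_mM=50.0),
        MethodStep("wash", 2.0, 1.0, mod_start_mM=50.0),
        MethodStep("gradient", 10.0, 1.0, mod_start_mM=50.0,
                   mod_end_mM=800.0),
        MethodStep("step", 3.0, 1.0, mod_start_mM=800.0),
    ])
    return sys_, prog


class TestIsothermFit:
    def test_self_fit_returns_guess(self, small_world):
        sys_, prog = small_world
        res = simulate_chromatography(sys_, prog, n_cells=25)
        obs = fractionate(res.chromatogram, 1.5)
        out = fit_isotherm(obs, sys_, prog, free=["K0.p"], n_cells=25)
        assert out["estimates"]["K0.p"] == pytest.approx(
            sys_.isotherm.K0[0], rel=1e-3)
        assert out["r_squared"]["p"] > 0.999

    def test_noiseless_recovery_from_perturbed_start(self, small_world):
        sys_, prog = small_world
        res = simulate_chromatography(sys_, prog, n_cells=25)
        obs = fractionate(res.chromatogram, 1.5)
        true_k0 = sys_.isotherm.K0[0]
        out = fit_isotherm(obs, sys_, prog, free=["K0.p"],
                           x0={"K0.p": true_k0 * 1.3}, n_cells=25)
        assert out["estimates"]["K0.p"] == pytest.approx(true_k0, rel=0.05)
        assert out["r_squared"]["p"] > 0.999
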