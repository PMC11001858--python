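import numpy as np
import pytest

import willisflow as wf
from willisflow import units
from willisflow.boundary_conditions import (
    dep_pressure,
    pm_pressure,
    sp_pressure,
    zp_pressure,
)
from willisflow.synthetic import pm_waveform


class TestZeroPressure:
    def test_stationary_regardless_of_time(self):
        spec = wf.ZPSpec(p_zp=87.0)
        assert zp_pressure(spec, 0.0) == zp_pressure(spec, 17.3) == 87.0
        assert zp_pressure(wf.ZPSpec(p_zp=0.0), 1.0) == 0.0

    def test_from_dataset_averages_all_outlet_pressures(self, clean_set):
        ci = wf.segment_cycles(clean_set.get("LACA", "pressure"), f=1.0)
        spec = wf.ZPSpec.from_dataset(clean_set, ci)
        # default synthetic outlet means average to 87 mmHg
        assert spec.p_zp == pytest.approx(87.0, abs=0.1)


class TestSymmetricalPressure:
    spec = wf.SPSpec(
        p_mean={"LMCA": 87.0},
        c_loss={"LMCA": 1.0},
        area={"LMCA": 5e-6},
        rho=1137.0,
    )

    def test_zero_flow_reduces_to_mean(self):
        assert sp_pressure(self.spec, 0.0, "LMCA") == pytest.approx(87.0, abs=1e-12)

    def test_dynamic_term_matches_hand_computation(self):
        # 150 mL/min = 2.5e-6 m^3/s; v = Q/A = 0.5 m/s; 0.5*rho*v^2 = 142.125 Pa
        got = sp_pressure(self.spec, 150.0, "LMCA")
        expected = 87.0 + 142.125 / 133.322
        assert got == pytest.approx(expected, rel=1e-9)

    def test_dynamic_term_scales_quadratically(self):
        d1 = sp_pressure(self.spec, 100.0, "LMCA") - 87.0
        d2 = sp_pressure(self.spec, 200.0, "LMCA") - 87.0
        assert d2 == pytest.approx(4.0 * d1, rel=1e-12)

    def test_unknown_outlet_rejected(self):
        with pytest.raises(KeyError):
            sp_pressure(self.spec, 0.0, "LACA")


class TestDirectExperimentalPressure:
    def setup_method(self):
        t = np.arange(1000) / 1000.0
        self.w = wf.Waveform("LACA", "pressure", 85 + 30 * np.sin(2 * np.pi * t), 1000.0)
        self.spec = wf.DEPSpec(pressures={"LACA": self.w}, f=1.0)

    def test_stored_samples_returned_exactly(self):
        for k in (0, 123, 999):
            assert dep_pressure(self.spec, "LACA", k / 1000.0) == pytest.approx(
                self.w.values[k], abs=1e-12
            )

    def test_periodic_extension(self):
        a = dep_pressure(self.spec, "LACA", 0.4)
        b = dep_pressure(self.spec, "LACA", 2.4)
        assert a == pytest.approx(b, abs=1e-9)

    def test_midpoint_is_neighbor_mean(self):
        mid = dep_pressure(self.spec, "LACA", 0.1235)
        assert mid == pytest.approx(
            0.5 * (self.w.values[123] + self.w.values[124]), abs=1e-12
        )


class TestPhaseModulationPressure:
    def test_constant_limit(self):
        spec = wf.PMSpec(p_mean={"LACA": 88.0}, pi_p=0.0, phi=0.3, beta=0.0)
        assert pm_pressure(spec, "LACA", 0.7) == pytest.approx(88.0)

    def test_cosine_extreme(self):
        spec = wf.PMSpec(p_mean={"LACA": 88.0}, pi_p=0.8, phi=0.0, beta=0.0)
        assert pm_pressure(spec, "LACA", 0.0) == pytest.approx(88.0 * 1.4)

    def test_modulated_value_against_independent_arithmetic(self):
        spec = wf.PMSpec(p_mean={"LACA": 90.0}, pi_p=0.8, phi=0.0, beta=0.5, f=1.0)
        # t=0: cos(0 + 0.5*cos(0)) = cos(0.5)
        assert pm_pressure(spec, "LACA", 0.0) == pytest.approx(
            90.0 * (1.0 + 0.4 * np.cos(0.5)), rel=1e-12
        )


class TestWindkesselStep:
    def test_fixed_point(self):
        p = wf.wm_step(p=6.0, Q=3.0, R=2.0, C=1.0, dt=0.1)
        assert p == pytest.approx(6.0, abs=1e-15)

    def test_single_hand_computed_step(self):
        assert wf.wm_step(p=1.0, Q=0.0, R=1.0, C=1.0, dt=0.1) == pytest.approx(0.9)

    def test_relaxation_matches_closed_form_within_euler_error(self):
        R, C, dt = 1.0, 1.0, 1e-3
        p, traj = 1.0, []
        n = 1000
        for _ in range(n):
            p = wf.wm_step(p, 0.0, R, C, dt)
            traj.append(p)
        t = dt * np.arange(1, n + 1)
        exact = np.exp(-t / (R * C))
        # first-order scheme: global error O(dt)
        assert np.abs(np.array(traj) - exact).max() <= 1.0 * dt

    def test_convergence_to_rq(self):
        p = 0.0
        for _ in range(10000):
            p = wf.wm_step(p, Q=5.0, R=2.0, C=1.0, dt=1e-2)
        assert p == pytest.approx(10.0, rel=1e-4)

    def test_stability_guards(self):
        with pytest.raises(ValueError, match="unstable"):
            wf.wm_step(1.0, 0.0, R=1.0, C=1.0, dt=2.5)
        with pytest.warns(RuntimeWarning):
            wf.wm_step(1.0, 0.0, R=1.0, C=1.0, dt=0.9)


class TestResistanceFit:
    def test_exact_linear_data_recovers_slope(self):
        q_mlmin = np.linspace(50, 200, 100)
        R_true = 3.0e9
        p_mmhg = units.pa_to_mmhg(R_true * units.mlmin_to_m3s(q_mlmin))
        R = wf.fit_resistance(
            wf.Waveform("LMCA", "pressure", p_mmhg, 100.0),
            wf.Waveform("LMCA", "flow", q_mlmin, 100.0),
        )
        assert R == pytest.approx(R_true, rel=1e-9)

    def test_steady_constants_are_exact(self):
        R_true = 4.0e9
        q = np.full(100, 170.0)
        p = units.pa_to_mmhg(R_true * units.mlmin_to_m3s(q))
        R = wf.fit_resistance(
            wf.Waveform("LMCA", "pressure", p, 100.0),
            wf.Waveform("LMCA", "flow", q, 100.0),
            mode="mean",
        )
        assert R == pytest.approx(R_true, rel=1e-12)

    def test_recovery_from_windkessel_truth(self):
        # pulsatile flow through a known RC element; instantaneous fit is
        # biased by the compliant phase lag (5% tolerance), the cycle-mean
        # fit in steady periodic state is essentially exact (1%).
        R_true, C_true = 4.0e9, 2.5e-11  # tau = 0.1 s, washes out quickly
        t = np.arange(5000) / 1000.0
        q = wf.Waveform(
            "LMCA", "flow", pm_waveform(t, 170.0, 0.5, beta=0.5), 1000.0
        )
        p0 = units.pa_to_mmhg(R_true * units.mlmin_to_m3s(170.0))
        p = wf.generate_windkessel_truth(R_true, C_true, q, p0=p0)
        last = slice(4000, 5000)
        p_last = wf.Waveform("LMCA", "pressure", p.values[last], 1000.0)
        q_last = wf.Waveform("LMCA", "flow", q.values[last], 1000.0)
        R_mean = wf.fit_resistance(p_last, q_last, mode="mean")
        assert R_mean == pytest.approx(R_true, rel=0.01)
        R_inst = wf.fit_resistance(p_last, q_last, mode="instantaneous")
        assert R_inst == pytest.approx(R_true, rel=0.05)

    def test_model_results_report(self):
        q = np.linspace(50, 200, 50)
        p = units.pa_to_mmhg(2.0e9 * units.mlmin_to_m3s(q))
        res = wf.WindkesselModel(
            wf.Waveform("LMCA", "pressure", p, 10.0),
            wf.Waveform("LMCA", "flow", q, 10.0),
        ).fit()
        assert "Windkessel" in res.summary()
        assert res.R == pytest.approx(2.0e9, rel=1e-9)

    def test_degenerate_flow_rejected(self):
        zeros = wf.Waveform("LMCA", "flow", np.zeros(10), 10.0)
        p = wf.Waveform("LMCA", "pressure", np.ones(10), 10.0)
        with pytest.raises(ValueError):
            wf.fit_resistance(p, zeros)


class TestCapacitanceDerivation:
    def test_uniform_tau_arithmetic(self):
        out = wf.derive_capacitances({"MCA": 2.0, "ACA": 3.0}, C_MCA=3.0)
        assert out["tau"] == pytest.approx(6.0)
        assert out["C"]["ACA"] == pytest.approx(2.0)

    def test_equal_resistances_give_equal_capacitances(self):
        out = wf.derive_capacitances({"MCA": 2.0, "ACA": 2.0, "PCA": 2.0}, C_MCA=1.5)
        assert all(c == pytest.approx(1.5) for c in out["C"].values())

    def test_tau_constraint_holds_for_every_class(self):
        R = {"MCA": 4.1e9, "ACA": 6.3e9, "PCA": 8.9e9}
        out = wf.derive_capacitances(R, C_MCA=2.5e-10)
        for cls, C in out["C"].items():
            assert R[cls] * C == pytest.approx(out["tau"], rel=1e-12)

    def test_missing_mca_rejected(self):
        with pytest.raises(KeyError, match="MCA"):
            wf.derive_capacitances({"ACA": 1.0}, C_MCA=1.0)


class TestPhaseModulationFit:
    f = 1.0

    def _pm_wave(self, vessel, mean, pi_p, phi, beta, n=3000):
        t = np.arange(n) / 1000.0
        return wf.Waveform(
            vessel, "pressure", pm_waveform(t, mean, pi_p, self.f, phi, beta), 1000.0
        )

    def test_noise_free_parameter_recovery(self):
        truth = dict(pi_p=0.78, phi=5.9, beta=0.55)
        pressures = {
            v: self._pm_wave(v, m, truth["pi_p"], truth["phi"], truth["beta"])
            for v, m in zip(wf.OUTLETS, (84.0, 85.0, 88.0, 86.0, 90.0, 89.0))
        }
        res = wf.fit_pm_params(pressures, f=self.f)
        assert res.spec.pi_p == pytest.approx(truth["pi_p"], rel=0.01)
        assert res.spec.beta == pytest.approx(truth["beta"], rel=0.01)
        assert res.spec.phi % (2 * np.pi) == pytest.approx(
            truth["phi"] % (2 * np.pi), rel=0.01
        )
        for v, m in zip(wf.OUTLETS, (84.0, 85.0, 88.0, 86.0, 90.0, 89.0)):
            assert res.spec.p_mean[v] == pytest.approx(m, rel=0.001)

    def test_pure_cosine_yields_negligible_modulation(self):
        pressures = {"LACA": self._pm_wave("LACA", 88.0, 0.8, 0.4, 0.0)}
        res = wf.fit_pm_params(pressures, f=self.f)
        assert abs(res.spec.beta) < 0.01

    def test_identical_outlets_give_identical_fits(self):
        w = self._pm_wave("LACA", 88.0, 0.8, 1.0, 0.4)
        pressures = {v: w.with_values(w.values) for v in wf.OUTLETS}
        res = wf.fit_pm_params(pressures, f=self.f)
        pi_ps = [d["pi_p"] for d in res.per_outlet.values()]
        assert np.ptp(pi_ps) <= 1e-8
        assert res.spec.pi_p == pytest.approx(pi_ps[0], abs=1e-10)

    def test_refit_of_generated_spec_is_idempotent(self):
        spec = wf.PMSpec(
            p_mean={"LACA": 88.0}, pi_p=0.8, phi=0.7, beta=0.45, f=self.f
        )
        t = np.arange(3000) / 1000.0
        w = wf.Waveform(
            "LACA", "pressure",
            [spec.pressure("LACA", ti) for ti in t], 1000.0,
        )
        res = wf.fit_pm_params({"LACA": w}, f=self.f)
        assert res.spec.pi_p == pytest.approx(0.8, abs=1e-6)
        assert res.spec.beta == pytest.approx(0.45, abs=1e-6)
        assert res.spec.phi == pytest.approx(0.7, abs=1e-6)

    def test_summary_lists_pooled_parameters(self):
        pressures = {"LACA": self._pm_wave("LACA", 88.0, 0.8, 0.4, 0.3)}
        s = wf.fit_pm_params(pressures, f=self.f).summary()
        assert "PI_p" in s and "beta" in s


class TestSymmetricalPressureDerivation:
    def test_left_right_class_means(self, clean_set):
        ci = wf.segment_cycles(clean_set.get("LACA", "pressure"), f=1.0)
        spec = wf.derive_sp_params(clean_set, ci=ci)
        # defaults: LACA 84, RACA 85 -> ACA class 84.5 on both sides
        assert spec.p_mean["LACA"] == pytest.approx(84.5, abs=0.05)
        assert spec.p_mean["LACA"] == spec.p_mean["RACA"]
        assert spec.p_mean["LMCA"] == spec.p_mean["RMCA"]

    def test_identical_sides_reduce_to_common_mean(self):
        t = np.arange(2000) / 1000.0
        vals = 88.0 + 30 * np.sin(2 * np.pi * t)
        waves = {
            (v, "pressure"): wf.Waveform(v, "pressure", vals, 1000.0)
            for v in wf.OUTLETS
        }
        spec = wf.derive_sp_params(wf.WaveformSet(waveforms=waves))
        for v in wf.OUTLETS:
            assert spec.p_mean[v] == pytest.approx(88.0, rel=1e-6)

    def test_outlet_weighted_mean_consistent_with_zp(self, clean_set):
        ci = wf.segment_cycles(clean_set.get("LACA", "pressure"), f=1.0)
        sp = wf.derive_sp_params(clean_set, ci=ci)
        zp = wf.ZPSpec.from_dataset(clean_set, ci)
        assert np.mean(list(sp.p_mean.values())) == pytest.approx(zp.p_zp, abs=1e-9)


class TestInterchangeability:
    def test_all_specs_share_the_pressure_interface(self, clean_set):
        t = np.arange(1000) / 1000.0
        w = clean_set.get("LACA", "pressure")
        specs = [
            wf.ZPSpec(87.0),
            wf.SPSpec({"LACA": 84.0}, {"LACA": 1.0}, {"LACA": 5e-6}),
            wf.DEPSpec({"LACA": w}),
            wf.WMSpec(R={"LACA": 4e9}, C={"LACA": 2.5e-10}, p_init={"LACA": 84.0}),
            wf.PMSpec({"LACA": 84.0}, pi_p=0.8, phi=0.0, beta=0.5),
        ]
        for spec in specs:
            p = spec.pressure("LACA", 0.25, Q=90.0)
            assert np.isfinite(p)
            spec.advance("LACA", 90.0, 1e-3)  # no-op except WM
        stateful = [s for s in specs if s.stateful]
        assert len(stateful) == 1 and isinstance(stateful[0], wf.WMSpec)

    def test_wm_state_bounded_for_physiological_forcing(self):
        spec = wf.WMSpec(R={"O": 4e9}, C={"O": 2.5e-10}, p_init={"O": 50.0})
        q_max = 200.0  # mL/min
        bound = units.pa_to_mmhg(4e9 * units.mlmin_to_m3s(q_max)) + 1e-9
        rng = np.random.default_rng(0)
        for _ in range(5000):
            spec.advance("O", rng.uniform(0, q_max), 1e-3)
            assert spec.pressure("O", 0.0) <= bound
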