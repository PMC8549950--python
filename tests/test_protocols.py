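"""Virtual experiments: Hill utilities, force-velocity and length-step
protocols, synthetic data generation and parameter recovery."""

import math

import numpy as np
import pytest

from xbkin import (
    GrowthKind,
    HillParams,
    MomentRateParams,
    QSpec,
    StepProtocol,
    asymptotic_step_tension,
    characteristic_quantities,
    end_of_step_tension,
    generate_noisy_measurements,
    hill_tension,
    hill_vmax,
    normalize_fiber_velocity,
    normalized_force_velocity,
    recover_measurements,
    run_force_velocity,
    run_length_step,
)


class TestHill:
    def test_stall_and_intercept(self):
        p = HillParams(a_over_tiso=0.22, b=0.27, t_iso=120e3)
        assert hill_tension(0.0, p) == pytest.approx(p.t_iso)
        assert hill_tension(hill_vmax(p), p) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_point(self):
        p = HillParams(a_over_tiso=0.22, b=0.27, t_iso=1.0)
        v = 0.1
        # direct algebraic solution of (T + a) v = b (T_iso - T)
        expected = (p.b * 1.0 - 0.22 * v) / (v + p.b)
        assert hill_tension(v, p) == pytest.approx(expected, rel=1e-14)

    def test_hill_1938_fit_values(self):
        """Hill's original fit: b = 1.03 cm/s over a 38 mm fiber gives
        b = 0.27 1/s and v_max = b/(a/T_iso) = 1.23 1/s."""
        b = normalize_fiber_velocity(10.3, 38.0)
        assert b == pytest.approx(0.27, abs=5e-3)
        p = HillParams(a_over_tiso=0.22, b=b)
        assert hill_vmax(p) == pytest.approx(1.23, abs=5e-3)

    def test_vmax_proportional_to_b(self):
        p1 = HillParams(a_over_tiso=0.22, b=0.27)
        p2 = HillParams(a_over_tiso=0.22, b=0.54)
        assert hill_vmax(p2) == pytest.approx(2 * hill_vmax(p1))

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            normalize_fiber_velocity(10.3, 0.0)


class TestForceVelocityProtocol:
    def test_matches_closed_form_and_endpoints(self, linear_model):
        meas = characteristic_quantities(linear_model, 1.0)
        v = np.linspace(0.0, meas.v_max, 41)
        curve = run_force_velocity(linear_model, 1.0, v)
        assert curve["T_over_Tiso"].iloc[0] == pytest.approx(1.0, rel=1e-12)
        assert curve["T_over_Tiso"].iloc[-1] == pytest.approx(0.0, abs=1e-13)
        assert curve["T_over_Tiso"].to_numpy() == pytest.approx(
            normalized_force_velocity(linear_model, v), rel=1e-12
        )

    def test_convex_decreasing(self, linear_model):
        meas = characteristic_quantities(linear_model, 1.0)
        v = np.linspace(0.0, meas.v_max, 101)
        y = run_force_velocity(linear_model, 1.0, v)["T_over_Tiso"].to_numpy()
        assert np.all(np.diff(y) < 0)
        assert np.all(np.diff(y, 2) >= -1e-12)

    def test_permissivity_invariance(self, linear_model):
        v = np.linspace(0.0, 6.0, 13)
        half = run_force_velocity(linear_model, 0.5, v)["T_over_Tiso"]
        full = run_force_velocity(linear_model, 1.0, v)["T_over_Tiso"]
        assert half.to_numpy() == pytest.approx(full.to_numpy(), rel=1e-12)


class TestLengthStepProtocol:
    def test_zero_step_flat_trace(self, linear_model):
        trace = run_length_step(
            linear_model, 1.0, StepProtocol(0.0, 200e-6), t_end=0.02, n_out=51
        )
        assert trace["T_over_Tiso"].to_numpy() == pytest.approx(
            np.ones(len(trace)), rel=1e-9
        )

    def test_end_of_step_matches_closed_form(self, linear_model):
        step = StepProtocol(0.02, 200e-6)
        trace = run_length_step(linear_model, 1.0, step, t_end=0.05)
        t_end_row = trace.loc[(trace["t_s"] - step.delta_t).abs().idxmin()]
        assert t_end_row["T_a_Pa"] == pytest.approx(
            end_of_step_tension(linear_model, 1.0, step), rel=1e-6
        )

    def test_recovery_towards_isometric(self, sublinear_model):
        step = StepProtocol(0.01, 200e-6)
        trace = run_length_step(sublinear_model, 1.0, step, t_end=0.08)
        after = trace[trace["t_s"] > step.delta_t]["T_over_Tiso"].to_numpy()
        assert np.all(np.diff(after) > -1e-10)
        assert after[-1] == pytest.approx(1.0, abs=2e-4)

    def test_slow_fast_asymptote_ordering_linear(self, linear_model):
        """Linear growth: heartbeat-speed steps (v = 0.5 1/s) saturate above
        laboratory fast steps (200 us), which sit above the instantaneous
        asymptote, at every step size."""
        m = linear_model
        t_iso = m.a_xb * m.mu_f1 / m.r0
        for dl in np.linspace(0.0025, 0.06, 24):
            t_slow = end_of_step_tension(m, 1.0, StepProtocol(dl, dl / 0.5))
            t_fast = end_of_step_tension(m, 1.0, StepProtocol(dl, 200e-6))
            t_asym = asymptotic_step_tension(m, 1.0, dl)
            assert t_slow >= t_fast - 1e-9 * t_iso
            assert t_fast >= t_asym - 1e-9 * t_iso

    def test_saturation_ordering_sublinear(self, sublinear_model):
        """Sublinear growth: in the saturation regime (larger steps) the
        slow-step tension stays above the fast-step tension, which stays
        above the instantaneous asymptote.  (At very small steps the
        approach to the asymptote is non-monotone in step duration for the
        sqrt destruction term, so the ordering is a large-step property.)"""
        m = sublinear_model
        t_iso = m.a_xb * m.mu_f1 / m.r0
        for dl in np.linspace(0.015, 0.06, 16):
            t_slow = end_of_step_tension(m, 1.0, StepProtocol(dl, dl / 0.5))
            t_fast = end_of_step_tension(m, 1.0, StepProtocol(dl, 200e-6))
            t_asym = asymptotic_step_tension(m, 1.0, dl)
            assert t_slow >= t_fast - 1e-9 * t_iso
            assert t_fast >= t_asym - 1e-9 * t_iso

    def test_fast_step_near_asymptote_for_small_steps(self, sublinear_model):
        m = sublinear_model
        t_iso = m.a_xb * m.mu_f1 / m.r0
        dl = 0.002
        t_fast = end_of_step_tension(m, 1.0, StepProtocol(dl, 200e-6))
        t_asym = asymptotic_step_tension(m, 1.0, dl)
        assert t_fast / t_iso == pytest.approx(t_asym / t_iso, abs=0.02)

    def test_superlinear_tension_vanishes_with_step_duration(self, linear_model):
        m = MomentRateParams(
            mu_f0=linear_model.mu_f0, mu_f1=linear_model.mu_f1,
            r0=linear_model.r0,
            q=QSpec(alpha=2.25, growth=GrowthKind.SUPERLINEAR),
            a_xb=linear_model.a_xb,
        )
        dl = 0.02
        vals = [
            end_of_step_tension(m, 1.0, StepProtocol(dl, dt))
            for dt in (1e-3, 1e-5, 1e-7)
        ]
        assert vals[0] > vals[1] > vals[2] > 0 or vals[2] < vals[1] < vals[0]
        assert abs(vals[2]) < 1e-3 * m.a_xb * m.mu_f1 / m.r0


class TestSyntheticData:
    def test_seed_reproducibility(self, linear_model):
        a = generate_noisy_measurements(linear_model, 1.0, sigma=0.05, seed=42)
        b = generate_noisy_measurements(linear_model, 1.0, sigma=0.05, seed=42)
        assert np.array_equal(a.fv_tension_pa, b.fv_tension_pa)
        assert np.array_equal(a.step_tension_norm, b.step_tension_norm)
        c = generate_noisy_measurements(linear_model, 1.0, sigma=0.05, seed=43)
        assert not np.array_equal(a.fv_tension_pa, c.fv_tension_pa)

    def test_noiseless_points_on_closed_forms(self, sublinear_model):
        d = generate_noisy_measurements(sublinear_model, 1.0, sigma=0.0, seed=0)
        meas = characteristic_quantities(sublinear_model, 1.0)
        assert d.fv_tension_pa == pytest.approx(
            meas.t_iso * normalized_force_velocity(sublinear_model, d.fv_v),
            rel=1e-12, abs=1e-9,
        )
        t_iso = sublinear_model.a_xb * sublinear_model.mu_f1 / sublinear_model.r0
        for dl, tn, dt in zip(d.step_dl, d.step_tension_norm, d.step_dt):
            assert tn == pytest.approx(
                end_of_step_tension(sublinear_model, 1.0, StepProtocol(dl, dt))
                / t_iso,
                rel=1e-12,
            )

    def test_noise_level_calibrated(self, linear_model):
        """Residual spread around the true curve matches sigma."""
        sigma = 0.02
        d = generate_noisy_measurements(
            linear_model, 1.0, sigma=sigma, n_points=400, seed=3
        )
        meas = characteristic_quantities(linear_model, 1.0)
        resid = (
            d.fv_tension_pa / meas.t_iso
            - normalized_force_velocity(linear_model, d.fv_v)
        )
        assert resid.std(ddof=1) == pytest.approx(sigma, rel=0.2)
        assert abs(resid.mean()) < 3 * sigma / math.sqrt(len(resid))


class TestRecovery:
    @pytest.mark.parametrize("fixture", ["linear_model", "sublinear_model"])
    def test_noiseless_recovery_exact(self, fixture, request):
        m = request.getfixturevalue(fixture)
        truth = characteristic_quantities(m, 1.0)
        d = generate_noisy_measurements(m, 1.0, sigma=0.0, seed=0)
        rec = recover_measurements(d)
        for name in ("t_iso", "mu0_iso", "v_max", "v0", "k2_tilde"):
            assert getattr(rec, name) == pytest.approx(
                getattr(truth, name), rel=1e-6
            ), name

    def test_pipeline_roundtrip_from_measurements(self, cardiac_measurements):
        from xbkin import calibrate_linear

        m = calibrate_linear(cardiac_measurements).params
        d = generate_noisy_measurements(m, 1.0, sigma=0.0, seed=5)
        rec = recover_measurements(d)
        for name in ("t_iso", "mu0_iso", "v_max", "v0", "k2_tilde"):
            assert getattr(rec, name) == pytest.approx(
                getattr(cardiac_measurements, name), rel=1e-6
            ), name

    def test_noisy_recovery_accuracy_and_bias(self, linear_model):
        """Monte Carlo over 200 noise replicates: the v_max estimate has a
        median relative error below 5% and no material bias."""
        truth = characteristic_quantities(linear_model, 1.0)
        errs, rels = [], []
        for seed in range(200):
            d = generate_noisy_measurements(
                linear_model, 1.0, sigma=0.02, seed=seed
            )
            rec = recover_measurements(d)
            errs.append(rec.v_max - truth.v_max)
            rels.append(abs(rec.v_max / truth.v_max - 1.0))
        assert np.median(rels) < 0.05
        bias = np.mean(errs)
        se = np.std(errs, ddof=1) / math.sqrt(len(errs))
        assert abs(bias) < 4 * se + 0.01 * truth.v_max

    def test_unbracketed_crossing_rejected(self, linear_model):
        d = generate_noisy_measurements(
            linear_model, 1.0, sigma=0.0, seed=0, v_span=0.5
        )
        with pytest.raises(ValueError, match="zero crossing"):
            recover_measurements(d)
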