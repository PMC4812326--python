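"""Staged inference pipeline: kinematics, halt, pre-tension, relaxation, grid."""

import math
import warnings

import numpy as np
import pytest

import fiberprobe as fp
import fiberprobe.fitting as F


def make_trace(t, delta_s, delta_clv, d=28.4, k_clv=2.0):
    return fp.ExperimentTrace(t=t, delta_s=delta_s, delta_clv=delta_clv, d=d, k_clv=k_clv)


class TestDeriveKinematics:
    def test_definition(self):
        tr = make_trace([0.0, 0.02, 0.04], [0.0, 1.0, 2.0], [0.0, 0.4, 0.8])
        e, f = fp.derive_kinematics(tr)
        np.testing.assert_allclose(e, [0.0, 0.6, 1.2])
        np.testing.assert_allclose(f, [0.0, 0.8, 1.6])

    def test_rigid_fiber_limit(self):
        ds = np.linspace(0, 5, 60)
        tr = make_trace(np.linspace(0, 1, 60), ds, ds)
        e, _ = fp.derive_kinematics(tr)
        np.testing.assert_allclose(e, 0.0, atol=1e-14)

    def test_round_trip_from_simulation(self, reference_sim, reference_trace):
        e, f = fp.derive_kinematics(reference_trace)
        np.testing.assert_allclose(e, reference_sim.e, atol=1e-12)
        np.testing.assert_allclose(f, reference_sim.F_clv, atol=1e-12)

    def test_invalid_traces_rejected(self):
        with pytest.raises(ValueError):
            make_trace([0.0, 0.02], [0.0, 1.0], [0.0])
        with pytest.raises(ValueError):
            make_trace([0.0, 0.0, 0.02], [0.0, 1.0, 2.0], [0.0, 0.1, 0.2])
        with pytest.raises(ValueError):  # 2 Hz sampling
            make_trace([0.0, 0.5, 1.0], [0.0, 1.0, 2.0], [0.0, 0.1, 0.2])


class TestDetectHalt:
    def test_ramp_hold_protocol_arithmetic(self, reference_trace):
        halt = fp.detect_halt(reference_trace)
        assert halt.t_star == pytest.approx(4.0, abs=1.0 / reference_trace.sample_rate)
        assert halt.delta_s_star == pytest.approx(20.0, abs=1e-9)

    def test_noisy_trace_within_two_samples(self, geometry, probe, mean_params):
        trace = fp.generate_trace(
            geometry, probe, mean_params,
            noise=fp.NoiseModel(sigma_stage=0.02, sigma_clv=0.05), seed=11,
        )
        halt = fp.detect_halt(trace)
        assert halt.t_star == pytest.approx(4.0, abs=2.0 / trace.sample_rate)

    def test_pure_ramp_raises(self):
        t = np.arange(0, 4, 0.02)
        tr = make_trace(t, 5.0 * t, 0.3 * t)
        with pytest.raises(fp.HaltNotFoundError):
            fp.detect_halt(tr)

    def test_hold_from_start_is_degenerate_halt(self):
        t = np.arange(0, 4, 0.02)
        tr = make_trace(t, np.full_like(t, 7.0), np.full_like(t, 1.0))
        halt = fp.detect_halt(tr)
        assert halt.t_star == 0.0
        assert halt.index == 0


class TestTensionCurve:
    def test_pure_elastic_round_trip(self, geometry, probe):
        params = fp.MechanicalParams(7.44, 3.23, 0.0, 1.0)
        sim = fp.forward_simulate(geometry, probe, params, fp.StageProtocol(t_hold=2.0))
        tr = fp.ExperimentTrace.from_sim(sim)
        curve = fp.tension_deformation_curve(tr)
        np.testing.assert_allclose(curve.T, 7.44 + 3.23 * curve.delta, rtol=1e-6)
        pre = fp.extract_pretension(curve)
        assert pre.T0_hat == pytest.approx(7.44, abs=1e-4)
        assert pre.slope == pytest.approx(3.23, abs=1e-4)

    def test_viscous_curve_lies_above_elastic_line(self, reference_trace, mean_params):
        curve = fp.tension_deformation_curve(reference_trace)
        elastic = mean_params.T0 + mean_params.k1 * curve.delta
        assert np.all(curve.T >= elastic - 1e-9)

    def test_hold_only_trace_raises(self):
        t = np.arange(0, 4, 0.02)
        tr = make_trace(t, np.full_like(t, 7.0), np.full_like(t, 1.0))
        with pytest.raises(F.InsufficientDataError):
            fp.tension_deformation_curve(tr)

    def test_retained_mask_respects_e_min(self, reference_trace):
        curve = fp.tension_deformation_curve(reference_trace, e_min=2.5)
        assert np.all(reference_trace.e[curve.retained] >= 2.5)


class TestExtractPretension:
    def test_exact_line(self):
        delta = np.linspace(1, 10, 40)
        curve = F.TensionCurve(delta=delta, T=5.0 + 2.0 * delta, retained=np.ones(40, bool))
        pre = fp.extract_pretension(curve)
        assert pre.T0_hat == pytest.approx(5.0, abs=1e-10)
        assert pre.slope == pytest.approx(2.0, abs=1e-10)

    def test_constant_tension(self):
        delta = np.linspace(0, 3, 20)
        curve = F.TensionCurve(delta=delta, T=np.full(20, 7.44), retained=np.ones(20, bool))
        assert fp.extract_pretension(curve).T0_hat == pytest.approx(7.44, abs=1e-10)

    def test_negative_intercept_warns(self):
        delta = np.linspace(1, 10, 40)
        curve = F.TensionCurve(delta=delta, T=-1.0 + 2.0 * delta, retained=np.ones(40, bool))
        with pytest.warns(UserWarning):
            pre = fp.extract_pretension(curve)
        assert pre.negative_intercept

    def test_viscous_intercept_biased_upward(self, reference_trace):
        """Loading-phase viscosity inflates the intercept above true T0."""
        pre = fp.extract_pretension(fp.tension_deformation_curve(reference_trace))
        assert pre.T0_hat > 7.44

    @pytest.mark.parametrize("k2", [5.0, 11.0, 22.0])
    @pytest.mark.parametrize("eta", [4.0, 8.0, 16.0])
    def test_overestimation_direction_across_sweep(self, geometry, probe, k2, eta):
        params = fp.MechanicalParams(7.44, 3.23, k2, eta)
        sim = fp.forward_simulate(
            geometry, probe, params, fp.StageProtocol(t_hold=2.0, sample_rate=20.0)
        )
        pre = fp.extract_pretension(
            fp.tension_deformation_curve(fp.ExperimentTrace.from_sim(sim))
        )
        assert pre.T0_hat >= params.T0


class TestFitRelaxation:
    def test_exact_exponential_self_consistency(self):
        t = np.arange(0, 14.0, 0.02)
        e = np.where(t <= 4.0, 2.5 * t, 10.0 + 3.0 * (1.0 - np.exp(-(t - 4.0) / 2.0)))
        ds = np.where(t <= 4.0, 5.0 * t, 20.0)
        tr = make_trace(t, ds, ds - e)
        rel = fp.fit_relaxation(tr)
        assert rel.tau == pytest.approx(2.0, rel=1e-6)
        assert rel.e_inf == pytest.approx(3.0, rel=1e-6)
        assert rel.r_squared == pytest.approx(1.0, abs=1e-9)
        assert not rel.rejected

    def test_flat_hold_flagged_degenerate(self):
        t = np.arange(0, 14.0, 0.02)
        e = np.where(t <= 4.0, 2.5 * t, 10.0)
        ds = np.where(t <= 4.0, 5.0 * t, 20.0)
        rel = fp.fit_relaxation(make_trace(t, ds, ds - e))
        assert rel.degenerate
        assert rel.e_inf == 0.0

    def test_simulated_hold_is_single_exponential(self, reference_trace):
        rel = fp.fit_relaxation(reference_trace)
        assert rel.r_squared > 0.999
        assert 0 < rel.tau < 10


class TestEtaFromK2:
    def test_vanishing_maxwell_branch(self):
        assert fp.eta_from_k2(3.0, 1e-9, 2.3, 0.47, 3.0) == pytest.approx(0.0, abs=1e-8)

    def test_rigid_cantilever_limit(self):
        eta = fp.eta_from_k2(3.0, 11.0, 2.3, 0.47, 1e9)
        assert eta == pytest.approx(2.3 * 11.0, rel=1e-6)

    @pytest.mark.parametrize("k_clv", [1.53, 6.25])
    @pytest.mark.parametrize("sin_star", [0.2, 0.5])
    @pytest.mark.parametrize("k2_over_k1", [0.5, 3.0, 10.0])
    def test_linearization_matches_hold_simulation(self, k_clv, sin_star, k2_over_k1):
        """Formula vs numerical oracle: simulate a small-amplitude hold from a
        prescribed state and time it with an independent exponential fit."""
        from oracles import exp_relax_tau

        d = 28.4
        k1 = 2.0
        k2 = k2_over_k1 * k1
        eta = 6.0
        T0 = 5.0
        geometry = fp.FiberGeometry(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probe = fp.CantileverProbe(k_clv)
        params = fp.MechanicalParams(T0, k1, k2, eta)
        e0 = d * sin_star / math.sqrt(1.0 - sin_star**2)
        tau_guess = eta / k2 * 3.0
        t, e, _ = fp.relax_from_state(
            geometry, probe, params, e0, T_m0=0.05,
            duration=8.0 * tau_guess, sample_rate=50.0,
        )
        tau_sim, amp, r2 = exp_relax_tau(t[1:], e[1:] - e[0])
        assert r2 > 0.999
        delta0 = fp.transverse_to_elongation(geometry, e0)
        T_star = fp.constitutive_tension(params, delta0, 0.0)
        eta_back = fp.eta_from_k2(k1, k2, tau_sim, sin_star, k_clv, T_star=T_star, d=d)
        assert eta_back == pytest.approx(eta, rel=0.02)


class TestAggregatedError:
    def test_identity_is_zero(self, rng):
        e = rng.normal(size=100)
        assert fp.aggregated_error(e, e) == 0.0

    def test_constant_offset_closed_form(self, rng):
        e_exp = np.abs(rng.normal(size=200)) + 1.0
        c = 0.17
        e_sim = e_exp + c * np.max(np.abs(e_exp))
        assert fp.aggregated_error(e_sim, e_exp) == pytest.approx(c, rel=1e-12)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            fp.aggregated_error(
                np.zeros(5), np.zeros(5), t_sim=np.arange(5), t_exp=np.arange(5) + 0.5
            )

    def test_distinguishes_neighboring_fine_grid_candidates(
        self, geometry, probe, mean_params, reference_trace
    ):
        protocol = fp.StageProtocol()
        a, _ = fp.simulate_ensemble(
            geometry, probe, mean_params.T0, mean_params.k1 + 0.1, mean_params.k2,
            mean_params.eta, protocol, t_eval=reference_trace.t,
        )
        assert fp.aggregated_error(a[0], reference_trace.e) > 0.0


class TestGridSearch:
    def test_error_at_truth_bounds_every_probed_point(
        self, geometry, probe, mean_params, reference_trace
    ):
        protocol = fp.StageProtocol()
        e_true, _ = fp.simulate_ensemble(
            geometry, probe, mean_params.T0, mean_params.k1, mean_params.k2,
            mean_params.eta, protocol, t_eval=reference_trace.t,
        )
        err_truth = fp.aggregated_error(e_true[0], reference_trace.e)
        rng = np.random.default_rng(5)
        k1s = rng.uniform(0.5, 6.0, 8)
        k2s = rng.uniform(1.0, 30.0, 8)
        etas = rng.uniform(1.0, 20.0, 8)
        e_probe, _ = fp.simulate_ensemble(
            geometry, probe, np.full(8, mean_params.T0), k1s, k2s, etas,
            protocol, t_eval=reference_trace.t,
        )
        errs = fp.aggregated_error(e_probe, reference_trace.e[None, :])
        assert err_truth <= np.min(errs)
        assert err_truth < 1e-10

    def test_unbiased_pretension_recovers_truth_to_grid_resolution(self, reference_trace):
        """Isolates the search itself: with T0 fixed at truth the optimum must
        sit within one-or-two fine steps of the generating parameters."""
        halt = fp.detect_halt(reference_trace)
        rel = fp.fit_relaxation(reference_trace, halt=halt)
        res = F.grid_search(reference_trace, 7.44, rel, halt=halt, k1_upper=6.0)
        assert res.params.k1 == pytest.approx(3.23, abs=0.2)
        assert res.params.k2 == pytest.approx(10.94, abs=1.0)
        assert res.params.eta == pytest.approx(7.85, rel=0.15)

    def test_determinism_bit_identical(self, reference_trace):
        import fiberprobe.io as io

        cfg = fp.FitConfig(fine_step=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fp.fit_experiment(reference_trace, cfg)
            b = fp.fit_experiment(reference_trace, cfg)
        assert io.fit_result_to_dict(a) == io.fit_result_to_dict(b)

    def test_degenerate_relaxation_rejected(self, geometry, probe):
        params = fp.MechanicalParams(7.44, 3.23, 0.0, 1.0)  # pure elastic
        sim = fp.forward_simulate(geometry, probe, params, fp.StageProtocol(t_hold=4.0))
        tr = fp.ExperimentTrace.from_sim(sim)
        rel = fp.fit_relaxation(tr)
        assert rel.degenerate
        with pytest.raises(F.InsufficientDataError):
            F.grid_search(tr, 7.44, rel, k1_upper=6.0)

    def test_fit_config_validation(self):
        with pytest.raises(ValueError):
            fp.FitConfig(coarse_step=0.1, fine_step=2.0)
        with pytest.raises(ValueError):
            fp.FitConfig(k2_min=5.0, k2_max=1.0)


class TestCompareConditions:
    def _result(self, T0=7.44, k1=3.23, k2=10.94, eta=7.85):
        params = fp.MechanicalParams(T0, k1, k2, eta)
        rel = F.RelaxationFit(tau=2.0, e_inf=1.0, r_squared=0.99, t_star=4.0, e_star=13.0)
        pre = F.PretensionEstimate(T0_hat=T0, slope=5.0, n=100)
        halt = F.HaltInfo(4.0, 13.0, 20.0, 200, 5.0)
        diag = F.GridDiagnostics(100, 0.0, 0.1, False, False, (k1, k2))
        return F.FitResult(params, rel, pre, halt, 0.0, diag, fp.FitConfig())

    def test_identical_fits_give_unit_ratios(self):
        r = fp.compare_conditions(self._result(), self._result())
        assert (r.T0, r.k1, r.k2, r.eta) == (1.0, 1.0, 1.0, 1.0)

    def test_pretension_drop_isolated(self):
        r = fp.compare_conditions(self._result(), self._result(T0=0.58 * 7.44))
        assert r.T0 == pytest.approx(0.58)
        assert r.k1 == r.k2 == r.eta == 1.0

    def test_near_zero_denominator_flagged(self):
        r = fp.compare_conditions(self._result(T0=0.0), self._result())
        assert math.isnan(r.T0)
        assert "T0" in r.undefined
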