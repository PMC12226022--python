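"""Calcium-based plasticity engine: model pieces, integrator, calibration."""

import numpy as np
import pandas as pd
import pytest

from plastinet import plasticity as pl


def oracle_simulate(syn_row, pre_times, post_times, duration_ms, kernels, params,
                    dt_ms=0.01):
    """Independent slow reference integrator for one synapse.

    Evaluates the voltage/conductance kernels analytically (explicit sums of
    double exponentials over spike times) and integrates calcium, the leaky
    integrator and the efficacy ODE with plain forward Euler at a fine step;
    shares no code with the engine's filter-based path.
    """
    k, p = kernels, params

    def dexp(t, amp, rise, decay):
        t = np.asarray(t, float)
        norm = None
        tp = (decay * rise / (decay - rise)) * np.log(decay / rise)
        norm = np.exp(-tp / decay) - np.exp(-tp / rise)
        v = np.where(t >= 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
        return amp * v / norm

    att = np.exp(-syn_row["path_offset"] / k.bap_attenuation_um)
    n = int(round(duration_ms / dt_ms))
    ca, cs, rho = 0.0, 0.0, float(syn_row["rho"])
    td, tp_ = float(syn_row["theta_d"]), float(syn_row["theta_p"])
    gain = p.ca_gain_uM_per_pA_ms
    pre = np.asarray(pre_times, float) + k.synaptic_delay_ms
    post = np.asarray(post_times, float)
    for i in range(1, n + 1):
        t = i * dt_ms
        v = k.v_rest_mV
        v += dexp(t - pre, k.epsp_amplitude_mV, k.epsp_rise_ms, k.epsp_decay_ms).sum()
        v += att * dexp(t - post, k.bap_amplitude_mV, k.bap_rise_ms, k.bap_decay_ms).sum()
        g = dexp(t - pre, syn_row["g_NMDA_hat"], k.nmda_rise_ms, k.nmda_decay_ms).sum()
        m = 1.0 / (1.0 + (p.mg_out_mM / p.mg_theta) * np.exp(-p.mg_kappa * v))
        influx = -(g * m * (v - p.e_nmda_mV)) * gain
        jump = k.vdcc_impulse_gain_uM * att * np.sum((post > t - dt_ms) & (post <= t))
        ca += dt_ms * (influx - ca / p.tau_ca_ms) + jump
        cs += dt_ms * (-cs / p.tau_star_ms + ca)
        fd = 1.0 if (td >= 0 and cs > td) else 0.0
        fp = 1.0 if (tp_ >= 0 and cs > tp_) else 0.0
        drho = (-rho * (1 - rho) * (p.rho_star - rho)
                + p.gamma_p * (1 - rho) * fp - p.gamma_d * rho * fd) / p.tau_rho_s
        rho = min(1.0, max(0.0, rho + dt_ms * 1e-3 * drho))
    return rho


class TestMgBlock:
    def test_limit_of_full_depolarization(self, default_params):
        assert pl.mg_block(400.0, default_params) == pytest.approx(1.0, abs=1e-9)

    def test_algebraic_midpoint(self, default_params):
        p = default_params
        v_mid = np.log(p.mg_out_mM / p.mg_theta) / p.mg_kappa
        assert pl.mg_block(v_mid, p) == pytest.approx(0.5)

    def test_hand_evaluation_at_rest(self, default_params):
        hand = 1.0 / (1.0 + (1.0 / 2.552) * np.exp(0.072 * 70.0))
        assert pl.mg_block(-70.0, default_params) == pytest.approx(hand, rel=1e-12)

    def test_strictly_increasing(self, default_params):
        v = np.linspace(-90, 40, 200)
        m = pl.mg_block(v, default_params)
        assert np.all(np.diff(m) > 0) and np.all((m > 0) & (m < 1))

    def test_non_finite_rejected(self, default_params):
        with pytest.raises(ValueError):
            pl.mg_block(np.nan, default_params)


class TestNMDACurrent:
    def test_zero_conductance(self, default_params):
        assert pl.nmda_calcium_current(0.0, -50.0, default_params) == 0.0

    def test_reversal_potential(self, default_params):
        assert pl.nmda_calcium_current(1.0, default_params.e_nmda_mV, default_params) == 0.0

    def test_linear_in_conductance(self, default_params):
        i1 = pl.nmda_calcium_current(0.5, -40.0, default_params)
        i2 = pl.nmda_calcium_current(1.0, -40.0, default_params)
        assert i2 == pytest.approx(2 * i1)

    def test_subreversal_voltage_gives_influx(self, default_params):
        # inward (negative) current below reversal => positive calcium influx
        assert pl.nmda_calcium_current(1.0, -50.0, default_params) < 0

    def test_negative_conductance_rejected(self, default_params):
        with pytest.raises(ValueError):
            pl.nmda_calcium_current(-1.0, 0.0, default_params)


class TestCalciumSteps:
    def test_rest_is_fixed_point(self, default_params):
        p = default_params
        assert pl.step_calcium(p.ca_rest_uM, 0.0, 0.1, p) == pytest.approx(p.ca_rest_uM)

    def test_exponential_decay_of_excess(self, default_params):
        p = default_params
        ca = p.ca_rest_uM + 1.0
        n = 1000
        dt = p.tau_ca_ms / n
        for _ in range(n):
            ca = pl.step_calcium(ca, 0.0, dt, p)
        assert ca - p.ca_rest_uM == pytest.approx(np.exp(-1.0), rel=1e-9)

    def test_constant_influx_steady_state(self, default_params):
        p = default_params
        influx = 0.37  # µM/ms
        ca = p.ca_rest_uM
        for _ in range(5000):
            ca = pl.step_calcium(ca, influx, 0.05, p)
        assert ca == pytest.approx(p.ca_rest_uM + influx * p.tau_ca_ms, rel=1e-6)

    def test_ca_star_zero_at_rest(self, default_params):
        p = default_params
        assert pl.step_ca_star(0.0, p.ca_rest_uM, 0.1, p) == 0.0

    def test_ca_star_steady_state(self, default_params):
        p = default_params
        delta = 0.2
        cs = 0.0
        for _ in range(40000):
            cs = pl.step_ca_star(cs, p.ca_rest_uM + delta, 0.5, p)
        assert cs == pytest.approx(p.tau_star_ms * delta, rel=1e-6)

    def test_ca_star_impulse_integral(self, default_params):
        # for the linear leaky integrator the time-integral of the response
        # equals tau* times the integral of the calcium excess
        p = default_params
        dt = 0.05
        excess = np.zeros(120000)
        excess[1000:1400] = 0.8
        cs = 0.0
        total = 0.0
        for e in excess:
            cs = pl.step_ca_star(cs, p.ca_rest_uM + e, dt, p)
            total += cs * dt
        area = excess.sum() * dt
        assert total == pytest.approx(p.tau_star_ms * area, rel=1e-3)

    def test_nonpositive_dt_rejected(self, default_params):
        with pytest.raises(ValueError):
            pl.step_calcium(0.1, 0.0, 0.0, default_params)
        with pytest.raises(ValueError):
            pl.step_ca_star(0.0, 0.1, -1.0, default_params)


class TestRhoDynamics:
    def test_zero_is_fixed_point(self, default_params):
        assert pl.step_rho(0.0, 0.0, 10.0, 20.0, 0.1, default_params) == 0.0

    def test_convergence_from_09_toward_one(self, default_params):
        final = pl.integrate_rho_free(0.9, duration_s=600.0, dt_s=0.01,
                                      params=default_params)[0]
        assert final > 0.995
        # approach to the stable fixed point has rate (1)(rho*)/tau = 1/(2 tau):
        # residual after 600 s is ~0.1 exp(-600/140) ~ 1.9e-3, shrinking further
        longer = pl.integrate_rho_free(0.9, duration_s=1200.0, dt_s=0.01,
                                       params=default_params)[0]
        assert 1 - longer < (1 - final) / 10

    def test_bistability_around_separatrix(self, default_params):
        # growth rate away from rho* is 1/(4 tau): give the 1e-3 perturbation
        # enough time to saturate at the stable fixed points
        eps = 1e-3
        lo, hi = pl.integrate_rho_free([0.5 - eps, 0.5 + eps], 4000.0, 0.1,
                                       default_params)
        assert lo < 0.01 and hi > 0.99

    def test_separatrix_found_by_bisection(self, default_params):
        sep = pl.find_separatrix(default_params, tol=1e-6, duration_s=600.0, dt_s=0.05)
        assert sep == pytest.approx(0.5, abs=1e-6)

    def test_sentinel_thresholds_disable_updates(self, default_params):
        r = pl.step_rho(0.7, 1e9, -1.0, -1.0, 0.1, default_params)
        drift_only = pl.step_rho(0.7, 0.0, 1e12, 1e13, 0.1, default_params)
        assert r == pytest.approx(drift_only)


class TestThresholds:
    def test_identity_matrix(self, default_params):
        import dataclasses
        p = dataclasses.replace(default_params,
                                theta_matrix_apical=((1, 0), (0, 1)),
                                theta_matrix_basal=((1, 0), (0, 1)))
        td, tp = pl.derive_thresholds([3.0], [0.5], ["apical"], p)
        assert td[0] == 3.0 and tp[0] == 0.5

    def test_zero_peaks_give_zero_thresholds(self, default_params):
        td, tp = pl.derive_thresholds([0.0], [0.0], ["basal"], default_params)
        assert td[0] == 0.0 and tp[0] == 0.0

    def test_default_matrix_hand_multiplication(self, default_params):
        a = np.asarray(default_params.theta_matrix_apical)
        td, tp = pl.derive_thresholds([1.0], [1.0], ["apical"], default_params)
        assert td[0] == pytest.approx(a[0, 0] + a[0, 1])
        assert tp[0] == pytest.approx(a[1, 0] + a[1, 1])

    def test_non_plastic_sentinels(self, default_params):
        td, tp = pl.derive_thresholds([1.0, 1.0], [1.0, 1.0], ["apical", "basal"],
                                      default_params, plastic=[True, False])
        assert td[1] == -1.0 and tp[1] == -1.0 and td[0] > 0

    def test_bad_matrix_shape_rejected(self, default_params):
        import dataclasses
        p = dataclasses.replace(default_params, theta_matrix_apical=((1, 0, 0), (0, 1, 0)))
        with pytest.raises(ValueError):
            pl.derive_thresholds([1.0], [1.0], ["apical"], p)

    def test_negative_peaks_rejected(self, default_params):
        with pytest.raises(ValueError):
            pl.derive_thresholds([-1.0], [0.0], ["apical"], default_params)


class TestUseGampa:
    def test_potentiated_fixed_point(self, default_params):
        ep = default_params.endpoints
        u, g = pl.update_use_gampa(1.0, ep.u_se_p, ep.g_ampa_p, 10.0, default_params)
        assert u == pytest.approx(ep.u_se_p) and g == pytest.approx(ep.g_ampa_p)

    def test_relaxation_over_one_time_constant(self, default_params):
        ep = default_params.endpoints
        u, _ = pl.update_use_gampa(0.0, ep.u_se_p, ep.g_ampa_p,
                                   default_params.tau_change_s, default_params)
        assert u == pytest.approx(ep.u_se_d + (ep.u_se_p - ep.u_se_d) / np.e)

    def test_half_rho_converges_to_midpoint(self, default_params):
        ep = default_params.endpoints
        u, g = 0.9, 1.2
        for _ in range(200):
            u, g = pl.update_use_gampa(0.5, u, g, 10.0, default_params)
        assert u == pytest.approx(0.5 * (ep.u_se_d + ep.u_se_p), rel=1e-6)
        assert g == pytest.approx(0.5 * (ep.g_ampa_d + ep.g_ampa_p), rel=1e-6)

    def test_invalid_endpoints_rejected(self):
        with pytest.raises(ValueError):
            pl.PathwayEndpoints(u_se_d=0.8, u_se_p=0.3)


class TestCalciumPeaks:
    def test_zero_amplitude_kernels(self, default_params):
        k = pl.DriverKernels(epsp_amplitude_mV=0.0, bap_amplitude_mV=0.0,
                             vdcc_impulse_gain_uM=0.0)
        ref = pl._reference_table(g_nmda=0.0)  # NMDA amplitude is per-synapse
        c_pre, c_post = pl.measure_c_pre_c_post(ref, k, default_params)
        assert np.all(c_pre == 0.0) and np.all(c_post == 0.0)

    def test_presynaptic_peak_dominates(self, default_params, default_kernels):
        ref = pl._reference_table()
        c_pre, c_post = pl.measure_c_pre_c_post(ref, default_kernels, default_params)
        assert np.all(c_pre / c_post >= 100)

    def test_vdcc_gain_linearity(self, default_params, default_kernels):
        import dataclasses
        ref = pl._reference_table()
        _, c1 = pl.measure_c_pre_c_post(ref, default_kernels, default_params)
        k2 = dataclasses.replace(default_kernels,
                                 vdcc_impulse_gain_uM=2 * default_kernels.vdcc_impulse_gain_uM)
        _, c2 = pl.measure_c_pre_c_post(ref, k2, default_params)
        assert np.allclose(c2, 2 * c1, rtol=1e-9)


class TestSimulate:
    def _pairing(self, reference_synapse, lag_ms, n_pairs=30, rho0=0.5):
        syn = reference_synapse.copy()
        syn["rho"] = rho0
        pre = np.array([100.0 + 100.0 * i for i in range(n_pairs)])
        post = np.sort(pre + lag_ms)
        trains = {int(syn.pre[0]): pre, int(syn.post[0]): post}
        return syn, trains

    def test_no_spikes_exactly_stationary(self, reference_synapse, default_params,
                                          default_kernels):
        for rho0 in (0.0, 1.0):
            syn = reference_synapse.copy()
            syn["rho"] = rho0
            tr = pl.simulate(syn, {}, 3000.0, default_kernels, default_params,
                             report_dt_ms=500.0)
            assert np.all(tr.rho == rho0)

    def test_low_rate_pre_only_below_threshold(self, reference_synapse,
                                               default_params, default_kernels):
        syn = reference_synapse.copy()
        syn["rho"] = 1.0
        rng = np.random.default_rng(0)
        pre = np.sort(rng.uniform(0, 20000.0, size=2))  # 0.1 Hz
        tr = pl.simulate(syn, {int(syn.pre[0]): pre}, 20000.0,
                         default_kernels, default_params)
        assert np.all(tr.rho == 1.0)

    def test_coincident_volleys_drive_rho_up(self, reference_synapse,
                                             default_params, default_kernels):
        syn, trains = self._pairing(reference_synapse, 10.0, rho0=0.0)
        tr = pl.simulate(syn, trains, 5000.0, default_kernels, default_params,
                         report_dt_ms=200.0)
        assert tr.rho[0].max() > 0.4

    def test_against_independent_oracle_integrator(self, reference_synapse,
                                                   default_params, default_kernels):
        syn, trains = self._pairing(reference_synapse, 10.0, n_pairs=5, rho0=0.5)
        tr = pl.simulate(syn, trains, 1500.0, default_kernels, default_params,
                         report_dt_ms=1500.0, dt_ms=0.1)
        oracle = oracle_simulate(syn.iloc[0],
                                 trains[int(syn.pre[0])], trains[int(syn.post[0])],
                                 1500.0, default_kernels, default_params, dt_ms=0.01)
        assert tr.rho[0, -1] == pytest.approx(oracle, abs=5e-3)

    def test_dt_halving_convergence(self, reference_synapse, default_params,
                                    default_kernels):
        syn, trains = self._pairing(reference_synapse, 10.0, n_pairs=10, rho0=0.5)
        a = pl.simulate(syn, trains, 3000.0, default_kernels, default_params, dt_ms=0.1)
        b = pl.simulate(syn, trains, 3000.0, default_kernels, default_params, dt_ms=0.05)
        assert abs(a.rho[0, -1] - b.rho[0, -1]) < 1e-4

    def test_stdp_like_asymmetry(self, reference_synapse, default_params,
                                 default_kernels):
        syn, causal = self._pairing(reference_synapse, 10.0)
        _, anti = self._pairing(reference_synapse, -10.0)
        r_causal = pl.simulate(syn, causal, 5000.0, default_kernels,
                               default_params).rho[0, -1]
        r_anti = pl.simulate(syn, anti, 5000.0, default_kernels,
                             default_params).rho[0, -1]
        assert r_causal > r_anti

    def test_bounds_and_endpoint_intervals_on_random_input(self, reference_synapse,
                                                           default_params,
                                                           default_kernels):
        ep = default_params.endpoints
        syn = reference_synapse.copy()
        syn["rho"], syn["U_SE"], syn["g_AMPA_hat"] = 0.5, 0.4, 0.8
        rng = np.random.default_rng(1)
        trains = {int(syn.pre[0]): np.unique(rng.uniform(0, 10000, 200)),
                  int(syn.post[0]): np.unique(rng.uniform(0, 10000, 150))}
        tr = pl.simulate(syn, trains, 10000.0, default_kernels, default_params)
        assert np.all((tr.rho >= 0) & (tr.rho <= 1))
        assert np.all((tr.u_se >= ep.u_se_d - 1e-12) & (tr.u_se <= ep.u_se_p + 1e-12))
        assert np.all((tr.g_ampa >= ep.g_ampa_d - 1e-12) & (tr.g_ampa <= ep.g_ampa_p + 1e-12))

    def test_non_plastic_synapse_never_changes(self, reference_synapse,
                                               default_params, default_kernels):
        syn, trains = self._pairing(reference_synapse, 10.0, rho0=0.3)
        syn["plastic"] = False
        tr = pl.simulate(syn, trains, 4000.0, default_kernels, default_params)
        assert np.all(tr.rho == 0.3)

    def test_spike_outside_duration_rejected(self, reference_synapse,
                                             default_params, default_kernels):
        with pytest.raises(ValueError, match="outside"):
            pl.simulate(reference_synapse, {int(reference_synapse.pre[0]): [5000.0]},
                        1000.0, default_kernels, default_params)

    def test_missing_thresholds_rejected(self, reference_synapse, default_params,
                                         default_kernels):
        syn = reference_synapse.copy()
        syn["theta_d"] = np.nan
        with pytest.raises(ValueError, match="thresholds"):
            pl.simulate(syn, {}, 1000.0, default_kernels, default_params)

    def test_calcium_linearity_for_disjoint_events(self, reference_synapse,
                                                   default_params, default_kernels):
        # two presynaptic spikes far apart produce the same peak as one
        one = pl._calcium_peaks(reference_synapse, [50.0], [], default_kernels,
                                default_params, 0.1, 900.0, "ca")
        two = pl._calcium_peaks(reference_synapse, [50.0, 650.0], [], default_kernels,
                                default_params, 0.1, 900.0, "ca")
        assert np.allclose(one, two, atol=1e-6)


class TestCalibration:
    def test_defaults_reproduce_calibration(self, default_params, default_kernels):
        a, b = pl.calibrate_threshold_matrices(default_kernels, default_params)
        assert np.allclose(a, default_params.theta_matrix_apical, rtol=1e-4)
        assert np.allclose(b, default_params.theta_matrix_basal, rtol=1e-4)

    def test_single_pre_spike_crosses_neither_threshold(self, reference_synapse,
                                                        default_params,
                                                        default_kernels):
        peak = pl._calcium_peaks(reference_synapse, [50.0], [], default_kernels,
                                 default_params, 0.1, 600.0, "ca_star")[0]
        assert peak < reference_synapse["theta_d"].iloc[0]

    def test_coincident_pair_crosses_depression_threshold_only(
            self, reference_synapse, default_params, default_kernels):
        peak = pl._calcium_peaks(reference_synapse, [50.0], [60.0], default_kernels,
                                 default_params, 0.1, 600.0, "ca_star")[0]
        assert reference_synapse["theta_d"].iloc[0] < peak < reference_synapse["theta_p"].iloc[0]
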