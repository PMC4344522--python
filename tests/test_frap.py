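"""FRAP quantification: normalization arithmetic, kinetics and comparisons."""

import numpy as np
import pytest

from chromodyn import frap, simkit
from chromodyn.frap import (
    CurveEnsemble,
    IntensityTrace,
    NormalizedCurve,
    aggregate_curves,
    compare_kinetics,
    extract_trace,
    fit_recovery,
    normalize_trace,
    register_stack,
)


def make_trace(roi, nuc, n_pre=5, dt=1.0):
    roi = np.asarray(roi, dtype=float)
    n = len(roi)
    frames = np.arange(n)
    times = np.where(frames < n_pre, (frames - n_pre - 1) * dt, (frames - n_pre) * dt)
    phase = np.where(frames < n_pre, "pre", "post").astype(object)
    return IntensityTrace(times=times, roi_mean=roi,
                          nucleus_mean=np.asarray(nuc, dtype=float), phase=phase)


class TestRegistration:
    def test_static_stack_is_returned_unchanged(self, rng):
        stack = np.tile(rng.uniform(1, 10, size=(16, 16)), (4, 1, 1))
        registered, shifts = register_stack(stack)
        assert np.all(shifts == 0)
        np.testing.assert_array_equal(registered, stack)

    def test_integer_shift_inverted_exactly(self, rng):
        base = np.zeros((32, 32))
        base[10:20, 12:22] = rng.uniform(50, 100, size=(10, 10))
        shifted = np.roll(np.roll(base, 3, axis=0), -2, axis=1)
        registered, shifts = register_stack(np.stack([base, shifted]))
        np.testing.assert_allclose(shifts[1], [-3, 2])
        np.testing.assert_array_equal(registered[1], base)

    def test_all_zero_frame_is_an_error(self):
        stack = np.zeros((3, 8, 8))
        stack[0, 2, 2] = 1.0
        with pytest.raises(ValueError, match="no registration signal"):
            register_stack(stack)


class TestExtractTrace:
    def test_uniform_frames_give_equal_channel_means(self):
        stack = np.full((12, 10, 10), 7.0)
        nucleus = np.zeros((10, 10), bool)
        nucleus[2:8, 2:8] = True
        roi = np.zeros((10, 10), bool)
        roi[4:6, 4:6] = True
        trace = extract_trace(stack, roi, nucleus, bleach_frame_index=5)
        np.testing.assert_allclose(trace.roi_mean, 7.0)
        np.testing.assert_allclose(trace.nucleus_mean, 7.0)
        assert trace.n_prebleach == 5 and trace.n_postbleach == 6

    def test_planted_disk_intensity_recovered_exactly(self):
        stack = np.full((12, 20, 20), 100.0)
        nucleus = np.zeros((20, 20), bool)
        nucleus[2:18, 2:18] = True
        roi = np.zeros((20, 20), bool)
        roi[8:12, 8:12] = True
        stack[:, roi] = 200.0
        trace = extract_trace(stack, roi, nucleus, bleach_frame_index=5)
        np.testing.assert_allclose(trace.roi_mean, 200.0)

    def test_degenerate_masks_rejected(self):
        stack = np.ones((12, 10, 10))
        nucleus = np.ones((10, 10), bool)
        with pytest.raises(ValueError, match="empty ROI"):
            extract_trace(stack, np.zeros((10, 10), bool), nucleus, 5)
        roi_outside = np.zeros((10, 10), bool)
        roi_outside[0, 0] = True
        nucleus_small = np.zeros((10, 10), bool)
        nucleus_small[4:8, 4:8] = True
        with pytest.raises(ValueError, match="inside the nucleus"):
            extract_trace(stack, roi_outside, nucleus_small, 5)


class TestNormalization:
    def test_proportional_channels_normalize_to_one(self):
        roi = np.linspace(100, 80, 20)
        curve = normalize_trace(make_trace(roi, roi * 10))
        np.testing.assert_allclose(curve.values, 1.0)
        np.testing.assert_allclose(curve.prebleach_values, 1.0)

    def test_hand_computed_double_normalization(self):
        # pre5 roi mean 100, pre5 nucleus mean 1000; post roi 40, nucleus 950
        roi = [100] * 5 + [40] * 10
        nuc = [1000] * 5 + [950] * 10
        curve = normalize_trace(make_trace(roi, nuc))
        assert curve.values[0] == pytest.approx((40 / 100) / (950 / 1000), abs=1e-12)
        assert curve.values[0] == pytest.approx(0.42105, abs=1e-5)

    def test_pure_acquisition_bleaching_gives_flat_unit_curve(self):
        # both channels decay together with no bleach event: the whole-nucleus
        # division must cancel the decay entirely
        decay = 0.998 ** np.arange(40)
        curve = normalize_trace(make_trace(500 * decay, 5000 * decay))
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-12)

    def test_normalization_is_idempotent(self):
        kin = simkit.KineticParams(noise_sd=0.01)
        trace = simkit.simulate_frap_traces(kin, seed=4)[0]
        curve = normalize_trace(trace)
        renorm_input = IntensityTrace(
            times=trace.times,
            roi_mean=np.concatenate([curve.prebleach_values, curve.values]),
            nucleus_mean=np.ones_like(trace.times),
            phase=trace.phase,
        )
        again = normalize_trace(renorm_input)
        # the pre-bleach reference of an already-normalized curve is 1
        np.testing.assert_allclose(
            again.values,
            curve.values / curve.prebleach_values[-5:].mean(),
            atol=1e-12,
        )

    def test_too_few_prebleach_frames_rejected(self):
        with pytest.raises(ValueError, match="pre-bleach"):
            make_trace([1] * 4 + [1] * 6, [1] * 10, n_pre=4)


class TestAggregation:
    def test_identical_curves_have_zero_sem(self):
        t = np.arange(10.0)
        c = NormalizedCurve(times=t, values=np.full(10, 0.7), prebleach_values=np.ones(5))
        ens = aggregate_curves([c, c, c])
        np.testing.assert_allclose(ens.mean, 0.7)
        np.testing.assert_allclose(ens.sem, 0.0, atol=1e-12)
        assert ens.n_nuclei == 3

    def test_two_point_sem_matches_hand_value(self):
        t = np.arange(10.0)
        a = NormalizedCurve(times=t, values=np.full(10, 0.4), prebleach_values=np.ones(5))
        b = NormalizedCurve(times=t, values=np.full(10, 0.6), prebleach_values=np.ones(5))
        ens = aggregate_curves([a, b])
        np.testing.assert_allclose(ens.mean, 0.5)
        np.testing.assert_allclose(ens.sem, 0.1, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = NormalizedCurve(times=np.arange(10.0), values=np.ones(10),
                            prebleach_values=np.ones(5))
        b = NormalizedCurve(times=np.arange(10.0) * 2, values=np.ones(10),
                            prebleach_values=np.ones(5))
        with pytest.raises(ValueError, match="time grid"):
            aggregate_curves([a, b])


class TestFitRecovery:
    def closed_form_curve(self, tau=14.1, f0=0.3, plateau=0.9, dt=1.0, n=180):
        t = np.arange(n) * dt
        k = np.log(2) / tau
        values = f0 + (plateau - f0) * (1 - np.exp(-k * t))
        return NormalizedCurve(times=t, values=values, prebleach_values=np.ones(5))

    def test_constant_curve_is_fully_immobile(self):
        c = NormalizedCurve(times=np.arange(20.0), values=np.full(20, 0.5),
                            prebleach_values=np.ones(5))
        s = fit_recovery(c)
        assert s.no_recovery and s.tau_half is None
        assert s.immobile_fraction == 1.0 and s.plateau == 0.5

    def test_closed_form_curve_recovers_parameters(self):
        s = fit_recovery(self.closed_form_curve())
        assert s.tau_half == pytest.approx(14.1, abs=1.0)
        assert s.plateau == pytest.approx(0.9, abs=0.005)
        assert s.mobile_fraction == pytest.approx(0.6 / 0.7, abs=0.01)

    @pytest.mark.parametrize("tau", [2.0, 8.0, 30.0])
    def test_interpolated_and_exponential_methods_agree(self, tau):
        c = self.closed_form_curve(tau=tau)
        si = fit_recovery(c, method="interpolated")
        se = fit_recovery(c, method="exponential_fit")
        assert abs(si.tau_half - se.tau_half) <= 1.0  # one frame interval

    @pytest.mark.parametrize("tau", [0.5, 2.0, 8.0, 14.0, 30.0])
    @pytest.mark.parametrize("immobile", [0.0, 0.13, 0.35])
    def test_parameter_recovery_over_kinetic_grid(self, tau, immobile):
        """12 noisy nuclei per condition; estimates within 15% (tau) and
        0.05 absolute (immobile fraction) of the generating values."""
        dt = 0.25 if tau < 2 else 1.0  # fast acquisition for fast recovery
        kin = simkit.KineticParams(tau_half=tau, immobile_fraction=immobile,
                                   bleach_depth=0.3, noise_sd=0.02)
        acq = simkit.AcquisitionParams(frame_interval=dt)
        traces = simkit.simulate_frap_traces(kin, acq, n_nuclei=12, seed=815)
        ens = aggregate_curves([normalize_trace(t) for t in traces])
        for method in ("interpolated", "exponential_fit"):
            s = fit_recovery(ens, method=method)
            assert s.tau_half == pytest.approx(tau, rel=0.15)
            assert s.immobile_fraction == pytest.approx(immobile, abs=0.05)

    def test_acquisition_bleaching_does_not_bias_estimates(self):
        summaries = {}
        for rate in (0.0, 0.002):
            kin = simkit.KineticParams(tau_half=10.0, immobile_fraction=0.2,
                                       acq_bleach_rate=rate, noise_sd=0.0)
            ens = aggregate_curves(
                [normalize_trace(t) for t in simkit.simulate_frap_traces(kin, seed=0)]
            )
            summaries[rate] = fit_recovery(ens)
        assert summaries[0.002].tau_half == pytest.approx(summaries[0.0].tau_half, rel=0.02)
        assert summaries[0.002].immobile_fraction == pytest.approx(
            summaries[0.0].immobile_fraction, abs=0.02)


class TestCompareKinetics:
    @staticmethod
    def summaries(kin, n, seed, method="interpolated"):
        traces = simkit.simulate_frap_traces(kin, n_nuclei=n, seed=seed)
        return [fit_recovery(normalize_trace(t), method=method) for t in traces]

    def test_identical_groups_are_null(self):
        kin = simkit.KineticParams(noise_sd=0.02)
        group = self.summaries(kin, 8, seed=10)
        result = compare_kinetics(group, list(group), seed=0)
        assert result["tau_fold"] == pytest.approx(1.0)
        assert result["tau_p"] >= 0.9

    def test_separated_kinetics_detected(self):
        slow = self.summaries(simkit.KineticParams(tau_half=14.0, noise_sd=0.02), 10, 1)
        fast = self.summaries(simkit.KineticParams(tau_half=2.0, noise_sd=0.02), 10, 2)
        result = compare_kinetics(slow, fast, seed=0)
        assert result["tau_p"] < 0.01
        assert result["tau_fold"] == pytest.approx(7.0, rel=0.2)

    def test_group_without_defined_tau_skips_tau_comparison(self):
        flat = NormalizedCurve(times=np.arange(20.0), values=np.full(20, 0.4),
                               prebleach_values=np.ones(5))
        immobile_group = [fit_recovery(flat)] * 4
        mobile_group = self.summaries(simkit.KineticParams(noise_sd=0.02), 6, 3)
        result = compare_kinetics(immobile_group, mobile_group, seed=0)
        assert result["tau_p"] is None and result["tau_fold"] is None
        assert result["immobile_p"] is not None
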