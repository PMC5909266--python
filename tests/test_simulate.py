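"""Synthetic breathing generator: determinism, round trips, events, cohort."""

import numpy as np
import pytest

import respsurro as rs
from respsurro.core import InsufficientCyclesError, InvalidInputError


class TestSurrogateGeneration:
    def test_round_trip_period(self):
        params = rs.BreathingParams(
            mean_period=4.0, period_sd=0.0, surrogate_noise_sd=0.0,
            amplitude_sd_frac=0.0, drift_rate=0.0,
        )
        traces = rs.simulate_surrogate(params, rng=np.random.default_rng(0))
        cycles = rs.detect_extrema(traces[0].positions, 0.2)
        assert rs.respiratory_period(cycles) == pytest.approx(4.0, abs=0.2)

    def test_apnea_suppresses_extrema(self):
        params = rs.BreathingParams(
            mean_period=4.0, period_sd=0.0, surrogate_noise_sd=0.0,
            amplitude_sd_frac=0.0,
        )
        event = rs.IrregularityEvent("apnea", 30.0, 10.0, 0.0)
        traces = rs.simulate_surrogate(params, events=(event,), rng=np.random.default_rng(0))
        cycles = rs.detect_extrema(traces[0].positions, 0.2)
        t_in = cycles.end_inhalation_indices * 0.2
        inside = (t_in > 31.0) & (t_in < 39.0)
        assert not inside.any()

    def test_same_seed_bit_identical(self):
        params = rs.BreathingParams()
        a = rs.simulate_surrogate(params, rng=np.random.default_rng(42))
        b = rs.simulate_surrogate(params, rng=np.random.default_rng(42))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)

    def test_invalid_params_rejected(self):
        with pytest.raises(InvalidInputError):
            rs.BreathingParams(mean_period=0.5)
        with pytest.raises(InvalidInputError):
            rs.BreathingParams(marker_amplitudes=(-1.0, 8.0, 8.0))


class TestTargetGeneration:
    def test_constant_only_truth(self):
        truth = rs.CouplingTruth.uniform(b=(0, 0, 0), c=(1.0, 2.0, 3.0))
        params = rs.BreathingParams(surrogate_noise_sd=0.0)
        traces = rs.simulate_surrogate(params, rng=np.random.default_rng(0))
        target = rs.simulate_target(traces, truth, 0.2)
        assert np.allclose(target.positions, [1.0, 2.0, 3.0])

    def test_estimation_consistency(self, two_tone_scan, known_truth):
        model = rs.fit_quadratic_model(two_tone_scan, 25.0)
        assert np.allclose(model.coeffs, known_truth.coeffs, rtol=1e-6)

    def test_hysteresis_loop_area(self):
        """A velocity term makes the target lead the surrogate: the w-P
        trajectory over one cycle encloses a nonzero area."""
        params = rs.BreathingParams(
            mean_period=4.0, period_sd=0.0, surrogate_noise_sd=0.0,
            amplitude_sd_frac=0.0,
        )
        traces = rs.simulate_surrogate(params, rng=np.random.default_rng(0))
        with_e = rs.CouplingTruth.uniform(b=(1, 1, 1), e=(0.3, 0.3, 0.3))
        without_e = rs.CouplingTruth.uniform(b=(1, 1, 1))

        def loop_area(truth):
            target = rs.simulate_target(traces, truth, 0.2)
            w = traces[0].positions[:20]  # one 4-s cycle
            p = target.positions[:20, 1]
            return 0.5 * abs(np.sum(w * np.roll(p, -1) - np.roll(w, -1) * p))

        assert loop_area(with_e) > loop_area(without_e) + 1e-6


class TestScanPair:
    def test_zero_jitter_pair_identical_breathing(self, noiseless_params):
        truth = rs.CouplingTruth.uniform()
        a, b = rs.simulate_scan_pair(noiseless_params, truth, seed=0)
        assert np.allclose(a.surrogate(1).positions, b.surrogate(1).positions)

    def test_shift_round_trip(self, noiseless_params):
        truth = rs.CouplingTruth.uniform(a=(0, 0, 0))
        a, b = rs.simulate_scan_pair(
            noiseless_params, truth, seed=3, surrogate_shift=3.0,
            target_shift=(2.0, 2.0, 2.0), share_breathing=True,
        )
        for m in (1, 2, 3):
            assert rs.surrogate_drift(a, b, m, 10.0) == pytest.approx(3.0, abs=1e-9)
        corrected = rs.inter_scan(a, b, t_m=10.0, t_c=10.0, corrected=True, anchor="scan_b")
        assert corrected.rmse_3d < 1e-6

    def test_elapsed_timestamps(self, noiseless_params):
        truth = rs.CouplingTruth.uniform()
        a, b = rs.simulate_scan_pair(noiseless_params, truth, seed=0, elapsed_min=12.5)
        assert (b.acquired_at - a.acquired_at).total_seconds() / 60 == pytest.approx(12.5)

    def test_correlation_change_worsens_corrected_rmse(self):
        """A coupling change on scan B raises corrected inter-scan RMSE
        relative to the no-event pair (median over 10 seeds)."""
        truth = rs.CouplingTruth.uniform(
            b=(0.2, 1.5, 0.8), e=(0.05, 0.1, 0.05), target_noise_sd=0.2
        )
        event = rs.IrregularityEvent("correlation_change", 40.0, 25.0, 0.6)
        with_event, without_event = [], []
        for seed in range(10):
            params = rs.BreathingParams(surrogate_noise_sd=0.1)
            a, b = rs.simulate_scan_pair(params, truth, seed=seed, events_b=(event,))
            with_event.append(
                rs.inter_scan(a, b, t_m=10.0, t_c=10.0, corrected=True).rmse_3d
            )
            a2, b2 = rs.simulate_scan_pair(params, truth, seed=seed)
            without_event.append(
                rs.inter_scan(a2, b2, t_m=10.0, t_c=10.0, corrected=True).rmse_3d
            )
        assert np.median(with_event) > np.median(without_event)


class TestPhaseAverages:
    def test_output_shape(self, noiseless_scan):
        w_ave, p_phase = rs.simulate_phase_averages(noiseless_scan)
        assert w_ave.shape == (8,) and p_phase.shape == (8, 3)

    def test_linear_coupling_preserved(self):
        params = rs.BreathingParams(period_sd=0.1, surrogate_noise_sd=0.0)
        truth = rs.CouplingTruth.uniform(b=(2.0, 2.0, 2.0), c=(1.0, 1.0, 1.0))
        scan = rs.simulate_scan("lin", params, truth, rng=np.random.default_rng(3))
        w_ave, p_phase = rs.simulate_phase_averages(scan)
        assert np.allclose(p_phase, 2.0 * w_ave[:, None] + 1.0, atol=1e-9)

    def test_bin_zero_is_end_exhalation(self, noiseless_scan):
        w_ave, _ = rs.simulate_phase_averages(noiseless_scan)
        # trough dwell at end-exhalation: bin 0 near the minimum, bin 4 near max
        assert w_ave[0] == min(w_ave)
        assert w_ave[4] == pytest.approx(max(w_ave), abs=0.5)

    def test_insufficient_cycles(self):
        params = rs.BreathingParams(mean_period=12.0, period_sd=0.0,
                                    surrogate_noise_sd=0.0, amplitude_sd_frac=0.0)
        truth = rs.CouplingTruth.uniform()
        scan = rs.simulate_scan(
            "short", params, truth, duration=14.0, rng=np.random.default_rng(0)
        )
        with pytest.raises(InsufficientCyclesError):
            rs.simulate_phase_averages(scan)


class TestCohort:
    def test_determinism(self):
        a = rs.simulate_cohort(3, seed=5)
        b = rs.simulate_cohort(3, seed=5)
        for ma, mb in zip(a, b):
            assert np.array_equal(
                ma.scan_a.target.positions, mb.scan_a.target.positions
            )
            assert ma.surrogate_shift == mb.surrogate_shift

    def test_single_patient_usable_end_to_end(self):
        (member,) = rs.simulate_cohort(1, seed=2)
        report = rs.inter_scan(member.scan_a, member.scan_b, t_m=10.0,
                               t_c=10.0, corrected=True)
        assert np.isfinite(report.rmse_3d)

    def test_descriptor_medians_inside_population_ranges(self):
        members = rs.simulate_cohort(20, seed=0)
        periods, ir_amps, a3ds = [], [], []
        for m in members:
            cycles = rs.detect_extrema(m.scan_a.mean_surrogate(), 0.2)
            periods.append(rs.respiratory_period(cycles))
            ir_amps.append(
                rs.respiratory_amplitude(
                    rs.detect_extrema(m.scan_a.surrogate(1).positions, 0.2)
                )
            )
            dir_amps = [
                rs.respiratory_amplitude(
                    rs.detect_extrema(m.scan_a.target.positions[:, g], 0.2)
                )
                for g in range(3)
            ]
            a3ds.append(rs.amplitude_3d(dir_amps))
        assert 2.4 <= np.median(periods) <= 13.0
        assert 1.7 <= np.median(ir_amps) <= 14.6
        assert 2.8 <= np.median(a3ds) <= 34.2

    def test_noiseless_members_round_trip(self):
        """Zero-noise cohort draws give exact intra-scan consistency."""
        overrides = {
            "surrogate_noise_sd_mm": (0.0, 0.0),
            "target_noise_sd_mm": (0.0, 0.0),
        }
        members = rs.simulate_cohort(3, param_ranges=overrides, seed=1,
                                     event_probability=0.0)
        for m in members:
            assert rs.intra_scan(m.scan_a, t_m=10.0).rmse_3d < 1e-6
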