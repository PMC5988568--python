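"""Tests for burst detection, burst-triggered averages and tuning nulls."""

import numpy as np
import pytest

from headmotion import bursts
from headmotion.bursts import (
    Burst,
    burst_motion_latency,
    burst_triggered_average,
    classify_motion_tuning,
    detect_bursts,
    rate_duration_regression,
    shuffled_null,
    sta_within_outside_bursts,
    wrap_around_shifts,
)

DT = 0.02


class TestBurstDetection:
    def test_three_tight_spikes_form_one_burst(self):
        found, _ = detect_bursts(np.array([0.0, 0.010, 0.020]))
        assert len(found) == 1
        (b,) = found
        assert b.n_spikes == 3
        assert b.duration == pytest.approx(0.020)
        # ISI-based rate: (n - 1) spikes over the first-to-last span
        assert b.rate == pytest.approx(100.0)
        assert b.mean_isi == pytest.approx(0.010)

    def test_slow_spikes_form_no_burst(self):
        found, _ = detect_bursts(np.array([0.0, 0.060, 0.120]))
        assert found == []

    def test_short_span_fails_minimum_duration(self):
        found, _ = detect_bursts(np.array([0.0, 0.005, 0.012]))
        assert found == []

    def test_eligibility_requires_five_bursts(self):
        one_burst = np.array([0.0, 0.01, 0.02])
        spikes = np.concatenate([one_burst + k for k in range(4)])
        found, eligible = detect_bursts(spikes)
        assert len(found) == 4 and not eligible
        spikes = np.concatenate([one_burst + k for k in range(5)])
        found, eligible = detect_bursts(spikes)
        assert len(found) == 5 and eligible

    def test_maximal_runs_are_not_split(self):
        spikes = np.arange(10) * 0.04  # one long run of 40-ms ISIs
        found, _ = detect_bursts(spikes)
        assert len(found) == 1
        assert found[0].n_spikes == 10


def ramp_angles(n_bins, onsets_bins, ramp=15.0, ramp_bins=10):
    """Flat heading with a +ramp-degree excursion starting at each onset."""
    angles = np.zeros(n_bins)
    for ob in onsets_bins:
        profile = np.linspace(0.0, ramp, ramp_bins)
        angles[ob : ob + ramp_bins] = angles[ob - 1] + profile
        angles[ob + ramp_bins :] = angles[ob + ramp_bins - 1]
    return angles


class TestBurstTriggeredAverage:
    def test_identical_ramps_recover_their_amplitude(self):
        onsets_bins = np.arange(10) * 200 + 100
        moving = np.isin(np.arange(3000), (onsets_bins[:, None] + 1 + np.arange(10)).ravel())
        angles = np.cumsum(moving * 1.5)
        bta = burst_triggered_average(onsets_bins * DT, angles, DT)
        assert bta.n_bursts == 10
        assert bta.mean_displacement == pytest.approx(15.0, abs=1e-9)
        assert bta.trace_mean[25] == pytest.approx(0.0, abs=1e-12)  # zero at onset

    def test_constant_heading_gives_zero_displacement_and_flat_trace(self):
        onsets = np.array([2.0, 4.0, 6.0])
        bta = burst_triggered_average(onsets, np.full(500, 33.0), DT)
        assert bta.mean_displacement == 0.0
        np.testing.assert_array_equal(bta.trace_mean, 0.0)

    def test_negated_angles_negate_the_average_exactly(self, foraging_trajectory):
        traj, _ = foraging_trajectory
        yaw = traj["yaw"].to_numpy()
        onsets = np.arange(1.0, 250.0, 1.7)
        fwd = burst_triggered_average(onsets, yaw, DT)
        rev = burst_triggered_average(onsets, -yaw, DT)
        assert rev.mean_displacement == pytest.approx(-fwd.mean_displacement, rel=1e-12)
        np.testing.assert_allclose(rev.trace_mean, -fwd.trace_mean, atol=1e-12)

    def test_sign_follows_temporal_order_of_extrema(self):
        # falling then rising within the window: minimum precedes maximum
        angles = np.concatenate([np.zeros(30), np.linspace(0, -5, 5), np.linspace(-5, 10, 15), np.full(60, 10.0)])
        bta = burst_triggered_average(np.array([30 * DT]), angles, DT)
        assert bta.per_burst_displacements[0] == pytest.approx(15.0)
        # mirrored: maximum precedes minimum -> negative
        bta = burst_triggered_average(np.array([30 * DT]), -angles, DT)
        assert bta.per_burst_displacements[0] == pytest.approx(-15.0)

    def test_edge_bursts_are_dropped(self):
        angles = np.zeros(200)
        bta = burst_triggered_average(np.array([0.1, 2.0, 3.9]), angles, DT)
        assert bta.n_bursts == 1  # only the middle onset has a full window


class TestShuffledNull:
    def test_shifts_stay_in_range_and_defaults_echo(self, rng):
        shifts = wrap_around_shifts(1000, 300.0, rng)
        assert ((shifts >= 20.0) & (shifts <= 150.0)).all()
        null = shuffled_null(np.arange(10.0, 290.0, 7.0), np.zeros(15000), 300.0, DT, seed=0)
        assert null.n_reps == 1000

    def test_wraparound_preserves_inter_burst_structure(self, rng):
        onsets = np.sort(rng.uniform(0, 300, 40))
        shift = 77.7
        shifted = np.sort((onsets + shift) % 300.0)
        orig = np.sort(np.diff(np.sort(onsets)))
        new = np.sort(np.diff(shifted))
        # rigid circular shift: the multiset of gaps differs in at most one gap
        assert np.isin(np.round(new, 9), np.round(np.concatenate([orig, [300.0]]), 9)).sum() >= len(new) - 2

    def test_null_covers_the_statistic_for_untuned_bursts(self, foraging_trial_pair):
        """Motion-independent onsets fall inside the null bounds ~95% of runs."""
        (traj, _), _ = foraging_trial_pair
        yaw = traj["yaw"].to_numpy()
        inside = 0
        n_runs = 40
        for k in range(n_runs):
            rng = np.random.default_rng(900 + k)
            onsets = np.sort(rng.uniform(2.0, 290.0, 40))
            bta = burst_triggered_average(onsets, yaw, DT)
            null = shuffled_null(onsets, yaw, 300.0, DT, n_reps=200, seed=1900 + k)
            inside += null.lower <= bta.mean_displacement <= null.upper
        assert inside >= int(0.85 * n_runs)

    def test_short_trial_caps_shift_range(self, rng, caplog):
        shifts = wrap_around_shifts(100, 100.0, rng)
        assert shifts.max() <= 100.0


class TestClassification:
    @staticmethod
    def _mock(stat, lo=-1.0, hi=1.0, n=20):
        bta = bursts.BtaResult("yaw", np.zeros(76), np.zeros(76), np.full(n, stat), stat, n, np.arange(n))
        null = bursts.ShuffleNull(np.array([0.0]), lo, hi, 1000)
        return bta, null

    def test_consistent_exceedance_in_both_trials_is_tuned(self):
        res = classify_motion_tuning(self._mock(5.0), self._mock(4.0))
        assert res.tuned and res.direction == 1

    def test_single_trial_exceedance_is_not_tuned(self):
        res = classify_motion_tuning(self._mock(5.0), self._mock(0.5))
        assert not res.tuned

    def test_sign_inconsistency_is_not_tuned(self):
        res = classify_motion_tuning(self._mock(5.0), self._mock(-5.0))
        assert not res.tuned

    def test_ineligible_trial_marks_component_untestable(self):
        res = classify_motion_tuning(self._mock(5.0), self._mock(5.0), eligible2=False)
        assert not res.testable and not res.tuned

    def test_planted_yaw_neuron_recovered_with_direction(self, foraging_trial_pair):
        from headmotion.synth import NeuronModel, simulate_spike_train

        per_trial = {}
        for li, (traj, events) in enumerate(foraging_trial_pair):
            nm = NeuronModel(
                kind="displacement_tuned", preferred_vector=(15.0, 0.0, 0.0),
                seed=70 + li,
            )
            spikes = simulate_spike_train(traj, events, nm)
            found, eligible = detect_bursts(spikes)
            onsets = np.array([b.onset for b in found])
            for ci, comp in enumerate(("yaw", "pitch", "roll")):
                ang = traj[comp].to_numpy()
                bta = burst_triggered_average(onsets, ang, DT, comp)
                null = shuffled_null(onsets, ang, 300.0, DT, seed=50 + 2 * ci + li)
                per_trial.setdefault(comp, []).append((bta, null, eligible))
        results = {
            comp: classify_motion_tuning(
                trials[0][:2], trials[1][:2], trials[0][2], trials[1][2]
            )
            for comp, trials in per_trial.items()
        }
        assert results["yaw"].tuned and results["yaw"].direction == 1
        assert not results["pitch"].tuned
        assert not results["roll"].tuned
        assert np.mean(results["yaw"].mean_displacements) == pytest.approx(15.0, rel=0.2)


class TestSpikeClassComparison:
    def test_within_burst_spikes_carry_the_tuning(self, foraging_trial_pair):
        from headmotion.synth import NeuronModel, simulate_spike_train

        traj, events = foraging_trial_pair[0]
        nm = NeuronModel(
            kind="displacement_tuned", preferred_vector=(15.0, 0.0, 0.0),
            baseline_rate=3.0, seed=71,
        )
        spikes = simulate_spike_train(traj, events, nm)
        found, _ = detect_bursts(spikes)
        cmp = sta_within_outside_bursts(spikes, found, traj["yaw"].to_numpy(), DT)
        assert abs(cmp.within_mean) > abs(cmp.outside_mean)

    def test_empty_classes_are_flagged_not_raised(self):
        angles = np.zeros(1000)
        burst = Burst(onset=5.0, offset=5.02, n_spikes=3)
        spikes = np.array([5.0, 5.01, 5.02])
        cmp = sta_within_outside_bursts(spikes, [burst], angles, DT)
        assert cmp.outside_mean is None and cmp.n_outside == 0
        cmp = sta_within_outside_bursts(spikes, [], angles, DT)
        assert cmp.within_mean is None


class TestBurstMotionLatency:
    def test_planted_lead_time_shows_up_in_the_premotor_window(self):
        rng = np.random.default_rng(3)
        event_onsets = np.sort(rng.uniform(5.0, 295.0, 60))
        # bursts lead motion by ~80 ms with a little physiological jitter
        burst_onsets = event_onsets - 0.08 + rng.normal(0.0, 0.005, 60)
        lat = burst_motion_latency(burst_onsets, event_onsets)
        assert lat.window_means[(-0.08, -0.02)] > lat.window_means[(-0.16, -0.10)]

    def test_independent_bursts_have_near_zero_window_means(self):
        rng = np.random.default_rng(4)
        events = np.sort(rng.uniform(5.0, 295.0, 80))
        onsets = np.sort(rng.uniform(5.0, 295.0, 300))
        lat = burst_motion_latency(onsets, events)
        for mean in lat.window_means.values():
            assert abs(mean) < 1.0  # z-scored: no window stands out

    def test_bursts_at_onset_peak_in_the_zero_bin(self):
        events = np.arange(10.0, 200.0, 3.0)
        lat = burst_motion_latency(events.copy(), events)
        assert lat.bin_starts[np.argmax(lat.z_scores)] == pytest.approx(0.0)

    def test_requires_ten_events(self):
        with pytest.raises(ValueError, match="10"):
            burst_motion_latency(np.arange(5.0), np.arange(5.0))


class TestRateDurationRegression:
    @staticmethod
    def _bursts(rng, n=200):
        onsets = np.sort(rng.uniform(0, 500, n))
        return [
            Burst(onset=o, offset=o + d, n_spikes=k)
            for o, d, k in zip(onsets, rng.uniform(0.02, 0.2, n), rng.integers(3, 12, n))
        ]

    def test_independent_displacements_have_low_r2(self, rng):
        bl = self._bursts(rng)
        disp = rng.normal(10.0, 5.0, len(bl))
        reg = rate_duration_regression(bl, disp)
        assert reg.r2_rate < 0.05
        assert reg.r2_duration < 0.05

    def test_constructed_rate_dependence_is_recovered(self, rng):
        bl = self._bursts(rng)
        disp = 0.5 * np.array([b.rate for b in bl])
        reg = rate_duration_regression(bl, disp)
        assert reg.slope_rate == pytest.approx(0.5, rel=1e-9)
        assert reg.r2_rate == pytest.approx(1.0)

    def test_duration_slope_is_reported_per_10ms(self, rng):
        bl = self._bursts(rng)
        disp = 100.0 * np.array([b.duration for b in bl])  # 1 deg per 10 ms
        reg = rate_duration_regression(bl, disp)
        assert reg.slope_duration_per_10ms == pytest.approx(1.0, rel=1e-9)

    def test_constant_displacement_gives_zero_slope_and_r2(self, rng):
        bl = self._bursts(rng)
        reg = rate_duration_regression(bl, np.full(len(bl), 7.0))
        assert reg.slope_rate == 0.0 and reg.r2_rate == 0.0
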