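"""Generator contracts: determinism, rate conservation, planted recoverability."""

import pickle

import numpy as np
import pytest

from scgate.laminar import THETA_GRID, channel_significance, trial_delta_fr
from scgate.saccades import compute_kinematics, detect_saccades
from scgate.synthetic_data import (GeneratorConfig, PlannedSaccade,
                                   generate_eye_trace, generate_laminar_mua,
                                   generate_session, motor_kernel,
                                   sample_inhomogeneous_poisson,
                                   truncated_normal, visual_kernel)


def _tiny_config(**overrides):
    defaults = dict(
        seed=5,
        n_neurons_by_class={"visual": 4, "visual_movement": 2, "movement": 1},
        n_stim_trials_per_phase=30,
        n_behavior_trials_per_phase=5,
        n_map_trials_per_phase=10,
        n_saccade_trials_per_phase=5,
        n_mua_trials=12,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


class TestConfigValidation:
    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            _tiny_config(n_stim_trials_per_phase=0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            _tiny_config(baseline_rate=-1.0)

    def test_v1_requires_aperture(self):
        with pytest.raises(ValueError):
            _tiny_config(scenario="V1", stimulus_aperture=None)

    def test_surface_channel_outside_probe_rejected(self):
        with pytest.raises(ValueError):
            _tiny_config(true_surface_channel=33)


class TestKernels:
    def test_visual_kernel_rises_at_30_peaks_at_50(self):
        t = np.arange(0.0, 200.0, 1.0)
        k = visual_kernel(t)
        assert k[np.searchsorted(t, 20)] < 0.05 * k.max()
        assert abs(t[np.argmax(k)] - 50.0) <= 2.0
        # second, smaller bump near 90 ms: local max after the trough
        after = k[(t > 75) & (t < 110)]
        assert after.max() > k[(t > 70) & (t < 75)].min()

    def test_visual_kernel_mean_over_response_window_is_one(self):
        t = np.arange(30.0, 130.0, 0.1) + 0.05
        assert np.mean(visual_kernel(t)) == pytest.approx(1.0, rel=1e-3)

    def test_motor_kernel_peaks_before_saccade_onset(self):
        t = np.arange(-100.0, 100.0, 0.5)
        k = motor_kernel(t)
        assert t[np.argmax(k)] == pytest.approx(-10.0, abs=1.0)
        w = np.arange(-50.0, 25.0, 0.1) + 0.05
        assert np.mean(motor_kernel(w)) == pytest.approx(1.0, rel=1e-3)


class TestDeterminismAndTruth:
    def test_same_seed_gives_byte_identical_bundles(self):
        cfg = _tiny_config()
        a = generate_session(cfg)
        b = generate_session(_tiny_config())
        assert pickle.dumps(a) == pickle.dumps(b)

    def test_different_seed_changes_output(self):
        a = generate_session(_tiny_config())
        b = generate_session(_tiny_config(seed=6))
        assert pickle.dumps(a) != pickle.dumps(b)

    def test_truncated_normal_matches_requested_mean(self, rng):
        x = truncated_normal(48.8, 36.0, 12.0, 40000, rng)
        assert x.min() >= 12.0
        assert np.mean(x) == pytest.approx(48.8, abs=2 * 36.0 / np.sqrt(40000) * 3)

    def test_population_mean_amplitude_within_two_sem(self):
        # law-of-large-numbers check on the drawn ground truth
        cfg = GeneratorConfig(
            seed=2, n_neurons_by_class={"visual": 90, "visual_movement": 25,
                                        "movement": 0},
            n_stim_trials_per_phase=5, n_saccade_trials_per_phase=5,
        )
        bundle = generate_session(cfg, parts=set())
        vis = [n.true_evoked_before for n in bundle.neurons
               if n.functional_class == "visual"]
        sem = 36.0 / np.sqrt(len(vis))
        assert abs(np.mean(vis) - 48.8) <= 2 * sem

    def test_class_invariants_hold(self, small_lgn_bundle):
        for n in small_lgn_bundle.neurons:
            if n.functional_class == "visual":
                assert n.true_motor_amplitude == 0.0
            if n.functional_class == "movement":
                assert n.true_evoked_before == 0.0 == n.true_evoked_during
            assert n.snr > 0

    def test_visual_gain_is_multiplicative_and_shared(self, small_lgn_bundle):
        cfg = small_lgn_bundle.config
        for n in small_lgn_bundle.neurons:
            if n.true_evoked_before > 0:
                gain = n.true_evoked_during / n.true_evoked_before
                assert gain == pytest.approx(
                    cfg.visual_gain(n.functional_class), rel=1e-12)


class TestSpikeStatistics:
    def test_expected_count_equals_rate_integral(self, rng):
        # conservation at 1% with >= 1e4 trials
        rate = 10.0 + 40.0 * visual_kernel(np.arange(-300.0, 500.0) + 0.5)
        trials = sample_inhomogeneous_poisson(rate, 10000, rng, t0_ms=-300.0)
        counts = np.array([t.size for t in trials])
        assert counts.mean() == pytest.approx(rate.sum() * 1e-3, rel=0.01)

    def test_zero_during_amplitude_gives_zero_mean_dfr(self):
        cfg = _tiny_config(
            evoked_mean_during={"visual": 0.0, "visual_movement": 0.0,
                                "movement": 0.0},
            n_neurons_by_class={"visual": 10, "visual_movement": 0,
                                "movement": 0},
            n_stim_trials_per_phase=80)
        bundle = generate_session(cfg, parts={"stimulus"})
        from scgate.evoked import delta_fr
        means = []
        for n in bundle.neurons:
            _, m = delta_fr(n.stim_spikes["during"],
                            bundle.stim_onsets("during"),
                            (30.0, 130.0), (-100.0, 0.0))
            means.append(m)
        assert abs(np.mean(means)) < 1.0       # spikes/s, Poisson error only

    def test_evoked_dfr_recovers_planted_amplitude(self, rng):
        amp = 40.0
        rate = 10.0 + amp * visual_kernel(np.arange(-300.0, 500.0) + 0.5)
        trials = sample_inhomogeneous_poisson(rate, 10000, rng, t0_ms=-300.0)
        dfr = trial_delta_fr(trials, (30.0, 130.0), (-100.0, 0.0))
        assert np.mean(dfr) == pytest.approx(amp, rel=0.02)


class TestEyeTraceGeneration:
    def test_empty_plan_never_crosses_velocity_threshold(self):
        trace = generate_eye_trace([], 1000.0, rng=np.random.default_rng(0))
        speed, _ = compute_kinematics(trace)
        assert np.nanmax(speed) < 30.0

    def test_planted_saccade_satisfies_detector_thresholds(self):
        trace = generate_eye_trace([PlannedSaccade(300.0, (8.0, 0.0))],
                                   1000.0, rng=np.random.default_rng(1))
        speed, accel = compute_kinematics(trace)
        above = speed > 30.0
        runs = np.flatnonzero(np.diff(np.concatenate(
            [[False], above, [False]]).astype(int)))
        assert runs.size == 2                      # exactly one interval
        start, stop = runs
        assert stop - start >= 12
        assert np.nanmax(np.abs(accel[start:stop])) > 8000.0

    def test_peak_velocity_grows_with_amplitude(self):
        peaks = []
        for amp in (2.0, 5.0, 10.0):
            trace = generate_eye_trace([PlannedSaccade(300.0, (amp, 0.0))],
                                       1000.0, noise_sd=0.0)
            speed, _ = compute_kinematics(trace)
            peaks.append(np.nanmax(speed))
        assert peaks[0] < peaks[1] < peaks[2]
        assert peaks[0] >= 30.0

    def test_endpoint_bounds_enforced(self):
        ok = [PlannedSaccade(100.0, (25.0, 18.0))]
        generate_eye_trace(ok, 500.0, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_eye_trace([PlannedSaccade(100.0, (25.0, 18.1))], 500.0)

    def test_overlapping_saccades_rejected(self):
        plan = [PlannedSaccade(100.0, (8.0, 0.0)),
                PlannedSaccade(105.0, (0.0, 0.0))]
        with pytest.raises(ValueError):
            generate_eye_trace(plan, 500.0)

    def test_free_viewing_saccades_recoverable(self, small_lgn_bundle):
        cfg = small_lgn_bundle.config
        trace = small_lgn_bundle.free_view_traces["before"]
        events = detect_saccades(trace)
        planted = small_lgn_bundle.saccade_onsets["before"]
        # one in-RF and one return saccade per slot
        assert len(events) == 2 * planted.size
        detected_onsets = np.array([e.onset_ms for e in events])
        for t0 in planted:
            assert np.min(np.abs(detected_onsets - t0)) <= 5.0


@pytest.fixture(scope="module")
def mua_before():
    cfg = _tiny_config(n_mua_trials=60)
    return cfg, generate_laminar_mua(cfg, "before", np.random.default_rng(3))


class TestLaminarMUAGeneration:

    def test_counts_non_increasing_with_threshold(self, mua_before):
        cfg, mua = mua_before
        thetas = sorted(mua.thetas, key=abs)
        totals = {t: np.array([sum(len(x) for x in mua.events[t][ch])
                               for ch in range(cfg.n_channels)])
                  for t in thetas}
        for a, b in zip(thetas, thetas[1:]):
            assert np.all(totals[b] <= totals[a])
        # noise thinning is strict between -3 and -4 for every channel
        assert np.all(totals[-4.0] < totals[-3.0])

    def test_channels_above_surface_carry_no_genuine_drive(self, mua_before):
        cfg, mua = mua_before
        # at -5 SD the volume-conducted bleed is gone: channels above the
        # surface are pure noise. A genuinely driven channel would show a
        # large evoked rate change at an astronomically small p; noise-only
        # channels may occasionally brush the FDR threshold but never that.
        table = channel_significance(mua, -5.0)
        above = table[table["channel"] < cfg.true_surface_channel]
        assert np.all(above["p"] > 1e-4)
        assert np.all(np.abs(above["delta_fr"]) < 5.0)

    def test_driven_channels_significant_at_minus_5(self, mua_before):
        cfg, mua = mua_before
        table = channel_significance(mua, -5.0)
        s = cfg.true_surface_channel
        run = table[(table["channel"] >= s) & (table["channel"] < s + 3)]
        assert run["significant"].all()

    def test_during_with_zero_gain_abolishes_evoked_mua(self):
        cfg = _tiny_config(
            evoked_mean_during={"visual": 0.0, "visual_movement": 0.0,
                                "movement": 0.0},
            n_mua_trials=60)
        mua = generate_laminar_mua(cfg, "during", np.random.default_rng(4))
        table = channel_significance(mua, -5.0)
        assert not table["significant"].any()


class TestScenarioContract:
    def test_motor_truth_identical_across_phases(self):
        bundle = generate_session(_tiny_config(scenario="LGN_plus_contraSC",
                                               n_neurons_by_class={
                                                   "visual": 2,
                                                   "visual_movement": 2,
                                                   "movement": 2}),
                                  parts={"stimulus", "motor"})
        assert bundle.config.phases == ("before", "during_lgn", "during_both")
        for n in bundle.neurons:
            assert set(n.stim_spikes) == set(bundle.config.phases)
            # a single motor amplitude drives every phase
            assert isinstance(n.true_motor_amplitude, float)

    def test_unknown_part_rejected(self):
        with pytest.raises(ValueError):
            generate_session(_tiny_config(), parts={"nope"})
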