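"""Envelope pipeline: filter responses, normalization contracts, invariances."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgrepro as er
from emgrepro.cohort import TrialRecording, draw_subject_effects, eval_template
from emgrepro.errors import DegenerateInputError, LengthError, ParameterError, SchemaError
from emgrepro.preprocessing import EnvelopeExtractor

FS = 2148.0


def tone(freq, fs=FS, seconds=3.0, amplitude=1.0):
    t = np.arange(int(fs * seconds)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


class TestBandpass:
    def test_stopband_5hz_attenuated(self):
        x = tone(5.0)
        assert rms(er.bandpass(x, FS)) < 0.05 * rms(x)

    def test_passband_100hz_preserved(self):
        x = tone(100.0)
        assert rms(er.bandpass(x, FS)) > 0.95 * rms(x)

    def test_zero_in_zero_out(self):
        out = er.bandpass(np.zeros(3000), FS)
        np.testing.assert_array_equal(out, 0.0)
        assert out.size == 3000

    def test_low_fs_rejected(self):
        with pytest.raises(ParameterError):
            er.bandpass(np.zeros(3000), 800.0)

    def test_short_signal_rejected(self):
        with pytest.raises(LengthError):
            er.bandpass(np.zeros(10), FS)


class TestNotch:
    def test_line_frequency_suppressed(self):
        x = tone(50.0)
        assert rms(er.notch(x, FS)) <= 0.10 * rms(x)

    def test_neighbouring_content_preserved(self):
        x = tone(100.0)
        assert rms(er.notch(x, FS)) >= 0.89 * rms(x)

    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(er.notch(np.zeros(3000), FS), 0.0)


class TestRectifyEnvelope:
    def test_rectify_is_absolute_value(self):
        np.testing.assert_array_equal(er.rectify([-3.0, 2.0, -0.5]), [3.0, 2.0, 0.5])

    def test_rectify_idempotent(self):
        x = np.sin(np.linspace(0, 20, 500))
        np.testing.assert_array_equal(er.rectify(er.rectify(x)), er.rectify(x))

    def test_rectified_sine_mean_is_2A_over_pi(self):
        # mean of |A sin| over whole cycles is 2A/pi
        x = er.rectify(tone(100.0, seconds=1.0, amplitude=3.0))
        assert abs(x.mean() - 2 * 3.0 / np.pi) < 0.01

    def test_envelope_dc_gain_is_unity(self):
        out = er.envelope(np.ones(3000), FS)
        np.testing.assert_allclose(out, 1.0, rtol=1e-6)

    @pytest.mark.parametrize("amplitude", [1.0, 2.5])
    def test_envelope_of_rectified_sine_is_2A_over_pi(self, amplitude):
        env = er.envelope(er.rectify(tone(100.0, amplitude=amplitude)), FS)
        mid = env[len(env) // 4 : -len(env) // 4]
        np.testing.assert_allclose(mid, 2 * amplitude / np.pi, rtol=0.05)

    def test_envelope_nonnegative(self):
        rng = np.random.default_rng(0)
        env = er.envelope(er.rectify(rng.standard_normal(4000)), FS)
        assert (env >= 0).all()

    def test_zero_lag_preserves_symmetry(self):
        # a symmetric pulse must come out symmetric: forward-backward filtering
        # cancels phase
        n = 4001
        pulse = np.exp(-((np.arange(n) - n // 2) ** 2) / (2 * 80.0**2))
        env = er.envelope(pulse, FS)
        # clipping sub-1e-8 negative overshoot breaks symmetry only at that scale
        np.testing.assert_allclose(env, env[::-1], atol=1e-6)


class TestTimeNormalize:
    def test_ramp_maps_to_fractions(self):
        for n in (37, 250, 4000):
            ramp = np.linspace(0.0, 1.0, n)
            np.testing.assert_allclose(er.time_normalize(ramp), np.arange(100) / 99,
                                       atol=1e-12)

    def test_constant_stays_constant(self):
        np.testing.assert_array_equal(er.time_normalize(np.full(777, 0.4)), 0.4)

    def test_identity_on_matching_grid(self):
        rng = np.random.default_rng(1)
        x = rng.random(100)
        np.testing.assert_allclose(er.time_normalize(x), x, atol=1e-12)

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(2)
        x = rng.random(321)
        out = er.time_normalize(x)
        assert out[0] == x[0] and out[-1] == x[-1]

    def test_too_short_rejected(self):
        with pytest.raises(LengthError):
            er.time_normalize([1.0])


class TestPeakNormalize:
    def test_cross_repetition_maximum(self):
        reps = [np.full(10, 2.0), np.full(10, 4.0), np.full(10, 3.0)]
        scaled, peak, rep_of_peak = er.peak_normalize(reps)
        assert peak == 4.0 and rep_of_peak == 2
        np.testing.assert_allclose([s.max() for s in scaled], [0.5, 1.0, 0.75])

    def test_single_repetition(self):
        scaled, peak, _ = er.peak_normalize([np.array([0.0, 2.0])])
        assert peak == 2.0
        np.testing.assert_array_equal(scaled[0], [0.0, 1.0])

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        reps = [rng.random(50) for _ in range(3)]
        a, _, _ = er.peak_normalize(reps)
        b, _, _ = er.peak_normalize([7.0 * r for r in reps])
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            er.peak_normalize([np.zeros(10), np.zeros(10)])


class TestTrialPipeline:
    def test_zero_trial_gives_zero_envelopes(self):
        trial = TrialRecording("S01", 1, FS, ("BB", "TB"), np.zeros((3000, 2)))
        for env in er.preprocess_trial(trial).values():
            np.testing.assert_array_equal(env, 0.0)
            assert env.size == 3000

    def test_recovers_generating_envelope_in_noise_free_case(self, mini_spec):
        # remove all randomness except the carrier: the recovered envelope must
        # track the modulator used to generate the trial
        spec = dataclasses.replace(
            mini_spec, line_amp=0.0, noise_floor=0.0, sigma_subject_amp=0.0,
            sigma_subject_time=0.0, sigma_trial_amp=0.0, sigma_trial_time=0.0,
        )
        trial = er.generate_trial(spec, draw_subject_effects(spec, 0), 0, 1)
        envs = er.preprocess_trial(trial)
        pos = np.linspace(0, 100, trial.n_samples)
        for muscle in spec.muscles:
            target = eval_template(spec.templates[muscle], pos)
            got = envs[muscle]
            coeff = np.dot(got, target) / (np.linalg.norm(got) * np.linalg.norm(target))
            assert coeff > 0.95


class TestCohortPipeline:
    def test_profile_counts_and_normalization_contract(self, mini_spec, mini_profiles):
        n = mini_spec.n_subjects * len(mini_spec.muscles) * mini_spec.n_reps
        groups = mini_profiles.groupby(["subject_id", "muscle", "rep_index"])
        assert len(groups) == n
        assert (mini_profiles["value"] >= 0).all()
        assert (mini_profiles["value"] <= 1.0 + 1e-9).all()
        # peak normalization: max over each subject x muscle's reps is exactly 1
        for _, grp in mini_profiles.groupby(["subject_id", "muscle"]):
            assert abs(grp["value"].max() - 1.0) < 1e-9

    def test_global_gain_invariance(self, mini_trials):
        scaled = [
            TrialRecording(t.subject_id, t.rep_index, t.fs, t.channels, 7.0 * t.samples)
            for t in mini_trials
        ]
        base, _ = er.preprocess_cohort(mini_trials)
        amplified, _ = er.preprocess_cohort(scaled)
        np.testing.assert_allclose(base["value"], amplified["value"], atol=1e-9)

    def test_missing_channel_names_offender(self, mini_trials):
        broken = list(mini_trials)
        t = broken[3]
        broken[3] = TrialRecording(
            t.subject_id, t.rep_index, t.fs, t.channels[:-1], t.samples[:, :-1]
        )
        with pytest.raises(SchemaError, match=t.subject_id):
            er.preprocess_cohort(broken)

    def test_pinned_reference_profile(self, mini_profiles):
        # regression guard on the full stage order for a seeded trial
        sel = mini_profiles[
            (mini_profiles.subject_id == "S01")
            & (mini_profiles.muscle == "AD")
            & (mini_profiles.rep_index == 1)
        ].sort_values("point_index")["value"].to_numpy()
        expected = [0.04652086, 0.05489057, 0.05596946, 0.65441499, 0.05381635, 0.06057700]
        np.testing.assert_allclose(sel[[0, 10, 25, 50, 75, 99]], expected, atol=1e-7)

    def test_transformer_matches_functional_pipeline(self, mini_trials, mini_profiles):
        ext = EnvelopeExtractor().fit(mini_trials)
        out = ext.transform(mini_trials)
        np.testing.assert_allclose(out["value"], mini_profiles["value"], atol=1e-12)
        assert ext.get_params()["env_cutoff"] == 8.0
        assert not ext.normalization_.empty

    @given(gain=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_time_normalize_commutes_with_scaling(self, gain):
        rng = np.random.default_rng(5)
        x = rng.random(333)
        np.testing.assert_allclose(
            er.time_normalize(gain * x), gain * er.time_normalize(x), rtol=1e-12
        )
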