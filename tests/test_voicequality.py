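"""Pitch tracking, period extraction, and perturbation measures against
generator ground truth and hand-evaluated formulas."""

import numpy as np
import pytest

from moodspeech.audio import AudioRecording
from moodspeech.synthdata import PulseTrainSpec, synthesize_pulse_train
from moodspeech.voicequality import (
    PeriodSequence,
    VoiceQualityExtractor,
    extract_periods,
    f0_statistics,
    frame_hnr_db,
    harmonics_to_noise,
    jitter_measures,
    shimmer_measures,
    track_pitch,
)


def _train(**kwargs):
    defaults = dict(f0_hz=150.0, duration_s=1.0, seed=0)
    defaults.update(kwargs)
    return synthesize_pulse_train(PulseTrainSpec(**defaults))


def _sequence(periods_ms=None, amplitudes=None):
    """Build a single-run PeriodSequence directly from period/amplitude lists."""
    if periods_ms is not None:
        epochs = np.concatenate([[0.0], np.cumsum(np.asarray(periods_ms) / 1e3)])
    else:
        epochs = np.arange(len(amplitudes)) * 0.01
    amps = (np.asarray(amplitudes, dtype=float)
            if amplitudes is not None else np.ones(epochs.size))
    return PeriodSequence(
        epochs_s=epochs, peak_amplitudes=amps,
        run_id=np.zeros(epochs.size, dtype=int),
    )


class TestPitch:
    def test_clean_train_tracked_within_one_percent(self):
        audio, _ = _train(f0_hz=150)
        track = track_pitch(audio)
        assert np.median(track.voiced_f0) == pytest.approx(150.0, rel=0.01)

    def test_silence_has_no_voiced_frames(self):
        rng = np.random.default_rng(1)
        silence = AudioRecording(1e-6 * rng.standard_normal(44100), 44100)
        assert track_pitch(silence).n_voiced == 0

    def test_floor_bound_enforced(self):
        audio, _ = _train(f0_hz=150)
        track = track_pitch(audio, floor_hz=200.0, ceiling_hz=600.0)
        assert np.all(track.voiced_f0 >= 200.0)

    def test_ceiling_above_nyquist_rejected(self):
        audio, _ = _train()
        with pytest.raises(ValueError):
            track_pitch(audio, floor_hz=75, ceiling_hz=30000)


class TestPeriodExtraction:
    def test_unperturbed_periods_exact_to_one_sample(self):
        audio, _ = _train(f0_hz=100)
        track = track_pitch(audio)
        p = extract_periods(audio, track)
        assert p.n_cycles > 80
        assert np.allclose(p.periods_s, 0.010, atol=1 / 44100)

    def test_jittered_period_spread_tracks_ground_truth(self):
        audio, truth = _train(f0_hz=120, duration_s=2.0, jitter_rel=0.02, seed=6)
        p = extract_periods(audio, track_pitch(audio))
        true_cv = np.std(truth.periods_s) / np.mean(truth.periods_s)
        est_cv = np.std(p.periods_s) / np.mean(p.periods_s)
        assert est_cv == pytest.approx(true_cv, rel=0.2)

    def test_silent_audio_yields_empty_sequence(self):
        rng = np.random.default_rng(2)
        silence = AudioRecording(1e-6 * rng.standard_normal(44100), 44100)
        p = extract_periods(silence, track_pitch(silence))
        assert p.n_cycles == 0
        assert p.insufficient


class TestJitter:
    def test_hand_value_alternating_periods(self):
        jm = jitter_measures(_sequence(periods_ms=[10, 11, 10, 11]))
        assert jm["jitter_local"] == pytest.approx(1.0 / 10.5, abs=1e-12)
        assert jm["jitter_local_abs_s"] == pytest.approx(1e-3, abs=1e-15)

    def test_constant_periods_give_zero(self):
        jm = jitter_measures(_sequence(periods_ms=[10] * 8))
        for key in ("jitter_local", "jitter_rap", "jitter_ppq5", "jitter_ddp"):
            # epoch cumsum carries ~1e-16 relative float noise
            assert jm[key] == pytest.approx(0.0, abs=1e-12)

    def test_ddp_is_three_rap_to_machine_precision(self):
        rng = np.random.default_rng(3)
        jm = jitter_measures(_sequence(periods_ms=10 + rng.standard_normal(30)))
        assert jm["jitter_ddp"] == 3.0 * jm["jitter_rap"]

    def test_insufficient_periods_reported_missing(self):
        jm = jitter_measures(_sequence(periods_ms=[10]))
        assert np.isnan(jm["jitter_local"])


class TestShimmer:
    def test_hand_values_alternating_amplitudes(self):
        sm = shimmer_measures(_sequence(amplitudes=[1.0, 1.1, 1.0, 1.1]))
        assert sm["shimmer_local"] == pytest.approx(0.1 / 1.05, abs=1e-12)
        assert sm["shimmer_local_db"] == pytest.approx(20 * np.log10(1.1), abs=1e-12)

    def test_constant_amplitudes_give_zero(self):
        sm = shimmer_measures(_sequence(amplitudes=[0.5] * 12))
        for key in ("shimmer_local", "shimmer_local_db", "shimmer_apq3",
                    "shimmer_apq5", "shimmer_apq11", "shimmer_dda"):
            assert sm[key] == 0.0

    def test_dda_is_three_apq3_to_machine_precision(self):
        rng = np.random.default_rng(4)
        sm = shimmer_measures(_sequence(amplitudes=1 + 0.1 * rng.random(25)))
        assert sm["shimmer_dda"] == 3.0 * sm["shimmer_apq3"]

    def test_zero_amplitude_excluded_from_db_form(self):
        sm = shimmer_measures(_sequence(amplitudes=[1.0, 0.0, 1.0, 1.1, 1.0]))
        assert np.isfinite(sm["shimmer_local_db"])


class TestHNR:
    def test_half_correlation_is_zero_db(self):
        assert frame_hnr_db(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_clean_train_is_highly_harmonic(self):
        audio, _ = _train(f0_hz=150)
        assert harmonics_to_noise(audio, track_pitch(audio)) >= 25.0

    def test_hnr_matches_additive_snr(self):
        audio, _ = _train(f0_hz=150, snr_db=10, seed=8)
        hnr = harmonics_to_noise(audio, track_pitch(audio))
        assert hnr == pytest.approx(10.0, abs=2.0)

    def test_unvoiced_track_gives_missing(self):
        rng = np.random.default_rng(5)
        silence = AudioRecording(1e-6 * rng.standard_normal(44100), 44100)
        assert np.isnan(harmonics_to_noise(silence, track_pitch(silence)))


class TestF0Statistics:
    def test_constant_track(self):
        audio, _ = _train(f0_hz=120)
        track = track_pitch(audio)
        mean, sd = f0_statistics(track)
        assert mean == pytest.approx(120.0, rel=0.01)
        assert sd <= 1.0

    def test_population_sd_convention(self):
        from moodspeech.voicequality import PitchTrack

        track = PitchTrack(
            frame_times_s=np.array([0.0, 0.01]),
            f0_hz=np.array([100.0, 140.0]),
            voicing_flag=np.array([True, True]),
            strength=np.array([0.9, 0.9]),
        )
        mean, sd = f0_statistics(track)
        assert mean == pytest.approx(120.0)
        assert sd == pytest.approx(20.0)  # divide-by-n convention

    def test_unvoiced_only_is_missing(self):
        from moodspeech.voicequality import PitchTrack

        track = PitchTrack(
            frame_times_s=np.array([0.0, 0.01]),
            f0_hz=np.zeros(2), voicing_flag=np.zeros(2, bool), strength=np.zeros(2),
        )
        assert all(np.isnan(v) for v in f0_statistics(track))


class TestInvariances:
    def test_amplitude_scaling_leaves_panel_unchanged(self):
        audio, _ = _train(f0_hz=130, duration_s=1.0, jitter_rel=0.01,
                          shimmer_rel=0.02, snr_db=20, seed=9)
        scaled = AudioRecording(0.37 * audio.samples, audio.sample_rate_hz)
        vq = VoiceQualityExtractor()
        a, _ = vq.extract(audio)
        b, _ = vq.extract(scaled)
        for key, va in a.as_dict().items():
            vb = b.as_dict()[key]
            assert va == pytest.approx(vb, rel=1e-6, abs=1e-9), key

    def test_prepended_silence_leaves_panel_unchanged(self):
        audio, _ = _train(f0_hz=140, duration_s=1.0, jitter_rel=0.01, seed=10)
        pad = np.zeros(int(0.2 * audio.sample_rate_hz))  # a whole number of hops
        shifted = AudioRecording(np.concatenate([pad, audio.samples]),
                                 audio.sample_rate_hz)
        vq = VoiceQualityExtractor()
        a, _ = vq.extract(audio)
        b, _ = vq.extract(shifted)
        for key, va in a.as_dict().items():
            # abs floor covers near-zero perturbation measures whose only
            # content is sub-1e-4 measurement noise
            assert va == pytest.approx(b.as_dict()[key], rel=0.05, abs=1e-4), key

    def test_mean_jitter_recovery_short_panel(self):
        # condensed analytic-recovery check; the full 50-train version runs
        # in the acceptance suite
        sigma = 0.01
        estimates = []
        for seed in range(10):
            audio, _ = _train(f0_hz=120, duration_s=2.0, jitter_rel=sigma,
                              seed=100 + seed)
            p = extract_periods(audio, track_pitch(audio))
            estimates.append(jitter_measures(p)["jitter_local"])
        expected = 2 * sigma / np.sqrt(np.pi)
        assert np.mean(estimates) == pytest.approx(expected, rel=0.25)
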