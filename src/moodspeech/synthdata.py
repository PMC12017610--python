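"""Synthetic speech and cohort generators with exact ground truth.

Two families of fixtures:

* **Glottal pulse trains** — a voiced-speech surrogate built from damped
  sinusoid pulses whose per-cycle periods and amplitudes are perturbed by
  controlled multiplicative Gaussian noise. Because the perturbations are
  drawn explicitly, jitter, shimmer, pitch and harmonics-to-noise ratio all
  have closed-form or directly computable ground truth, which makes every
  downstream acoustic extractor testable without any recorded speech.

* **Cohorts** — participant tables whose feature columns carry configured
  Spearman correlations with MADRS / YMRS symptom totals via a Gaussian
  copula, with optional sex-dependent effect modification. Symptom totals
  follow a truncated negative-binomial marginal on 0-60, which reproduces
  the right-skewed severity distributions typical of mood-disorder samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import nbinom

from .audio import AudioRecording
from .langfeatures import TimedTranscript, Word

MAX_SCORE = 60

# Negative-binomial (size k, mean mu) marginals for symptom totals, chosen to
# mimic skewed clinical severity distributions (MADRS median 13, IQR 21;
# YMRS median 5, IQR 16).
DEFAULT_SCORE_DISTRIBUTION: dict[str, tuple[float, float]] = {
    "madrs": (1.1, 19.0),
    "ymrs": (0.45, 13.0),
}


# --------------------------------------------------------------------------
# pulse trains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseTrainSpec:
    """Parameters of a perturbed glottal pulse train.

    jitter_rel and shimmer_rel are the relative standard deviations of the
    multiplicative Gaussian perturbations applied per period and per pulse
    amplitude; snr_db is the additive white-noise SNR (np.inf = noiseless).
    """

    f0_hz: float
    duration_s: float = 2.0
    jitter_rel: float = 0.0
    shimmer_rel: float = 0.0
    snr_db: float = np.inf
    sample_rate_hz: int = 44100
    seed: int = 0
    base_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if not self.f0_hz > 0:
            raise ValueError("f0_hz must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if self.jitter_rel < 0 or self.shimmer_rel < 0:
            raise ValueError("jitter_rel and shimmer_rel must be >= 0")
        if self.sample_rate_hz < 8000:
            raise ValueError("sample_rate_hz must be >= 8000")
        if not self.f0_hz < self.sample_rate_hz / 4:
            raise ValueError("f0_hz must be below sample_rate_hz / 4")


@dataclass
class PulseTrainTruth:
    """Ground truth drawn while synthesizing a pulse train."""

    epochs_s: np.ndarray          # pulse onset times
    periods_s: np.ndarray         # successive inter-pulse intervals, len = n_pulses - 1
    amplitudes: np.ndarray        # per-pulse amplitude factors A_i
    clean_signal: np.ndarray      # rendered train before noise
    noise: np.ndarray             # additive noise component (zeros if snr=inf)
    n_period_redraws: int = 0
    n_amplitude_redraws: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "epochs_s": self.epochs_s.tolist(),
                "periods_s": self.periods_s.tolist(),
                "amplitudes": self.amplitudes.tolist(),
                "n_period_redraws": self.n_period_redraws,
                "n_amplitude_redraws": self.n_amplitude_redraws,
            }
        )


def _redraw_nonpositive(values: np.ndarray, rng: np.random.Generator,
                        mean: float, sd: float) -> tuple[np.ndarray, int]:
    """Reject-and-redraw entries <= 0 (keeps the perturbation distribution
    conditionally positive); returns the repaired array and redraw count."""
    n_redraws = 0
    bad = values <= 0
    while np.any(bad):
        n_redraws += int(bad.sum())
        values = values.copy()
        values[bad] = mean * (1.0 + sd * rng.standard_normal(int(bad.sum())))
        bad = values <= 0
    return values, n_redraws


def synthesize_pulse_train(spec: PulseTrainSpec) -> tuple[AudioRecording, PulseTrainTruth]:
    """Render a pulse train; return the audio and its exact ground truth.

    Periods are T_i = (1/f0) * (1 + jitter_rel * z_i) and amplitudes
    A_i = A0 * (1 + shimmer_rel * w_i) with z, w iid standard normal from
    the spec seed. Each pulse is an exponentially damped sinusoid placed at
    a continuous-time epoch (evaluated analytically on the sample grid, so
    epoch timing is not quantized to samples). White Gaussian noise is
    scaled from the rendered signal power to meet snr_db.
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate_hz
    t0 = 1.0 / spec.f0_hz
    n_samples = int(round(spec.duration_s * sr))

    # draw a comfortable surplus of periods, then trim to the duration
    n_draw = int(np.ceil(spec.duration_s * spec.f0_hz * 1.5)) + 16
    periods = t0 * (1.0 + spec.jitter_rel * rng.standard_normal(n_draw))
    periods, n_period_redraws = _redraw_nonpositive(periods, rng, t0, spec.jitter_rel)
    epochs = np.concatenate([[0.0], np.cumsum(periods)])
    keep = epochs < spec.duration_s
    epochs = epochs[keep]
    periods = np.diff(epochs)

    amps = spec.base_amplitude * (
        1.0 + spec.shimmer_rel * rng.standard_normal(epochs.size)
    )
    amps, n_amp_redraws = _redraw_nonpositive(
        amps, rng, spec.base_amplitude, spec.shimmer_rel
    )

    # damped sinusoid kernel: carrier well above f0 for a sharp, band-limited
    # pulse; decay tied to f0 so the tail is ~0.1% by the next epoch
    carrier_hz = min(6.0 * spec.f0_hz, 0.35 * sr)
    tau = 1.0 / (7.0 * spec.f0_hz)
    kernel_len = int(np.ceil(tau * np.log(1e5) * sr))  # envelope below 1e-5

    clean = np.zeros(n_samples + kernel_len)
    grid = np.arange(kernel_len) / sr
    for t_e, a in zip(epochs, amps):
        start = int(np.ceil(t_e * sr))
        span = min(kernel_len, clean.size - start)
        if span <= 0:
            continue
        t_rel = grid[:span] + (start / sr - t_e)
        clean[start:start + span] += (
            a * np.exp(-t_rel / tau) * np.sin(2.0 * np.pi * carrier_hz * t_rel)
        )
    clean = clean[:n_samples]

    if np.isfinite(spec.snr_db):
        p_signal = float(np.mean(clean**2))
        noise_sd = np.sqrt(p_signal / 10.0 ** (spec.snr_db / 10.0))
        noise = noise_sd * rng.standard_normal(n_samples)
    else:
        noise = np.zeros(n_samples)

    audio = AudioRecording(samples=clean + noise, sample_rate_hz=sr)
    truth = PulseTrainTruth(
        epochs_s=epochs,
        periods_s=periods,
        amplitudes=amps,
        clean_signal=clean,
        noise=noise,
        n_period_redraws=n_period_redraws,
        n_amplitude_redraws=n_amp_redraws,
    )
    return audio, truth


# --------------------------------------------------------------------------
# sessions (speech / silence plans with word timestamps)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSpec:
    """A planned recording: alternating speech/silence segments, a word plan
    consistent with the speech segments, and the voice used for speech."""

    segments: Sequence[tuple[str, float]]
    voice: PulseTrainSpec
    word_plan: Sequence[tuple[str, float, float]] = ()
    seed: int = 0
    silence_floor_db: float = -60.0  # noise floor relative to speech RMS

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("segments must be non-empty")
        for kind, dur in self.segments:
            if kind not in ("speech", "silence"):
                raise ValueError(f"unknown segment kind {kind!r}")
            if not dur > 0:
                raise ValueError("segment durations must be positive")
        if self.silence_floor_db > -40.0:
            raise ValueError("silence floor must be at least 40 dB below speech")
        speech_spans = self.speech_spans()
        prev_start = -np.inf
        prev_end = 0.0
        for token, start, end in self.word_plan:
            if not start < end:
                raise ValueError(f"word {token!r}: start must precede end")
            if start <= prev_start:
                raise ValueError(f"word {token!r}: onsets must strictly increase")
            if start < prev_end:
                raise ValueError(f"word {token!r}: word intervals overlap")
            if not any(s - 1e-9 <= start and end <= e + 1e-9 for s, e in speech_spans):
                raise ValueError(
                    f"word {token!r} [{start:.3f}, {end:.3f}] lies outside every "
                    "speech segment"
                )
            prev_start, prev_end = start, end

    def speech_spans(self) -> list[tuple[float, float]]:
        spans, t = [], 0.0
        for kind, dur in self.segments:
            if kind == "speech":
                spans.append((t, t + dur))
            t += dur
        return spans

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))


@dataclass
class SessionTruth:
    """Planned segment boundaries: list of (start_s, end_s, kind)."""

    boundaries: list[tuple[float, float, str]]

    def silence_spans(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, k in self.boundaries if k == "silence"]

    def speech_spans(self) -> list[tuple[float, float]]:
        return [(s, e) for s, e, k in self.boundaries if k == "speech"]

    def to_json(self) -> str:
        return json.dumps({"boundaries": self.boundaries})


def synthesize_session(
    spec: SessionSpec,
) -> tuple[AudioRecording, TimedTranscript, SessionTruth]:
    """Render the planned session; silence segments are a near-zero noise
    floor at spec.silence_floor_db relative to the speech RMS."""
    sr = spec.voice.sample_rate_hz
    seeds = np.random.SeedSequence(spec.seed).spawn(len(spec.segments) + 1)
    floor_rng = np.random.default_rng(seeds[-1])

    pieces: list[np.ndarray] = []
    boundaries: list[tuple[float, float, str]] = []
    t = 0.0
    speech_rms = None
    for i, (kind, dur) in enumerate(spec.segments):
        n = int(round(dur * sr))
        if kind == "speech":
            sub = PulseTrainSpec(
                f0_hz=spec.voice.f0_hz,
                duration_s=dur,
                jitter_rel=spec.voice.jitter_rel,
                shimmer_rel=spec.voice.shimmer_rel,
                snr_db=spec.voice.snr_db,
                sample_rate_hz=sr,
                seed=int(seeds[i].generate_state(1)[0] % (2**31)),
                base_amplitude=spec.voice.base_amplitude,
            )
            seg_audio, _ = synthesize_pulse_train(sub)
            piece = seg_audio.samples[:n]
            if piece.size < n:
                piece = np.pad(piece, (0, n - piece.size))
            if speech_rms is None:
                speech_rms = float(np.sqrt(np.mean(piece**2)))
            pieces.append(piece)
        else:
            pieces.append(np.full(n, np.nan))  # filled once speech RMS known
        boundaries.append((t, t + dur, kind))
        t += dur

    if speech_rms is None:
        speech_rms = spec.voice.base_amplitude  # all-silence session
    floor_sd = speech_rms * 10.0 ** (spec.silence_floor_db / 20.0)
    for i, piece in enumerate(pieces):
        if np.isnan(piece).any():
            pieces[i] = floor_sd * floor_rng.standard_normal(piece.size)

    audio = AudioRecording(samples=np.concatenate(pieces), sample_rate_hz=sr)
    transcript = TimedTranscript(
        words=[Word(token, start, end) for token, start, end in spec.word_plan]
    )
    return audio, transcript, SessionTruth(boundaries=boundaries)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """A synthetic participant cohort with configured feature-symptom effects.

    effect_map maps feature name -> (target, spearman_target) where target is
    "madrs" or "ymrs". sex_modifier maps feature name -> multiplier applied
    to that feature's copula correlation among females. noise_sd adds
    independent Gaussian noise on the feature scale after the copula draw.
    """

    n: int
    effect_map: Mapping[str, tuple[str, float]]
    sex_modifier: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    score_distribution: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_DISTRIBUTION)
    )
    target_correlation: float = 0.0  # latent MADRS-YMRS correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("cohort size must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (target, rho) in self.effect_map.items():
            if target not in ("madrs", "ymrs"):
                raise ValueError(f"feature {name!r}: unknown target {target!r}")
            if not abs(rho) < 1:
                raise ValueError(f"feature {name!r}: |spearman_target| must be < 1")
        if not abs(self.target_correlation) < 1:
            raise ValueError("|target_correlation| must be < 1")


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: latent Pearson r giving Spearman rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table: id, sex, madrs_total, ymrs_total, features.

    Construction is a one-factor Gaussian copula per feature: each feature's
    latent is r*Z_target + sqrt(1-r^2)*eps with r = 2 sin(pi*rho_s/6), so the
    population Spearman correlation with the (continuous) target latent is
    exactly the configured value before noise and score discretization. The
    sex modifier rescales r among females; a rescaled |r| >= 1 is infeasible
    and raises with the offending feature named.
    """
    offending = [
        name
        for name, (_, rho_s) in spec.effect_map.items()
        if abs(_spearman_to_pearson(rho_s) * spec.sex_modifier.get(name, 1.0)) >= 1.0
    ]
    if offending:
        raise ValueError(
            "infeasible correlation after sex modification for: "
            + ", ".join(sorted(offending))
        )

    rng = np.random.default_rng(spec.seed)
    n = spec.n
    sex = np.array(["female", "male"])[rng.permutation(np.arange(n) % 2)]

    rho_t = spec.target_correlation
    z_madrs = rng.standard_normal(n)
    z_ymrs = rho_t * z_madrs + np.sqrt(1 - rho_t**2) * rng.standard_normal(n)
    latents = {"madrs": z_madrs, "ymrs": z_ymrs}

    data: dict[str, np.ndarray] = {}
    data["id"] = np.array([f"P{i:04d}" for i in range(n)])
    data["sex"] = sex
    for target, latent in latents.items():
        k, mu = spec.score_distribution[target]
        p = k / (k + mu)
        u = np.clip(ndtr(latent), 1e-12, 1 - 1e-12)
        scores = nbinom.ppf(u, k, p)
        data[f"{target}_total"] = np.minimum(scores, MAX_SCORE).astype(int)

    female = sex == "female"
    for name, (target, rho_s) in spec.effect_map.items():
        r = _spearman_to_pearson(rho_s)
        r_vec = np.where(female, np.clip(r * spec.sex_modifier.get(name, 1.0), -1, 1), r)
        eps = rng.standard_normal(n)
        feature = r_vec * latents[target] + np.sqrt(1 - r_vec**2) * eps
        if spec.noise_sd > 0:
            feature = feature + spec.noise_sd * rng.standard_normal(n)
        data[name] = feature

    return pd.DataFrame(data)


def write_ground_truth(path: str | Path, truth: PulseTrainTruth | SessionTruth) -> None:
    Path(path).write_text(truth.to_json())


# --------------------------------------------------------------------------
# demo dataset (synthetic stand-in for a recorded study)
# --------------------------------------------------------------------------

DEMO_STORY = (
    "Anna was driving home along the river road when a sudden storm broke "
    "over the valley. The car slid on the wet stones and crashed against "
    "the old bridge. A young farmer heard the noise and pulled her from "
    "the wreck before the water rose. She was taken to the hospital in "
    "town where the doctors said she would recover."
)


def make_demo_dataset(out_dir: str | Path, n: int = 6, seed: int = 0) -> Path:
    """Write a complete synthetic study to out_dir and return the manifest
    path: story text, a toy embedding table over the story vocabulary,
    per-participant session WAVs + transcript JSONs (each participant
    retells a seeded subset of the story), and a manifest CSV with sex and
    MADRS/YMRS totals.

    Synthetic stand-in for recorded data; every value is drawn from the
    generators in this module.
    """
    from .audio import write_wav
    from .langfeatures import normalize_tokens

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    story_path = out_dir / "story.txt"
    story_path.write_text(DEMO_STORY, encoding="utf-8")
    vocab = sorted(set(normalize_tokens(DEMO_STORY)))
    emb_path = out_dir / "embeddings.txt"
    with open(emb_path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(vocab)} 8\n")
        for word in vocab:
            vec = rng.standard_normal(8)
            fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")

    tokens = normalize_tokens(DEMO_STORY)
    rows = []
    for i in range(n):
        pid = f"S{i:03d}"
        sex = "female" if i % 2 == 0 else "male"
        f0 = float(rng.uniform(180, 230) if sex == "female" else rng.uniform(100, 150))
        n_recall = int(rng.integers(8, min(16, len(tokens))))
        start_idx = int(rng.integers(0, len(tokens) - n_recall))
        recalled = tokens[start_idx:start_idx + n_recall]

        word_len, gap = 0.22, 0.08
        per_span = 6
        spans_needed = int(np.ceil(len(recalled) / per_span))
        # initial pause = latency from task start to the first word
        segments: list[tuple[str, float]] = [
            ("silence", float(rng.uniform(0.3, 0.9)))
        ]
        for k in range(spans_needed):
            n_words_here = min(per_span, len(recalled) - k * per_span)
            segments.append(("speech", n_words_here * (word_len + gap) + 0.1))
            if k < spans_needed - 1:
                segments.append(("silence", float(rng.uniform(0.3, 0.7))))
        word_plan = []
        t = 0.0
        wi = 0
        for kind, dur in segments:
            if kind == "speech":
                cursor = t + 0.05
                while wi < len(recalled) and cursor + word_len <= t + dur:
                    word_plan.append((recalled[wi], cursor, cursor + word_len))
                    cursor += word_len + gap
                    wi += 1
            t += dur

        spec = SessionSpec(
            segments=segments,
            voice=PulseTrainSpec(
                f0_hz=f0,
                duration_s=1.0,
                jitter_rel=float(rng.uniform(0.002, 0.02)),
                shimmer_rel=float(rng.uniform(0.01, 0.05)),
                snr_db=float(rng.uniform(15, 30)),
                sample_rate_hz=22050,
            ),
            word_plan=word_plan,
            seed=int(rng.integers(0, 2**31)),
        )
        audio, transcript, _truth = synthesize_session(spec)
        wav_path = out_dir / f"{pid}.wav"
        ts_path = out_dir / f"{pid}.json"
        write_wav(wav_path, audio)
        ts_path.write_text(transcript.to_json())

        k_m, mu_m = DEFAULT_SCORE_DISTRIBUTION["madrs"]
        k_y, mu_y = DEFAULT_SCORE_DISTRIBUTION["ymrs"]
        rows.append({
            "id": pid,
            "wav": wav_path.name,
            "transcript": ts_path.name,
            "sex": sex,
            "madrs_total": int(min(nbinom.rvs(k_m, k_m / (k_m + mu_m), random_state=rng), MAX_SCORE)),
            "ymrs_total": int(min(nbinom.rvs(k_y, k_y / (k_y + mu_y), random_state=rng), MAX_SCORE)),
        })

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path
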