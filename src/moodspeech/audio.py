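"""Mono audio container and 16-bit PCM WAV I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioRecording:
    """A mono waveform with its sample rate.

    Samples are dimensionless amplitudes, nominally in [-1, 1]; values
    outside that range are clipped on write, not on construction.
    """

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"audio must be mono 1-D, got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("audio must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("audio contains non-finite samples")
        if int(self.sample_rate_hz) <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "sample_rate_hz", int(self.sample_rate_hz))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


def read_wav(path: str | Path) -> AudioRecording:
    """Read a mono WAV file (PCM integer or float) into [-1, 1] floats."""
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(-np.iinfo(data.dtype).min)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioRecording(samples=samples, sample_rate_hz=int(rate))


def write_wav(path: str | Path, audio: AudioRecording) -> None:
    """Write 16-bit PCM. Samples are clipped to [-1, 1 - 2**-15]."""
    clipped = np.clip(audio.samples, -1.0, 1.0 - 2.0**-15)
    pcm = np.round(clipped * 32768.0).astype(np.int16)
    wavfile.write(str(path), audio.sample_rate_hz, pcm)
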