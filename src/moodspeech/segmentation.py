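"""Phonation/silence segmentation and conversational timing indices.

An intensity-based detector splits a recording into sounding and silent
intervals: frame-wise RMS intensity on sliding windows, a peak-relative dB
cutoff (with a robust percentile peak reference), minimum-duration merging,
and fine-grained boundary refinement. From the segmentation and a word
count, the conversational panel follows: speech duration, phonation time,
silence time, phonation/duration and silence/phonation ratios, and speech
rate in words per second.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .audio import AudioRecording

SOUNDING = "sounding"
SILENT = "silent"


@dataclass(frozen=True)
class VoicingSegmentation:
    """Alternating sounding/silent intervals tiling [0, total_duration_s).

    Intervals are half-open [start, end) in seconds from recording start;
    adjacent intervals carry different labels.
    """

    intervals: tuple[tuple[float, float, str], ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("segmentation must contain at least one interval")
        prev_end = 0.0
        prev_label = None
        for start, end, label in self.intervals:
            if label not in (SOUNDING, SILENT):
                raise ValueError(f"unknown label {label!r}")
            if abs(start - prev_end) > 1e-9:
                raise ValueError("intervals must tile the duration without gaps")
            if not end > start:
                raise ValueError("intervals must have positive length")
            if label == prev_label:
                raise ValueError("adjacent intervals must alternate labels")
            prev_end, prev_label = end, label
        if abs(prev_end - self.total_duration_s) > 1e-9:
            raise ValueError("intervals must end at total_duration_s")

    def spans(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def total(self, label: str) -> float:
        return float(sum(e - s for s, e, lab in self.intervals if lab == label))

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_duration_s": self.total_duration_s,
                "intervals": [list(iv) for iv in self.intervals],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        lines = [f"{s:.6f}\t{e:.6f}\t{lab}" for s, e, lab in self.intervals]
        Path(path).write_text("\n".join(lines) + "\n")


def frame_intensity(
    audio: AudioRecording, window_s: float, hop_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-center times and RMS intensity on sliding windows (edge frames
    use the available part of the window)."""
    x = audio.samples
    sr = audio.sample_rate_hz
    win = max(1, int(round(window_s * sr)))
    hop = max(1, int(round(hop_s * sr)))
    csum = np.concatenate([[0.0], np.cumsum(x**2)])
    centers = np.arange(0, x.size, hop)
    lo = np.maximum(centers - win // 2, 0)
    hi = np.minimum(centers + (win - win // 2), x.size)
    rms = np.sqrt((csum[hi] - csum[lo]) / np.maximum(hi - lo, 1))
    return centers / sr, rms


def _merge_short_runs(labels: np.ndarray, min_len: int, target: bool) -> np.ndarray:
    """Flip runs of value `target` shorter than min_len samples-of-frames."""
    labels = labels.copy()
    n = labels.size
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] == target and (j - i) < min_len and not (i == 0 and j == n):
            labels[i:j] = not target
        i = j
    return labels


class SilenceSegmenter(BaseEstimator):
    """Intensity-threshold silence detector.

    Parameters
    ----------
    silence_threshold_db : float
        Cutoff relative to the peak intensity, in dB (negative; default -25).
        Frames quieter than peak + threshold are silent, so raising the
        threshold toward 0 can only increase detected silence.
    min_silent_s, min_sounding_s : float
        Runs shorter than these are merged into their neighbors.
    window_s, hop_s : float
        Analysis window and hop for the coarse intensity track.
    peak_percentile : float
        Percentile of frame intensity used as the peak reference (robust to
        clicks; default 99.5).
    floor_db : float
        Absolute floor (dBFS): frames below it are silent regardless of the
        peak-relative rule, so an all-quiet recording is labeled silent.
    refine_s : float
        Resolution of the fine intensity track used to refine boundaries
        (0 disables refinement).
    """

    def __init__(
        self,
        silence_threshold_db: float = -25.0,
        min_silent_s: float = 0.10,
        min_sounding_s: float = 0.10,
        window_s: float = 0.05,
        hop_s: float = 0.01,
        peak_percentile: float = 99.5,
        floor_db: float = -55.0,
        refine_s: float = 0.001,
    ):
        self.silence_threshold_db = silence_threshold_db
        self.min_silent_s = min_silent_s
        self.min_sounding_s = min_sounding_s
        self.window_s = window_s
        self.hop_s = hop_s
        self.peak_percentile = peak_percentile
        self.floor_db = floor_db
        self.refine_s = refine_s

    # -- internal -----------------------------------------------------------

    def _cutoff_db(self, frames_db: np.ndarray) -> float:
        peak = float(np.percentile(frames_db, self.peak_percentile))
        return max(peak + self.silence_threshold_db, self.floor_db)

    def _refine_boundary(
        self, audio: AudioRecording, t_coarse: float, cutoff_db: float
    ) -> float:
        """Locate the cutoff crossing near a coarse boundary on a fine track."""
        half = self.window_s
        fine_win = max(0.005, 2 * self.refine_s)
        sr = audio.sample_rate_hz
        lo = max(0.0, t_coarse - half)
        hi = min(audio.duration_s, t_coarse + half)
        seg = AudioRecording(
            samples=audio.samples[int(lo * sr): max(int(hi * sr), int(lo * sr) + 1)],
            sample_rate_hz=sr,
        )
        times, rms = frame_intensity(seg, fine_win, self.refine_s)
        db = 20.0 * np.log10(rms + 1e-12)
        above = db >= cutoff_db
        # choose the crossing closest to the coarse boundary
        flips = np.nonzero(above[1:] != above[:-1])[0]
        if flips.size == 0:
            return t_coarse
        cross_times = lo + (times[flips] + times[flips + 1]) / 2.0
        return float(cross_times[np.argmin(np.abs(cross_times - t_coarse))])

    # -- public -------------------------------------------------------------

    def segment(self, audio: AudioRecording) -> VoicingSegmentation:
        sr = audio.sample_rate_hz
        duration = audio.duration_s
        if audio.n_samples < int(round(self.window_s * sr)):
            # too short for one window: label the whole thing by its level
            db = 20.0 * np.log10(audio.rms() + 1e-12)
            label = SILENT if db < self.floor_db else SOUNDING
            return VoicingSegmentation(
                intervals=((0.0, duration, label),), total_duration_s=duration
            )

        times, rms = frame_intensity(audio, self.window_s, self.hop_s)
        frames_db = 20.0 * np.log10(rms + 1e-12)
        cutoff = self._cutoff_db(frames_db)
        sounding = frames_db >= cutoff

        hop_frames = lambda secs: int(round(secs / self.hop_s))
        sounding = _merge_short_runs(sounding, hop_frames(self.min_silent_s), False)
        sounding = _merge_short_runs(sounding, hop_frames(self.min_sounding_s), True)

        # frame labels -> intervals at frame centers, then refined boundaries
        flips = np.nonzero(sounding[1:] != sounding[:-1])[0]
        boundaries = [(times[i] + times[i + 1]) / 2.0 for i in flips]
        if self.refine_s > 0:
            boundaries = [self._refine_boundary(audio, t, cutoff) for t in boundaries]

        labels = [bool(sounding[0])]
        for i in flips:
            labels.append(bool(sounding[i + 1]))
        edges = [0.0] + boundaries + [duration]
        # refinement can in principle reorder nearly-coincident boundaries;
        # drop any empty interval that would result
        intervals = []
        for k in range(len(labels)):
            if edges[k + 1] - edges[k] > 1e-9:
                lab = SOUNDING if labels[k] else SILENT
                if intervals and intervals[-1][2] == lab:
                    intervals[-1] = (intervals[-1][0], edges[k + 1], lab)
                else:
                    intervals.append((edges[k], edges[k + 1], lab))
        # re-tile exactly
        tiled = []
        prev = 0.0
        for _, end, lab in intervals:
            tiled.append((prev, end, lab))
            prev = end
        tiled[-1] = (tiled[-1][0], duration, tiled[-1][2])
        return VoicingSegmentation(intervals=tuple(tiled), total_duration_s=duration)

    def transform(self, recordings) -> list[VoicingSegmentation]:
        return [self.segment(a) for a in recordings]


def segment_voicing(
    audio: AudioRecording,
    silence_threshold_db: float = -25.0,
    min_silent_s: float = 0.10,
    min_sounding_s: float = 0.10,
    **kwargs,
) -> VoicingSegmentation:
    """Functional wrapper over SilenceSegmenter."""
    return SilenceSegmenter(
        silence_threshold_db=silence_threshold_db,
        min_silent_s=min_silent_s,
        min_sounding_s=min_sounding_s,
        **kwargs,
    ).segment(audio)


@dataclass(frozen=True)
class ConversationalFeatures:
    """The conversational timing panel; undefined ratios are NaN."""

    speech_duration_s: float
    phonation_s: float
    silence_s: float
    phonation_over_duration: float
    silence_over_phonation: float
    speech_rate_wps: float

    def as_dict(self) -> dict[str, float]:
        return {
            "speech_duration_s": self.speech_duration_s,
            "phonation_s": self.phonation_s,
            "silence_s": self.silence_s,
            "phonation_over_duration": self.phonation_over_duration,
            "silence_over_phonation": self.silence_over_phonation,
            "speech_rate_wps": self.speech_rate_wps,
        }


CONVERSATIONAL_FEATURES = [
    "speech_duration_s",
    "phonation_s",
    "silence_s",
    "phonation_over_duration",
    "silence_over_phonation",
    "speech_rate_wps",
]


def conversational_features(
    seg: VoicingSegmentation, n_words: int
) -> ConversationalFeatures:
    """Durations, ratios and speech rate from a segmentation and word count.

    silence_over_phonation is reported missing (NaN), not infinite, when
    there is no phonation.
    """
    if n_words < 0:
        raise ValueError("n_words must be >= 0")
    phonation = seg.total(SOUNDING)
    silence = seg.total(SILENT)
    duration = seg.total_duration_s
    return ConversationalFeatures(
        speech_duration_s=duration,
        phonation_s=phonation,
        silence_s=silence,
        phonation_over_duration=phonation / duration if duration > 0 else float("nan"),
        silence_over_phonation=silence / phonation if phonation > 0 else float("nan"),
        speech_rate_wps=n_words / duration if duration > 0 else float("nan"),
    )
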