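"""Voice-quality indices: F0 statistics, jitter, shimmer, harmonics-to-noise.

Pitch is tracked by short-time normalized cross-correlation (NCC) with
parabolic peak interpolation and cost-based path selection to suppress
octave jumps. Glottal cycle epochs are then located by waveform peak
picking guided by the local F0 estimate, giving a per-cycle period and
peak-amplitude sequence from which the Praat-style perturbation measures
are computed:

* jitter: local, local absolute, RAP, PPQ5, DDP (= 3 x RAP)
* shimmer: local, local dB, APQ3, APQ5, APQ11, DDA (= 3 x APQ3)
* HNR: per-frame 10*log10(r / (1 - r)) at the F0 lag, averaged over voiced
  frames, where r is the normalized autocorrelation.

All measures are computed within voiced runs only — cycles from different
voiced stretches are never bridged — and pooled across runs weighted by
cycle count. Everything is scale-invariant: only amplitude ratios and
normalized correlations enter the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin

from .audio import AudioRecording

_EPS_R = 1e-6  # autocorrelation clip for the HNR transform


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PitchTrack:
    """Per-frame F0 estimates. Unvoiced frames have f0_hz = 0 and
    voicing_flag False; strength is the NCC value at the chosen lag."""

    frame_times_s: np.ndarray
    f0_hz: np.ndarray
    voicing_flag: np.ndarray
    strength: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame times must strictly increase")

    @property
    def n_voiced(self) -> int:
        return int(np.sum(self.voicing_flag))

    @property
    def voiced_f0(self) -> np.ndarray:
        return self.f0_hz[self.voicing_flag]

    def voiced_fraction(self) -> float:
        return self.n_voiced / max(self.f0_hz.size, 1)


@dataclass
class PeriodSequence:
    """Glottal cycle epochs, grouped into voiced runs.

    epochs_s, peak_amplitudes and run_id are parallel arrays; periods are the
    successive epoch differences within a run (runs from separate voiced
    stretches are never bridged). n_dropped counts cycles discarded for
    violating the period bounds.
    """

    epochs_s: np.ndarray
    peak_amplitudes: np.ndarray
    run_id: np.ndarray
    n_dropped: int = 0

    def runs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """List of (epochs, amplitudes) per voiced run."""
        out = []
        for rid in np.unique(self.run_id):
            m = self.run_id == rid
            out.append((self.epochs_s[m], self.peak_amplitudes[m]))
        return out

    def periods_by_run(self) -> list[np.ndarray]:
        return [np.diff(e) for e, _ in self.runs() if e.size >= 2]

    def amplitudes_by_run(self) -> list[np.ndarray]:
        return [a for e, a in self.runs()]

    @property
    def periods_s(self) -> np.ndarray:
        runs = self.periods_by_run()
        return np.concatenate(runs) if runs else np.array([])

    @property
    def n_cycles(self) -> int:
        return int(self.epochs_s.size)

    @property
    def insufficient(self) -> bool:
        """Too few cycles for perturbation measures."""
        return self.n_cycles < 3


@dataclass(frozen=True)
class AcousticFeatureSet:
    f0_mean_hz: float = np.nan
    f0_sd_hz: float = np.nan
    jitter_local: float = np.nan
    jitter_local_abs_s: float = np.nan
    jitter_rap: float = np.nan
    jitter_ppq5: float = np.nan
    jitter_ddp: float = np.nan
    shimmer_local: float = np.nan
    shimmer_local_db: float = np.nan
    shimmer_apq3: float = np.nan
    shimmer_apq5: float = np.nan
    shimmer_apq11: float = np.nan
    shimmer_dda: float = np.nan
    hnr_mean_db: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ACOUSTIC_FEATURES}


ACOUSTIC_FEATURES = [
    "f0_mean_hz",
    "f0_sd_hz",
    "jitter_local",
    "jitter_local_abs_s",
    "jitter_rap",
    "jitter_ppq5",
    "jitter_ddp",
    "shimmer_local",
    "shimmer_local_db",
    "shimmer_apq3",
    "shimmer_apq5",
    "shimmer_apq11",
    "shimmer_dda",
    "hnr_mean_db",
]


# --------------------------------------------------------------------------
# pitch tracking
# --------------------------------------------------------------------------

def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (i-1, y[i-1]), (i, y[i]), (i+1, y[i+1]).
    Returns (offset in [-0.5, 0.5], peak value)."""
    if i <= 0 or i >= y.size - 1:
        return 0.0, float(y[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0 or abs(denom) < 1e-300:
        return 0.0, float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    peak = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return delta, float(peak)


def _ncc_curve(
    x: np.ndarray, start: int, window: int, lag_max: int
) -> np.ndarray | None:
    """NCC r(tau) for tau = 0..lag_max between x[start:start+window] and its
    lagged copy; None when the signal is too short for this frame."""
    end = start + window + lag_max
    if start < 0 or end > x.size:
        return None
    seg = x[start:start + window]
    ext = x[start:end]
    e0 = float(np.dot(seg, seg))
    if e0 <= 0:
        return None
    num = fftconvolve(ext, seg[::-1])[window - 1:window + lag_max]
    csum = np.concatenate([[0.0], np.cumsum(ext**2)])
    e_tau = csum[window:window + lag_max + 1] - csum[:lag_max + 1]
    denom = np.sqrt(e0 * np.maximum(e_tau, 1e-300))
    return num / denom


class PitchTracker(BaseEstimator):
    """Short-time NCC pitch tracker with Viterbi path selection.

    Defaults (floor 75 Hz, ceiling 500 Hz, window 3/floor, hop 10 ms,
    voicing threshold 0.45) span adult male and female speaking ranges and
    are all configurable.
    """

    def __init__(
        self,
        floor_hz: float = 75.0,
        ceiling_hz: float = 500.0,
        window_s: float | None = None,
        hop_s: float = 0.01,
        voicing_threshold: float = 0.45,
        octave_cost: float = 0.01,
        octave_jump_cost: float = 0.35,
        voiced_unvoiced_cost: float = 0.14,
        max_candidates: int = 4,
    ):
        self.floor_hz = floor_hz
        self.ceiling_hz = ceiling_hz
        self.window_s = window_s
        self.hop_s = hop_s
        self.voicing_threshold = voicing_threshold
        self.octave_cost = octave_cost
        self.octave_jump_cost = octave_jump_cost
        self.voiced_unvoiced_cost = voiced_unvoiced_cost
        self.max_candidates = max_candidates

    def _check(self, audio: AudioRecording) -> None:
        if not 0 < self.floor_hz < self.ceiling_hz:
            raise ValueError("need 0 < floor_hz < ceiling_hz")
        if not self.ceiling_hz < audio.sample_rate_hz / 2:
            raise ValueError("ceiling_hz must be below Nyquist")

    def _candidates(self, r: np.ndarray, lag_min: int, sr: int):
        """(f0, strength) candidates from local NCC maxima within bounds."""
        cands = []
        for i in range(max(lag_min, 1), r.size - 1):
            if r[i] >= r[i - 1] and r[i] > r[i + 1] and r[i] > 0.2:
                delta, peak = _parabolic_refine(r, i)
                lag = i + delta
                f0 = sr / lag
                if self.floor_hz <= f0 <= self.ceiling_hz:
                    cands.append((f0, min(peak, 1.0 - _EPS_R)))
        cands.sort(key=lambda c: -c[1])
        return cands[: self.max_candidates]

    def track(self, audio: AudioRecording) -> PitchTrack:
        """Per-frame F0; frames whose best candidate is weaker than the
        voicing threshold come out unvoiced via the path cost."""
        self._check(audio)
        sr = audio.sample_rate_hz
        x = audio.samples
        window_s = self.window_s if self.window_s is not None else 3.0 / self.floor_hz
        window = int(round(window_s * sr))
        hop = max(1, int(round(self.hop_s * sr)))
        lag_min = int(np.floor(sr / self.ceiling_hz))
        lag_max = int(np.ceil(sr / self.floor_hz))

        starts = np.arange(0, max(x.size - window - lag_max, 0) + 1, hop)
        if starts.size == 0:
            starts = np.array([0])
        times = (starts + window / 2.0) / sr

        frame_cands: list[list[tuple[float, float]]] = []
        for s in starts:
            r = _ncc_curve(x, int(s), window, lag_max)
            frame_cands.append([] if r is None else self._candidates(r, lag_min, sr))

        f0, voiced, strength = self._viterbi(frame_cands)
        return PitchTrack(
            frame_times_s=times,
            f0_hz=f0,
            voicing_flag=voiced,
            strength=strength,
        )

    def _viterbi(self, frame_cands):
        """States per frame: candidates + one unvoiced state. Local cost of a
        voiced candidate is 1 - r plus an octave cost favoring higher-F0
        candidates (disambiguates subharmonic lags whose correlation ties
        the true one); unvoiced costs 1 - voicing_threshold. Transitions pay
        an octave-jump cost on |log2 f1/f2| and a flat voiced<->unvoiced
        switch cost."""
        n = len(frame_cands)
        unvoiced_cost = 1.0 - self.voicing_threshold
        states = [cands + [(0.0, None)] for cands in frame_cands]

        def local_cost(f, s):
            if s is None:
                return unvoiced_cost
            return (1.0 - s) + self.octave_cost * np.log2(self.ceiling_hz / f)

        costs = [np.array([local_cost(f, s) for f, s in states[0]])]
        back: list[np.ndarray] = []
        for t in range(1, n):
            cur = states[t]
            local = np.array([local_cost(f, s) for f, s in cur])
            prev_cost = costs[-1]
            trans = np.zeros((len(states[t - 1]), len(cur)))
            for i, (f_prev, s_prev) in enumerate(states[t - 1]):
                for j, (f_cur, s_cur) in enumerate(cur):
                    if s_prev is None and s_cur is None:
                        trans[i, j] = 0.0
                    elif s_prev is None or s_cur is None:
                        trans[i, j] = self.voiced_unvoiced_cost
                    else:
                        trans[i, j] = self.octave_jump_cost * abs(
                            np.log2(f_prev / f_cur)
                        )
            total = prev_cost[:, None] + trans + local[None, :]
            back.append(np.argmin(total, axis=0))
            costs.append(np.min(total, axis=0))

        f0 = np.zeros(n)
        voiced = np.zeros(n, dtype=bool)
        strength = np.zeros(n)
        j = int(np.argmin(costs[-1]))
        for t in range(n - 1, -1, -1):
            f, s = states[t][j]
            if s is not None:
                f0[t], voiced[t], strength[t] = f, True, s
            if t > 0:
                j = int(back[t - 1][j])
        return f0, voiced, strength


def track_pitch(
    audio: AudioRecording, floor_hz: float = 75.0, ceiling_hz: float = 500.0, **kwargs
) -> PitchTrack:
    """Functional wrapper over PitchTracker."""
    return PitchTracker(floor_hz=floor_hz, ceiling_hz=ceiling_hz, **kwargs).track(audio)


# --------------------------------------------------------------------------
# period extraction
# --------------------------------------------------------------------------

def extract_periods(
    audio: AudioRecording,
    track: PitchTrack,
    floor_hz: float = 75.0,
    ceiling_hz: float = 500.0,
    search_frac: float = 0.3,
) -> PeriodSequence:
    """Locate glottal cycle epochs by F0-guided waveform peak picking.

    Within each voiced run, walk from the strongest waveform peak in both
    directions in steps of the local period, snapping each predicted epoch
    to the nearest waveform peak (of consistent polarity) within
    +/- search_frac of a period, with parabolic sub-sample refinement.
    Cycles whose period falls outside [1/ceiling, 1/floor] (with 25% slack)
    are dropped, counted, and split the run.
    """
    x = audio.samples
    sr = audio.sample_rate_hz
    times = track.frame_times_s
    n_dropped = 0

    epochs_all: list[float] = []
    amps_all: list[float] = []
    run_ids: list[int] = []
    next_run = 0

    flags = track.voicing_flag
    idx = 0
    while idx < flags.size:
        if not flags[idx]:
            idx += 1
            continue
        j = idx
        while j < flags.size and flags[j]:
            j += 1
        run_frames = np.arange(idx, j)
        idx = j

        t_lo = times[run_frames[0]] - 0.5 / track.f0_hz[run_frames[0]]
        t_hi = times[run_frames[-1]] + 1.5 / track.f0_hz[run_frames[-1]]
        s_lo = max(int(t_lo * sr), 0)
        s_hi = min(int(t_hi * sr), x.size)
        if s_hi - s_lo < 3:
            continue

        def local_period(t: float) -> float:
            k = int(np.clip(np.searchsorted(times[run_frames], t),
                            0, run_frames.size - 1))
            return 1.0 / track.f0_hz[run_frames[k]]

        anchor = s_lo + int(np.argmax(np.abs(x[s_lo:s_hi])))
        polarity = 1.0 if x[anchor] >= 0 else -1.0
        y = x * polarity

        def snap(pred_t: float) -> tuple[float, float] | None:
            period = local_period(pred_t)
            half = search_frac * period
            a = int((pred_t - half) * sr)
            b = int((pred_t + half) * sr) + 1
            a, b = max(a, 0), min(b, x.size)
            if b - a < 3:
                return None
            k = a + int(np.argmax(y[a:b]))
            if y[k] <= 0:
                return None
            delta, peak = _parabolic_refine(y, k)
            return (k + delta) / sr, peak

        d0, p0 = _parabolic_refine(y, anchor)
        epochs = [((anchor + d0) / sr, p0)]
        # forward walk
        while True:
            t_cur = epochs[-1][0]
            nxt = snap(t_cur + local_period(t_cur))
            if nxt is None or nxt[0] <= t_cur or nxt[0] > t_hi:
                break
            epochs.append(nxt)
        # backward walk
        while True:
            t_cur = epochs[0][0]
            prv = snap(t_cur - local_period(t_cur))
            if prv is None or prv[0] >= t_cur or prv[0] < t_lo:
                break
            epochs.insert(0, prv)

        # enforce period bounds; violations split the run
        t_min = 0.8 / ceiling_hz
        t_max = 1.25 / floor_hz
        current: list[tuple[float, float]] = []
        for k, (t_e, a_e) in enumerate(epochs):
            if current:
                dt = t_e - current[-1][0]
                if not (t_min <= dt <= t_max):
                    n_dropped += 1
                    if len(current) >= 1:
                        for te, ae in current:
                            epochs_all.append(te)
                            amps_all.append(ae)
                            run_ids.append(next_run)
                        next_run += 1
                    current = []
            current.append((t_e, a_e))
        for te, ae in current:
            epochs_all.append(te)
            amps_all.append(ae)
            run_ids.append(next_run)
        next_run += 1

    return PeriodSequence(
        epochs_s=np.array(epochs_all),
        peak_amplitudes=np.array(amps_all),
        run_id=np.array(run_ids, dtype=int),
        n_dropped=n_dropped,
    )


# --------------------------------------------------------------------------
# perturbation measures
# --------------------------------------------------------------------------

def _pooled_window_dev(values_by_run: list[np.ndarray], width: int) -> float | None:
    """Pooled mean |v_i - mean(window of `width` centered at i)| across runs;
    None when no run is long enough."""
    half = width // 2
    devs: list[np.ndarray] = []
    for v in values_by_run:
        if v.size >= width:
            windows = np.lib.stride_tricks.sliding_window_view(v, width)
            devs.append(np.abs(v[half:v.size - half] - windows.mean(axis=1)))
    if not devs:
        return None
    return float(np.mean(np.concatenate(devs)))


def jitter_measures(p: PeriodSequence) -> dict[str, float]:
    """Praat-style jitter family from within-run period sequences.

    local = mean|T_i - T_{i-1}| / mean(T); local_abs the unnormalized form;
    rap and ppq5 use 3- and 5-point moving-average reference periods;
    ddp = 3 * rap identically. NaN when there are too few periods.
    """
    out = {k: float("nan") for k in
           ("jitter_local", "jitter_local_abs_s", "jitter_rap",
            "jitter_ppq5", "jitter_ddp")}
    periods = p.periods_by_run()
    all_periods = np.concatenate(periods) if periods else np.array([])
    if all_periods.size < 2:
        return out
    mean_t = float(np.mean(all_periods))
    diffs = [np.abs(np.diff(t)) for t in periods if t.size >= 2]
    if diffs and all_periods.size >= 3:
        local_abs = float(np.mean(np.concatenate(diffs)))
        out["jitter_local_abs_s"] = local_abs
        out["jitter_local"] = local_abs / mean_t
    rap_dev = _pooled_window_dev(periods, 3)
    if rap_dev is not None:
        out["jitter_rap"] = rap_dev / mean_t
        out["jitter_ddp"] = 3.0 * out["jitter_rap"]
    ppq5_dev = _pooled_window_dev(periods, 5)
    if ppq5_dev is not None and all_periods.size >= 6:
        out["jitter_ppq5"] = ppq5_dev / mean_t
    return out


def shimmer_measures(p: PeriodSequence) -> dict[str, float]:
    """Praat-style shimmer family from within-run peak-amplitude sequences.

    local = mean|A_i - A_{i-1}| / mean(A); local_db = mean|20 log10(A_i /
    A_{i-1})| (cycles with a zero amplitude are excluded from the dB form);
    apqN uses N-point moving-average reference amplitudes, N in {3, 5, 11};
    dda = 3 * apq3 identically.
    """
    out = {k: float("nan") for k in
           ("shimmer_local", "shimmer_local_db", "shimmer_apq3",
            "shimmer_apq5", "shimmer_apq11", "shimmer_dda")}
    amps = [a for a in p.amplitudes_by_run() if a.size >= 2]
    all_amps = np.concatenate(amps) if amps else np.array([])
    if all_amps.size < 3:
        return out
    mean_a = float(np.mean(all_amps))
    if mean_a <= 0:
        return out
    diffs = [np.abs(np.diff(a)) for a in amps]
    out["shimmer_local"] = float(np.mean(np.concatenate(diffs))) / mean_a
    db_terms = []
    for a in amps:
        ratio = a[1:] / np.where(a[:-1] > 0, a[:-1], np.nan)
        ratio = ratio[np.isfinite(ratio) & (ratio > 0)]
        if ratio.size:
            db_terms.append(np.abs(20.0 * np.log10(ratio)))
    if db_terms:
        out["shimmer_local_db"] = float(np.mean(np.concatenate(db_terms)))
    for width, key in ((3, "shimmer_apq3"), (5, "shimmer_apq5"), (11, "shimmer_apq11")):
        dev = _pooled_window_dev(amps, width)
        if dev is not None:
            out[key] = dev / mean_a
    if np.isfinite(out["shimmer_apq3"]):
        out["shimmer_dda"] = 3.0 * out["shimmer_apq3"]
    return out


def frame_hnr_db(r: float) -> float:
    """Harmonicity of one frame from its normalized autocorrelation r."""
    r = float(np.clip(r, _EPS_R, 1.0 - _EPS_R))
    return 10.0 * np.log10(r / (1.0 - r))


def harmonics_to_noise(audio: AudioRecording, track: PitchTrack) -> float:
    """Mean HNR (dB) over voiced frames: the frame strength (NCC at the F0
    lag) r maps to 10*log10(r/(1-r)). NaN when no frame is voiced."""
    if track.n_voiced == 0:
        return float("nan")
    rs = track.strength[track.voicing_flag]
    return float(np.mean([frame_hnr_db(r) for r in rs]))


def f0_statistics(track: PitchTrack) -> tuple[float, float]:
    """(mean, population SD) of F0 over voiced frames; NaN when none."""
    voiced = track.voiced_f0
    if voiced.size == 0:
        return float("nan"), float("nan")
    return float(np.mean(voiced)), float(np.std(voiced))


# --------------------------------------------------------------------------
# panel extractor
# --------------------------------------------------------------------------

class VoiceQualityExtractor(BaseEstimator, TransformerMixin):
    """Extracts the full acoustic panel (one AcousticFeatureSet per
    recording) and a QC record with voicing fraction and dropped-cycle
    counts."""

    def __init__(
        self,
        floor_hz: float = 75.0,
        ceiling_hz: float = 500.0,
        hop_s: float = 0.01,
        voicing_threshold: float = 0.45,
    ):
        self.floor_hz = floor_hz
        self.ceiling_hz = ceiling_hz
        self.hop_s = hop_s
        self.voicing_threshold = voicing_threshold

    def _tracker(self) -> PitchTracker:
        return PitchTracker(
            floor_hz=self.floor_hz,
            ceiling_hz=self.ceiling_hz,
            hop_s=self.hop_s,
            voicing_threshold=self.voicing_threshold,
        )

    def fit(self, X=None, y=None):
        return self

    def extract(self, audio: AudioRecording) -> tuple[AcousticFeatureSet, dict]:
        track = self._tracker().track(audio)
        qc: dict[str, float] = {"voiced_fraction": track.voiced_fraction()}
        if track.n_voiced == 0:
            return AcousticFeatureSet(), qc
        periods = extract_periods(
            audio, track, floor_hz=self.floor_hz, ceiling_hz=self.ceiling_hz
        )
        qc["n_cycles"] = periods.n_cycles
        qc["n_dropped_cycles"] = periods.n_dropped
        qc["insufficient_cycles"] = float(periods.insufficient)
        f0_mean, f0_sd = f0_statistics(track)
        values = {"f0_mean_hz": f0_mean, "f0_sd_hz": f0_sd,
                  "hnr_mean_db": harmonics_to_noise(audio, track)}
        values.update(jitter_measures(periods))
        values.update(shimmer_measures(periods))
        return AcousticFeatureSet(**values), qc

    def transform(self, recordings: Iterable[AudioRecording]) -> pd.DataFrame:
        return pd.DataFrame([self.extract(a)[0].as_dict() for a in recordings])
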