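"""Simplified internal computation of the named acoustic descriptors.

The primary path for non-verbal features is ingestion of a per-session
acoustic table produced by external extractors; this module provides a
self-contained fallback that computes the same named descriptors from
audio samples: an autocorrelation F0 tracker, prosodic summaries of the
semitone-scale pitch track, and cycle-level perturbation measures
(jitter, shimmer in dB, 5-point pitch perturbation quotient).

Conventions: semitones are referenced to 27.5 Hz, the F0 percentile
range is the 80th minus the 20th percentile, per-segment slopes are
least-squares fits in semitones per second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["F0Track", "f0_track", "prosodic_features", "perturbation_features"]

SEMITONE_REF_HZ = 27.5


@dataclass(frozen=True)
class F0Track:
    """Frame-wise pitch track; f0 > 0 exactly on voiced frames."""

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray
    frame_step_s: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.array_equal(self.f0 > 0, self.voiced):
            raise ValueError("f0 must be positive exactly on voiced frames")


def f0_track(
    samples: np.ndarray,
    rate: int,
    frame_s: float = 0.04,
    step_s: float = 0.01,
    fmin: float = 50.0,
    fmax: float = 500.0,
    voicing_threshold: float = 0.5,
) -> F0Track:
    """Deterministic frame-wise autocorrelation pitch tracker.

    A frame is voiced when its energy is non-negligible and the
    normalized autocorrelation peak in the [fmin, fmax] lag range
    exceeds the voicing threshold.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty signal")
    if rate < 8000:
        raise ValueError("sampling rate must be at least 8000 /s")
    frame = int(frame_s * rate)
    step = int(step_s * rate)
    lag_min = max(2, int(rate / fmax))
    lag_max = min(frame - 1, int(rate / fmin))
    times, f0s, voiced = [], [], []
    energy_floor = 1e-6 * (np.abs(samples).max() or 1.0) ** 2
    for start in range(0, max(1, samples.size - frame + 1), step):
        seg = samples[start : start + frame]
        seg = seg - seg.mean()
        t = (start + frame / 2) / rate
        e0 = float(seg @ seg)
        f0 = 0.0
        if e0 > energy_floor * frame and lag_max > lag_min:
            ac = np.correlate(seg, seg, mode="full")[seg.size - 1 :]
            window = ac[lag_min : lag_max + 1] / ac[0]
            peak = int(np.argmax(window))
            if window[peak] > voicing_threshold:
                lag = lag_min + peak
                # parabolic interpolation around the peak for sub-sample lag
                if 0 < peak < window.size - 1:
                    a, b, c = window[peak - 1], window[peak], window[peak + 1]
                    denom = a - 2 * b + c
                    if denom != 0:
                        lag = lag + 0.5 * (a - c) / denom
                f0 = rate / lag
        times.append(t)
        f0s.append(f0)
        voiced.append(f0 > 0)
    return F0Track(
        times=np.asarray(times),
        f0=np.asarray(f0s),
        voiced=np.asarray(voiced),
        frame_step_s=step_s,
    )


def _segments(voiced: np.ndarray, min_len: int = 2) -> list[slice]:
    """Runs of consecutive voiced frames with at least ``min_len`` frames."""
    out = []
    start = None
    for i, v in enumerate(voiced):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                out.append(slice(start, i))
            start = None
    if start is not None and voiced.size - start >= min_len:
        out.append(slice(start, voiced.size))
    return out


def semitones(f0: np.ndarray) -> np.ndarray:
    return 12.0 * np.log2(np.asarray(f0, dtype=float) / SEMITONE_REF_HZ)


def prosodic_features(track: F0Track) -> dict[str, float]:
    """Prosodic descriptors N1-N10 from one pitch track.

    Per voiced segment a least-squares semitone slope is fit; N10/N3 are
    the mean/SD of the rising (positive) slopes, N5/N8 of the falling
    ones.  N4 is the SD of the mean-normalized f0, N9 the 80th - 20th
    percentile range of the voiced f0 values.  With no voiced frames all
    entries fall back to the imputation value 0.
    """
    voiced_f0 = track.f0[track.voiced]
    if voiced_f0.size == 0:
        return {f"N{i}": 0.0 for i in (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 13)}
    st = semitones(voiced_f0)
    slopes = []
    total_time = track.times[-1] - track.times[0] + track.frame_step_s
    segs = _segments(track.voiced)
    for seg in segs:
        t = track.times[seg]
        y = semitones(track.f0[seg])
        slopes.append(float(np.polyfit(t, y, 1)[0]))
    slopes = np.asarray(slopes)
    rising = slopes[slopes > 0]
    falling = slopes[slopes < 0]
    return {
        "N1": float(st.mean()),
        "N2": float(st.std()),
        "N3": float(rising.std()) if rising.size else 0.0,
        "N4": float((voiced_f0 / voiced_f0.mean()).std()),
        "N5": float(falling.mean()) if falling.size else 0.0,
        "N6": float(np.median(voiced_f0)),
        "N7": float(track.voiced.mean()),
        "N8": float(falling.std()) if falling.size else 0.0,
        "N9": float(np.percentile(voiced_f0, 80) - np.percentile(voiced_f0, 20)),
        "N10": float(rising.mean()) if rising.size else 0.0,
        "N13": float(len(segs) / total_time) if total_time > 0 else 0.0,
    }


def perturbation_features(
    periods: np.ndarray, amplitudes: np.ndarray
) -> dict[str, float]:
    """Cycle-level voice-quality descriptors N11, N12, N14-N17.

    jitter(local) = mean |T_i - T_{i-1}| / mean T;
    shimmer_i(dB) = |20 log10(A_{i+1} / A_i)|, N12 its mean and N14 its
    SD; PPQ5_i = |T_i - centered 5-point mean| / mean T, N15 its mean.
    """
    periods = np.asarray(periods, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if np.any(periods <= 0) or np.any(amplitudes <= 0):
        raise ValueError("periods and amplitudes must be positive")
    if periods.size < 5:
        raise ValueError("need at least 5 periods for PPQ5")
    mean_t = periods.mean()
    jitter_series = np.abs(np.diff(periods)) / mean_t
    shimmer_db = np.abs(20.0 * np.log10(amplitudes[1:] / amplitudes[:-1]))
    # centered 5-point moving average of the period series
    kernel = np.ones(5) / 5.0
    centered = np.convolve(periods, kernel, mode="valid")
    ppq5 = np.abs(periods[2:-2] - centered) / mean_t
    return {
        "N11": float(jitter_series.mean()),
        "N12": float(shimmer_db.mean()),
        "N14": float(shimmer_db.std()),
        "N15": float(ppq5.mean()),
        "N16": float(jitter_series.std()),
        "N17": float(ppq5.std()),
    }
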