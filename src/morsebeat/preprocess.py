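"""Denoising, edge trimming, R-peak detection and beat segmentation.

The cleaning chain for a raw single-lead record is

1. baseline-wander removal: subtract a 500-sample moving average,
2. high-frequency smoothing: a 10-sample moving average,
3. trim 600 samples from each end to discard filter edge distortion,
4. R-peak detection (Pan–Tompkins-style stages),
5. cut 784-sample windows centered on each R-peak.

Filter widths and the trim count are expressed in samples; the defaults
assume a 1000 Hz sampling rate, where the 500-sample average spans 0.5 s
(cutting drift well below the heart rate) and the 10-sample average nulls
100 Hz and strongly attenuates 50–60 Hz mains pickup.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .records import DEFAULT_BEAT_LENGTH, BeatSegment, EcgRecord

BASELINE_WIDTH = 500
SMOOTH_WIDTH = 10
TRIM_SAMPLES = 600
#: Minimum spacing between detected R-peaks, in seconds.
REFRACTORY_S = 0.25


def moving_average(signal: np.ndarray, width: int) -> np.ndarray:
    """Uniform moving average with reflect-padded edges.

    Each output sample is the mean of a ``width``-sample window (kernel
    value 1/width). Output length equals input length; edges are handled
    by reflecting the signal about its end samples, so a constant signal
    maps to itself exactly.
    """
    signal = np.asarray(signal, dtype=np.float64)
    width = int(width)
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    if width > signal.size:
        raise ValueError(
            f"width {width} exceeds signal length {signal.size}")
    # uniform_filter1d in "reflect" mode is the reflect-padded box mean;
    # for even widths the window is [i - width//2, i + width//2 - 1].
    return uniform_filter1d(signal, size=width, mode="reflect")


def remove_baseline(record: EcgRecord, width: int = BASELINE_WIDTH) -> EcgRecord:
    """Subtract the ``width``-sample moving average from the record.

    The wide moving average tracks only the slow baseline wander (muscle
    movement, respiration); subtracting it leaves the cardiac waveform on
    a zero baseline. A constant record maps to all zeros.
    """
    if len(record) <= width:
        raise ValueError(
            f"record length {len(record)} must exceed filter width {width}")
    baseline = moving_average(record.samples, width)
    return record.replace_samples(record.samples - baseline)


def smooth_highfreq(record: EcgRecord, width: int = SMOOTH_WIDTH) -> EcgRecord:
    """Suppress mains and wideband noise with a short moving average."""
    if len(record) <= width:
        raise ValueError(
            f"record length {len(record)} must exceed filter width {width}")
    return record.replace_samples(moving_average(record.samples, width))


def trim_edges(record: EcgRecord, n: int = TRIM_SAMPLES) -> EcgRecord:
    """Drop the first and last ``n`` samples (filter edge distortion)."""
    n = int(n)
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0:
        return record.replace_samples(record.samples.copy())
    if len(record) <= 2 * n:
        raise ValueError(
            f"record length {len(record)} must exceed 2*n = {2 * n}")
    return record.replace_samples(record.samples[n:-n])


def denoise(record: EcgRecord,
            baseline_width: int = BASELINE_WIDTH,
            smooth_width: int = SMOOTH_WIDTH,
            trim: int = TRIM_SAMPLES) -> EcgRecord:
    """Full cleaning chain: baseline removal, smoothing, edge trim."""
    rec = remove_baseline(record, baseline_width)
    rec = smooth_highfreq(rec, smooth_width)
    return trim_edges(rec, trim)


def _detection_function(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan–Tompkins-style QRS emphasis: derivative, squaring, integration.

    Works on the absolute amplitude so records with inverted polarity
    still produce positive QRS energy.
    """
    # Five-point derivative emphasizes the steep QRS slopes.
    deriv = np.convolve(np.abs(x), np.array([1.0, 2.0, 0.0, -2.0, -1.0]) / 8.0,
                        mode="same")
    squared = deriv * deriv
    # Moving-window integration over ~150 ms merges the QRS slope energy
    # into a single hump per beat.
    win = max(1, int(round(0.15 * fs)))
    return uniform_filter1d(squared, size=win, mode="nearest")


def detect_r_peaks(record: EcgRecord,
                   refractory_s: float = REFRACTORY_S) -> np.ndarray:
    """Detect R-peak sample indices on a preprocessed record.

    Stages: absolute-amplitude derivative -> squaring -> 150 ms
    moving-window integration -> adaptive signal/noise threshold with a
    refractory period -> R localization at the maximum absolute amplitude
    near each accepted detection.

    Returns a strictly increasing index array; an empty array when the
    record is shorter than one refractory period or contains no
    above-threshold activity.
    """
    x = record.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("record contains non-finite samples")
    fs = record.fs
    refr = max(1, int(round(refractory_s * fs)))
    if x.size <= refr or not np.any(x):
        return np.zeros(0, dtype=np.intp)

    det = _detection_function(x, fs)
    cand, _ = find_peaks(det, distance=refr)
    if cand.size == 0:
        return np.zeros(0, dtype=np.intp)

    # Adaptive two-level threshold (running signal / noise peak estimates).
    heights = det[cand]
    spki = float(np.max(heights))        # signal-peak running estimate
    npki = float(np.median(heights))     # noise-peak running estimate
    accepted = []
    for idx, h in zip(cand, heights):
        thr = npki + 0.25 * (spki - npki)
        if h >= thr:
            accepted.append(idx)
            spki = 0.125 * h + 0.875 * spki
        else:
            npki = 0.125 * h + 0.875 * npki
    if not accepted:
        return np.zeros(0, dtype=np.intp)

    # Localize the R-peak: the integrator hump lags the R wave, so search
    # the absolute amplitude in a window around each accepted detection.
    half = int(round(0.10 * fs))
    peaks = []
    for idx in accepted:
        lo = max(0, idx - half)
        hi = min(x.size, idx + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    # Deduplicate peaks that localized to the same maximum and re-impose
    # the refractory spacing (keep the larger of two close peaks).
    peaks = sorted(set(peaks))
    out: list[int] = []
    for p in peaks:
        if out and p - out[-1] < refr:
            if np.abs(x[p]) > np.abs(x[out[-1]]):
                out[-1] = p
        else:
            out.append(p)
    return np.asarray(out, dtype=np.intp)


def segment_beats(record: EcgRecord, peaks: np.ndarray,
                  beat_length: int = DEFAULT_BEAT_LENGTH) -> list[BeatSegment]:
    """Cut a centered, fixed-length window around each R-peak.

    The window for a peak at ``r`` spans ``[r - L//2, r - L//2 + L)``.
    Peaks whose window would cross a record boundary are dropped, so every
    returned segment has exactly ``beat_length`` samples.
    """
    beat_length = int(beat_length)
    if beat_length < 1:
        raise ValueError("beat_length must be >= 1")
    n = len(record)
    half = beat_length // 2
    segments: list[BeatSegment] = []
    for r in np.asarray(peaks, dtype=np.intp):
        if r < 0 or r >= n:
            raise ValueError(f"peak index {r} outside record bounds [0, {n})")
        start = int(r) - half
        if start < 0 or start + beat_length > n:
            continue
        segments.append(BeatSegment(
            samples=record.samples[start:start + beat_length].copy(),
            r_index=int(r), subject_id=record.subject_id))
    return segments
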