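"""Contraction-beat extraction and summarization from cantilever
displacement traces.

A beating cardiomyocyte layer deflects the cantilever once per beat; the
laser vibrometer records tip displacement versus time.  Beats are
detected as local maxima whose prominence clears a robust noise
threshold floored at the instrument noise floor (~120 nm for the laser
vibrometer used here).  Per-beat amplitude is measured against the
preceding local minimum, and force follows from the cantilever spring
constant (F = k * amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "DisplacementTrace",
    "BeatSummary",
    "detrend",
    "detect_beats",
    "beat_durations",
    "summarize",
    "relative_force_course",
    "average_beat",
    "DEFAULT_NOISE_FLOOR",
]

DEFAULT_NOISE_FLOOR = 120e-9  # m; minimum displacement the vibrometer resolves
MIN_BEAT_SEPARATION_S = 0.150  # s; caps detectable rate at ~6.7 Hz


@dataclass(frozen=True)
class DisplacementTrace:
    """Uniformly sampled cantilever tip displacement.

    samples are metres; ``noise_floor`` is the smallest displacement the
    readout can resolve and floors the beat-detection threshold.
    """

    sampling_rate: float  # Hz
    samples: np.ndarray  # m
    start_time: float = 0.0  # s
    noise_floor: float = DEFAULT_NOISE_FLOOR  # m

    def __post_init__(self) -> None:
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be > 0")
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("trace needs >= 2 samples")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        object.__setattr__(self, "samples", x)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.sampling_rate


@dataclass(frozen=True)
class BeatSummary:
    """Per-session aggregate of the detected beats.

    beating_frequency is 1 / median(inter-beat interval); interval_cv is
    sd(intervals)/mean(intervals), an irregularity (arrhythmia proxy)
    index.  Frequency and CV are NaN with fewer than 2 beats; amplitude
    and force are 0 for a flat (no-beat) trace.
    """

    beat_count: int
    beating_frequency: float  # Hz
    mean_amplitude: float  # m
    mean_force: float  # N
    mean_duration: float  # s
    interval_cv: float


SMOOTH_WINDOW_S = 0.031  # Savitzky-Golay / running-median denoising window


def _robust_noise_scale(detrended: np.ndarray) -> float:
    med = np.median(detrended)
    return 1.4826 * float(np.median(np.abs(detrended - med)))


def detrend(trace: DisplacementTrace) -> np.ndarray:
    """Remove slow drift with a running median, window = 3x the median
    beat period (coarse first-pass estimate).  Deterministic, so every
    operation on the same trace sees the same detrended signal."""
    x = trace.samples
    fs = trace.sampling_rate
    distance = max(int(round(MIN_BEAT_SEPARATION_S * fs)), 1)
    peaks, _ = signal.find_peaks(x, distance=distance, prominence=max(np.ptp(x) / 4, 1e-18))
    if len(peaks) >= 3:
        period = float(np.median(np.diff(peaks))) / fs
    else:
        period = 1.0
    win = int(round(3.0 * period * fs))
    win = max(min(win | 1, x.size | 1), 3)  # odd, bounded by trace length
    baseline = ndimage.median_filter(x, size=win, mode="nearest")
    return x - baseline


def _smooth(x: np.ndarray, fs: float) -> np.ndarray:
    """Savitzky-Golay low-pass (quadratic, ~31 ms) used for peak picking
    and baseline estimation.  Preserves the locally quadratic beat apex
    while suppressing readout noise, so prominence thresholds compare
    against the beat, not against noise extremes."""
    win = int(round(SMOOTH_WINDOW_S * fs)) | 1
    win = max(min(win, (x.size - 1) | 1), 5)
    return signal.savgol_filter(x, window_length=win, polyorder=2)


def detect_beats(trace: DisplacementTrace) -> pd.DataFrame:
    """Detect contraction beats in a displacement trace.

    The drift-removed trace is low-pass filtered (Savitzky-Golay); local
    maxima with prominence >= max(3 * robust noise scale (1.4826 * MAD
    of the detrended trace), instrument noise floor) and minimum
    separation 150 ms are kept.  Per-beat baseline is the preceding
    local minimum of a running-median denoised signal (between the
    previous peak, or trace start, and the peak); the peak value is the
    raw sample at the local maximum, so noise-free amplitudes are exact
    and a constant offset cancels out of every amplitude.

    Returns a DataFrame with one row per beat: ``peak_index``,
    ``peak_time_s``, ``peak_displacement_m``, ``baseline_m``,
    ``amplitude_m``, ``interval_s`` (NaN for the first beat).  A flat
    trace yields an empty table; NaN samples raise.
    """
    x = trace.samples
    if np.any(np.isnan(x)):
        raise ValueError("trace contains NaN samples")
    fs = trace.sampling_rate

    d = detrend(trace)
    threshold = max(3.0 * _robust_noise_scale(d), trace.noise_floor)
    smoothed = _smooth(d, fs)
    distance = max(int(round(MIN_BEAT_SEPARATION_S * fs)), 1)
    peaks, _props = signal.find_peaks(smoothed, prominence=threshold, distance=distance)

    # baseline signal: running median denoises the flat diastolic
    # stretches without the undershoot a least-squares smoother shows
    # at the contraction onset; measurement happens in raw coordinates
    # (peak minus preceding minimum cancels any offset) while the
    # detrended signal is used only for detection
    med_win = max(int(round(SMOOTH_WINDOW_S * fs)) | 1, 3)
    base_sig = ndimage.median_filter(x, size=med_win, mode="nearest")

    # re-centre each detected peak on the raw local maximum (low-pass
    # filtering can shift an asymmetric apex by a few samples)
    half_win = max(int(round(SMOOTH_WINDOW_S * fs)) // 2, 1)

    rows = []
    prev_peak = 0
    prev_time = None
    for p in peaks:
        lo = max(p - half_win, 0)
        p = lo + int(np.argmax(x[lo:p + half_win + 1]))
        seg = base_sig[prev_peak:p + 1]
        baseline = float(seg.min()) if seg.size else float(base_sig[p])
        peak_val = float(x[p])
        t = trace.start_time + p / fs
        rows.append(
            dict(
                peak_index=int(p),
                peak_time_s=t,
                peak_displacement_m=peak_val,
                baseline_m=baseline,
                amplitude_m=peak_val - baseline,
                interval_s=(t - prev_time) if prev_time is not None else np.nan,
            )
        )
        prev_peak = p
        prev_time = t

    return pd.DataFrame(
        rows,
        columns=[
            "peak_index",
            "peak_time_s",
            "peak_displacement_m",
            "baseline_m",
            "amplitude_m",
            "interval_s",
        ],
    )


def beat_durations(
    trace: DisplacementTrace, table: pd.DataFrame, threshold_fraction: float = 0.1
) -> np.ndarray:
    """Per-beat duration at a fractional threshold (a QT-like width).

    Duration is the time between the upward and downward crossings of
    ``baseline + threshold_fraction * amplitude`` around each peak, with
    linear interpolation between samples.  Beats truncated by the trace
    edge (or running into a neighbouring peak before crossing) get NaN.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    x = trace.samples
    fs = trace.sampling_rate
    out = np.full(len(table), np.nan)
    peak_indices = table["peak_index"].to_numpy(dtype=int) if len(table) else np.array([], int)

    for i, row in enumerate(table.itertuples(index=False)):
        p = int(row.peak_index)
        level = row.baseline_m + threshold_fraction * row.amplitude_m
        lo_bound = peak_indices[i - 1] if i > 0 else 0
        hi_bound = peak_indices[i + 1] if i + 1 < len(peak_indices) else x.size - 1

        # upward crossing, scanning left from the peak
        j = p
        while j > lo_bound and x[j - 1] >= level:
            j -= 1
        if j == lo_bound and x[j] >= level:
            continue  # truncated: never dropped below level
        t_up = (j - 1 + (level - x[j - 1]) / (x[j] - x[j - 1])) / fs if j > 0 else np.nan

        # downward crossing, scanning right
        j = p
        while j < hi_bound and x[j + 1] >= level:
            j += 1
        if j == hi_bound and x[j] >= level:
            continue
        t_dn = (j + (level - x[j]) / (x[j + 1] - x[j])) / fs

        out[i] = t_dn - t_up
    return out


def summarize(
    trace: DisplacementTrace,
    table: pd.DataFrame,
    k: float,
    threshold_fraction: float = 0.1,
) -> BeatSummary:
    """Aggregate a beat table into session metrics.

    mean_force = k * mean_amplitude.  With < 2 beats frequency and
    interval CV are NaN; with 0 beats amplitude/force are 0 (quiescent
    preparation).
    """
    if not (k > 0):
        raise ValueError("spring constant must be > 0")
    count = len(table)
    if count == 0:
        return BeatSummary(0, np.nan, 0.0, 0.0, np.nan, np.nan)

    amp = float(table["amplitude_m"].mean())
    durations = beat_durations(trace, table, threshold_fraction)
    mean_dur = float(np.nanmean(durations)) if np.any(np.isfinite(durations)) else np.nan

    intervals = table["interval_s"].to_numpy(dtype=float)
    intervals = intervals[np.isfinite(intervals)]
    if intervals.size >= 1 and count >= 2:
        freq = 1.0 / float(np.median(intervals))
        cv = (
            float(np.std(intervals, ddof=1) / np.mean(intervals))
            if intervals.size >= 2
            else 0.0
        )
    else:
        freq, cv = np.nan, np.nan

    return BeatSummary(
        beat_count=count,
        beating_frequency=freq,
        mean_amplitude=amp,
        mean_force=k * amp,
        mean_duration=mean_dur,
        interval_cv=cv,
    )


def relative_force_course(
    summaries: "list[BeatSummary]", baseline_index: int = 0
) -> np.ndarray:
    """Per-session mean force as percent of a baseline session.

    The baseline entry maps to exactly 100; scaling every amplitude by a
    common factor leaves the course unchanged.
    """
    forces = np.array([s.mean_force for s in summaries], dtype=float)
    f0 = forces[baseline_index]
    if not (f0 > 0):
        raise ValueError("baseline mean force must be > 0")
    return 100.0 * forces / f0


def average_beat(trace: DisplacementTrace, table: pd.DataFrame):
    """Pointwise-mean beat waveform, peak-aligned.

    Beats are windowed around their peaks (window = median inter-beat
    interval, centred on the peak) and averaged; beats whose window
    exceeds the trace are dropped.  The returned waveform is
    mean-centred, so it is exactly invariant to a constant trace
    offset.  Returns ``(offsets_s, waveform_m)``.  Requires >= 2 beats.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 beats to average")
    fs = trace.sampling_rate
    x = trace.samples
    intervals = table["interval_s"].to_numpy(dtype=float)
    period = float(np.median(intervals[np.isfinite(intervals)]))
    win = max(int(round(period * fs)), 3)
    half = win // 2

    # sub-sample alignment on the low-pass-filtered apex (parabola
    # vertex): integer-sample alignment would smear the steep
    # relaxation flank across beats under readout noise
    smoothed = _smooth(x, fs)
    align_half = max(int(round(SMOOTH_WINDOW_S * fs)) // 2, 1)
    offsets_idx = np.arange(win, dtype=float) - half
    grid = np.arange(x.size, dtype=float)

    segs = []
    for p in table["peak_index"].to_numpy(dtype=int):
        a_lo = max(p - align_half, 0)
        p0 = a_lo + int(np.argmax(smoothed[a_lo:p + align_half + 1]))
        centre = float(p0)
        if 2 <= p0 <= x.size - 3:
            c2, c1, _ = np.polyfit(np.arange(-2.0, 3.0), smoothed[p0 - 2:p0 + 3], 2)
            if c2 < 0:
                centre = p0 + float(np.clip(-c1 / (2.0 * c2), -2.0, 2.0))
        sample_pos = centre + offsets_idx
        if sample_pos[0] < 0 or sample_pos[-1] > x.size - 1:
            continue
        segs.append(np.interp(sample_pos, grid, x))
    if len(segs) < 2:
        raise ValueError("fewer than 2 complete beat windows in trace")
    waveform = np.mean(segs, axis=0)
    waveform -= waveform.mean()
    offsets = (np.arange(win) - half) / fs
    return offsets, waveform
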