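"""ECG to quality-controlled RR intervals.

Stages: zero-phase Butterworth band-pass (0.5-45 Hz), Pan-Tompkins R-peak
detection, RR computation, local-median artifact flagging, cubic-spline
correction of flagged beats, >20% artifact exclusion, and extraction of
the pre-awakening (hypnopompic) window.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sig
from scipy.interpolate import CubicSpline
from scipy.ndimage import median_filter

from .series import ECGSignal, RPeakSeries, RRIntervalSeries

__all__ = [
    "bandpass_filter",
    "detect_r_peaks",
    "compute_rr",
    "flag_artifacts",
    "correct_artifacts",
    "qc_exclude",
    "extract_hypnopompic_window",
    "ecg_to_rr",
]


def bandpass_filter(ecg: ECGSignal, low: float = 0.5, high: float = 45.0,
                    order: int = 4) -> ECGSignal:
    """Zero-phase Butterworth band-pass; length preserved.

    Forward-backward filtering (``sosfiltfilt``) is used so that R-peak
    timing is not shifted by filter group delay.
    """
    if not (0 < low < high < ecg.fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {ecg.fs / 2}"
        )
    sos = sig.butter(order, [low, high], btype="bandpass", fs=ecg.fs, output="sos")
    filtered = sig.sosfiltfilt(sos, ecg.samples)
    return ECGSignal(filtered, ecg.fs, ecg.start_time)


def _moving_window_integration(x: np.ndarray, width: int) -> np.ndarray:
    return np.convolve(x, np.ones(width) / width, mode="same")


def detect_r_peaks(ecg: ECGSignal, refractory: float = 0.200) -> RPeakSeries:
    """Pan-Tompkins R-wave detection.

    Pipeline: 5-15 Hz band-pass -> derivative -> squaring -> 150 ms
    moving-window integration -> adaptive dual thresholds (signal/noise
    peak running estimates initialised from the first 2 s) with a 200 ms
    refractory period and 1.66*RR search-back -> each accepted peak is
    refined to the local maximum of the input signal within +/-100 ms.

    Returns an empty series (with a warning) for flat or too-short input.
    """
    fs = ecg.fs
    if fs < 100:
        raise ValueError(f"Pan-Tompkins detection requires fs >= 100 Hz, got {fs}")
    x = ecg.samples
    if len(x) < 10 * fs or np.ptp(x) == 0:
        warnings.warn("signal flat or shorter than 10 s; no peaks detected")
        return RPeakSeries(np.array([], dtype=np.int64), fs)

    sos = sig.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sig.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    squared = deriv ** 2
    integ = _moving_window_integration(squared, max(1, int(round(0.150 * fs))))

    refr = max(1, int(round(refractory * fs)))
    cand, _ = sig.find_peaks(integ, distance=refr)
    if len(cand) == 0:
        warnings.warn("no candidate peaks found")
        return RPeakSeries(np.array([], dtype=np.int64), fs)

    # adaptive thresholding, constants from the canonical published recipe
    init = integ[: int(2 * fs)]
    spki = float(np.max(init))
    npki = float(np.mean(init))
    threshold = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_buffer: list[float] = []
    last_rejected: list[int] = []
    for p in cand:
        if integ[p] > threshold:
            _accept(accepted, rr_buffer, p)
            spki = 0.125 * integ[p] + 0.875 * spki
            last_rejected.clear()
        else:
            npki = 0.125 * integ[p] + 0.875 * npki
            last_rejected.append(p)
            # search-back: if we have gone > 1.66 average RR without a beat,
            # take the best rejected candidate above half threshold
            if accepted and rr_buffer:
                rr_avg = float(np.mean(rr_buffer[-8:]))
                if (p - accepted[-1]) > 1.66 * rr_avg:
                    back = [q for q in last_rejected if integ[q] > 0.5 * threshold]
                    if back:
                        q = max(back, key=lambda i: integ[i])
                        _accept(accepted, rr_buffer, q)
                        spki = 0.25 * integ[q] + 0.75 * spki
                        last_rejected.clear()
        threshold = npki + 0.25 * (spki - npki)

    if not accepted:
        warnings.warn("no peaks exceeded the adaptive threshold")
        return RPeakSeries(np.array([], dtype=np.int64), fs)

    # refine to local maximum of the (already band-passed) input signal
    half = int(round(0.100 * fs))
    refined = []
    for p in sorted(accepted):
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    # dedupe and enforce refractory spacing, keeping the larger amplitude
    refined = sorted(set(refined))
    kept: list[int] = []
    for p in refined:
        if kept and p - kept[-1] < refr:
            if x[p] > x[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return RPeakSeries(np.asarray(kept, dtype=np.int64), fs)


def _accept(accepted: list[int], rr_buffer: list[float], p: int) -> None:
    if accepted:
        rr_buffer.append(p - accepted[-1])
    accepted.append(p)


def compute_rr(peaks: RPeakSeries) -> RRIntervalSeries:
    """Intervals between successive R peaks, in ms; N peaks -> N-1 intervals."""
    if len(peaks) < 2:
        raise ValueError(f"need at least 2 peaks to form intervals, got {len(peaks)}")
    rr = np.diff(peaks.peak_indices) / peaks.fs * 1000.0
    return RRIntervalSeries(rr, origin="measured")


def flag_artifacts(rr: RRIntervalSeries, rel_threshold: float = 0.20,
                   window: int = 11) -> RRIntervalSeries:
    """Flag beats deviating from the local median by more than ``rel_threshold``.

    The local median is taken over a centred ``window``-beat neighbourhood
    (edges replicate the nearest value).  Returns a copy with the artifact
    mask filled; interval values are untouched.
    """
    if len(rr) == 0:
        raise ValueError("RR series is empty")
    med = median_filter(rr.rr, size=window, mode="nearest")
    mask = np.abs(rr.rr - med) / med > rel_threshold
    return rr.replace(artifact_mask=mask)


def correct_artifacts(rr: RRIntervalSeries) -> RRIntervalSeries:
    """Replace flagged beats by cubic-spline interpolation over clean neighbours.

    Unflagged values are never modified.  A consecutive flagged run longer
    than half the series triggers an uncorrectable-segment warning (the
    interpolation is still attempted).
    """
    mask = rr.artifact_mask
    if not mask.any():
        return rr.replace(origin="corrected")
    if mask.all():
        raise ValueError("all beats flagged; nothing to interpolate from")
    runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0])))))
    longest_run = int(runs[::2].max()) if len(runs) else 0
    if longest_run > 0.5 * len(rr):
        warnings.warn(
            f"consecutive flagged run of {longest_run} beats exceeds half the series; "
            "corrected values are unreliable"
        )
    idx = np.arange(len(rr))
    spline = CubicSpline(idx[~mask], rr.rr[~mask])
    corrected = rr.rr.copy()
    corrected[mask] = spline(idx[mask])
    corrected = np.maximum(corrected, 1.0)  # keep intervals positive
    return RRIntervalSeries(corrected, rr.artifact_mask.copy(), origin="corrected")


def qc_exclude(rr: RRIntervalSeries, max_artifact_fraction: float = 0.20) -> bool:
    """True when the flagged fraction *strictly exceeds* the threshold.

    Subjects with more than 20% artifact/ectopic beats are excluded from
    analysis; exactly 20% is kept.
    """
    if len(rr) == 0:
        raise ValueError("RR series is empty")
    return rr.artifact_fraction > max_artifact_fraction


def extract_hypnopompic_window(rr: RRIntervalSeries, wake_time: float,
                               window: float = 3600.0) -> RRIntervalSeries:
    """Beats in the half-open interval ``[wake_time - window, wake_time)``.

    Beat membership is decided by cumulative RR time at the *end* of each
    interval, measured from the start of the recording.  Raises when the
    recording does not cover the requested window.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if wake_time - window < 0:
        raise ValueError(
            f"window [{wake_time - window:.1f}, {wake_time:.1f}) starts before the recording"
        )
    t_end = rr.end_times
    total = t_end[-1] if len(rr) else 0.0
    if wake_time > total + 1e-9:
        raise ValueError(
            f"wake_time {wake_time:.1f} s beyond end of recording ({total:.1f} s)"
        )
    sel = (t_end >= wake_time - window) & (t_end < wake_time)
    return RRIntervalSeries(rr.rr[sel], rr.artifact_mask[sel], origin=rr.origin)


def ecg_to_rr(ecg: ECGSignal, low: float = 0.5, high: float = 45.0,
              rel_threshold: float = 0.20,
              max_artifact_fraction: float = 0.20) -> tuple[RRIntervalSeries, bool]:
    """Convenience chain: filter -> detect -> RR -> flag -> correct -> QC.

    Returns the corrected series and the QC exclusion decision.
    """
    filtered = bandpass_filter(ecg, low, high)
    peaks = detect_r_peaks(filtered)
    rr = compute_rr(peaks)
    rr = flag_artifacts(rr, rel_threshold=rel_threshold)
    exclude = qc_exclude(rr, max_artifact_fraction)
    rr = correct_artifacts(rr)
    return rr, exclude
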