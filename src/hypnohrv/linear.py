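"""Time- and frequency-domain HRV metrics.

Frequency-domain analysis follows standard short-term practice: each
5-minute RR segment is cubic-spline resampled to an evenly sampled 4 Hz
tachogram, linearly detrended, and its Welch periodogram (Hann window,
2-minute sub-windows, 50% overlap) integrated over the classical bands

* TP: 0.003-0.4 Hz (total power, ms^2)
* LF: 0.04-0.15 Hz
* HF: 0.15-0.4 Hz
* HFnorm = HF / (LF + HF) * 100 (normalised units)

The boundary bin at exactly 0.15 Hz belongs to HF.  Band powers per
segment are averaged over the 12 segments of a one-hour recording; SDNN
and RMSSD are computed on the whole series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig
from scipy.interpolate import CubicSpline

from .series import RRIntervalSeries

__all__ = [
    "SpectralBands",
    "TimeDomainMetrics",
    "segment_rr",
    "band_powers",
    "average_band_powers",
    "sdnn",
    "rmssd",
    "linear_metrics",
]

TP_BAND = (0.003, 0.4)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)


@dataclass
class SpectralBands:
    """Band powers in ms^2 plus normalised HF (0-100 n.u.)."""

    tp: float
    lf: float
    hf: float
    hfnorm: float


@dataclass
class TimeDomainMetrics:
    sdnn: float
    rmssd: float


def segment_rr(rr: RRIntervalSeries, segment_length: float = 300.0) -> list[RRIntervalSeries]:
    """Split a series into consecutive non-overlapping time segments.

    Beats are assigned to segments by their interval *start* time; only
    full segments are returned (a trailing partial segment is dropped), so
    one hour of beats yields 12 five-minute segments.
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    n_seg = int(rr.duration // segment_length)
    if n_seg == 0:
        raise ValueError(
            f"series duration {rr.duration:.1f} s shorter than one segment "
            f"({segment_length:.0f} s)"
        )
    seg_idx = (rr.start_times // segment_length).astype(int)
    return [
        RRIntervalSeries(rr.rr[seg_idx == j], rr.artifact_mask[seg_idx == j], origin=rr.origin)
        for j in range(n_seg)
    ]


def band_powers(segment: RRIntervalSeries, resample_fs: float = 4.0,
                subwindow: float = 120.0) -> SpectralBands:
    """Spectral band powers of one RR segment.

    The tachogram (RR value vs cumulative beat time) is resampled with a
    cubic spline onto a uniform ``resample_fs`` grid, linearly detrended,
    and its Welch PSD (Hann, ``subwindow``-second sub-windows, 50%
    overlap) integrated by the trapezoidal rule over bins whose centres
    fall in each band.  HFnorm is ``nan`` when LF + HF vanishes.
    """
    if segment.duration < 120.0 or len(segment) < 8:
        raise ValueError(
            f"segment of {segment.duration:.1f} s / {len(segment)} beats too short "
            "for spectral analysis (need >= 2 min)"
        )
    t = segment.end_times
    spline = CubicSpline(t, segment.rr)
    grid = np.arange(t[0], t[-1], 1.0 / resample_fs)
    x = sig.detrend(spline(grid), type="linear")
    nperseg = min(len(grid), int(round(subwindow * resample_fs)))
    freqs, psd = sig.welch(
        x, fs=resample_fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend=False,
    )

    def integrate(lo: float, hi: float, hi_inclusive: bool) -> float:
        mask = (freqs >= lo) & ((freqs <= hi) if hi_inclusive else (freqs < hi))
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    tp = integrate(*TP_BAND, hi_inclusive=True)
    lf = integrate(LF_BAND[0], LF_BAND[1], hi_inclusive=False)  # 0.15 Hz bin -> HF
    hf = integrate(*HF_BAND, hi_inclusive=True)
    hfnorm = float("nan") if lf + hf == 0 else hf / (lf + hf) * 100.0
    return SpectralBands(tp=tp, lf=lf, hf=hf, hfnorm=hfnorm)


def average_band_powers(bands: list[SpectralBands]) -> SpectralBands:
    """Field-wise arithmetic mean over segments (HFnorm averaged as values)."""
    if not bands:
        raise ValueError("cannot average an empty list of band powers")
    return SpectralBands(
        tp=float(np.mean([b.tp for b in bands])),
        lf=float(np.mean([b.lf for b in bands])),
        hf=float(np.mean([b.hf for b in bands])),
        hfnorm=float(np.mean([b.hfnorm for b in bands])),
    )


def sdnn(rr: RRIntervalSeries) -> float:
    """Sample standard deviation (n-1 denominator) of all RR intervals, ms."""
    if len(rr) < 2:
        raise ValueError("need at least 2 beats for SDNN")
    return float(np.std(rr.rr, ddof=1))


def rmssd(rr: RRIntervalSeries) -> float:
    """Root mean square of successive RR differences, ms."""
    if len(rr) < 2:
        raise ValueError("need at least 2 beats for RMSSD")
    return float(np.sqrt(np.mean(np.diff(rr.rr) ** 2)))


def linear_metrics(rr: RRIntervalSeries, segment_length: float = 300.0) -> dict[str, float]:
    """TP/LF/HF/HFnorm averaged over segments plus whole-series SDNN/RMSSD."""
    bands = average_band_powers([band_powers(s) for s in segment_rr(rr, segment_length)])
    td = TimeDomainMetrics(sdnn=sdnn(rr), rmssd=rmssd(rr))
    return {
        "tp": bands.tp, "lf": bands.lf, "hf": bands.hf, "hfnorm": bands.hfnorm,
        "sdnn": td.sdnn, "rmssd": td.rmssd,
    }
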