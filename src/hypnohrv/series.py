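"""Core signal containers shared by every pipeline stage.

The central object is :class:`RRIntervalSeries`: an ordered series of
RR intervals in milliseconds together with a boolean artifact mask and an
``origin`` annotation recording whether the values were measured from an
ECG, corrected by interpolation, or generated synthetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ECGSignal", "RPeakSeries", "RRIntervalSeries"]

_ORIGINS = ("measured", "corrected", "synthetic")


@dataclass
class ECGSignal:
    """Single-channel ECG: sample values (mV), sampling rate (Hz), start time (s)."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("ECG samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs


@dataclass
class RPeakSeries:
    """Detected R-wave peak positions as sample indices, strictly increasing."""

    peak_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.peak_indices) > 1 and not np.all(np.diff(self.peak_indices) > 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_indices)


@dataclass
class RRIntervalSeries:
    """Ordered RR intervals (ms) with an artifact mask of equal length.

    Parameters
    ----------
    rr : array-like
        RR intervals in milliseconds; all values must be strictly positive.
    artifact_mask : array-like of bool, optional
        True where a beat is flagged as artifact/ectopic.  Defaults to all
        False (no beats flagged).
    origin : {"measured", "corrected", "synthetic"}
        Provenance of the interval values.
    """

    rr: np.ndarray
    artifact_mask: np.ndarray | None = None
    origin: str = "measured"

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1:
            raise ValueError("rr must be one-dimensional")
        if len(self.rr) and not np.all(self.rr > 0):
            raise ValueError("RR intervals must be strictly positive")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(len(self.rr), dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if len(self.artifact_mask) != len(self.rr):
            raise ValueError("artifact mask length must equal rr length")
        if self.origin not in _ORIGINS:
            raise ValueError(f"origin must be one of {_ORIGINS}, got {self.origin!r}")

    def __len__(self) -> int:
        return len(self.rr)

    @property
    def end_times(self) -> np.ndarray:
        """Cumulative time (s) at the *end* of each interval, from recording start."""
        return np.cumsum(self.rr) / 1000.0

    @property
    def start_times(self) -> np.ndarray:
        """Cumulative time (s) at the start of each interval."""
        t = np.cumsum(self.rr) / 1000.0
        return t - self.rr / 1000.0

    @property
    def duration(self) -> float:
        """Total duration covered by the intervals, in seconds."""
        return float(np.sum(self.rr)) / 1000.0

    @property
    def artifact_fraction(self) -> float:
        return float(np.mean(self.artifact_mask)) if len(self.rr) else 0.0

    def replace(self, **kwargs) -> "RRIntervalSeries":
        """Return a copy with selected fields replaced (arrays are copied)."""
        data = {
            "rr": self.rr.copy(),
            "artifact_mask": self.artifact_mask.copy(),
            "origin": self.origin,
        }
        data.update(kwargs)
        return RRIntervalSeries(**data)
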