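"""Nonlinear complexity metrics for RR-interval series.

Implements the three entropy-based measures used to characterise
hypnopompic heart-rate dynamics:

* **Sample entropy** (SampEn): the negative log of the conditional
  probability that two sequences matching for ``m`` points (Chebyshev
  distance at most ``r``, self-matches excluded) also match for ``m + 1``
  points.  Lower values mean more regularity.
* **Multiscale sample entropy** (MSE): SampEn evaluated on coarse-grained
  (non-overlapping window-averaged) versions of the series at scale
  factors 1..10, denoted MSE1..MSE10.  The tolerance ``r`` is fixed from
  the *original* (scale-1) series and reused at every scale.
* **Modified permutation entropy** (MPE): the Shannon entropy of ordinal
  patterns of length-``m`` embedded vectors in which *equal values receive
  equal rank symbols*.  Unlike the classic permutation entropy, MPE does
  not break ties arbitrarily, which matters for RR series quantised by a
  finite ECG sampling rate.  For ``m = 4`` there are 75 tied-rank
  patterns (the ordered set partitions of four items), so
  ``0 <= MPE <= log2(75)`` in bits.

Degenerate entropies (no template matches) are returned as ``nan`` rather
than infinity so downstream feature tables stay finite; callers drop such
subjects explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "EntropyParams",
    "EntropyProfile",
    "coarse_grain",
    "sample_entropy",
    "mse_profile",
    "modified_permutation_entropy",
]


@dataclass
class EntropyParams:
    """Parameters of the entropy analysis.

    ``r_coeff`` scales the SampEn tolerance: ``r = r_coeff * SD`` where SD
    is the sample standard deviation of the original series.  ``m`` is the
    SampEn embedding dimension, ``max_scale`` the largest coarse-graining
    factor, and ``mpe_m`` the MPE embedding dimension.
    """

    m: int = 2
    r_coeff: float = 0.15
    max_scale: int = 10
    mpe_m: int = 4

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r_coeff < 0:
            raise ValueError("r_coeff must be >= 0")
        if self.max_scale < 1:
            raise ValueError("max_scale must be >= 1")
        if self.mpe_m < 2:
            raise ValueError("mpe_m must be >= 2")


@dataclass
class EntropyProfile:
    """MSE1..MSEmax values (nan where undefined) plus MPE for one series."""

    mse: np.ndarray
    mpe: float

    def as_dict(self) -> dict[str, float]:
        out = {f"mse{i + 1}": float(v) for i, v in enumerate(self.mse)}
        out["mpe"] = float(self.mpe)
        return out


def _as_array(series) -> np.ndarray:
    rr = getattr(series, "rr", series)
    x = np.asarray(rr, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    return x


def coarse_grain(series, scale: int) -> np.ndarray:
    """Average consecutive non-overlapping windows of ``scale`` points.

    Returns a series of length ``floor(N / scale)``; a trailing partial
    window is discarded.  ``scale=1`` is the identity.
    """
    x = _as_array(series)
    scale = int(scale)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    n = len(x) // scale
    if n == 0:
        raise ValueError(f"series of length {len(x)} too short for scale {scale}")
    return x[: n * scale].reshape(n, scale).mean(axis=1)


@njit(cache=False)
def _match_counts(x, m, r):  # pragma: no cover - exercised via sample_entropy
    """Count template pairs matching at length m (B) and m+1 (A).

    Pairs are drawn with i < j from the N - m templates that admit an
    (m+1)-point extension; Chebyshev distance, inclusive tolerance.
    """
    n = x.shape[0]
    b = 0
    a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return b, a


def sample_entropy(series, m: int = 2, r: float | None = None,
                   r_coeff: float = 0.15) -> float:
    """Sample entropy ``-ln(A/B)`` of a series.

    Parameters
    ----------
    series : array-like or RRIntervalSeries
    m : int
        Embedding dimension.
    r : float, optional
        Absolute tolerance (same units as the series).  If omitted it is
        derived as ``r_coeff * SD`` of this series.
    r_coeff : float
        Tolerance coefficient used when ``r`` is not given.

    Returns
    -------
    float
        ``-ln(A/B)``; ``nan`` when no length-``m`` or length-``m+1``
        template pairs match (entropy undefined).
    """
    x = _as_array(series)
    if len(x) <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} points, got {len(x)}")
    if r is None:
        r = r_coeff * float(np.std(x, ddof=1))
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    b, a = _match_counts(np.ascontiguousarray(x), m, float(r))
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_profile(series, params: EntropyParams | None = None) -> np.ndarray:
    """Multiscale sample entropy at scales ``1..params.max_scale``.

    The tolerance ``r = r_coeff * SD`` is computed once from the original
    series and reused for every coarse-grained scale (no per-scale
    renormalisation).  Scales whose coarse-grained series is too short or
    has no matches yield ``nan``.
    """
    params = params or EntropyParams()
    x = _as_array(series)
    if len(x) // params.max_scale <= params.m + 1:
        raise ValueError(
            f"series of length {len(x)} too short for scale {params.max_scale} "
            f"with m={params.m}"
        )
    r = params.r_coeff * float(np.std(x, ddof=1))
    out = np.empty(params.max_scale)
    for tau in range(1, params.max_scale + 1):
        cg = coarse_grain(x, tau)
        out[tau - 1] = sample_entropy(cg, m=params.m, r=r)
    return out


def _tied_rank_patterns(emb: np.ndarray) -> np.ndarray:
    """Map each embedded row to an integer tied-rank pattern code.

    The rank of element j within its row is the count of strictly smaller
    elements in that row, so equal values share a rank symbol.
    """
    m = emb.shape[1]
    ranks = (emb[:, None, :] < emb[:, :, None]).sum(axis=2)
    return ranks @ (m ** np.arange(m, dtype=np.int64))


def modified_permutation_entropy(series, m: int = 4) -> float:
    """Tied-rank (modified) permutation entropy in bits.

    The series is embedded with delay 1 into overlapping vectors of length
    ``m``; each vector is mapped to its tied-rank ordinal pattern and the
    Shannon entropy (base 2) of the empirical pattern distribution is
    returned.  A strictly monotone or constant series has a single pattern
    and entropy 0; a long i.i.d. continuous series approaches
    ``log2(m!)`` since ties then have probability zero.
    """
    x = _as_array(series)
    if m < 2:
        raise ValueError("embedding dimension m must be >= 2")
    if len(x) < m:
        raise ValueError(f"need at least m={m} points, got {len(x)}")
    emb = sliding_window_view(x, m)
    codes = _tied_rank_patterns(emb)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_profile(series, params: EntropyParams | None = None) -> EntropyProfile:
    """Full complexity profile (MSE1..MSEmax and MPE) for one RR series."""
    params = params or EntropyParams()
    return EntropyProfile(
        mse=mse_profile(series, params),
        mpe=modified_permutation_entropy(series, m=params.mpe_m),
    )
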