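"""Time-domain features computed per channel.

Basic signal statistics, Hjorth parameters, the non-stationary index (NSI),
the Higuchi fractal dimension, and higher-order crossings (HOC).  All
operate on a single 1-D signal vector; the feature bank in
:mod:`emosda.pipeline` applies them channel by channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TimeStats:
    """Power, mean, std, (normalized) first and second absolute differences.

    ``power`` is the mean squared amplitude (units^2); the differences are
    mean absolute forward differences at lags 1 and 2, and the normalized
    variants divide by the sample standard deviation (defined as 0 when the
    standard deviation vanishes).
    """

    power: float
    mean: float
    std: float
    first_diff: float
    norm_first_diff: float
    second_diff: float
    norm_second_diff: float


@dataclass
class HjorthParams:
    activity: float      # biased variance, units^2
    mobility: float      # dimensionless
    complexity: float    # dimensionless


@dataclass
class NSIResult:
    value: float
    n_segments: int
    local_means: np.ndarray


@dataclass
class FDResult:
    dimension: float
    kmax: int
    curve_lengths: np.ndarray   # <L(k)> for k = 1..kmax


@dataclass
class HOCSequence:
    counts: np.ndarray          # D_k for k = 1..max_order


def time_stats(x: np.ndarray) -> TimeStats:
    """Basic statistics of a signal vector (length T >= 3)."""
    x = np.asarray(x, dtype=np.float64)
    T = x.size
    if T < 3:
        raise ValueError("need at least 3 samples")
    power = float(np.mean(x ** 2))
    mean = float(np.mean(x))
    # the standard deviation uses the T-1 denominator
    std = float(np.sqrt(np.sum((x - mean) ** 2) / (T - 1)))
    d1 = float(np.sum(np.abs(np.diff(x))) / (T - 1))
    d2 = float(np.sum(np.abs(x[2:] - x[:-2])) / (T - 2))
    nd1 = d1 / std if std > 0 else 0.0
    nd2 = d2 / std if std > 0 else 0.0
    return TimeStats(power=power, mean=mean, std=std, first_diff=d1,
                     norm_first_diff=nd1, second_diff=d2,
                     norm_second_diff=nd2)


def hjorth(x: np.ndarray) -> HjorthParams:
    """Hjorth activity, mobility and complexity.

    The derivative is the first forward difference.  Activity is the biased
    (1/T) variance; mobility is sqrt(var(dx)/var(x)); complexity is
    mobility(dx)/mobility(x).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    var_x = float(np.var(x))
    if var_x == 0.0:
        raise ValueError("degenerate signal: zero variance")
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_dx = float(np.var(dx))
    var_ddx = float(np.var(ddx))
    mobility = float(np.sqrt(var_dx / var_x))
    if var_dx == 0.0:
        raise ValueError("degenerate signal: zero derivative variance")
    mobility_dx = float(np.sqrt(var_ddx / var_dx))
    return HjorthParams(activity=var_x, mobility=mobility,
                        complexity=mobility_dx / mobility)


def nsi(x: np.ndarray, n_segments: int = 32) -> NSIResult:
    """Non-stationary index: variance of segment-wise local means.

    The signal is z-normalized first, split into ``n_segments`` equal parts
    (the tail beyond an even division is truncated), and the index is the
    variance of the per-segment means.
    """
    x = np.asarray(x, dtype=np.float64)
    if n_segments < 2:
        raise ValueError("n_segments must be at least 2")
    if x.size < n_segments:
        raise ValueError("signal shorter than n_segments")
    std = x.std()
    z = (x - x.mean()) / std if std > 0 else np.zeros_like(x)
    seg = x.size // n_segments
    local = z[: seg * n_segments].reshape(n_segments, seg).mean(axis=1)
    return NSIResult(value=float(np.var(local)), n_segments=n_segments,
                     local_means=local)


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> FDResult:
    """Higuchi fractal dimension.

    For each interval k = 1..kmax and offset m = 1..k, the curve length of
    the subsampled sequence x(m), x(m+k), ... is

        L_m(k) = (T-1) / (k^2 * floor((T-m)/k)) * sum_i |x(m+ik) - x(m+(i-1)k)|

    and <L(k)> is the mean over m.  The dimension is the negative slope of
    the least-squares line of ln<L(k)> on ln k, clipped to [1, 2].  The
    estimate is exactly invariant to affine changes a*x + b of the signal.
    """
    x = np.asarray(x, dtype=np.float64)
    T = x.size
    if kmax < 2:
        raise ValueError("kmax must be at least 2")
    if T < 2 * kmax:
        raise ValueError("kmax too large for signal length")
    Lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(1, k + 1):
            n_i = (T - m) // k
            if n_i < 1:
                continue
            idx = m - 1 + np.arange(n_i + 1) * k
            diff_sum = np.sum(np.abs(np.diff(x[idx])))
            norm = (T - 1) / (k * k * n_i)
            lengths.append(norm * diff_sum)
        Lk[k - 1] = np.mean(lengths)
    k_arr = np.arange(1, kmax + 1, dtype=np.float64)
    valid = Lk > 0
    if valid.sum() < 2:
        # flat (constant) signal: no scaling information
        return FDResult(dimension=1.0, kmax=kmax, curve_lengths=Lk)
    slope = np.polyfit(np.log(k_arr[valid]), np.log(Lk[valid]), 1)[0]
    dim = float(np.clip(-slope, 1.0, 2.0))
    return FDResult(dimension=dim, kmax=kmax, curve_lengths=Lk)


def hoc_features(x: np.ndarray, max_order: int = 10) -> HOCSequence:
    """Higher-order crossings: zero-crossing counts after repeated
    backward differencing.

    The signal is demeaned; D_k is the number of strict sign changes of the
    (k-1)-times differenced series, with exact zeros removed before
    counting, for k = 1..max_order.
    """
    x = np.asarray(x, dtype=np.float64)
    if max_order < 1:
        raise ValueError("max_order must be at least 1")
    if x.size <= max_order:
        raise ValueError("signal too short for max_order")
    y = x - x.mean()
    counts = np.empty(max_order, dtype=np.int64)
    for k in range(max_order):
        nz = y[y != 0]
        if nz.size < 2:
            counts[k] = 0
        else:
            counts[k] = int(np.sum(np.sign(nz[1:]) != np.sign(nz[:-1])))
        y = np.diff(y)
    return HOCSequence(counts=counts)
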