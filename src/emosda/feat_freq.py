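"""Frequency-domain features.

Welch power spectral density, the power-law (1/f) exponent, short-time
band-power statistics, the bispectrum (indirect, cumulant-based estimate)
and its four scalar summaries, magnitude-squared coherence between
electrode pairs, and differential/rational band-power asymmetry over the
14 symmetric electrode pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from emosda import montage
from emosda.synthio import TrialRecording

NFFT = 853          # Welch FFT / window length
NOVERLAP = 426      # half-window overlap
BISPEC_SEGMENTS = 30
BISPEC_SEGLEN = 128
BISPEC_MAXLAG = 63


@dataclass
class PSDEstimate:
    freqs: np.ndarray
    power: np.ndarray
    nfft: int = NFFT
    overlap: int = NOVERLAP
    window: str = "hamming"


@dataclass
class PowerLawResult:
    eta: float
    fit_range: tuple[float, float]
    r_squared: float


@dataclass
class BandPowerFeatures:
    """14 values per channel: per band log mean/max/min short-time power,
    the power variance across bands, and the beta/alpha power ratio."""

    log_avg_power: dict[str, float]
    log_max_power: dict[str, float]
    log_min_power: dict[str, float]
    power_variance: float
    ratio_beta_alpha: float
    band_avg_power: dict[str, float] = field(default_factory=dict)

    def as_vector(self) -> tuple[list[float], list[str]]:
        vals, names = [], []
        for b in montage.BAND_ORDER:
            for stat, d in (("logavg", self.log_avg_power),
                            ("logmax", self.log_max_power),
                            ("logmin", self.log_min_power)):
                vals.append(d[b])
                names.append(f"bp.{b}.{stat}")
        vals += [self.power_variance, self.ratio_beta_alpha]
        names += ["bp.variance", "bp.ratio_beta_alpha"]
        return vals, names


@dataclass
class BispectrumEstimate:
    B: np.ndarray               # 128 x 128 complex, fftshifted grid
    freqs: np.ndarray           # Hz per axis (fftshifted)
    principal_region: np.ndarray  # boolean mask over B
    n_segments: int = BISPEC_SEGMENTS
    segment_len: int = BISPEC_SEGLEN


@dataclass
class BispectralSummaries:
    be1: float
    be2: float
    mmob: float
    fosm: float
    pn: np.ndarray
    qn: np.ndarray


@dataclass
class CoherenceEstimate:
    pairs: list[tuple[int, int]]
    band_coherence: np.ndarray   # (n_pairs, 4) mean coherence per band
    freqs: np.ndarray
    coherence: np.ndarray        # (n_pairs, n_freqs) full curves


@dataclass
class AsymmetryFeatures:
    pairs: list[tuple[int, int]]
    dasm: np.ndarray   # (n_pairs, 4) left - right band power
    rasm: np.ndarray   # (n_pairs, 4) left / right band power (NaN if xr = 0)


def welch_psd(x: np.ndarray, fs: float = float(montage.FS)) -> PSDEstimate:
    """Welch's averaged modified periodogram.

    853-point Hamming window with 426-sample overlap; density scaling so
    that sum(power) * df approximates the signal power.  A 3840-sample
    input yields 7 averaged segments.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < NFFT:
        raise ValueError(f"need at least {NFFT} samples")
    freqs, power = sps.welch(x, fs=fs, window="hamming", nperseg=NFFT,
                             noverlap=NOVERLAP, nfft=NFFT, detrend=False,
                             scaling="density")
    return PSDEstimate(freqs=freqs, power=power)


def power_law_index(psd: PSDEstimate,
                    fit_range: tuple[float, float] = (3.0, 47.0)) -> PowerLawResult:
    """Exponent eta of P(f) ~ f^-eta by least squares on the log-log PSD.

    Only strictly positive power bins inside ``fit_range`` enter the fit;
    at least 5 must remain.
    """
    f, p = psd.freqs, psd.power
    keep = (f >= fit_range[0]) & (f <= fit_range[1]) & (p > 0)
    if keep.sum() < 5:
        raise ValueError("fewer than 5 usable bins in fit range")
    lx, ly = np.log10(f[keep]), np.log10(p[keep])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else 1.0
    return PowerLawResult(eta=float(-slope), fit_range=fit_range,
                          r_squared=max(0.0, min(1.0, r2)))


def _stft_band_powers(x: np.ndarray, fs: float) -> np.ndarray:
    """Per-frame band powers from a 1000 ms Hamming STFT with no overlap.

    Returns an array (n_frames, 4) of summed squared spectral magnitudes
    per band (band energy), frames of 128 samples.
    """
    frame_len = int(fs)  # 1000 ms
    n_frames = x.size // frame_len
    if n_frames < 1:
        raise ValueError("signal shorter than one 1000 ms frame")
    w = np.hamming(frame_len)
    frames = x[: n_frames * frame_len].reshape(n_frames, frame_len) * w
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    freqs = np.fft.rfftfreq(frame_len, d=1.0 / fs)
    out = np.empty((n_frames, len(montage.BAND_ORDER)))
    for j, b in enumerate(montage.BAND_ORDER):
        lo, hi = montage.BANDS[b]
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {b} empty at fs={fs}")
        out[:, j] = spec[:, sel].sum(axis=1)
    return out


def band_power_features(x: np.ndarray, fs: float = float(montage.FS)) -> BandPowerFeatures:
    """Short-time band-power statistics (natural log).

    Per band: ln of the average, maximum and minimum per-frame band power;
    across bands: the variance of the four average band powers and the
    ratio of the average beta power over the average alpha power.
    """
    x = np.asarray(x, dtype=np.float64)
    bp = _stft_band_powers(x, fs)           # (n_frames, 4)
    avg = bp.mean(axis=0)
    eps = np.finfo(float).tiny
    log_avg, log_max, log_min = {}, {}, {}
    band_avg = {}
    for j, b in enumerate(montage.BAND_ORDER):
        log_avg[b] = float(np.log(avg[j] + eps))
        log_max[b] = float(np.log(bp[:, j].max() + eps))
        log_min[b] = float(np.log(bp[:, j].min() + eps))
        band_avg[b] = float(avg[j])
    ratio = float(avg[2] / avg[1]) if avg[1] > 0 else np.nan
    return BandPowerFeatures(log_avg_power=log_avg, log_max_power=log_max,
                             log_min_power=log_min,
                             power_variance=float(np.var(avg)),
                             ratio_beta_alpha=ratio, band_avg_power=band_avg)


# ---------------------------------------------------------------------------
# bispectrum (indirect / cumulant method)

def _third_order_cumulants(seg: np.ndarray, maxlag: int) -> np.ndarray:
    """C3(k, l) = 1/M sum_n x(n) x(n+k) x(n+l) for |k|,|l| <= maxlag.

    The segment is demeaned; out-of-range samples are treated as zero
    (biased estimate).  Returns a (2*maxlag+1)^2 matrix, symmetric in (k,l).
    """
    x = seg - seg.mean()
    M = x.size
    n_lags = 2 * maxlag + 1
    # S[i] = x shifted by lag (i - maxlag), zero-padded
    S = np.zeros((n_lags, M))
    for i, lag in enumerate(range(-maxlag, maxlag + 1)):
        if lag >= 0:
            S[i, : M - lag] = x[lag:]
        else:
            S[i, -lag:] = x[: M + lag]
    return (S * x[None, :]) @ S.T / M


def _rao_gabr_window(maxlag: int) -> np.ndarray:
    """Optimum (Rao-Gabr) lag window over the cumulant support."""
    n_lags = 2 * maxlag + 1
    k = np.arange(-maxlag, maxlag + 1)
    K, L = np.meshgrid(k, k, indexing="ij")
    w = np.zeros((n_lags, n_lags))
    inside = (np.abs(K) <= maxlag) & (np.abs(L) <= maxlag) & (np.abs(K - L) <= maxlag)
    r = (K ** 2 + L ** 2 - K * L) / float(maxlag ** 2)
    w[inside] = np.maximum(0.0, 1.0 - r[inside])
    return w


def bispectrum_estimate(x: np.ndarray, fs: float = float(montage.FS),
                        lag_window: str = "uniform") -> BispectrumEstimate:
    """Indirect bispectrum estimate on 30 non-overlapping 128-sample slices.

    Per demeaned segment the third-order cumulants C3(k, l) are computed for
    lags up to +/-63, averaged over segments, optionally tapered by a lag
    window ('uniform' or 'rao_gabr'), and transformed by a 2-D 128-point
    FFT with quadrant shifting for proper orientation.
    """
    x = np.asarray(x, dtype=np.float64)
    need = BISPEC_SEGMENTS * BISPEC_SEGLEN
    if x.size < need:
        raise ValueError(f"need at least {need} samples")
    segs = x[:need].reshape(BISPEC_SEGMENTS, BISPEC_SEGLEN)
    c3 = np.zeros((2 * BISPEC_MAXLAG + 1,) * 2)
    for seg in segs:
        c3 += _third_order_cumulants(seg, BISPEC_MAXLAG)
    c3 /= BISPEC_SEGMENTS
    if lag_window == "rao_gabr":
        c3 = c3 * _rao_gabr_window(BISPEC_MAXLAG)
    elif lag_window != "uniform":
        raise ValueError(f"unknown lag window {lag_window!r}")
    # embed lags into the 128-point FFT grid: index = lag mod 128
    n = BISPEC_SEGLEN
    grid = np.zeros((n, n))
    lags = np.arange(-BISPEC_MAXLAG, BISPEC_MAXLAG + 1)
    grid[np.ix_(lags % n, lags % n)] = c3
    B = np.fft.fftshift(np.fft.fft2(grid))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / fs))
    F1, F2 = np.meshgrid(freqs, freqs, indexing="ij")
    omega = (F2 >= 0) & (F2 <= F1) & (F1 + F2 <= fs / 2.0)
    return BispectrumEstimate(B=B, freqs=freqs, principal_region=omega)


def bispectral_summaries(bisp: BispectrumEstimate) -> BispectralSummaries:
    """The four scalar bispectral features.

    BE1 / BE2 are the entropies (natural log) of the bispectral magnitude
    and squared-magnitude distributions normalized over the principal
    region Omega; MMOB is the mean magnitude over Omega; FOSM is the sum of
    log magnitudes over the whole matrix, skipping exact zeros.
    """
    mag = np.abs(bisp.B)
    if not bisp.principal_region.any():
        raise ValueError("empty principal region")
    m = mag[bisp.principal_region]
    tot = m.sum()
    if tot == 0 or mag.max() == 0:
        raise ValueError("degenerate all-zero bispectrum")
    pn = m / tot
    qn = m ** 2 / np.sum(m ** 2)
    def _entropy(p: np.ndarray) -> float:
        nz = p[p > 0]
        return float(-np.sum(nz * np.log(nz)))
    nz_all = mag[mag > 0]
    return BispectralSummaries(be1=_entropy(pn), be2=_entropy(qn),
                               mmob=float(m.mean()),
                               fosm=float(np.sum(np.log(nz_all))),
                               pn=pn, qn=qn)


# ---------------------------------------------------------------------------
# coherence and asymmetry over electrode pairs

def msce_features(trial: TrialRecording,
                  pairs: list[tuple[int, int]] | None = None) -> CoherenceEstimate:
    """Magnitude-squared coherence per electrode pair, averaged per band.

    Uses the same Welch parameters as :func:`welch_psd`.  With the default
    14 symmetric pairs this yields 14 x 4 = 56 features.
    """
    if pairs is None:
        pairs = montage.symmetric_pair_indices()
    curves = []
    band_means = np.empty((len(pairs), len(montage.BAND_ORDER)))
    freqs = None
    for r, (i, j) in enumerate(pairs):
        if i == j:
            raise ValueError(f"pair ({i}, {j}) uses one channel twice")
        freqs, cxy = sps.coherence(trial.signal[i], trial.signal[j], fs=trial.fs,
                                   window="hamming", nperseg=NFFT,
                                   noverlap=NOVERLAP, nfft=NFFT, detrend=False)
        cxy = np.clip(cxy, 0.0, 1.0)
        curves.append(cxy)
        for b_idx, b in enumerate(montage.BAND_ORDER):
            lo, hi = montage.BANDS[b]
            sel = (freqs >= lo) & (freqs <= hi)
            band_means[r, b_idx] = cxy[sel].mean()
    return CoherenceEstimate(pairs=list(pairs), band_coherence=band_means,
                             freqs=freqs, coherence=np.array(curves))


def asymmetry_features(trial: TrialRecording,
                       pairs: list[tuple[int, int]] | None = None) -> AsymmetryFeatures:
    """Differential and rational band-power asymmetry per symmetric pair.

    Band powers are the per-band averages from :func:`band_power_features`.
    A zero right-channel band power makes the corresponding rational value
    missing (NaN).
    """
    if pairs is None:
        pairs = montage.symmetric_pair_indices()
    n_pairs = len(pairs)
    dasm = np.empty((n_pairs, 4))
    rasm = np.empty((n_pairs, 4))
    cache: dict[int, np.ndarray] = {}

    def _avg(ch: int) -> np.ndarray:
        if ch not in cache:
            bp = band_power_features(trial.signal[ch], fs=trial.fs)
            cache[ch] = np.array([bp.band_avg_power[b] for b in montage.BAND_ORDER])
        return cache[ch]

    for r, (l, rr) in enumerate(pairs):
        xl, xr = _avg(l), _avg(rr)
        dasm[r] = xl - xr
        with np.errstate(divide="ignore", invalid="ignore"):
            rasm[r] = np.where(xr > 0, xl / xr, np.nan)
    return AsymmetryFeatures(pairs=list(pairs), dasm=dasm, rasm=rasm)
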