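"""Time-frequency features: empirical mode decomposition with the
Hilbert-Huang spectrum, and db4 discrete-wavelet features.

The EMD here follows a segment-wise sifting procedure: within each
fixed-length block one local maximum and one local minimum anchor the
cubic-spline upper/lower envelopes (a standard all-local-extrema mode is
available behind ``extrema_mode='local'``).  Sifting repeats until the
normalized squared change between iterations falls below the stopping
threshold; outer extraction stops once the mean residue is small enough or
the IMF budget is exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from emosda import montage

#: Wavelet sub-band -> EEG band mapping for db4 at fs = 128 Hz
#: (D4: 4-8 Hz ~ theta, D3: 8-16 ~ alpha, D2: 16-32 ~ beta, D1: 32-64 ~ gamma).
DWT_BAND_LEVELS: tuple[tuple[str, str], ...] = (
    ("theta", "D4"), ("alpha", "D3"), ("beta", "D2"), ("gamma", "D1"),
)


@dataclass
class EMDConfig:
    seg_len: int = 128
    residue_threshold: float = 1e-3
    sd_threshold: float = 0.25
    max_imfs: int = 10
    max_sift_iters: int = 200
    extrema_mode: str = "segment"   # 'segment' (one max/min per block) or 'local'

    def __post_init__(self) -> None:
        if self.seg_len < 4:
            raise ValueError("seg_len must be at least 4")
        if not 0 < self.sd_threshold < 1:
            raise ValueError("sd_threshold must be in (0, 1)")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be at least 1")


@dataclass
class IMFSet:
    imfs: list[np.ndarray]
    residue: np.ndarray
    converged: bool = True

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.imfs, axis=0) + self.residue


@dataclass
class HHSpectrum:
    energy: np.ndarray       # (n_imfs, T) instantaneous energy, units^2
    frequency: np.ndarray    # (n_imfs, T) instantaneous frequency, Hz
    band_energy: dict[str, float]


@dataclass
class WaveletDecomp:
    coefficients: dict[str, np.ndarray]   # A4, D4, D3, D2, D1
    entropy: dict[str, float]             # per EEG band
    rms: dict[str, float]
    abs_log_ree: dict[str, float]
    ree: dict[str, float]                 # REE per sub-band (all five, sums to 1)


# ---------------------------------------------------------------------------
# EMD

def _segment_extrema(x: np.ndarray, seg_len: int) -> tuple[np.ndarray, np.ndarray]:
    """One max and one min index per fixed-length block."""
    n_seg = x.size // seg_len
    max_idx, min_idx = [], []
    for j in range(n_seg):
        seg = x[j * seg_len:(j + 1) * seg_len]
        max_idx.append(j * seg_len + int(np.argmax(seg)))
        min_idx.append(j * seg_len + int(np.argmin(seg)))
    return np.array(max_idx), np.array(min_idx)


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    max_idx = np.where((np.hstack([d, [-1.0]]) < 0) & (np.hstack([[1.0], d]) > 0))[0]
    min_idx = np.where((np.hstack([d, [1.0]]) > 0) & (np.hstack([[-1.0], d]) < 0))[0]
    return max_idx, min_idx


def _envelope(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through (idx, vals), mirror-extended at the ends
    to tame boundary divergence."""
    if idx.size < 2:
        return np.full(n, vals[0] if vals.size else 0.0)
    # mirror the two outermost anchor points across each boundary
    ext_i = np.concatenate([[2 * idx[0] - idx[1]], idx, [2 * idx[-1] - idx[-2]]])
    ext_v = np.concatenate([[vals[1]], vals, [vals[-2]]])
    order = np.argsort(ext_i)
    ext_i, ext_v = ext_i[order], ext_v[order]
    keep = np.concatenate([[True], np.diff(ext_i) > 0])
    spline = CubicSpline(ext_i[keep], ext_v[keep])
    return spline(np.arange(n))


def emd_decompose(x: np.ndarray, cfg: EMDConfig | None = None) -> IMFSet:
    """Sift a signal into intrinsic mode functions plus a residue.

    Completeness holds by construction: the residue is the input minus the
    sum of extracted IMFs, so sum(imfs) + residue reconstructs the input
    exactly (up to float round-off).
    """
    cfg = cfg or EMDConfig()
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2 * cfg.seg_len and cfg.extrema_mode == "segment":
        raise ValueError("signal must span at least two segments")
    imfs: list[np.ndarray] = []
    converged = True
    for _ in range(cfg.max_imfs):
        xi = x - (np.sum(imfs, axis=0) if imfs else 0.0)
        # residue criterion on the mean absolute residue: a scalar mean
        # would stop immediately on any zero-mean signal
        if float(np.mean(np.abs(xi))) < cfg.residue_threshold and imfs:
            break
        h = xi.copy()
        ok = False
        for _ in range(cfg.max_sift_iters):
            if cfg.extrema_mode == "segment":
                max_idx, min_idx = _segment_extrema(h, cfg.seg_len)
            else:
                max_idx, min_idx = _local_extrema(h)
            if max_idx.size < 2 or min_idx.size < 2:
                break
            upper = _envelope(max_idx, h[max_idx], n)
            lower = _envelope(min_idx, h[min_idx], n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.sum(h ** 2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < cfg.sd_threshold:
                ok = True
                break
        if not ok and max_idx.size >= 2 and min_idx.size >= 2:
            converged = False
            warnings.warn("sifting hit the iteration cap; keeping current IMF",
                          RuntimeWarning, stacklevel=2)
        if max_idx.size < 2 or min_idx.size < 2:
            break  # residue is monotone-ish: stop extracting
        imfs.append(h)
    if not imfs:
        imfs = [x - x.mean() if n else x]
    residue = x - np.sum(imfs, axis=0)
    return IMFSet(imfs=imfs, residue=residue, converged=converged)


# ---------------------------------------------------------------------------
# Hilbert-Huang spectrum

def hilbert_spectrum(imfs: IMFSet, fs: float = float(montage.FS)) -> HHSpectrum:
    """Instantaneous energy and frequency per IMF via the analytic signal.

    Energy is |z(t)|^2; instantaneous frequency is the unwrapped phase
    difference scaled by fs / (2 pi), clipped to [0, fs/2].  The band
    energies average the energy of all (IMF, sample) points whose
    instantaneous frequency falls inside each band, normalized by the
    signal length.
    """
    if not imfs.imfs:
        raise ValueError("need at least one IMF")
    T = imfs.imfs[0].size
    n = len(imfs.imfs)
    energy = np.empty((n, T))
    freq = np.empty((n, T))
    for i, imf in enumerate(imfs.imfs):
        z = hilbert(imf)
        energy[i] = np.abs(z) ** 2
        phase = np.unwrap(np.angle(z))
        inst = np.diff(phase) * fs / (2.0 * np.pi)
        inst = np.concatenate([inst, inst[-1:]])
        freq[i] = np.clip(inst, 0.0, fs / 2.0)
    band_energy: dict[str, float] = {}
    for b in montage.BAND_ORDER:
        lo, hi = montage.BANDS[b]
        sel = (freq >= lo) & (freq <= hi)
        band_energy[b] = float(energy[sel].sum() / T)
    return HHSpectrum(energy=energy, frequency=freq, band_energy=band_energy)


# ---------------------------------------------------------------------------
# discrete wavelet transform

def dwt_features(x: np.ndarray) -> WaveletDecomp:
    """4-level db4 decomposition with per-band entropy, RMS, and |ln REE|.

    Sub-bands A4, D4, D3, D2, D1 partition the spectrum; REE is each
    sub-band's share of the total coefficient energy (the five shares sum
    to 1).  Per EEG band (theta=D4 ... gamma=D1): the Shannon entropy
    (natural log) of the normalized squared coefficients, the RMS of the
    coefficients, and |ln REE|.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 16:
        raise ValueError("need at least 16 samples")
    if not np.any(x):
        raise ValueError("degenerate all-zero signal")
    coeffs = pywt.wavedec(x, "db4", level=4, mode="zero")
    names = ["A4", "D4", "D3", "D2", "D1"]
    cmap = dict(zip(names, coeffs))
    energies = {k: float(np.sum(v ** 2)) for k, v in cmap.items()}
    total = sum(energies.values())
    ree = {k: e / total for k, e in energies.items()}
    entropy, rms, alr = {}, {}, {}
    for band, level in DWT_BAND_LEVELS:
        c = cmap[level]
        e = energies[level]
        if e > 0:
            p = c ** 2 / e
            nz = p[p > 0]
            entropy[band] = float(-np.sum(nz * np.log(nz)))
        else:
            entropy[band] = 0.0
        rms[band] = float(np.sqrt(np.mean(c ** 2)))
        alr[band] = float(abs(np.log(ree[level]))) if ree[level] > 0 else np.inf
    return WaveletDecomp(coefficients=cmap, entropy=entropy, rms=rms,
                         abs_log_ree=alr, ree=ree)
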