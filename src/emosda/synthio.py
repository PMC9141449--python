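"""Synthetic DEAP-shaped datasets, on-disk container, and label binarization.

The generator emulates the geometry of the common 32-subject / 40-trial
benchmark: per trial a 40 x 8064 array (32 EEG + 8 peripheral channels,
128 Hz, 63 s) plus continuous valence/arousal/dominance/liking ratings in
(0, 9).  A controllable emotion effect is injected into EEG band powers —
alpha-band amplitude decreases with the latent arousal rating and beta-band
amplitude increases with valence — so every downstream feature family has a
detectable class signal whose strength scales with ``effect_size``.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from emosda import montage

RATING_SCALES = ("valence", "arousal", "dominance", "liking")
RATING_THRESHOLD = 4.5


class DatasetFormatError(ValueError):
    """Raised when an on-disk container is malformed."""


@dataclass
class TrialRecording:
    """One trial: channels x samples signal plus metadata and ratings."""

    subject_id: int
    trial_id: int
    signal: np.ndarray          # (n_channels, n_samples)
    fs: float = float(montage.FS)
    channel_labels: tuple[str, ...] = montage.ALL_CHANNELS
    ratings: tuple[float, float, float, float] = (5.0, 5.0, 5.0, 5.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels length must match signal rows")
        if not all(np.isfinite(r) and 0.0 < r < 9.0 for r in self.ratings):
            raise ValueError("ratings must be finite and strictly inside (0, 9)")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def eeg(self) -> np.ndarray:
        """The 32 EEG rows (requires the combined 40-channel layout)."""
        return self.signal[:32]

    def peripheral(self) -> np.ndarray:
        """The 8 peripheral rows (requires the combined 40-channel layout)."""
        return self.signal[32:40]

    def rating(self, scale: str) -> float:
        return self.ratings[RATING_SCALES.index(scale)]


@dataclass
class Dataset:
    trials: list[TrialRecording]
    n_subjects: int
    n_trials_per_subject: int
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.trials) != self.n_subjects * self.n_trials_per_subject:
            raise ValueError("|trials| must equal n_subjects * n_trials_per_subject")

    def __len__(self) -> int:
        return len(self.trials)

    def ratings_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": t.subject_id, "trial": t.trial_id,
             **dict(zip(RATING_SCALES, t.ratings))}
            for t in self.trials
        ]
        return pd.DataFrame(rows)


@dataclass
class LabelSet:
    """Binary high/low labels for one affective scale."""

    scale: str
    labels: np.ndarray
    threshold: float = RATING_THRESHOLD

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")


# ---------------------------------------------------------------------------
# generation

# Baseline band amplitudes (arbitrary normalized units) for the synthetic EEG
# oscillations; chosen so effect_size = 1 yields moderate class separability
# against the AR(1) background noise.
_BAND_AMPLITUDES = {"theta": 0.7, "alpha": 1.0, "beta": 0.8, "gamma": 0.5}
_AR_COEF = 0.6
_AR_NOISE_STD = 1.0
_EFFECT_GAIN = 0.4          # fractional amplitude change per unit latent score
_SUBJECT_GAIN_SIGMA = 0.2   # lognormal sigma of per-subject multiplicative gain


def _oscillation_templates(rng: np.random.Generator,
                           t: np.ndarray) -> np.ndarray:
    """Unit-scale band oscillations, one per (EEG channel, band).

    Each template is a sum of three tones drawn uniformly inside the band
    with random phases.  Tone frequencies and phases are fixed per channel
    across all trials of a dataset (stimulus-locked oscillatory structure),
    so band-amplitude modulation is observable both spectrally and as a
    coherent waveform component that raw-signal learners can pick up.
    """
    templates = np.zeros((32, len(montage.BAND_ORDER), t.size))
    for ch in range(32):
        for bi, band in enumerate(montage.BAND_ORDER):
            lo, hi = montage.BANDS[band]
            freqs = rng.uniform(lo, hi, size=3)
            phases = rng.uniform(0, 2 * np.pi, size=3)
            for f, ph in zip(freqs, phases):
                templates[ch, bi] += np.sin(2 * np.pi * f * t + ph)
            templates[ch, bi] /= np.sqrt(3)
    return templates


def _ar1(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    e = rng.normal(0.0, _AR_NOISE_STD, size=shape)
    return lfilter([1.0], [1.0, -_AR_COEF], e, axis=-1)


def generate_dataset(n_subjects: int, n_trials: int, seed: int = 0,
                     effect_size: float = 1.0) -> Dataset:
    """Generate a synthetic dataset with DEAP geometry.

    Per trial, latent ratings are drawn uniformly on (1, 9).  EEG channels
    are sums of band-limited oscillations (theta/alpha/beta/gamma) plus
    AR(1) noise; the alpha amplitude decreases linearly with arousal and
    the beta amplitude increases with valence, both scaled by
    ``effect_size``.  Peripheral channels carry slow drifts plus
    rating-modulated variance.  A per-subject lognormal gain emulates
    inter-subject variability.

    Determinism: equal arguments reproduce the dataset bit-for-bit.
    """
    if n_subjects < 1 or n_trials < 1:
        raise ValueError("n_subjects and n_trials must be positive")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")

    rng = np.random.default_rng(seed)
    n_samples = montage.TRIAL_SAMPLES
    t = np.arange(n_samples) / montage.FS
    templates = _oscillation_templates(rng, t)
    base_amps = np.array([_BAND_AMPLITUDES[b] for b in montage.BAND_ORDER])
    trials: list[TrialRecording] = []

    for s in range(1, n_subjects + 1):
        gain = float(np.exp(rng.normal(0.0, _SUBJECT_GAIN_SIGMA)))
        for tr in range(1, n_trials + 1):
            ratings = tuple(float(r) for r in rng.uniform(1.0, 9.0, size=4))
            valence, arousal = ratings[0], ratings[1]
            # latent scores in (-1, 1), centered on the rating midpoint 5
            v = (valence - 5.0) / 4.0
            a = (arousal - 5.0) / 4.0
            amps = base_amps.copy()
            amps[1] = max(0.05, amps[1] * (1.0 - _EFFECT_GAIN * effect_size * a))
            amps[2] = max(0.05, amps[2] * (1.0 + _EFFECT_GAIN * effect_size * v))

            signal = np.empty((40, n_samples))
            eeg = _ar1(rng, (32, n_samples))
            eeg += np.einsum("b,cbt->ct", amps, templates)
            signal[:32] = gain * eeg
            for ch in range(8):
                f_slow = rng.uniform(0.05, 0.4)
                phase = rng.uniform(0, 2 * np.pi)
                drift = np.sin(2 * np.pi * f_slow * t + phase)
                noise_std = 0.3 * (1.0 + 0.2 * effect_size * (a + v) / 2.0)
                x = drift + rng.normal(0.0, max(noise_std, 0.05), size=n_samples)
                signal[32 + ch] = gain * x
            trials.append(TrialRecording(subject_id=s, trial_id=tr,
                                         signal=signal, ratings=ratings))
    return Dataset(trials=trials, n_subjects=n_subjects,
                   n_trials_per_subject=n_trials, seed=seed)


# ---------------------------------------------------------------------------
# trimming and labels

def trim_stimulus_segment(rec: TrialRecording) -> TrialRecording:
    """Keep the final 3840 samples (last 30 s of the stimulus).

    The 3 s baseline and the first 30 s are dropped.  Idempotent on inputs
    that are already exactly 3840 samples long.
    """
    n = montage.STIMULUS_SAMPLES
    if rec.n_samples < n:
        raise ValueError(f"need at least {n} samples, got {rec.n_samples}")
    if rec.n_samples == n:
        return rec
    return TrialRecording(subject_id=rec.subject_id, trial_id=rec.trial_id,
                          signal=rec.signal[:, -n:], fs=rec.fs,
                          channel_labels=rec.channel_labels, ratings=rec.ratings)


def binarize_ratings(dataset: Dataset, scale: str) -> LabelSet:
    """Binary labels: 1 iff rating strictly exceeds 4.5 (the scale midpoint).

    A rating of exactly 4.5 maps to class low.
    """
    if scale not in ("valence", "arousal", "dominance"):
        raise ValueError(f"unknown scale: {scale!r}")
    labels = np.array([1 if t.rating(scale) > RATING_THRESHOLD else 0
                       for t in dataset.trials])
    return LabelSet(scale=scale, labels=labels)


# ---------------------------------------------------------------------------
# HDF5 container

def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the dataset to one HDF5 container.

    Layout: ``/signals/s{SS}`` holds one float array per subject of shape
    (n_trials, n_channels, n_samples); ``/ratings`` is a table with columns
    subject, trial, valence, arousal, dominance, liking, also exported as a
    CSV side-car ``<path>.ratings.csv``.
    """
    path = Path(path)
    frame = dataset.ratings_frame()
    with h5py.File(path, "w") as f:
        f.attrs["n_subjects"] = dataset.n_subjects
        f.attrs["n_trials_per_subject"] = dataset.n_trials_per_subject
        f.attrs["seed"] = dataset.seed
        f.attrs["fs"] = montage.FS
        f.attrs["channel_labels"] = list(montage.ALL_CHANNELS)
        g = f.create_group("signals")
        for s in range(1, dataset.n_subjects + 1):
            block = np.stack([t.signal for t in dataset.trials
                              if t.subject_id == s])
            g.create_dataset(f"s{s:02d}", data=block)
        f.create_dataset("ratings", data=frame.to_numpy(dtype=np.float64))
        f["ratings"].attrs["columns"] = list(frame.columns)
    frame.to_csv(path.with_suffix(path.suffix + ".ratings.csv"), index=False)


def read_dataset(path: str | Path) -> Dataset:
    """Read a container written by :func:`write_dataset` (lossless round-trip)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "ratings" not in f:
            raise DatasetFormatError("container missing the ratings table")
        if "signals" not in f:
            raise DatasetFormatError("container missing the signals group")
        n_subjects = int(f.attrs["n_subjects"])
        n_trials = int(f.attrs["n_trials_per_subject"])
        seed = int(f.attrs["seed"])
        ratings = np.asarray(f["ratings"])
        rmap = {(int(r[0]), int(r[1])): tuple(r[2:6]) for r in ratings}
        trials: list[TrialRecording] = []
        for s in range(1, n_subjects + 1):
            key = f"s{s:02d}"
            if key not in f["signals"]:
                raise DatasetFormatError(f"missing signals for subject {s}")
            block = np.asarray(f["signals"][key])
            for tr in range(1, n_trials + 1):
                if (s, tr) not in rmap:
                    raise DatasetFormatError(
                        f"missing ratings for subject {s} trial {tr}")
                trials.append(TrialRecording(
                    subject_id=s, trial_id=tr, signal=block[tr - 1],
                    ratings=rmap[(s, tr)]))
    return Dataset(trials=trials, n_subjects=n_subjects,
                   n_trials_per_subject=n_trials, seed=seed)


# ---------------------------------------------------------------------------
# optional adapter for the per-subject preprocessed dialect

def write_preprocessed_dialect(dataset: Dataset, directory: str | Path) -> list[Path]:
    """Write per-subject files in the preprocessed python dialect.

    Each file ``s{SS}.dat`` pickles a dict with 'data' (n_trials x 40 x 8064)
    and 'labels' (n_trials x 4 ratings).  Used to exercise the adapter on
    synthetic data; real study files share this layout.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(1, dataset.n_subjects + 1):
        subj = [t for t in dataset.trials if t.subject_id == s]
        payload = {
            "data": np.stack([t.signal for t in subj]),
            "labels": np.array([t.ratings for t in subj]),
        }
        p = directory / f"s{s:02d}.dat"
        with open(p, "wb") as fh:
            pickle.dump(payload, fh)
        paths.append(p)
    return paths


def read_preprocessed_subject(path: str | Path, subject_id: int = 1) -> list[TrialRecording]:
    """Read one per-subject preprocessed file into TrialRecordings."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if not isinstance(payload, dict) or "data" not in payload or "labels" not in payload:
        raise DatasetFormatError("preprocessed file must hold 'data' and 'labels'")
    data = np.asarray(payload["data"], dtype=np.float64)
    labels = np.asarray(payload["labels"], dtype=np.float64)
    if data.ndim != 3 or data.shape[1:] != (40, montage.TRIAL_SAMPLES):
        raise DatasetFormatError(
            f"expected n x 40 x {montage.TRIAL_SAMPLES} data, got {data.shape}")
    if labels.shape != (data.shape[0], 4):
        raise DatasetFormatError(f"expected {data.shape[0]} x 4 ratings")
    return [TrialRecording(subject_id=subject_id, trial_id=i + 1,
                           signal=data[i], ratings=tuple(labels[i]))
            for i in range(data.shape[0])]
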