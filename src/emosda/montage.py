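"""Channel layout and frequency-band conventions.

The combined-modality recording has 40 rows: 32 EEG electrodes in the
standard 32-channel montage order used by affective-computing benchmarks
(left hemisphere + midline first, then right hemisphere), followed by
8 peripheral channels derived from EOG, EMG, GSR, respiration,
plethysmograph and temperature sensors.
"""

from __future__ import annotations

EEG_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

PERIPHERAL_CHANNELS: tuple[str, ...] = (
    "hEOG", "vEOG", "zEMG", "tEMG", "GSR", "Resp", "Plet", "Temp",
)

ALL_CHANNELS: tuple[str, ...] = EEG_CHANNELS + PERIPHERAL_CHANNELS

MIDLINE_CHANNELS: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz")

#: The 14 lateral left/right symmetric electrode pairs of the 32-channel
#: montage (the 4 midline electrodes have no mirror partner).
SYMMETRIC_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("C3", "C4"), ("T7", "T8"),
    ("CP1", "CP2"), ("CP5", "CP6"), ("P3", "P4"), ("P7", "P8"),
    ("PO3", "PO4"), ("O1", "O2"),
)


def symmetric_pair_indices() -> list[tuple[int, int]]:
    """Index pairs (left, right) into the 32-row EEG block."""
    idx = {name: i for i, name in enumerate(EEG_CHANNELS)}
    return [(idx[l], idx[r]) for l, r in SYMMETRIC_PAIRS]


#: Frequency bands (Hz, inclusive edges) used throughout the feature bank.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 29.0),
    "gamma": (30.0, 47.0),
}

BAND_ORDER: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")

FS: int = 128          #: sampling rate of the preprocessed recordings (Hz)
TRIAL_SAMPLES: int = 8064    #: 63 s at 128 Hz (3 s baseline + 60 s stimulus)
STIMULUS_SAMPLES: int = 3840  #: last 30 s of the stimulus, used downstream
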