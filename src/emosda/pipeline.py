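"""Pipeline orchestration.

Channel-level augmentation and normalization, per-channel PCA compression,
assembly of the full hand-engineered feature bank (1896 EEG + 248
peripheral columns), decision fusion with exhaustive weight search, and
the cross-subject / single-subject evaluation protocols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, train_test_split

from emosda import feat_freq, feat_time, feat_tf, montage
from emosda.features import FeatureTable
from emosda.models import make_classifier
from emosda.synthio import (Dataset, LabelSet, TrialRecording,
                            binarize_ratings, generate_dataset,
                            trim_stimulus_segment)

MODALITY_CHANNELS = {"eeg": list(range(32)),
                     "periphery": list(range(32, 40)),
                     "fused": list(range(40))}


# ---------------------------------------------------------------------------
# augmentation

@dataclass
class AugmentedSet:
    """One instance per (trial, channel): vectors of length 3840.

    Every instance inherits the labels of its source trial; ``origin``
    records (subject, trial, channel) per row so splits can be grouped.
    """

    instances: np.ndarray        # (n_instances, 3840)
    origin: np.ndarray           # (n_instances, 3) subject, trial, channel
    modality: str

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    def trial_keys(self) -> np.ndarray:
        """A (subject, trial) group id per instance."""
        return self.origin[:, 0] * 10_000 + self.origin[:, 1]


def augment_by_channel(dataset: Dataset, modality: str = "eeg") -> AugmentedSet:
    """Treat each channel of each trimmed trial as a separate instance.

    EEG yields 32 instances per trial, periphery 8, fused 40 — the full
    32-subject x 40-trial dataset gives 40,960 EEG instances.
    """
    if modality not in MODALITY_CHANNELS:
        raise ValueError(f"unknown modality {modality!r}")
    chans = MODALITY_CHANNELS[modality]
    rows, origin = [], []
    for t in dataset.trials:
        if t.n_samples != montage.STIMULUS_SAMPLES:
            raise ValueError("trials must be trimmed to 3840 samples first")
        for c in chans:
            rows.append(t.signal[c])
            origin.append((t.subject_id, t.trial_id, c))
    return AugmentedSet(instances=np.array(rows), origin=np.array(origin),
                        modality=modality)


def normalize_channels(aug: AugmentedSet) -> AugmentedSet:
    """Z-score every instance over its samples (zero-variance rows -> 0)."""
    X = aug.instances
    mean = X.mean(axis=1, keepdims=True)
    std = X.std(axis=1, keepdims=True)
    flat = (std == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance instances set to zero",
                      RuntimeWarning, stacklevel=2)
    std_safe = np.where(std == 0, 1.0, std)
    Z = (X - mean) / std_safe
    Z[flat] = 0.0
    return AugmentedSet(instances=Z, origin=aug.origin.copy(),
                        modality=aug.modality)


def expand_labels(aug: AugmentedSet, dataset: Dataset, scale: str) -> np.ndarray:
    """Per-instance binary labels inherited from the source trial."""
    trial_labels = {(t.subject_id, t.trial_id): 1 if t.rating(scale) > 4.5 else 0
                    for t in dataset.trials}
    return np.array([trial_labels[(s, tr)] for s, tr, _ in aug.origin])


# ---------------------------------------------------------------------------
# per-channel PCA compression

class PerChannelPCA:
    """Top-k principal components of each channel's signal, fitted on the
    training split only and concatenated across channels (25 components x
    32 EEG channels = 800 values per trial; 200 for periphery)."""

    def __init__(self, n_components: int = 25) -> None:
        self.n_components = n_components
        self.models: list[PCA] = []
        self.channels: list[int] = []

    def fit(self, trials: list[TrialRecording], modality: str = "eeg") -> "PerChannelPCA":
        self.channels = MODALITY_CHANNELS[modality]
        n = len(trials)
        if self.n_components > n:
            raise ValueError("n_components exceeds the number of training trials")
        if self.n_components > trials[0].n_samples:
            raise ValueError("n_components exceeds the sample count")
        self.models = []
        for c in self.channels:
            X = np.stack([t.signal[c] for t in trials])
            self.models.append(PCA(n_components=self.n_components,
                                   svd_solver="randomized",
                                   random_state=0).fit(X))
        return self

    def transform(self, trials: list[TrialRecording]) -> FeatureTable:
        if not self.models:
            raise RuntimeError("fit must be called first")
        blocks, names = [], []
        for c, m in zip(self.channels, self.models):
            X = np.stack([t.signal[c] for t in trials])
            blocks.append(m.transform(X))
            names += [f"ch{c}.pc{k}" for k in range(self.n_components)]
        values = np.hstack(blocks)
        return FeatureTable(values, names, ["pca"] * values.shape[1])


# ---------------------------------------------------------------------------
# feature bank

def _channel_features_eeg(x: np.ndarray, fs: float) -> tuple[list[float], list[str], list[str]]:
    """54 per-channel EEG features."""
    vals: list[float] = []
    names: list[str] = []
    fams: list[str] = []

    ts = feat_time.time_stats(x)
    vals += [ts.power, ts.mean, ts.std, ts.norm_first_diff, ts.norm_second_diff]
    names += ["stats.power", "stats.mean", "stats.std", "stats.nd1", "stats.nd2"]
    fams += ["stats"] * 5

    try:
        hj = feat_time.hjorth(x)
        vals += [hj.mobility, hj.complexity]
    except ValueError:
        vals += [np.nan, np.nan]
    names += ["hjorth.mobility", "hjorth.complexity"]
    fams += ["hjorth"] * 2

    vals.append(feat_time.nsi(x).value)
    names.append("nsi")
    fams.append("nsi")

    vals.append(feat_time.higuchi_fd(x).dimension)
    names.append("fd")
    fams.append("fd")

    hoc = feat_time.hoc_features(x)
    vals += list(hoc.counts.astype(float))
    names += [f"hoc.k{k}" for k in range(1, 11)]
    fams += ["hoc"] * 10

    psd = feat_freq.welch_psd(x, fs)
    vals.append(feat_freq.power_law_index(psd).eta)
    names.append("powerlaw.eta")
    fams.append("powerlaw")

    bp = feat_freq.band_power_features(x, fs)
    bp_vals, bp_names = bp.as_vector()
    vals += bp_vals
    names += bp_names
    fams += ["bandpower"] * len(bp_vals)

    bisp = feat_freq.bispectrum_estimate(x, fs)
    summ = feat_freq.bispectral_summaries(bisp)
    vals += [summ.be1, summ.be2, summ.mmob, summ.fosm]
    names += ["hos.be1", "hos.be2", "hos.mmob", "hos.fosm"]
    fams += ["hos"] * 4

    dw = feat_tf.dwt_features(x)
    for b in montage.BAND_ORDER:
        vals += [dw.entropy[b], dw.rms[b], dw.abs_log_ree[b]]
        names += [f"dwt.{b}.entropy", f"dwt.{b}.rms", f"dwt.{b}.alree"]
        fams += ["dwt"] * 3

    imfs = feat_tf.emd_decompose(x)
    hhs = feat_tf.hilbert_spectrum(imfs, fs)
    for b in montage.BAND_ORDER:
        vals.append(hhs.band_energy[b])
        names.append(f"hhs.{b}")
        fams.append("hhs")
    return vals, names, fams


def _channel_features_periphery(x: np.ndarray, fs: float) -> tuple[list[float], list[str], list[str]]:
    """31 per-channel peripheral features (no fractal dimension, no
    band-power/bispectral block; wavelet entropy and |ln REE| only)."""
    vals: list[float] = []
    names: list[str] = []
    fams: list[str] = []

    ts = feat_time.time_stats(x)
    vals += [ts.power, ts.mean, ts.std, ts.norm_first_diff, ts.norm_second_diff]
    names += ["stats.power", "stats.mean", "stats.std", "stats.nd1", "stats.nd2"]
    fams += ["stats"] * 5

    try:
        hj = feat_time.hjorth(x)
        vals += [hj.mobility, hj.complexity]
    except ValueError:
        vals += [np.nan, np.nan]
    names += ["hjorth.mobility", "hjorth.complexity"]
    fams += ["hjorth"] * 2

    vals.append(feat_time.nsi(x).value)
    names.append("nsi")
    fams.append("nsi")

    hoc = feat_time.hoc_features(x)
    vals += list(hoc.counts.astype(float))
    names += [f"hoc.k{k}" for k in range(1, 11)]
    fams += ["hoc"] * 10

    psd = feat_freq.welch_psd(x, fs)
    vals.append(feat_freq.power_law_index(psd).eta)
    names.append("powerlaw.eta")
    fams.append("powerlaw")

    dw = feat_tf.dwt_features(x)
    for b in montage.BAND_ORDER:
        vals.append(dw.entropy[b])
        names.append(f"dwt.{b}.entropy")
        fams.append("dwt")
    for b in montage.BAND_ORDER:
        vals.append(dw.abs_log_ree[b])
        names.append(f"dwt.{b}.alree")
        fams.append("dwt")

    imfs = feat_tf.emd_decompose(x)
    hhs = feat_tf.hilbert_spectrum(imfs, fs)
    for b in montage.BAND_ORDER:
        vals.append(hhs.band_energy[b])
        names.append(f"hhs.{b}")
        fams.append("hhs")
    return vals, names, fams


def extract_feature_bank(dataset: Dataset, modality: str = "eeg") -> FeatureTable:
    """The full hand-engineered feature bank.

    EEG: 54 per-channel features x 32 channels + 56 coherence + 56
    differential + 56 rational asymmetry = 1896 columns.  Periphery: 31
    per-channel x 8 = 248 columns.  Per-feature failures become missing
    values and are imputed with the column median.
    """
    if modality not in ("eeg", "periphery"):
        raise ValueError("modality must be 'eeg' or 'periphery'")
    rows = []
    names: list[str] | None = None
    fams: list[str] | None = None
    for t in dataset.trials:
        if t.n_samples != montage.STIMULUS_SAMPLES:
            raise ValueError("trials must be trimmed to 3840 samples first")
        vals: list[float] = []
        row_names: list[str] = []
        row_fams: list[str] = []
        if modality == "eeg":
            for c in range(32):
                v, n, f = _channel_features_eeg(t.signal[c], t.fs)
                vals += v
                row_names += [f"eeg.ch{c}.{x}" for x in n]
                row_fams += f
            pairs = montage.symmetric_pair_indices()
            msce = feat_freq.msce_features(t, pairs)
            asym = feat_freq.asymmetry_features(t, pairs)
            for (l, r), coh in zip(pairs, msce.band_coherence):
                for b, cval in zip(montage.BAND_ORDER, coh):
                    vals.append(cval)
                    row_names.append(f"eeg.pair{l}-{r}.msce.{b}")
                    row_fams.append("msce")
            for (l, r), d in zip(pairs, asym.dasm):
                for b, dval in zip(montage.BAND_ORDER, d):
                    vals.append(dval)
                    row_names.append(f"eeg.pair{l}-{r}.dasm.{b}")
                    row_fams.append("dasm")
            for (l, r), rv in zip(pairs, asym.rasm):
                for b, rval in zip(montage.BAND_ORDER, rv):
                    vals.append(rval)
                    row_names.append(f"eeg.pair{l}-{r}.rasm.{b}")
                    row_fams.append("rasm")
        else:
            for c in range(32, 40):
                v, n, f = _channel_features_periphery(t.signal[c], t.fs)
                vals += v
                row_names += [f"per.ch{c}.{x}" for x in n]
                row_fams += f
        if names is None:
            names, fams = row_names, row_fams
        rows.append(vals)
    table = FeatureTable(np.array(rows), names, fams)
    return table.impute_median()


# ---------------------------------------------------------------------------
# fusion

@dataclass
class FusionWeights:
    w_eeg: float
    step: float = 0.01
    search_trace: np.ndarray | None = None

    @property
    def w_periphery(self) -> float:
        return 1.0 - self.w_eeg


def fuse_decisions(p_eeg: np.ndarray, p_per: np.ndarray,
                   w: FusionWeights | float) -> np.ndarray:
    """Weighted average of the two modalities' class probabilities."""
    w_eeg = w.w_eeg if isinstance(w, FusionWeights) else float(w)
    p_eeg = np.asarray(p_eeg, dtype=np.float64)
    p_per = np.asarray(p_per, dtype=np.float64)
    if p_eeg.shape != p_per.shape:
        raise ValueError("probability arrays are misaligned")
    return w_eeg * p_eeg + (1.0 - w_eeg) * p_per


def search_fusion_weights(p_eeg: np.ndarray, p_per: np.ndarray,
                          labels: np.ndarray, step: float = 0.01) -> FusionWeights:
    """Exhaustive grid search over w in {0, step, ..., 1}.

    Returns the accuracy-maximizing weight; ties break to the smallest w.
    """
    labels = np.asarray(labels)
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    trace = np.empty(grid.size)
    for i, w in enumerate(grid):
        pred = fuse_decisions(p_eeg, p_per, w).argmax(axis=1)
        trace[i] = np.mean(pred == labels)
    best = int(np.argmax(trace))   # argmax returns the first (smallest w) tie
    return FusionWeights(w_eeg=float(grid[best]), step=step, search_trace=trace)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalReport:
    task: str
    protocol: str
    per_fold_accuracy: list[float]
    model: str
    seed: int
    extra: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "task": self.task, "protocol": self.protocol, "model": self.model,
            "fold": np.arange(len(self.per_fold_accuracy)),
            "accuracy": self.per_fold_accuracy, "seed": self.seed,
        })


def crossval_cross_subject(features: FeatureTable, labels: LabelSet,
                           model: str = "svm", folds: int = 5, seed: int = 0,
                           fixed_split: bool = False) -> EvalReport:
    """Stratified seeded k-fold CV over all subjects' trials mixed together.

    With ``fixed_split`` a single stratified 60/20/20-style split
    (768/256/256 at full scale) replaces the fold loop: the model is
    trained on the training part and scored on the test part.
    """
    X, y = features.values, labels.labels
    if np.unique(y).size < 2:
        raise ValueError("need both classes present")
    accs: list[float] = []
    extra: dict = {}
    if fixed_split:
        n = len(y)
        n_val = n_test = round(n * 0.2)
        idx_rest, idx_test = train_test_split(
            np.arange(n), test_size=n_test, stratify=y, random_state=seed)
        idx_train, idx_val = train_test_split(
            idx_rest, test_size=n_val, stratify=y[idx_rest], random_state=seed)
        clf = make_classifier(model, seed=seed)
        clf.fit(X[idx_train], y[idx_train])
        accs = [float(np.mean(clf.predict(X[idx_test]) == y[idx_test]))]
        extra = {"train_size": len(idx_train), "val_size": len(idx_val),
                 "test_size": len(idx_test)}
        protocol = "cross_subject_fixed_split"
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for tr, te in skf.split(X, y):
            clf = make_classifier(model, seed=seed)
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        protocol = "cross_subject_5fold"
    return EvalReport(task=labels.scale, protocol=protocol,
                      per_fold_accuracy=accs, model=model, seed=seed,
                      extra=extra)


def loocv_single_subject(features: FeatureTable, labels: LabelSet,
                         model: str = "svm", seed: int = 0) -> EvalReport | None:
    """Leave-one-out CV over one subject's trials (accuracy = correct / n).

    Returns None (with a warning) when a class has fewer than 2 trials.
    """
    X, y = features.values, labels.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        warnings.warn("degenerate subject: a class has fewer than 2 trials; "
                      "task skipped", RuntimeWarning, stacklevel=2)
        return None
    n = len(y)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = make_classifier(model, seed=seed)
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
    return EvalReport(task=labels.scale, protocol="single_subject_loocv",
                      per_fold_accuracy=[correct / n], model=model, seed=seed,
                      extra={"n_trials": n, "n_correct": correct})


# ---------------------------------------------------------------------------
# end-to-end driver

DEFAULT_CONFIG = {
    "dataset": {"n_subjects": 4, "n_trials": 10, "effect_size": 1.0},
    "tasks": ["valence", "arousal"],
    "models": ["knn"],
    "selection": {"rflv_threshold": 0.01, "top_k": 200, "wrapper": False},
    "evaluation": {"folds": 5, "single_subject": False},
    "seed": 0,
}


def _validate_config(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for section in ("dataset", "selection", "evaluation"):
        merged = {**DEFAULT_CONFIG[section], **cfg.get(section, {})}
        cfg[section] = merged
    for task in cfg["tasks"]:
        if task not in ("valence", "arousal", "dominance"):
            raise ValueError(f"tasks: unknown scale {task!r}")
    for m in cfg["models"]:
        from emosda.models import CLASSIFIERS
        if m not in CLASSIFIERS:
            raise ValueError(f"models: unknown classifier {m!r}")
    if cfg["dataset"]["n_subjects"] < 1 or cfg["dataset"]["n_trials"] < 1:
        raise ValueError("dataset.n_subjects and dataset.n_trials must be positive")
    return cfg


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path | None = None) -> list[EvalReport]:
    """Synthesize, trim, extract features, select, train and evaluate.

    Deterministic under the config seed; writes per-report CSVs when
    ``out_dir`` is given.
    """
    from emosda import selection as sel

    cfg = _validate_config(config or {})
    seed = int(cfg["seed"])
    ds_cfg = cfg["dataset"]
    dataset = generate_dataset(ds_cfg["n_subjects"], ds_cfg["n_trials"],
                               seed=seed, effect_size=ds_cfg["effect_size"])
    trimmed = Dataset([trim_stimulus_segment(t) for t in dataset.trials],
                      dataset.n_subjects, dataset.n_trials_per_subject,
                      seed=dataset.seed)
    table = extract_feature_bank(trimmed, "eeg")
    reports: list[EvalReport] = []
    for task in cfg["tasks"]:
        labels = binarize_ratings(trimmed, task)
        kept = sel.rflv(table, cfg["selection"]["rflv_threshold"])
        sub = table.select(kept.mask)
        if np.unique(labels.labels).size > 1 and cfg["selection"]["top_k"]:
            chi = sel.score_features(sub, labels, "chi2")
            mi = sel.score_features(sub, labels, "mutual_info")
            uni = sel.union_topk(chi, mi, k=cfg["selection"]["top_k"])
            sub = sub.select(uni.mask)
        for model in cfg["models"]:
            rep = crossval_cross_subject(sub, labels, model=model,
                                         folds=cfg["evaluation"]["folds"],
                                         seed=seed)
            reports.append(rep)
            if cfg["evaluation"]["single_subject"]:
                for s in range(1, trimmed.n_subjects + 1):
                    idx = [i for i, t in enumerate(trimmed.trials)
                           if t.subject_id == s]
                    sub_feats = FeatureTable(sub.values[idx], list(sub.names),
                                             list(sub.family))
                    sub_labels = LabelSet(task, labels.labels[idx])
                    r = loocv_single_subject(sub_feats, sub_labels,
                                             model=model, seed=seed)
                    if r is not None:
                        r.extra["subject"] = s
                        reports.append(r)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame = pd.concat([r.to_frame() for r in reports], ignore_index=True)
        frame.to_csv(out_dir / "eval_reports.csv", index=False)
    return reports
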