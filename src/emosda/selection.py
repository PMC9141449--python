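"""Hybrid feature selection.

A variance filter (removing features with low variance, RFLV), three
univariate supervised scorers (chi-square on min-max scaled features,
a deterministic plug-in mutual-information estimate, and the Fisher
score), a top-k union combiner, and a greedy forward wrapper evaluated by
cross-validated classifier accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_selection import chi2 as sk_chi2
from sklearn.model_selection import StratifiedKFold

from emosda.features import FeatureTable
from emosda.models import make_classifier
from emosda.synthio import LabelSet

MI_BINS = 10


@dataclass
class SelectionResult:
    scores: np.ndarray
    ranking: np.ndarray        # feature indices, descending score
    mask: np.ndarray           # boolean keep-vector
    method: str
    names: list[str] | None = None
    family: list[str] | None = None

    def to_csv(self, path: str | Path) -> None:
        rank_of = np.empty(len(self.scores), dtype=int)
        rank_of[self.ranking] = np.arange(len(self.scores))
        pd.DataFrame({
            "name": self.names or [f"f{i}" for i in range(len(self.scores))],
            "family": self.family or [""] * len(self.scores),
            "score": self.scores,
            "rank": rank_of,
            "kept": self.mask,
        }).to_csv(path, index=False)


def _ranking(scores: np.ndarray) -> np.ndarray:
    # stable sort so ties resolve to the lower feature index
    return np.argsort(-scores, kind="stable")


def rflv(table: FeatureTable, threshold: float = 0.01) -> SelectionResult:
    """Remove features whose sample variance is strictly below threshold.

    A feature with variance exactly equal to the threshold is kept.
    Idempotent: re-filtering the surviving columns removes nothing.
    """
    if table.n_instances < 2:
        raise ValueError("need at least 2 instances")
    var = table.values.var(axis=0, ddof=1)
    mask = var >= threshold
    return SelectionResult(scores=var, ranking=_ranking(var), mask=mask,
                           method="rflv", names=list(table.names),
                           family=list(table.family))


def _quantile_discretize(col: np.ndarray, bins: int = MI_BINS) -> np.ndarray:
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, col, side="right")


def _plugin_mi(d: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) between a discrete feature and labels."""
    n = y.size
    mi = 0.0
    for dv in np.unique(d):
        pd_ = np.mean(d == dv)
        for yv in np.unique(y):
            pj = np.mean((d == dv) & (y == yv))
            if pj > 0:
                mi += pj * np.log(pj / (pd_ * np.mean(y == yv)))
    return max(0.0, mi)


def score_features(table: FeatureTable, labels: LabelSet,
                   method: str = "chi2") -> SelectionResult:
    """Score every feature against binary labels.

    ``chi2``: classical chi-square statistic on features min-max scaled to
    [0, 1] (non-negativity).  ``mutual_info``: deterministic plug-in
    estimate of I(feature; label) after 10-bin quantile discretization.
    ``fisher``: between-class mean separation over within-class variance.
    """
    y = labels.labels
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    X = table.values
    if method == "chi2":
        lo = X.min(axis=0)
        span = X.max(axis=0) - lo
        span[span == 0] = 1.0
        Xs = (X - lo) / span
        scores, _ = sk_chi2(Xs, y)
        scores = np.nan_to_num(scores, nan=0.0)
    elif method == "mutual_info":
        scores = np.array([_plugin_mi(_quantile_discretize(X[:, j]), y)
                           for j in range(X.shape[1])])
    elif method == "fisher":
        mu = X.mean(axis=0)
        num = np.zeros(X.shape[1])
        den = np.zeros(X.shape[1])
        for c in (0, 1):
            Xc = X[y == c]
            nc = Xc.shape[0]
            num += nc * (Xc.mean(axis=0) - mu) ** 2
            den += nc * Xc.var(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            # zero within-class variance with separated means -> infinite score
            scores = np.where(den > 0, num / den,
                              np.where(num > 0, np.inf, 0.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    return SelectionResult(scores=scores, ranking=_ranking(scores),
                           mask=np.ones(X.shape[1], dtype=bool), method=method,
                           names=list(table.names), family=list(table.family))


def union_topk(a: SelectionResult, b: SelectionResult, k: int = 200) -> SelectionResult:
    """Union of the top-k features of two rankings over the same feature set."""
    if len(a.scores) != len(b.scores) or (a.names and b.names and a.names != b.names):
        raise ValueError("selection results cover different feature sets")
    k = min(k, len(a.scores))
    mask = np.zeros(len(a.scores), dtype=bool)
    mask[a.ranking[:k]] = True
    mask[b.ranking[:k]] = True
    combined = np.maximum(a.scores / max(a.scores.max(), 1e-300),
                          b.scores / max(b.scores.max(), 1e-300))
    return SelectionResult(scores=combined, ranking=_ranking(combined),
                           mask=mask, method=f"union({a.method},{b.method})",
                           names=a.names, family=a.family)


def forward_wrapper(table: FeatureTable, labels: LabelSet, model: str = "svm",
                    folds: int = 5, seed: int = 0,
                    skip_perfect_singletons: bool = False,
                    max_features: int | None = None) -> SelectionResult:
    """Greedy forward wrapper search maximizing mean CV accuracy.

    Folds are stratified and fixed once (seeded) so all candidate
    evaluations share them.  A candidate must improve the running best
    mean accuracy by more than 1e-6 to be accepted; ties between
    candidates break to the lowest feature index.  Optionally skips single
    features that alone reach perfect accuracy (an overfitting guard for
    tiny datasets).
    """
    y = labels.labels
    if folds > table.n_instances:
        raise ValueError("more folds than instances")
    X = table.values
    cv = list(StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=seed).split(X, y))

    def _acc(cols: list[int]) -> float:
        accs = []
        for tr, te in cv:
            clf = make_classifier(model, seed=seed)
            clf.fit(X[np.ix_(tr, cols)], y[tr])
            accs.append(np.mean(clf.predict(X[np.ix_(te, cols)]) == y[te]))
        return float(np.mean(accs))

    skipped: set[int] = set()
    if skip_perfect_singletons:
        for j in range(X.shape[1]):
            if _acc([j]) >= 1.0:
                skipped.add(j)

    selected: list[int] = []
    best = 0.0
    trace = np.zeros(X.shape[1])
    while True:
        cand_best, cand_acc = None, -np.inf
        for j in range(X.shape[1]):
            if j in selected or j in skipped:
                continue
            a = _acc(selected + [j])
            if a > cand_acc:      # strict >, so ties keep the lowest index
                cand_best, cand_acc = j, a
        if cand_best is None or cand_acc <= best + 1e-6:
            break
        selected.append(cand_best)
        best = cand_acc
        trace[cand_best] = best
        if max_features is not None and len(selected) >= max_features:
            break
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[selected] = True
    scores = trace
    return SelectionResult(scores=scores, ranking=_ranking(scores), mask=mask,
                           method=f"forward_wrapper({model})",
                           names=list(table.names), family=list(table.family))
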