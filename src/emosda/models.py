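"""Classifier factory for the seven standard shallow models.

Hyperparameters follow widely used defaults (RBF SVM with C = 1 and
gamma = 1/d, k = 5 neighbors, ...); each model is seeded where stochastic.
"""

from __future__ import annotations

from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIERS = ("svm", "dt", "rf", "lda", "lr", "nb", "knn")


def make_classifier(name: str, seed: int = 0, **overrides):
    """Instantiate a named classifier by its short name.

    Pass ``probability=True`` for an SVM whose ``predict_proba`` feeds
    decision fusion; accuracy-only paths skip the Platt calibration.
    """
    if name == "svm":
        return SVC(C=1.0, kernel="rbf", gamma="scale",
                   random_state=seed, **overrides)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed, **overrides)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed,
                                      **overrides)
    if name == "lda":
        return LinearDiscriminantAnalysis(**overrides)
    if name == "lr":
        return LogisticRegression(max_iter=1000, random_state=seed, **overrides)
    if name == "nb":
        return GaussianNB(**overrides)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5, **overrides)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")
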