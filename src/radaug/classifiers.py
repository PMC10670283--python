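"""The 13 classifiers and the train-only fit/predict path.

``fit_predict`` learns standardization parameters, both selection levels
and the classifier on the training rows only and returns positive-class
probability scores in [0, 1] for the test rows.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import BernoulliNB, GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from radaug.grid import PipelineSetting
from radaug.selection import rank_first_level, select_second_level


def make_classifier(name: str, seed: int = 0):
    if name == "GNB":
        return GaussianNB()
    if name == "MNB":
        return MultinomialNB()
    if name == "BNB":
        return BernoulliNB()
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "BAG":
        return BaggingClassifier(random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "GBDT":
        return GradientBoostingClassifier(random_state=seed)
    if name == "Adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=100, random_state=seed, verbosity=0, eval_metric="logloss")
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "SVM":
        return SVC(probability=True, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def fit_predict(
    setting: PipelineSetting,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    seed: int = 0,
    knn_k: int | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Returns (positive-class probabilities for x_test, selected indices).

    Selected indices refer to columns of the input matrices.
    """
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training fold")

    ranked, _ = rank_first_level(x_train, y_train, setting.filter_method, setting.first_level_keep, seed)
    x1 = x_train[:, ranked]
    sel = select_second_level(x1, y_train, setting.embedded_method, setting.max_selected, seed)
    cols = ranked[sel]

    mean = x_train[:, cols].mean(axis=0)
    sd = x_train[:, cols].std(axis=0)
    sd[sd == 0] = 1.0
    if setting.classifier == "MNB":  # multinomial NB needs non-negative inputs
        lo = x_train[:, cols].min(axis=0)
        rng = x_train[:, cols].max(axis=0) - lo
        rng[rng == 0] = 1.0
        tr = (x_train[:, cols] - lo) / rng
        te = np.clip((x_test[:, cols] - lo) / rng, 0.0, None)
    else:
        tr = (x_train[:, cols] - mean) / sd
        te = (x_test[:, cols] - mean) / sd

    clf = make_classifier(setting.classifier, seed)
    if setting.classifier == "KNN" and knn_k is not None:
        clf.set_params(n_neighbors=knn_k)
    clf.fit(tr, y_train)
    probs = clf.predict_proba(te)[:, list(clf.classes_).index(1)]
    return np.clip(probs, 0.0, 1.0), cols
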