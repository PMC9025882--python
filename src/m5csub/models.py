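"""Classifier training and evaluation: SVM / logistic GLM / random forest /
gradient boosting, stratified 5-fold cross-validation and independent test,
scored by AUROC, sensitivity, specificity and accuracy.

The propensity (PSNP) encoder is a training-set statistic, so every
evaluation path here re-fits the encoder on the training portion only —
inside each cross-validation fold and on the training split of an
independent test.  Fitting it once on all data before cross-validation
leaks the held-out labels and inflates AUROC (a regression test guards
this).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .encoders import Encoder

ALGORITHMS = ("svm", "glm", "rf", "xgb")


@dataclass
class EvalReport:
    """Performance record for one task/configuration."""

    task: str = ""
    algorithm: str = ""
    scheme: str = ""
    auroc: float = float("nan")
    sn: float = float("nan")
    sp: float = float("nan")
    acc: float = float("nan")
    threshold: float = 0.5
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    fold_aurocs: list[float] = field(default_factory=list)
    fold_assignment: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Confusion counts and Sn/Sp/Acc at a score threshold.

    A sample is called positive when its score >= threshold.
    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least one sample of each class")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    return EvalReport(
        auroc=auroc(labels, scores),
        sn=tp / (tp + fn),
        sp=tn / (tn + fp),
        acc=(tp + tn) / (tp + fn + fp + tn),
        threshold=threshold,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def auroc(labels, scores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation
    with tie correction: P(score_pos > score_neg) + 0.5 * P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one sample of each class")
    ranks = rankdata(scores)  # average ranks handle ties
    pos_rank_sum = ranks[labels == 1].sum()
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def train_classifier(X, y, algorithm: str = "svm", seed: int = 0, **params):
    """Fit a classifier exposing probability scores via ``predict_proba``.

    Defaults are fixed and documented: SVM uses an RBF kernel with C=1 and
    gamma='scale' (1/(d*var)) plus Platt probability calibration; the other
    three use library defaults with pinned seeds.  Extra keyword arguments
    override them.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match len(y)")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("feature matrix is degenerate: every column is constant")
    if algorithm == "svm":
        svc = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed, **params)
        clf = Pipeline(
            [
                ("scale", StandardScaler()),
                # Platt-style probability calibration on cross-validated margins
                ("svc", CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)),
            ]
        )
    elif algorithm == "glm":
        clf = Pipeline(
            [
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(max_iter=1000, random_state=seed, **params)),
            ]
        )
    elif algorithm == "rf":
        clf = RandomForestClassifier(random_state=seed, **params)
    elif algorithm == "xgb":
        clf = XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            **params,
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    clf.fit(X, y)
    return clf


def predict_scores(model, X) -> np.ndarray:
    """Positive-class probability scores in [0, 1]."""
    return model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def _fit_encoder_on(encoder: Encoder, windows: list[str], labels: np.ndarray) -> Encoder:
    enc = encoder.clone()
    if enc.trainable:
        pos = [w for w, y in zip(windows, labels) if y == 1]
        neg = [w for w, y in zip(windows, labels) if y == 0]
        enc.fit(pos, neg)
    return enc


def crossvalidate(
    windows: list[str],
    labels,
    algorithm: str = "svm",
    encoder: Encoder | None = None,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    refit_encoder: bool = True,
    **params,
) -> EvalReport:
    """Stratified k-fold cross-validation with per-fold encoder refit.

    Held-out scores are pooled over folds before computing the metrics.
    ``refit_encoder=False`` fits trainable encoders once on all data — the
    leaky variant, kept only so the leakage effect can be demonstrated.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need >= {k} members per class for {k}-fold CV")
    if encoder is None:
        raise ValueError("an encoder is required")
    if not refit_encoder and encoder.trainable:
        encoder = _fit_encoder_on(encoder, windows, labels)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_scores = np.empty(len(labels))
    fold_of = np.empty(len(labels), dtype=int)
    fold_aurocs = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        tr_windows = [windows[i] for i in tr]
        te_windows = [windows[i] for i in te]
        enc = (
            _fit_encoder_on(encoder, tr_windows, labels[tr])
            if refit_encoder
            else encoder
        )
        model = train_classifier(
            enc.transform(tr_windows), labels[tr], algorithm, seed=seed, **params
        )
        scores = predict_scores(model, enc.transform(te_windows))
        pooled_scores[te] = scores
        fold_of[te] = fold
        if len(np.unique(labels[te])) == 2:
            fold_aurocs.append(auroc(labels[te], scores))
    report = compute_metrics(labels, pooled_scores, threshold)
    report.algorithm = algorithm
    report.scheme = encoder.name
    report.fold_aurocs = fold_aurocs
    report.fold_assignment = fold_of.tolist()
    return report


def evaluate_independent(
    train_windows: list[str],
    train_labels,
    test_windows: list[str],
    test_labels,
    algorithm: str = "svm",
    encoder: Encoder | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    allow_overlap: bool = False,
    **params,
) -> EvalReport:
    """Fit encoder + classifier on the training split only; report on test."""
    if not test_windows:
        raise ValueError("empty test set")
    if encoder is None:
        raise ValueError("an encoder is required")
    if not allow_overlap and set(train_windows) & set(test_windows):
        raise ValueError("train and test sets overlap; pass allow_overlap=True to force")
    train_labels = np.asarray(train_labels)
    test_labels = np.asarray(test_labels)
    enc = _fit_encoder_on(encoder, train_windows, train_labels)
    model = train_classifier(
        enc.transform(train_windows), train_labels, algorithm, seed=seed, **params
    )
    scores = predict_scores(model, enc.transform(test_windows))
    report = compute_metrics(test_labels, scores, threshold)
    report.algorithm = algorithm
    report.scheme = enc.name
    return report
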