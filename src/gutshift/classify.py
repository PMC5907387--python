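"""Diet prediction from microbiome profiles.

Rank-normalized, penalized logistic regression evaluated by leave-one-out
cross-validation: for every held-out sample, features are rank-normalized on the
training remainder only, the penalty strength is chosen by inner stratified
cross-validation on the remainder only, and the held-out sample is scored by the
refitted model — so no information about the held-out sample leaks into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

logger = logging.getLogger(__name__)

__all__ = ["ClassificationReport", "rank_normalize", "loo_classify", "roc_auc"]

DEFAULT_PENALTY_GRID = tuple(10.0 ** np.linspace(-3, 3, 7))


@dataclass
class ClassificationReport:
    scores: pd.Series
    true_labels: pd.Series
    predicted_labels: pd.Series
    roc: pd.DataFrame = field(repr=False, default=None)
    auc: float = float("nan")

    def to_json_dict(self) -> dict:
        return {
            "auc": self.auc,
            "scores": self.scores.to_dict(),
            "true_labels": self.true_labels.to_dict(),
            "predicted_labels": self.predicted_labels.to_dict(),
        }


def rank_normalize(
    train: pd.DataFrame, apply_to: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-feature rank normalization to (0, 1], ties averaged.

    Training values become rank/n_train.  Held-out values are mapped by linear
    interpolation into the training empirical distribution (value -> normalized rank),
    clipped to the training [min, max] ranks.  A constant training feature maps
    everything to 0.5.
    """
    n = train.shape[1]
    train_out = pd.DataFrame(index=train.index, columns=train.columns, dtype=float)
    apply_out = (
        pd.DataFrame(index=apply_to.index, columns=apply_to.columns, dtype=float)
        if apply_to is not None
        else None
    )
    for f in train.index:
        v = train.loc[f].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            logger.debug("feature %s constant in training; mapped to 0.5", f)
            train_out.loc[f] = 0.5
            if apply_out is not None:
                apply_out.loc[f] = 0.5
            continue
        ranks = stats.rankdata(v) / n
        train_out.loc[f] = ranks
        if apply_out is not None:
            order = np.argsort(v, kind="stable")
            xs, rs = v[order], ranks[order]
            held = apply_to.loc[f].to_numpy(dtype=float)
            apply_out.loc[f] = np.interp(held, xs, rs)  # np.interp clips at both ends
    return train_out, apply_out


def loo_classify(
    features: pd.DataFrame,
    labels: pd.Series,
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
    penalty: str = "l2",
    inner_folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Leave-one-out diet classification report with ROC/AUC.

    ``features`` is feature x sample; ``labels`` maps sample -> one of exactly two
    classes.  Scores are the out-of-fold predicted probability of the
    lexicographically larger class.
    """
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("binary labels required")
    counts = labels.value_counts()
    if (counts < 6).any():
        raise ValueError("need at least 6 samples per class")
    positive = classes[1]
    samples = list(features.columns)
    y = (labels[samples] == positive).to_numpy(dtype=int)

    if penalty not in ("l1", "l2"):
        raise ValueError("penalty must be 'l1' or 'l2'")

    def make_model(c: float) -> LogisticRegression:
        kwargs = {"l1_ratio": 1.0} if penalty == "l1" else {}
        return LogisticRegression(C=c, solver="liblinear", max_iter=1000, **kwargs)

    scores = {}
    for i, held in enumerate(samples):
        train_cols = [s for s in samples if s != held]
        y_train = np.delete(y, i)
        if len(np.unique(y_train)) < 2:
            raise ValueError("a class is absent from a training fold")
        x_train_df, x_held_df = rank_normalize(
            features[train_cols], features[[held]]
        )
        x_train = x_train_df.to_numpy(dtype=float).T
        x_held = x_held_df.to_numpy(dtype=float).T

        best_c, best_score = None, -np.inf
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        for c in penalty_grid:
            cv = cross_val_score(
                make_model(c), x_train, y_train, cv=inner, scoring="roc_auc"
            )
            # ties go to the weakest penalty: rank-based inner scores saturate, and an
            # over-shrunk model emits near-constant out-of-fold scores whose ordering
            # across the LOO models is dominated by fold composition, not features
            if cv.mean() >= best_score - 1e-9:
                best_score, best_c = max(cv.mean(), best_score), c
        model = make_model(best_c)
        model.fit(x_train, y_train)
        scores[held] = float(model.predict_proba(x_held)[0, list(model.classes_).index(1)])

    score_series = pd.Series(scores)[samples]
    predicted = pd.Series(
        np.where(score_series.to_numpy() >= 0.5, positive, classes[0]), index=samples
    )
    roc, auc = roc_auc(score_series.to_numpy(), y)
    return ClassificationReport(
        scores=score_series,
        true_labels=labels[samples],
        predicted_labels=predicted,
        roc=roc,
        auc=auc,
    )


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep over unique scores) and trapezoidal AUC.

    The AUC equals the Mann-Whitney concordance U/(n1*n2), with ties counting half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    pts = []
    for t in thresholds:
        pred = s >= t
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        pts.append((fpr, tpr, t))
    roc = pd.DataFrame(pts, columns=["fpr", "tpr", "threshold"])
    auc = float(np.trapezoid(roc.tpr, roc.fpr))
    return roc, auc
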