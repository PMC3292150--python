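"""Pairwise Fisher LDA with a longitudinal (train-early, test-late) protocol.

Classification is strictly two classes at a time - non-fatigue vs
transition-to-fatigue, and transition-to-fatigue vs fatigue.  The decision is
``y = W.x + w0`` with the less severe class on the positive side (y > 0) and
the more severe class on the negative side.  ``W`` is the Fisher direction
``Sw^-1 (mu+ - mu-)`` with a midpoint threshold (equal priors).

"Longitudinal" means: within each trial and each class, the chronologically
first ``ceil(train_frac * n)`` seconds train the model and the remainder test
it, so the model must generalize forward in time and never sees future data.
Confusion counting uses the more severe class of the pair as "actual +".
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FatigueClass, FeatureSeries, LabelSeries, Trial, ValidationError
from .features import extract_all
from .report import ConfusionMatrix

__all__ = [
    "LdaModel",
    "ClassPairDataset",
    "ZeroMarginWarning",
    "fit_lda",
    "predict",
    "longitudinal_split",
    "build_pair_dataset",
    "run_pairwise",
    "PAIR_NF_TF",
    "PAIR_TF_F",
]

logger = logging.getLogger(__name__)

# pairs as (less severe = positive side of y, more severe = negative side)
PAIR_NF_TF = (FatigueClass.NON_FATIGUE, FatigueClass.TRANSITION_TO_FATIGUE)
PAIR_TF_F = (FatigueClass.TRANSITION_TO_FATIGUE, FatigueClass.FATIGUE)


class ZeroMarginWarning(UserWarning):
    """The two class means coincide; the discriminant has no margin."""


@dataclass
class LdaModel:
    W: np.ndarray
    w0: float
    positive_class: FatigueClass
    negative_class: FatigueClass

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.positive_class == self.negative_class:
            raise ValidationError("positive and negative class must differ")

    def decision(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != self.W.shape:
            raise ValidationError(
                f"feature dimension {x.shape} does not match weights {self.W.shape}"
            )
        return float(self.W @ x + self.w0)


@dataclass
class ClassPairDataset:
    """Per-second feature vectors restricted to one class pair."""

    pair: tuple[FatigueClass, FatigueClass]
    X: np.ndarray                 # (n, d)
    y: np.ndarray                 # (n,) int codes
    t: np.ndarray                 # (n,) second timestamps
    trial_ids: np.ndarray         # (n,) str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != np.asarray(self.y).size:
            self.X = self.X.T
        self.y = np.asarray(self.y, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        allowed = {int(c) for c in self.pair}
        present = set(np.unique(self.y).tolist())
        if not present <= allowed:
            raise ValidationError(
                f"dataset contains classes {present} outside the pair {allowed}"
            )
        for tid in np.unique(self.trial_ids):
            tt = self.t[self.trial_ids == tid]
            if tt.size > 1 and not np.all(np.diff(tt) > 0):
                raise ValidationError(
                    f"timestamps not strictly increasing within trial {tid!r}"
                )

    def __len__(self) -> int:
        return self.y.size

    def take(self, idx: np.ndarray) -> "ClassPairDataset":
        return ClassPairDataset(
            pair=self.pair, X=self.X[idx], y=self.y[idx], t=self.t[idx],
            trial_ids=self.trial_ids[idx], subject_id=self.subject_id,
        )


def fit_lda(X: np.ndarray, y: np.ndarray,
            positive_class: FatigueClass = FatigueClass.NON_FATIGUE,
            negative_class: FatigueClass = FatigueClass.TRANSITION_TO_FATIGUE,
            ridge: float = 1e-6) -> LdaModel:
    """Fisher discriminant: ``W = Sw^-1 (mu+ - mu-)``, midpoint threshold.

    ``y`` holds booleans (True = positive class).  The pooled within-class
    covariance gets a ridge of ``ridge * trace/d`` if it is singular.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=bool)
    if X.shape[0] != y.size:
        X = X.T
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"each class needs >= 2 examples; got {n_pos} positive, {n_neg} negative"
        )
    Xp, Xn = X[y], X[~y]
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    d = X.shape[1]
    scatter = np.zeros((d, d))
    for part, mu in ((Xp, mu_p), (Xn, mu_n)):
        centred = part - mu
        scatter += centred.T @ centred
    sw = scatter / (n_pos + n_neg - 2)
    delta = mu_p - mu_n
    if not np.any(delta):
        warnings.warn(
            "identical class means: zero-margin discriminant", ZeroMarginWarning
        )
        return LdaModel(W=np.zeros(d), w0=0.0,
                        positive_class=positive_class, negative_class=negative_class)
    try:
        W = np.linalg.solve(sw, delta)
        if not np.all(np.isfinite(W)):
            raise np.linalg.LinAlgError("non-finite solution")
    except np.linalg.LinAlgError:
        reg = ridge * np.trace(sw) / d
        if reg == 0.0:
            reg = ridge
        logger.info("singular within-class covariance; applying ridge %.3g", reg)
        W = np.linalg.solve(sw + reg * np.eye(d), delta)
    w0 = float(-W @ (mu_p + mu_n) / 2.0)
    return LdaModel(W=W, w0=w0, positive_class=positive_class,
                    negative_class=negative_class)


def predict(model: LdaModel, x: np.ndarray) -> FatigueClass:
    """``y > 0`` (or exactly 0, by the documented tie rule) -> positive class."""
    return model.positive_class if model.decision(x) >= 0 else model.negative_class


def longitudinal_split(ds: ClassPairDataset, train_frac: float = 0.5
                       ) -> tuple[ClassPairDataset, ClassPairDataset]:
    """Chronological split within each trial and class.

    The first ``ceil(train_frac * n)`` seconds of every (trial, class) group
    go to train; every train timestamp precedes every test timestamp of the
    same group.
    """
    if not 0 < train_frac < 1:
        raise ValidationError("train_frac must lie in (0, 1)")
    for cls in ds.pair:
        count = int((ds.y == int(cls)).sum())
        if count < 4:
            raise ValidationError(
                f"class {cls.code} has only {count} seconds; need >= 4"
            )
    train_idx, test_idx = [], []
    for tid in np.unique(ds.trial_ids):
        for cls in ds.pair:
            idx = np.flatnonzero((ds.trial_ids == tid) & (ds.y == int(cls)))
            if idx.size == 0:
                continue
            idx = idx[np.argsort(ds.t[idx], kind="stable")]
            n_train = math.ceil(train_frac * idx.size)
            train_idx.extend(idx[:n_train])
            test_idx.extend(idx[n_train:])
    return (ds.take(np.sort(np.array(train_idx, dtype=int))),
            ds.take(np.sort(np.array(test_idx, dtype=int))))


def build_pair_dataset(
    labeled: list[tuple[Trial, LabelSeries, dict[str, FeatureSeries]]],
    feature_name: str,
    pair: tuple[FatigueClass, FatigueClass],
) -> ClassPairDataset:
    """Assemble per-second 1-D feature vectors for the two classes of a pair."""
    xs, ys, ts, tids = [], [], [], []
    subject = ""
    for k, (trial, labels, feats) in enumerate(labeled):
        if feature_name not in feats:
            raise ValidationError(
                f"feature {feature_name!r} missing; have {sorted(feats)}"
            )
        series = feats[feature_name]
        subject = subject or trial.subject_id
        tid = trial.trial_id or f"trial{k}"
        for t, v in zip(series.times, series.values):
            sec = int(np.floor(t - labels.start_time + 1e-9))
            if not 0 <= sec < len(labels):
                continue
            lab = labels.labels[sec]
            if lab in pair:
                xs.append([v])
                ys.append(int(lab))
                ts.append(t)
                tids.append(tid)
    if not xs:
        raise ValidationError(f"no seconds of classes {[c.code for c in pair]} found")
    return ClassPairDataset(pair=pair, X=np.array(xs), y=np.array(ys),
                            t=np.array(ts), trial_ids=np.array(tids),
                            subject_id=subject)


def run_pairwise(
    labeled_trials: list[tuple[Trial, LabelSeries]],
    feature_name: str,
    pair: tuple[FatigueClass, FatigueClass],
    features: list[dict[str, FeatureSeries]] | None = None,
    train_frac: float = 0.5,
    **extract_kwargs,
) -> tuple[float, ConfusionMatrix]:
    """Longitudinal pairwise evaluation for one subject's trials.

    Returns the percent of correctly classified test seconds and the
    confusion matrix in seconds (more severe class = actual +).
    """
    if features is None:
        features = [extract_all(trial, **extract_kwargs)
                    for trial, _ in labeled_trials]
    labeled = [(trial, labels, feats)
               for (trial, labels), feats in zip(labeled_trials, features)]
    ds = build_pair_dataset(labeled, feature_name, pair)
    train, test = longitudinal_split(ds, train_frac)
    less_severe, more_severe = pair
    model = fit_lda(train.X, train.y == int(less_severe),
                    positive_class=less_severe, negative_class=more_severe)
    decisions = test.X @ model.W + model.w0
    predicted = np.where(decisions >= 0, int(less_severe), int(more_severe))
    actual_pos = test.y == int(more_severe)
    predicted_pos = predicted == int(more_severe)
    cm = ConfusionMatrix(
        a=float(np.sum(~actual_pos & ~predicted_pos)),
        b=float(np.sum(~actual_pos & predicted_pos)),
        c=float(np.sum(actual_pos & ~predicted_pos)),
        d=float(np.sum(actual_pos & predicted_pos)),
    )
    percent_correct = 100.0 * (cm.a + cm.d) / cm.total
    return percent_correct, cm
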