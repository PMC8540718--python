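"""Supervised dataset handling and the two evaluation protocols.

The classifier is a radial-basis-function support vector machine with C and
γ chosen by exhaustive grid search under stratified cross-validation, after
per-feature scaling of the training rows to [−1, 1]. Two protocols are
implemented: repeated stratified 75/25 splits (10 repeats by default) and
leave-one-day-out, where each wear day in turn is held out for testing.

Classes holding less than 10 % of the samples are removed before training;
the removal is iterative because shares change as classes disappear. The
scaler and the grid search only ever see training rows.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.svm import SVC

from .ema_labeling import Mood
from .features import feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "SupervisedDataset",
    "RangeScaler",
    "SvmConfig",
    "EvalReport",
    "drop_rare_classes",
    "grid_search_svm",
    "evaluate_split",
    "evaluate_leave_one_day_out",
    "project_labels",
]


@dataclass
class SupervisedDataset:
    """Feature matrix with mood labels and per-row day indices."""

    X: np.ndarray
    y: np.ndarray
    day_index: np.ndarray
    feature_names: list[str]
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.day_index = np.asarray(self.day_index, dtype=np.int64)
        if not (self.X.shape[0] == self.y.size == self.day_index.size):
            raise ValueError("X, y and day_index must have aligned rows")
        if np.any(self.y < 0):
            raise ValueError("labels must be valid mood codes (no -1)")

    def __len__(self) -> int:
        return self.y.size

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    @property
    def class_names(self) -> list[str]:
        return [Mood(c).name.lower() for c in self.classes]

    def subset(self, mask: np.ndarray) -> "SupervisedDataset":
        return SupervisedDataset(
            X=self.X[mask],
            y=self.y[mask],
            day_index=self.day_index[mask],
            feature_names=self.feature_names,
            participant_id=self.participant_id,
        )

    @classmethod
    def from_table(cls, table: pd.DataFrame, participant_id: str = "") -> "SupervisedDataset":
        cols = [c for c in feature_columns() if c in table.columns]
        return cls(
            X=table[cols].to_numpy(dtype=float),
            y=table["label"].to_numpy(dtype=np.int64),
            day_index=table["day_index"].to_numpy(dtype=np.int64),
            feature_names=cols,
            participant_id=participant_id,
        )


def project_labels(dataset: SupervisedDataset, dimension: str) -> SupervisedDataset:
    """Replace circumplex labels by one-dimensional valence or arousal classes.

    ``dimension`` is ``"pleasure"`` (valence sign) or ``"arousal"``; each
    mood code is mapped to low/neutral/high (0/1/2) along that axis, which
    supports the single-dimension experiments.
    """
    signs = {
        Mood.PLEASURE: (1, 0), Mood.EXCITEMENT: (1, 1), Mood.AROUSAL: (0, 1),
        Mood.DISTRESS: (-1, 1), Mood.DISPLEASURE: (-1, 0), Mood.DEPRESSION: (-1, -1),
        Mood.SLEEPINESS: (0, -1), Mood.CONTENTMENT: (1, -1), Mood.NEUTRAL: (0, 0),
    }
    idx = 0 if dimension == "pleasure" else 1
    if dimension not in ("pleasure", "arousal"):
        raise ValueError("dimension must be 'pleasure' or 'arousal'")
    mapped = np.array([signs[Mood(c)][idx] + 1 for c in dataset.y], dtype=np.int64)
    out = SupervisedDataset(
        X=dataset.X, y=mapped, day_index=dataset.day_index,
        feature_names=dataset.feature_names, participant_id=dataset.participant_id,
    )
    return out


def drop_rare_classes(
    dataset: SupervisedDataset, min_fraction: float = 0.10
) -> SupervisedDataset:
    """Iteratively remove classes below ``min_fraction`` of remaining samples.

    Shares are recomputed after each removal (removing one class raises the
    others' shares), repeating until stable. Classes at exactly the
    threshold are kept.
    """
    ds = dataset
    while True:
        classes, counts = np.unique(ds.y, return_counts=True)
        shares = counts / counts.sum()
        below = classes[shares < min_fraction]
        if below.size == 0:
            break
        victim = below[np.argmin(counts[np.isin(classes, below)])]
        ds = ds.subset(ds.y != victim)
    if np.unique(ds.y).size < 2:
        raise ValueError("degenerate dataset: fewer than 2 classes survive the prevalence filter")
    return ds


@dataclass
class RangeScaler:
    """Per-feature affine map sending train min → −1 and train max → +1.

    Constant features map to 0; values outside the train range are not
    clipped, so test rows may exceed [−1, 1].
    """

    min_: np.ndarray | None = None
    max_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y=None) -> "RangeScaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        span = self.max_ - self.min_
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = 2.0 * (X[:, nz] - self.min_[nz]) / span[nz] - 1.0
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM search space: exponential grids and stratified CV folds."""

    c_grid: tuple[float, ...] = tuple(float(2.0**k) for k in range(-5, 17, 2))
    gamma_grid: tuple[float, ...] = tuple(float(2.0**k) for k in range(-15, 5, 2))
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not self.c_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


#: a small grid for quick synthetic-data evaluations
FAST_SVM = SvmConfig(
    c_grid=(1.0, 16.0, 256.0),
    gamma_grid=(2.0**-11, 2.0**-7, 2.0**-3),
    cv_folds=3,
)


def _fit_predict(X_train, y_train, X_test, C, gamma):
    scaler = RangeScaler().fit(X_train)
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(scaler.transform(X_train), y_train)
    return clf.predict(scaler.transform(X_test))


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    config: SvmConfig = SvmConfig(),
    seed: int = 0,
) -> tuple[float, float, float]:
    """Exhaustive (C, γ) grid search by stratified k-fold CV accuracy.

    Returns ``(C, gamma, cv_accuracy)``. Ties go to the smallest C, then the
    smallest γ (the grids are scanned in ascending order and only strictly
    better scores replace the incumbent). The [−1, 1] scaler is fitted
    inside each fold, so no test-fold statistics leak into training.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"class with {counts.min()} sample(s) cannot be stratified into "
            f"{config.cv_folds} folds; reduce cv_folds"
        )
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = (config.c_grid[0], config.gamma_grid[0], -1.0)
    for C, gamma in product(sorted(config.c_grid), sorted(config.gamma_grid)):
        correct = total = 0
        for tr, te in folds:
            pred = _fit_predict(X[tr], y[tr], X[te], C, gamma)
            correct += int(np.sum(pred == y[te]))
            total += te.size
        acc = correct / total
        if acc > best[2]:
            best = (C, gamma, acc)
    return best


@dataclass
class EvalReport:
    """Accuracy mean ± std and confusion matrices for one protocol."""

    protocol: str
    accuracy_mean: float  # percent
    accuracy_std: float  # percent
    confusion: np.ndarray  # summed over runs, rows = true class
    class_codes: list[int]
    class_names: list[str]
    per_run_accuracy: list[float] = field(default_factory=list)
    per_run_confusion: list[np.ndarray] = field(default_factory=list)
    chosen_params: list[tuple[float, float]] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "accuracy_mean_pct": self.accuracy_mean,
            "accuracy_std_pct": self.accuracy_std,
            "class_codes": list(map(int, self.class_codes)),
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
            "per_run_accuracy_pct": self.per_run_accuracy,
            "chosen_params": [[float(c), float(g)] for c, g in self.chosen_params],
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.class_names, columns=self.class_names)


def _run_report(protocol, accs, confusions, params, class_codes, seed) -> EvalReport:
    accs = [100.0 * a for a in accs]
    mean = float(np.mean(accs)) if accs else 0.0
    std = float(np.std(accs)) if len(accs) > 1 else 0.0
    total = np.sum(confusions, axis=0) if confusions else np.zeros((0, 0), dtype=int)
    return EvalReport(
        protocol=protocol,
        accuracy_mean=mean,
        accuracy_std=std,
        confusion=total,
        class_codes=list(map(int, class_codes)),
        class_names=[Mood(c).name.lower() if c in set(int(m) for m in Mood) else str(c)
                     for c in class_codes],
        per_run_accuracy=accs,
        per_run_confusion=confusions,
        chosen_params=params,
        seed=seed,
    )


def evaluate_split(
    dataset: SupervisedDataset,
    config: SvmConfig = SvmConfig(),
    train_frac: float = 0.75,
    repeats: int = 10,
    seed: int = 0,
    splits: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvalReport:
    """Repeated stratified hold-out evaluation (75/25 × 10 by default).

    Each repeat draws a fresh stratified split, runs the grid search on the
    training rows only, refits on the whole training set and scores the test
    rows. ``splits`` overrides the random splits with explicit
    (train_idx, test_idx) pairs, which is useful for leakage checks.
    """
    X, y = dataset.X, dataset.y
    classes = dataset.classes
    if splits is None:
        sss = StratifiedShuffleSplit(
            n_splits=repeats, train_size=train_frac, random_state=seed
        )
        splits = list(sss.split(X, y))
    accs, confs, params = [], [], []
    for r, (tr, te) in enumerate(splits):
        C, gamma, _ = grid_search_svm(X[tr], y[tr], config, seed=seed + r)
        pred = _fit_predict(X[tr], y[tr], X[te], C, gamma)
        accs.append(float(np.mean(pred == y[te])))
        confs.append(confusion_matrix(y[te], pred, labels=classes))
        params.append((C, gamma))
    return _run_report("split_75_25", accs, confs, params, classes, seed)


def evaluate_leave_one_day_out(
    dataset: SupervisedDataset,
    config: SvmConfig = SvmConfig(),
    seed: int = 0,
) -> EvalReport:
    """Hold out each wear day in turn; accuracy is the mean over days.

    Test samples whose class never occurs in the training days are
    necessarily misclassified and count as errors. Days for which no
    training class survives are skipped with a warning.
    """
    days = np.unique(dataset.day_index)
    if days.size < 2:
        raise ValueError("leave-one-day-out needs at least 2 distinct days")
    classes = dataset.classes
    accs, confs, params = [], [], []
    for d in days:
        te = dataset.day_index == d
        tr = ~te
        y_tr = dataset.y[tr]
        if np.unique(y_tr).size < 2:
            warnings.warn(f"day {d}: fewer than 2 training classes; skipped")
            continue
        C, gamma, _ = grid_search_svm(dataset.X[tr], y_tr, config, seed=seed + int(d))
        pred = _fit_predict(dataset.X[tr], y_tr, dataset.X[te], C, gamma)
        accs.append(float(np.mean(pred == dataset.y[te])))
        confs.append(confusion_matrix(dataset.y[te], pred, labels=classes))
        params.append((C, gamma))
    return _run_report("leave_one_day_out", accs, confs, params, classes, seed)
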