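"""Flight/ground phase labeling and the Gaussian-kernel SVM classifier.

A sample is labeled *ground* when the plate GRF is at least 0.05 BW and
*flight* otherwise; the classifier then learns to reproduce these labels from
the per-sensor acceleration vector magnitudes alone, so phase can be detected
in the field where no force plate exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

PHASE_THRESHOLD_BW = 0.05
FLIGHT, GROUND = 0, 1
PHASE_NAMES = {FLIGHT: "flight", GROUND: "ground"}


def label_phases(grf_bw: np.ndarray, threshold: float = PHASE_THRESHOLD_BW) -> np.ndarray:
    """Label each sample ground (1) or flight (0) from the plate GRF in BW.

    Ground iff ``grf_bw >= threshold``; the boundary value itself is assigned
    ground (conservative toward load detection).
    """
    grf_bw = np.asarray(grf_bw, dtype=float)
    if not np.all(np.isfinite(grf_bw)):
        raise ValueError("grf_bw contains non-finite values")
    return np.where(grf_bw >= threshold, GROUND, FLIGHT).astype(np.int8)


def phase_names(labels: np.ndarray) -> np.ndarray:
    return np.asarray([PHASE_NAMES[int(v)] for v in np.asarray(labels)])


def trial_phase_codes(trial) -> np.ndarray:
    """Integer phase codes for a trial, whether it stores names or codes."""
    phase = getattr(trial, "phase", None)
    if phase is None:
        phase = trial.phase_labels
    phase = np.asarray(phase)
    if phase.dtype.kind in "US":
        return np.where(phase == "flight", FLIGHT, GROUND).astype(np.int8)
    return phase.astype(np.int8)


@dataclass(frozen=True)
class ClassifierSpec:
    """Training-protocol constants for the phase SVM."""

    sensor_subset: tuple[str, ...] = ("sacrum",)
    n_train: int = 500
    n_test: int = 200
    cv_folds: int = 5
    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple[float | str, ...] = ("scale", 0.1, 1.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_test <= 0:
            raise ValueError("n_train and n_test must be positive")
        if not self.sensor_subset:
            raise ValueError("sensor subset must be non-empty")


def _magnitudes(trial, subset: tuple[str, ...]) -> np.ndarray:
    accel = trial.sensor_accel
    missing = [s for s in subset if s not in accel]
    if missing:
        raise KeyError(f"trial lacks sensors {missing}")
    return np.column_stack([np.linalg.norm(accel[s], axis=1) for s in subset])


def build_point_sets(train_datasets, test_datasets, spec: ClassifierSpec):
    """Assemble balanced, shuffled SVM train/test point sets.

    From each subject, an equal number of samples per jump type (the minimum
    cell count across all subject x jump-type cells of that split) is taken
    sequentially, the pool is shuffled with a seeded RNG, and the first
    ``n_train`` (train split) / ``n_test`` (test split) points are kept.
    Features are per-sensor acceleration magnitudes; targets are the
    0.05 BW-rule phase labels.
    """
    if not train_datasets or not test_datasets:
        raise ValueError("need at least one training and one held-out subject")
    rng = np.random.default_rng(spec.seed)

    def collect(datasets, n_points, what):
        cells = []
        for ds in datasets:
            by_type: dict[str, list] = {}
            for trial in ds.trials:
                by_type.setdefault(trial.landing_type, []).append(trial)
            for trials in by_type.values():
                X = np.concatenate([_magnitudes(t, spec.sensor_subset) for t in trials])
                y = np.concatenate([trial_phase_codes(t) for t in trials])
                cells.append((X, y))
        k = min(len(y) for _, y in cells)
        X = np.concatenate([X[:k] for X, _ in cells])
        y = np.concatenate([y[:k] for _, y in cells])
        if len(y) < n_points:
            raise ValueError(
                f"only {len(y)} balanced points available for the {what} set, "
                f"need {n_points} ({len(cells)} cells x {k} points)")
        order = rng.permutation(len(y))
        return X[order][:n_points], y[order][:n_points]

    X_train, y_train = collect(train_datasets, spec.n_train, "training")
    X_test, y_test = collect(test_datasets, spec.n_test, "test")
    return X_train, y_train, X_test, y_test


class PhaseClassifier(ClassifierMixin, BaseEstimator):
    """Gaussian-kernel SVM over acceleration magnitudes.

    Kernel width and regularisation are selected by k-fold cross-validation
    over a small logarithmic grid, as the training protocol prescribes.

    Attributes (after fit): ``svm_`` the refit best SVC, ``cv_accuracy_`` the
    mean CV accuracy of the selected model, ``best_params_`` the chosen grid
    point.
    """

    def __init__(self, C_grid=(0.1, 1.0, 10.0, 100.0),
                 gamma_grid=("scale", 0.1, 1.0, 10.0),
                 cv_folds: int = 5, seed: int = 0):
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_sensors)")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training points contain a single class; "
                             "both flight and ground samples are required")
        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                             random_state=self.seed)
        search = GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(self.C_grid), "gamma": list(self.gamma_grid)},
            cv=cv, scoring="accuracy", n_jobs=None)
        search.fit(X, y)
        self.svm_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.cv_accuracy_ = float(search.best_score_)
        self.classes_ = classes
        return self

    def predict(self, X):
        check_is_fitted(self, "svm_")
        return self.svm_.predict(np.asarray(X, dtype=float))


def train_classifier(X_train, y_train, spec: ClassifierSpec) -> PhaseClassifier:
    """Fit the phase SVM under a :class:`ClassifierSpec`."""
    clf = PhaseClassifier(C_grid=spec.C_grid, gamma_grid=spec.gamma_grid,
                          cv_folds=spec.cv_folds, seed=spec.seed)
    return clf.fit(X_train, y_train)


@dataclass
class ConfusionMatrix:
    """2x2 phase confusion counts with per-class and overall percent correct."""

    counts: np.ndarray  # rows: true (flight, ground); cols: predicted
    percent_overall: float
    percent_flight: float
    percent_ground: float
    n: int = 0

    def __post_init__(self) -> None:
        self.n = int(self.counts.sum())


def evaluate_classifier(model, X_test, y_test) -> ConfusionMatrix:
    """Confusion matrix of predicted vs true phase on held-out points."""
    pred = model.predict(X_test)
    y_test = np.asarray(y_test)
    counts = _sk_confusion(y_test, pred, labels=[FLIGHT, GROUND])

    def pct(mask_true, value):
        m = int(mask_true.sum())
        return 100.0 * value / m if m else float("nan")

    return ConfusionMatrix(
        counts=counts,
        percent_overall=100.0 * float(np.trace(counts)) / len(y_test),
        percent_flight=pct(y_test == FLIGHT, counts[0, 0]),
        percent_ground=pct(y_test == GROUND, counts[1, 1]),
    )
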