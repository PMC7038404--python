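"""The combined phase-gated GRF model.

A fitted bundle holds one Gaussian-kernel SVM phase classifier and two
phase-specific regression networks sharing a sensor subset and feature
convention.  At prediction time every sample is classified flight/ground from
its acceleration magnitudes and routed to the matching network; the outputs
are concatenated in time order with no smoothing across the phase switch —
the model is strictly pointwise, so it could run sample-by-sample in real
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy.signal import medfilt
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted

from .phase import (FLIGHT, GROUND, PHASE_THRESHOLD_BW, PhaseClassifier,
                    label_phases)
from .regression import GRFNetwork, architecture_search

BUNDLE_FORMAT_VERSION = 1


def trial_features(trial, sensor_subset, convention: str = "components") -> np.ndarray:
    """Per-sample feature matrix for a trial.

    ``components`` stacks the tri-axial channels of each subset sensor
    (3 columns per sensor, in subset order); ``magnitudes`` uses one vector-
    magnitude column per sensor.
    """
    accel = trial.sensor_accel
    missing = [s for s in sensor_subset if s not in accel]
    if missing:
        raise KeyError(f"trial lacks required sensor(s): {', '.join(missing)}")
    if convention == "components":
        return np.column_stack([np.asarray(accel[s], dtype=float)
                                for s in sensor_subset])
    if convention == "magnitudes":
        return np.column_stack([np.linalg.norm(accel[s], axis=1)
                                for s in sensor_subset])
    raise ValueError(f"unknown feature convention {convention!r}")


def trial_grf_100(trial) -> np.ndarray:
    """The trial's reference GRF on the 100 Hz grid, in BW."""
    grf = getattr(trial, "grf_bw_sensor", None)
    if grf is None:
        grf = trial.grf_bw
    return np.asarray(grf, dtype=float)


def _magnitudes_from_components(X: np.ndarray) -> np.ndarray:
    n, w = X.shape
    if w % 3:
        raise ValueError("component feature width must be a multiple of 3")
    return np.linalg.norm(X.reshape(n, w // 3, 3), axis=2)


class PhaseGatedGRFEstimator(RegressorMixin, BaseEstimator):
    """Classifier-gated pair of regression networks, as one estimator.

    ``fit(X, y)`` takes per-sample accelerometer features ``X`` (tri-axial
    components grouped in threes per sensor, or magnitudes) and the plate GRF
    ``y`` in BW.  Phase labels are derived from ``y`` by the 0.05 BW rule; the
    SVM is trained on acceleration magnitudes of a seeded random subsample of
    at most ``n_svm_train`` points, and each network on the samples of its
    phase.  ``predict(X)`` routes every sample through exactly one network.
    """

    def __init__(self, classifier=None, flight_net=None, ground_net=None,
                 feature_convention: str = "components",
                 n_svm_train: int = 500, threshold: float = PHASE_THRESHOLD_BW,
                 smooth_window: int | None = None, seed: int = 0):
        self.classifier = classifier
        self.flight_net = flight_net
        self.ground_net = ground_net
        self.feature_convention = feature_convention
        self.n_svm_train = n_svm_train
        self.threshold = threshold
        self.smooth_window = smooth_window
        self.seed = seed

    def _svm_features(self, X: np.ndarray) -> np.ndarray:
        if self.feature_convention == "components":
            return _magnitudes_from_components(X)
        return X  # magnitudes already

    def fit(self, X, y, svm_points: tuple[np.ndarray, np.ndarray] | None = None):
        """Fit all three sub-models.

        ``svm_points`` optionally supplies pre-built (magnitude-feature,
        label) training points for the classifier — the study protocol builds
        these balanced across subjects and jump types — otherwise a seeded
        subsample of the regression data is used.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        labels = label_phases(y, self.threshold)
        if not (np.any(labels == FLIGHT) and np.any(labels == GROUND)):
            raise ValueError("training data must contain both phases")

        clf = clone(self.classifier) if self.classifier is not None \
            else PhaseClassifier(seed=self.seed)
        if svm_points is not None:
            clf.fit(*svm_points)
        else:
            mags = self._svm_features(X)
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(X))[:min(self.n_svm_train, len(X))]
            if len(np.unique(labels[order])) < 2:  # tiny-data guard
                order = np.arange(len(X))
            clf.fit(mags[order], labels[order])
        self.classifier_ = clf

        fl = clone(self.flight_net) if self.flight_net is not None \
            else GRFNetwork(hidden_layer_sizes=(4,), seed=self.seed)
        gr = clone(self.ground_net) if self.ground_net is not None \
            else GRFNetwork(hidden_layer_sizes=(8,), seed=self.seed)
        self.flight_net_ = fl.fit(X[labels == FLIGHT], y[labels == FLIGHT])
        self.ground_net_ = gr.fit(X[labels == GROUND], y[labels == GROUND])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_phase(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        X = np.asarray(X, dtype=float)
        phase = np.asarray(self.classifier_.predict(self._svm_features(X)),
                           dtype=np.int8)
        if self.smooth_window:
            phase = medfilt(phase.astype(float),
                            kernel_size=self.smooth_window).astype(np.int8)
        return phase

    def predict(self, X):
        check_is_fitted(self, "flight_net_")
        X = np.asarray(X, dtype=float)
        phase = self.predict_phase(X)
        flight_pred = self.flight_net_.predict(X)
        ground_pred = self.ground_net_.predict(X)
        return np.where(phase == GROUND, ground_pred, flight_pred)


@dataclass
class ModelBundle:
    """A deployable combined model with its training conventions."""

    landing_type: str
    sensor_subset: tuple[str, ...]
    estimator: PhaseGatedGRFEstimator
    feature_convention: str = "components"
    format_version: int = BUNDLE_FORMAT_VERSION
    search_tables: dict = field(default_factory=dict)


def fit_bundle(datasets, landing_type: str, sensor_subset,
               feature_convention: str = "components",
               search: bool = False, search_kwargs: dict | None = None,
               classifier: PhaseClassifier | None = None,
               flight_layers: tuple[int, ...] = (4,),
               ground_layers: tuple[int, ...] = (8,),
               n_svm_train: int = 500, seed: int = 0,
               svm_points: tuple | None = None) -> ModelBundle:
    """Train a combined model for one landing type on a list of
    :class:`~grfest.simulate.SubjectDataset`.

    With ``search=True`` the network architectures are chosen by
    :func:`~grfest.regression.architecture_search` (keyword arguments in
    ``search_kwargs`` control the candidate grid); otherwise the fixed
    ``flight_layers``/``ground_layers`` are used.
    """
    sensor_subset = tuple(sensor_subset)
    trials = [t for ds in datasets for t in ds.trials
              if t.landing_type == landing_type]
    if not trials:
        raise ValueError(f"no {landing_type} trials in the datasets")
    X = np.concatenate([trial_features(t, sensor_subset, feature_convention)
                        for t in trials])
    y = np.concatenate([trial_grf_100(t) for t in trials])
    labels = label_phases(y)

    tables: dict = {}
    if search:
        kw = dict(search_kwargs or {})
        spec_f, _, tables["flight"] = architecture_search(
            X[labels == FLIGHT], y[labels == FLIGHT], "flight", seed=seed, **kw)
        spec_g, _, tables["ground"] = architecture_search(
            X[labels == GROUND], y[labels == GROUND], "ground", seed=seed, **kw)
        flight_layers = spec_f.hidden_layers
        ground_layers = spec_g.hidden_layers

    est = PhaseGatedGRFEstimator(
        classifier=classifier,
        flight_net=GRFNetwork(hidden_layer_sizes=flight_layers, seed=seed),
        ground_net=GRFNetwork(hidden_layer_sizes=ground_layers, seed=seed),
        feature_convention=feature_convention, n_svm_train=n_svm_train,
        seed=seed)
    est.fit(X, y, svm_points=svm_points)
    return ModelBundle(landing_type=landing_type, sensor_subset=sensor_subset,
                       estimator=est, feature_convention=feature_convention,
                       search_tables=tables)


def estimate_profile(bundle: ModelBundle, trial):
    """Estimate the whole-activity GRF profile of a trial.

    Returns ``(grf_est_bw, phase_pred)`` on the trial's 100 Hz grid.
    """
    X = trial_features(trial, bundle.sensor_subset, bundle.feature_convention)
    est = bundle.estimator
    return est.predict(X), est.predict_phase(X)


def peak_grf(estimated_bw, phase_pred) -> float:
    """Peak GRF: the maximum estimated value within the ground phase."""
    estimated_bw = np.asarray(estimated_bw, dtype=float)
    phase_pred = np.asarray(phase_pred)
    ground = phase_pred == GROUND
    if not np.any(ground):
        raise ValueError("no ground phase detected; peak GRF undefined")
    return float(np.max(estimated_bw[ground]))


def landing_peaks(estimated_bw, phase_pred) -> list[float]:
    """Per-landing peaks for multi-jump recordings: the recording is split at
    flight intervals and the peak of each post-flight ground segment reported."""
    estimated_bw = np.asarray(estimated_bw, dtype=float)
    phase_pred = np.asarray(phase_pred)
    peaks = []
    current: list[float] = []
    seen_flight = False
    for value, ph in zip(estimated_bw, phase_pred):
        if ph == FLIGHT:
            if current:
                peaks.append(max(current))
                current = []
            seen_flight = True
        elif seen_flight:
            current.append(float(value))
    if current:
        peaks.append(max(current))
    return peaks


def save_bundle(bundle: ModelBundle, path) -> None:
    joblib.dump({"format_version": BUNDLE_FORMAT_VERSION, "bundle": bundle}, path)


def load_bundle(path) -> ModelBundle:
    payload = joblib.load(path)
    if payload.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise ValueError("unsupported bundle format version")
    return payload["bundle"]
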