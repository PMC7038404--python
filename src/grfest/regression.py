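"""Phase-specific feed-forward GRF regression networks.

Each network maps a single time point's accelerometer features (tri-axial
components, or magnitudes, per sensor) to GRF in body weights — no history,
so prediction is strictly pointwise.  The flight network sees only airborne
samples (GRF truth is zero); the ground network only contact samples.
Architecture is selected by exhaustive search over hidden-layer sizes
between 1 and 35 neurons: one hidden layer for flight, one or two for ground.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

NEURON_MIN, NEURON_MAX = 1, 35


@dataclass(frozen=True)
class NetworkSpec:
    """One candidate network architecture for a given jump phase."""

    phase: str  # 'flight' or 'ground'
    hidden_layers: tuple[int, ...] = (8,)
    activation: str = "tanh"
    max_epochs: int = 500
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in ("flight", "ground"):
            raise ValueError("phase must be 'flight' or 'ground'")
        n = len(self.hidden_layers)
        if self.phase == "flight" and n != 1:
            raise ValueError("flight networks use exactly one hidden layer")
        if self.phase == "ground" and n not in (1, 2):
            raise ValueError("ground networks use one or two hidden layers")
        for size in self.hidden_layers:
            if not (NEURON_MIN <= size <= NEURON_MAX):
                raise ValueError(
                    f"layer size {size} outside [{NEURON_MIN}, {NEURON_MAX}]")

    @property
    def total_neurons(self) -> int:
        return sum(self.hidden_layers)


class GRFNetwork(RegressorMixin, BaseEstimator):
    """Small feed-forward regressor: tanh hidden units, linear output,
    L-BFGS training from seeded random initial weights.

    A seeded fraction of the samples is held back as a validation split;
    its RMSE (``validation_rmse_``) is the model-selection score used by
    :func:`architecture_search`.
    """

    def __init__(self, hidden_layer_sizes=(8,), activation="tanh",
                 max_iter: int = 500, validation_fraction: float = 0.15,
                 seed: int = 0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.max_iter = max_iter
        self.validation_fraction = validation_fraction
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) == 0:
            raise ValueError("no training samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite training data")
        n_weights = self._count_weights(X.shape[1])
        if len(X) < 10 * n_weights:
            import warnings
            warnings.warn(f"{len(X)} samples for {n_weights} weights "
                          "(< 10x); the fit may overfit")
        if self.validation_fraction > 0 and len(X) >= 10:
            X_tr, X_val, y_tr, y_val = train_test_split(
                X, y, test_size=self.validation_fraction, random_state=self.seed)
        else:
            X_tr, X_val, y_tr, y_val = X, X, y, y
        # standardized inputs keep L-BFGS well conditioned; tight tol because
        # the flight target is ~0 BW and a loose stop leaves a visible bias
        self.net_ = make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=tuple(self.hidden_layer_sizes),
                activation=self.activation, solver="lbfgs", tol=1e-7,
                max_iter=self.max_iter, random_state=self.seed))
        self.net_.fit(X_tr, y_tr)
        self.train_rmse_ = _rmse(self.net_.predict(X_tr), y_tr)
        self.validation_rmse_ = _rmse(self.net_.predict(X_val), y_val)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        out = self.net_.predict(np.atleast_2d(X))
        return float(out[0]) if single else out

    def _count_weights(self, n_in: int) -> int:
        sizes = [n_in, *self.hidden_layer_sizes, 1]
        return sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:]))


def _rmse(pred, truth) -> float:
    return float(np.sqrt(np.mean((np.asarray(pred) - np.asarray(truth)) ** 2)))


def train_network(X, y, spec: NetworkSpec) -> GRFNetwork:
    """Fit one network under a :class:`NetworkSpec`."""
    net = GRFNetwork(hidden_layer_sizes=spec.hidden_layers,
                     activation=spec.activation, max_iter=spec.max_epochs,
                     validation_fraction=spec.validation_fraction,
                     seed=spec.seed)
    return net.fit(X, y)


def candidate_architectures(phase: str, one_layer_stride: int = 1,
                            two_layer_stride: int = 2,
                            include_two_layer: bool = True,
                            sizes: tuple[int, ...] | None = None
                            ) -> list[tuple[int, ...]]:
    """Enumerate the hidden-layer candidates for a phase.

    Flight: single layers of 1..35.  Ground: the same single layers plus, when
    enabled, all two-layer combinations on a (possibly strided) grid.  A
    stride of 1 reproduces the full 35 + 35^2 ground space.
    """
    if sizes is None:
        one = tuple(range(NEURON_MIN, NEURON_MAX + 1, one_layer_stride))
        two = tuple(range(NEURON_MIN, NEURON_MAX + 1, two_layer_stride))
    else:
        one = two = tuple(sizes)
    cands: list[tuple[int, ...]] = [(s,) for s in one]
    if phase == "ground" and include_two_layer:
        cands += [(a, b) for a, b in itertools.product(two, two)]
    return cands


def architecture_search(X, y, phase: str, seed: int = 0,
                        max_epochs: int = 500,
                        one_layer_stride: int = 1, two_layer_stride: int = 2,
                        include_two_layer: bool = True,
                        sizes: tuple[int, ...] | None = None):
    """Exhaustively train the candidate architectures and pick the best.

    Returns ``(best_spec, best_net, table)`` where ``table`` is a DataFrame of
    (architecture, total neurons, train RMSE, validation RMSE) sorted by
    validation RMSE; ties are broken toward fewer total neurons.
    """
    cands = candidate_architectures(phase, one_layer_stride, two_layer_stride,
                                    include_two_layer, sizes)
    rows, nets = [], {}
    for layers in cands:
        spec = NetworkSpec(phase=phase, hidden_layers=layers, seed=seed,
                           max_epochs=max_epochs)
        net = train_network(X, y, spec)
        nets[layers] = (spec, net)
        rows.append({"hidden_layers": layers, "total_neurons": spec.total_neurons,
                     "train_rmse": net.train_rmse_,
                     "validation_rmse": net.validation_rmse_})
    table = pd.DataFrame(rows).sort_values(
        ["validation_rmse", "total_neurons", "hidden_layers"],
        ignore_index=True)
    best_layers = tuple(table.loc[0, "hidden_layers"])
    best_spec, best_net = nets[best_layers]
    return best_spec, best_net, table
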