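"""Second-stage "ratios" classifier and the combined two-stage pipeline.

The shallow dense network consumes the 9-component band-ratio record (the
last component being the first-stage CNN class).  Internally the eight
numeric components are robust-standardized with training-set statistics
and the class component is expanded to 7 indicator inputs — an
integer-coded category would impose a false ordering on a dense net — but
the record at the interface stays 9 components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_array

from .core import WavenumberAxis, canonical_axis
from .cnn import SpectralCNNClassifier, one_hot
from .features import feature_matrix
from .nn import Dense, SequentialNet

__all__ = [
    "DenseConfig",
    "RatioDenseClassifier",
    "TwoStageClassifier",
    "train_dense",
    "predict_combined",
]


@dataclass(frozen=True)
class DenseConfig:
    """Dense-classifier settings (reference protocol defaults)."""

    n_layers: int = 3
    epochs: int = 17
    batch_size: int = 9
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


class RatioDenseClassifier(ClassifierMixin, BaseEstimator):
    """Shallow fully connected classifier over 9-component ratio records.

    ``hidden_units`` lists the hidden widths; the layer count is
    ``len(hidden_units) + 1`` (hidden layers plus the softmax output), so
    the default ``(32, 16)`` gives the reference 3-layer head.
    """

    def __init__(
        self,
        hidden_units: tuple = (32, 16),
        n_classes: int = 7,
        epochs: int = 17,
        batch_size: int = 9,
        learning_rate: float = 1e-3,
        random_state: int | None = None,
    ) -> None:
        self.hidden_units = hidden_units
        self.n_classes = n_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    @property
    def n_layers(self) -> int:
        return len(self.hidden_units) + 1

    def _expand(self, R: np.ndarray) -> np.ndarray:
        """Robust-standardize numeric components, one-hot expand the class.

        Median/IQR scaling with +-10 clipping keeps the occasional wild
        ratio (near-zero band denominator on a weak spectrum) from
        dominating the input scale.
        """
        numeric = np.clip((R[:, :8] - self.center_) / self.scale_, -10.0, 10.0)
        classes = one_hot(R[:, 8].astype(int), self.n_classes)
        return np.hstack([numeric, classes]).astype(np.float32)

    def fit(self, R: np.ndarray, y: np.ndarray) -> "RatioDenseClassifier":
        R = check_array(R, dtype=float, ensure_2d=True)
        if R.shape[1] != 9:
            raise ValueError(f"expected 9-component records, got {R.shape[1]}")
        y = np.asarray(y, dtype=int)
        self.center_ = np.median(R[:, :8], axis=0)
        q75, q25 = np.percentile(R[:, :8], [75, 25], axis=0)
        iqr = (q75 - q25) / 1.349  # IQR of a normal ~ 1.349 sigma
        std = R[:, :8].std(axis=0)
        self.scale_ = np.where(iqr > 0, iqr, np.where(std > 0, std, 1.0))
        X = self._expand(R)
        rng = np.random.default_rng(self.random_state)
        layers: list = []
        n_in = X.shape[1]
        for width in self.hidden_units:
            layers.append(Dense(n_in, width, rng, activation="relu"))
            n_in = width
        layers.append(Dense(n_in, self.n_classes, rng, activation="linear"))
        self.net_ = SequentialNet(layers)
        self.history_ = self.net_.fit(
            X,
            one_hot(y, self.n_classes),
            epochs=self.epochs,
            batch_size=self.batch_size,
            rng=rng,
            lr=self.learning_rate,
        )
        self.classes_ = np.arange(self.n_classes)
        self.n_features_in_ = 9
        return self

    def predict_proba(self, R: np.ndarray) -> np.ndarray:
        R = check_array(R, dtype=float, ensure_2d=True)
        if R.shape[1] != 9:
            raise ValueError(f"expected 9-component records, got {R.shape[1]}")
        return self.net_.predict_proba(self._expand(R))

    def predict(self, R: np.ndarray) -> np.ndarray:
        return self.predict_proba(R).argmax(axis=1)


class TwoStageClassifier(ClassifierMixin, BaseEstimator):
    """CNN over spectra followed by the dense classifier over ratio records.

    ``fit`` trains both stages on the same labeled spectra: stage 2 learns
    from ground-truth labels, with its ``cnn_class`` feature taken from
    stage-1 predictions so that training matches deployment.
    """

    def __init__(
        self,
        cnn: SpectralCNNClassifier | None = None,
        dense: RatioDenseClassifier | None = None,
        axis: WavenumberAxis | None = None,
    ) -> None:
        self.cnn = cnn
        self.dense = dense
        self.axis = axis

    def _axis(self) -> WavenumberAxis:
        return self.axis if self.axis is not None else canonical_axis()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TwoStageClassifier":
        y = np.asarray(y, dtype=int)
        self.cnn_ = clone(self.cnn) if self.cnn is not None else SpectralCNNClassifier()
        self.dense_ = clone(self.dense) if self.dense is not None else RatioDenseClassifier()
        if self.cnn_.n_classes != self.dense_.n_classes:
            raise ValueError(
                "class-scheme mismatch: CNN predicts "
                f"{self.cnn_.n_classes} classes, dense expects {self.dense_.n_classes}"
            )
        self.cnn_.fit(X, y)
        cnn_classes = self.cnn_.predict(X)
        records = feature_matrix(X, self._axis(), cnn_classes)
        self.dense_.fit(records, y)
        self.classes_ = self.cnn_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_combined(self.cnn_, self.dense_, X, self._axis())

    def predict_stage1(self, X: np.ndarray) -> np.ndarray:
        return self.cnn_.predict(X)


def train_dense(
    records: np.ndarray, labels: np.ndarray, cfg: DenseConfig = DenseConfig()
) -> RatioDenseClassifier:
    """Fit the shallow dense classifier from a config."""
    model = RatioDenseClassifier(
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        random_state=cfg.seed,
    )
    if model.n_layers != cfg.n_layers:
        # honour a non-default layer count by adjusting the hidden stack
        hidden = tuple(32 // (2**i) for i in range(cfg.n_layers - 1))
        model.set_params(hidden_units=hidden)
    return model.fit(records, labels)


def predict_combined(
    cnn_model: SpectralCNNClassifier,
    dense_model: RatioDenseClassifier,
    X: np.ndarray,
    axis: WavenumberAxis | None = None,
) -> np.ndarray:
    """Stage-1 CNN class, then stage-2 final class, one per input spectrum."""
    if cnn_model.n_classes != dense_model.n_classes:
        raise ValueError(
            "class-scheme mismatch: CNN predicts "
            f"{cnn_model.n_classes} classes, dense expects {dense_model.n_classes}"
        )
    if axis is None:
        axis = canonical_axis()
    cnn_classes = cnn_model.predict(X)
    records = feature_matrix(np.asarray(X, dtype=float), axis, cnn_classes)
    return dense_model.predict(records)
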