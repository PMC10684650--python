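"""First-stage spectral classifier: a 1-D CNN over preprocessed spectra.

The reference architecture has 13 one-dimensional convolutional layers for
feature extraction (four blocks of 4+3+3+3 layers, kernel sizes 7/5/3/3,
max-pool 2 after each block) followed by 3 fully connected layers ending in
a 7-way softmax.  Glorot-uniform initialization, Adam, and categorical
cross-entropy throughout; all randomness (initialization and shuffling)
flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_array

from .core import CANONICAL_LEN
from .nn import Conv1D, Dense, Flatten, MaxPool1D, SequentialNet

__all__ = [
    "CNNConfig",
    "SpectralCNNClassifier",
    "one_hot",
    "from_one_hot",
    "split_train_test",
    "build_cnn",
    "train_cnn",
    "predict_cnn",
]


@dataclass(frozen=True)
class CNNConfig:
    """Training configuration (reference protocol defaults)."""

    n_conv_layers: int = 13
    n_dense_layers: int = 3
    n_classes: int = 7
    input_len: int = CANONICAL_LEN
    epochs: int = 40
    batch_size: int = 105
    split_train: float = 0.7
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split_train < 1.0):
            raise ValueError("split_train must lie strictly between 0 and 1")
        if self.n_conv_layers < 4 or self.n_dense_layers < 1:
            raise ValueError("need at least 4 conv layers (one per block) and 1 dense layer")


def one_hot(labels, n_classes: int = 7) -> np.ndarray:
    """Integer labels 0..n_classes-1 -> one-hot rows."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise ValueError("labels must be 1-D")
    if np.any((labels < 0) | (labels >= n_classes)):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def from_one_hot(matrix: np.ndarray) -> np.ndarray:
    """Inverse of :func:`one_hot`."""
    return np.asarray(matrix).argmax(axis=1)


def split_train_test(
    records: np.ndarray,
    labels: np.ndarray,
    split_train: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
):
    """Disjoint, exhaustive train/test split; train size = round(f * n)."""
    records = np.asarray(records)
    labels = np.asarray(labels)
    if records.shape[0] == 0:
        raise ValueError("cannot split an empty record set")
    n_train = int(round(split_train * records.shape[0]))
    n_train = min(max(n_train, 1), records.shape[0] - 1)
    return train_test_split(
        records,
        labels,
        train_size=n_train,
        random_state=seed,
        stratify=labels if stratified else None,
        shuffle=True,
    )


def _block_schedule(n_conv_layers: int) -> tuple[int, ...]:
    """Distribute conv layers over 4 pooled blocks, extras to early blocks."""
    base, extra = divmod(n_conv_layers, 4)
    return tuple(base + (1 if i < extra else 0) for i in range(4))


class SpectralCNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the 1-D spectral CNN.

    Parameters
    ----------
    n_conv_layers, n_dense_layers:
        Architecture audit counts; the convolutional layers are spread over
        four max-pooled blocks with the ``conv_filters``/``conv_kernels``
        schedules, and the dense head uses ``dense_units`` hidden widths
        followed by the ``n_classes``-way softmax output layer.
    epochs, batch_size, learning_rate:
        Adam mini-batch training settings.
    random_state:
        Seeds initialization and epoch shuffling; same seed, same model.
    """

    def __init__(
        self,
        n_conv_layers: int = 13,
        n_dense_layers: int = 3,
        n_classes: int = 7,
        input_len: int = CANONICAL_LEN,
        conv_filters: tuple = (8, 16, 32, 64),
        conv_kernels: tuple = (7, 5, 3, 3),
        dense_units: tuple = (256, 64),
        epochs: int = 40,
        batch_size: int = 105,
        learning_rate: float = 1e-3,
        random_state: int | None = None,
    ) -> None:
        self.n_conv_layers = n_conv_layers
        self.n_dense_layers = n_dense_layers
        self.n_classes = n_classes
        self.input_len = input_len
        self.conv_filters = conv_filters
        self.conv_kernels = conv_kernels
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    # -- architecture ---------------------------------------------------

    def _build(self, rng: np.random.Generator) -> SequentialNet:
        if len(self.dense_units) != self.n_dense_layers - 1:
            raise ValueError(
                "dense_units must list the hidden widths: "
                f"{self.n_dense_layers - 1} values expected"
            )
        blocks = _block_schedule(self.n_conv_layers)
        length = self.input_len
        layers: list = []
        in_ch = 1
        for block, (n_layers, filters, kernel) in enumerate(
            zip(blocks, self.conv_filters, self.conv_kernels)
        ):
            for _ in range(n_layers):
                layers.append(Conv1D(in_ch, filters, kernel, rng))
                in_ch = filters
            if length % 2:
                raise ValueError(
                    f"input_len {self.input_len} incompatible with the pooling "
                    f"schedule (odd length {length} at block {block})"
                )
            layers.append(MaxPool1D(2))
            length //= 2
        layers.append(Flatten())
        n_in = length * in_ch
        for width in self.dense_units:
            layers.append(Dense(n_in, width, rng, activation="relu"))
            n_in = width
        layers.append(Dense(n_in, self.n_classes, rng, activation="linear"))
        return SequentialNet(layers)

    # -- estimator API ---------------------------------------------------

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = check_array(X, dtype=np.float32, ensure_2d=True)
        if X.shape[1] != self.input_len:
            raise ValueError(
                f"expected spectra of length {self.input_len}, got {X.shape[1]}"
            )
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SpectralCNNClassifier":
        X = self._validate_X(X)
        y = np.asarray(y, dtype=int)
        Y = one_hot(y, self.n_classes)
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build(rng)
        self.history_ = self.net_.fit(
            X[:, :, None],
            Y,
            epochs=self.epochs,
            batch_size=self.batch_size,
            rng=rng,
            lr=self.learning_rate,
        )
        self.classes_ = np.arange(self.n_classes)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._validate_X(X)
        return self.net_.predict_proba(X[:, :, None])

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax breaks ties toward the lowest class index
        return self.predict_proba(X).argmax(axis=1)


def build_cnn(cfg: CNNConfig) -> SpectralCNNClassifier:
    """An untrained estimator configured from a :class:`CNNConfig`."""
    return SpectralCNNClassifier(
        n_conv_layers=cfg.n_conv_layers,
        n_dense_layers=cfg.n_dense_layers,
        n_classes=cfg.n_classes,
        input_len=cfg.input_len,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        random_state=cfg.seed,
    )


def train_cnn(spectra: np.ndarray, labels: np.ndarray, cfg: CNNConfig = CNNConfig()):
    """Split per the config, train, and report held-out accuracy.

    Returns ``(model, test_accuracy)``; the per-epoch history is on
    ``model.history_``.
    """
    X_train, X_test, y_train, y_test = split_train_test(
        spectra, labels, cfg.split_train, seed=cfg.seed
    )
    model = build_cnn(cfg).fit(X_train, y_train)
    accuracy = float(np.mean(model.predict(X_test) == y_test))
    return model, accuracy


def predict_cnn(model: SpectralCNNClassifier, spectra: np.ndarray):
    """Per-spectrum class probabilities and argmax classes."""
    proba = model.predict_proba(spectra)
    return proba, proba.argmax(axis=1)
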