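"""The two heatmap classifiers and their training protocol.

Both models consume one subject's heatmap (1 row x 28 time bins x 3
channels, fed to the layers as width x channels).  The CNN stacks two
convolution blocks (32 then 64 filters, ReLU, same padding, each with
time-axis max pooling), a 128-unit dense layer and a 5-class softmax.
The FCN is an encoder-decoder: 32/64-filter conv+pool blocks, a
128-filter bottleneck, two upsample+conv steps (64 then 32 filters)
restoring the input width, and a 1x1 convolution giving a per-bin
distribution over the 5 diagnostic groups; subject-level predictions
average the per-bin probabilities.

Training: Adam (lr 0.001), sparse categorical cross-entropy, batch 32,
70 epochs (CNN) / 50 epochs (FCN), subject-level stratified 80:20
split.  Heatmap intensities on the [0, 255] scale are divided by 255
before entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from trajheat.nn import Conv1D, Dense, Flatten, MaxPool1D, ReLU, Sequential, Upsample1D, softmax

__all__ = [
    "CnnSpec", "FcnSpec", "TrainConfig", "TrainedModel",
    "build_cnn", "build_fcn", "stratified_split", "train_model",
    "predict", "architecture_audit", "prepare_inputs",
]

N_CLASSES = 5


@dataclass(frozen=True)
class CnnSpec:
    input_width: int = 28
    input_channels: int = 3
    conv_filters: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    dense_units: int = 128
    n_classes: int = N_CLASSES


@dataclass(frozen=True)
class FcnSpec:
    input_width: int = 28
    input_channels: int = 3
    encoder_filters: tuple[int, int] = (32, 64)
    bottleneck_filters: int = 128
    decoder_filters: tuple[int, int] = (64, 32)
    kernel_size: int = 3
    n_classes: int = N_CLASSES


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 70
    batch_size: int = 32
    learning_rate: float = 0.001
    test_fraction: float = 0.2
    seed: int = 0
    mask_loss: bool = False  # FCN: weight per-bin loss by the availability mask

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.epochs <= 0:
            raise ValueError("epochs must be > 0")


#: Published per-architecture epoch counts.
CNN_EPOCHS = 70
FCN_EPOCHS = 50


@dataclass
class TrainedModel:
    model: Sequential
    history: dict
    config: TrainConfig
    arch: str  # "cnn" | "fcn"
    feature_name: str = ""


def build_cnn(spec: CnnSpec = CnnSpec(), seed: int = 0) -> Sequential:
    """CNN: [conv32-relu-pool, conv64-relu-pool, flatten, dense128-relu, dense5]."""
    rng = np.random.default_rng([seed, 0])
    f1, f2 = spec.conv_filters
    pooled = spec.input_width // 2 // 2
    return Sequential([
        Conv1D(spec.input_channels, f1, spec.kernel_size, rng=rng),
        ReLU(),
        MaxPool1D(2),
        Conv1D(f1, f2, spec.kernel_size, rng=rng),
        ReLU(),
        MaxPool1D(2),
        Flatten(),
        Dense(pooled * f2, spec.dense_units, rng=rng),
        ReLU(),
        Dense(spec.dense_units, spec.n_classes, rng=rng),
    ])


def build_fcn(spec: FcnSpec = FcnSpec(), seed: int = 0) -> Sequential:
    """FCN encoder-decoder with a per-bin 5-class head (width preserved)."""
    rng = np.random.default_rng([seed, 1])
    e1, e2 = spec.encoder_filters
    d1, d2 = spec.decoder_filters
    return Sequential([
        Conv1D(spec.input_channels, e1, spec.kernel_size, rng=rng),
        ReLU(),
        MaxPool1D(2),
        Conv1D(e1, e2, spec.kernel_size, rng=rng),
        ReLU(),
        MaxPool1D(2),
        Conv1D(e2, spec.bottleneck_filters, spec.kernel_size, rng=rng),
        ReLU(),
        Upsample1D(2),
        Conv1D(spec.bottleneck_filters, d1, spec.kernel_size, rng=rng),
        ReLU(),
        Upsample1D(2),
        Conv1D(d1, d2, spec.kernel_size, rng=rng),
        ReLU(),
        Conv1D(d2, spec.n_classes, 1, rng=rng),
    ])


def prepare_inputs(X: np.ndarray) -> np.ndarray:
    """Scale heatmap intensities from [0, 255] to [0, 1] for the network."""
    X = np.asarray(X, dtype=float).copy()
    X[:, :, :2] /= 255.0
    return X


def stratified_split(y: np.ndarray, test_fraction: float = 0.2, seed: int = 0):
    """Stratified index split; returns (train_idx, test_idx).

    Operates on one entry per subject (one heatmap per subject per
    feature), so the split is at subject level by construction.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise ValueError(f"class {small} has fewer than 2 subjects; cannot stratify")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed)
    return np.sort(train_idx), np.sort(test_idx)


def train_model(model: Sequential, X: np.ndarray, y: np.ndarray,
                config: TrainConfig, *, arch: str = "cnn",
                feature_name: str = "") -> TrainedModel:
    """Train on already-split training data; inputs on the [0,255] scale.

    For the FCN (per-bin logits) the subject label is broadcast to
    every time bin; with ``config.mask_loss`` the per-bin loss is
    weighted by the availability channel.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    y = np.asarray(y, dtype=int)
    if y.min() < 0 or y.max() >= N_CLASSES:
        raise ValueError("labels must be in 0..4")
    Xs = prepare_inputs(X)
    pw = None
    if arch == "fcn" and config.mask_loss:
        pw = np.asarray(X)[:, :, 2].astype(float)
    history = model.fit(
        Xs, y, epochs=config.epochs, batch_size=config.batch_size,
        lr=config.learning_rate, seed=config.seed, position_weights=pw,
    )
    return TrainedModel(model, history, config, arch, feature_name)


def predict(trained: TrainedModel, X: np.ndarray):
    """Class probabilities (and per-bin probabilities for the FCN).

    Returns ``(proba, per_bin)`` where ``proba`` is (N, 5) subject-level
    probabilities and ``per_bin`` is (N, W, 5) for the FCN, else None.
    Subject-level FCN probabilities are the mean over bins.
    """
    logits = trained.model.forward(prepare_inputs(X))
    if logits.ndim == 3:
        per_bin = softmax(logits)
        return per_bin.mean(axis=1), per_bin
    return softmax(logits), None


def predict_labels(trained: TrainedModel, X: np.ndarray) -> np.ndarray:
    proba, _ = predict(trained, X)
    return proba.argmax(axis=1)


def architecture_audit(model: Sequential) -> list[str]:
    """Compact layer descriptors for checking the printed architecture."""
    out = []
    for l in model.layers:
        if isinstance(l, Conv1D):
            out.append(f"conv{l.out_channels}k{l.kernel_size}")
        elif isinstance(l, Dense):
            out.append(f"dense{l.W.shape[1]}")
        elif isinstance(l, MaxPool1D):
            out.append("pool2")
        elif isinstance(l, Upsample1D):
            out.append("up2")
        elif isinstance(l, ReLU):
            out.append("relu")
        elif isinstance(l, Flatten):
            out.append("flatten")
    return out
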