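"""LeNet-5-style feature extractor: 28x28 grayscale image -> 50-D vector.

Stage 1 of the pipeline trains this backbone as an ordinary 10-way digit
classifier; afterwards its parameters are frozen and the activations of
the second fully connected layer (FC2, width 50) serve as the image's
feature vector.  The Euclidean distance E between two feature vectors is
the similarity signal used to supervise the sequence encoder.

Modern LeNet-5 conventions are used: ReLU activations and 2x2 max
pooling, conv1 padded so the 28x28 input maps onto the classic 32x32
geometry.  Training is plain mini-batch Adam on cross-entropy; everything
is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn

FEATURE_DIM = 50


@dataclass
class FeatureExtractorConfig:
    seed: int = 0
    conv1_channels: int = 6
    conv2_channels: int = 16
    fc1_width: int = 120
    n_classes: int = 10


@dataclass
class TrainConfig:
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0


class FeatureExtractor:
    """LeNet-5 backbone with FC2 sized 50 and a 10-way classification head."""

    def __init__(self, config: FeatureExtractorConfig | None = None) -> None:
        self.config = config or FeatureExtractorConfig()
        rng = np.random.default_rng(self.config.seed)
        c = self.config
        self.body = _nn.Sequential(
            [
                _nn.Conv2d(1, c.conv1_channels, (5, 5), (2, 2), rng),  # 28x28
                _nn.ReLU(),
                _nn.MaxPool2x2(),  # 14x14
                _nn.Conv2d(c.conv1_channels, c.conv2_channels, (5, 5), (0, 0), rng),  # 10x10
                _nn.ReLU(),
                _nn.MaxPool2x2(),  # 5x5
                _nn.Flatten(),
                _nn.Linear(c.conv2_channels * 25, c.fc1_width, rng),
                _nn.ReLU(),
                _nn.Linear(c.fc1_width, FEATURE_DIM, rng),  # FC2
                _nn.ReLU(),
            ]
        )
        self.head = _nn.Linear(FEATURE_DIM, c.n_classes, rng)
        self.trained = False

    # -- forward passes ----------------------------------------------------
    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3 or images.shape[1:] != (28, 28):
            raise ValueError(f"expected (n, 28, 28) images, got shape {images.shape}")
        return images[:, None, :, :]

    def forward(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (class logits [n,10], FC2 features [n,50])."""
        x = self._check_images(images)
        feats = self.body.forward(x)
        logits = self.head.forward(feats)
        return logits, feats

    def features(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images)[1]

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"body_{k}": v for k, v in self.body.state_dict().items()}
        state["head_w"] = self.head.w
        state["head_b"] = self.head.b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.body.load_state_dict(
            {k[len("body_"):]: v for k, v in state.items() if k.startswith("body_")}
        )
        self.head.w[...] = state["head_w"]
        self.head.b[...] = state["head_b"]
        self.trained = True

    def checksum(self) -> float:
        return self.body.checksum() + float(np.abs(self.head.w).sum() + np.abs(self.head.b).sum())


def build_feature_extractor(config: FeatureExtractorConfig | None = None) -> FeatureExtractor:
    return FeatureExtractor(config)


def train_feature_extractor(
    model: FeatureExtractor,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    config: TrainConfig | None = None,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    val_fraction: float = 0.1,
) -> dict:
    """Train the backbone on 10-way classification; returns a history dict
    with the per-epoch loss trace and held-out accuracy.

    When no validation set is given, a fraction of the training data is
    held out (deterministically, from the shuffled order).
    """
    cfg = config or TrainConfig()
    train_labels = np.asarray(train_labels, dtype=np.int64)
    if len(train_images) == 0:
        raise ValueError("empty training set")
    if len(np.unique(train_labels)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    rng = np.random.default_rng(cfg.seed)
    n = len(train_images)
    order = rng.permutation(n)
    if val_images is None:
        n_val = max(1, int(round(val_fraction * n)))
        val_idx, train_idx = order[:n_val], order[n_val:]
        val_images, val_labels = train_images[val_idx], train_labels[val_idx]
        images, labels = train_images[train_idx], train_labels[train_idx]
    else:
        images, labels = train_images[order], train_labels[order]
        val_labels = np.asarray(val_labels, dtype=np.int64)

    params = model.body.params + model.head.params
    grads = model.body.grads + model.head.grads
    opt = _nn.Adam(params, grads, lr=cfg.learning_rate)
    loss_trace: list[float] = []
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(images))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(images), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            logits, _ = model.forward(images[idx])
            loss, dlogits = _nn.cross_entropy_with_logits(logits, labels[idx])
            dfeats = model.head.backward(dlogits)
            model.body.backward(dfeats)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        loss_trace.append(epoch_loss / n_batches)
    model.trained = True
    val_logits, _ = model.forward(val_images)
    val_acc = float(np.mean(np.argmax(val_logits, axis=1) == val_labels))
    return {"loss_trace": loss_trace, "val_accuracy": val_acc, "n_val": len(val_labels)}


def extract_features(model: FeatureExtractor, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """FC2 activations for a batch of images; pure, no parameter updates."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    out = np.empty((len(images), FEATURE_DIM))
    for start in range(0, len(images), batch_size):
        out[start : start + batch_size] = model.features(images[start : start + batch_size])
    return out


def euclidean_distance(f1: np.ndarray, f2: np.ndarray) -> float:
    """L2 distance between two feature vectors (raw FC2 units, no scaling)."""
    f1 = np.asarray(f1, dtype=np.float64)
    f2 = np.asarray(f2, dtype=np.float64)
    if f1.shape != f2.shape or f1.ndim != 1:
        raise ValueError(f"dimension mismatch: {f1.shape} vs {f2.shape}")
    return float(np.linalg.norm(f1 - f2))


def save_checkpoint(model: FeatureExtractor, path) -> None:
    np.savez(path, kind="feature_extractor", version=1, **model.state_dict())


def load_checkpoint(path, config: FeatureExtractorConfig | None = None) -> FeatureExtractor:
    state = np.load(path, allow_pickle=False)
    if str(state["kind"]) != "feature_extractor":
        raise ValueError(f"not a feature-extractor checkpoint: {path}")
    model = FeatureExtractor(config)
    model.load_state_dict({k: state[k] for k in state.files if k not in ("kind", "version")})
    return model
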