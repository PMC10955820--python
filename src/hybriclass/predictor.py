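"""Differentiable surrogate of the hybridization-yield oracle.

A two-layer convolutional network regresses the equilibrium yield of a
sequence pair from its one-hot form.  The input stacks two 4xL base
matrices as channels: the first sequence as given and the *reverse
complement* of the second — so a perfectly complementary pair presents as
two identical channels, and the network's job is essentially to score
position-wise (mis)matches in their stacking context.  The head is a
sigmoid, so predictions live in [0, 1] like the yields they approximate.

The network exists to make encoder training differentiable (stage 3
backpropagates through it into soft base matrices); classification-time
yields always come from the thermodynamic backend, never from here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .nucleic import one_hot, soft_reverse_complement

SEQ_LEN = 59


@dataclass
class PredictorConfig:
    seed: int = 0
    length: int = SEQ_LEN
    conv1_channels: int = 32
    conv2_channels: int = 64
    kernel_width: int = 5


@dataclass
class PredictorTrainConfig:
    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 3e-3
    seed: int = 0
    holdout_fraction: float = 0.1


class YieldPredictor:
    """Two convolution layers over the stacked 2x4xL input, then a sigmoid
    regression head producing one scalar per pair."""

    def __init__(self, config: PredictorConfig | None = None) -> None:
        self.config = config or PredictorConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        pad_w = c.kernel_width // 2
        self.net = _nn.Sequential(
            [
                # first conv spans all four base rows jointly
                _nn.Conv2d(2, c.conv1_channels, (4, c.kernel_width), (0, pad_w), rng),
                _nn.ReLU(),
                _nn.Conv2d(c.conv1_channels, c.conv2_channels, (1, c.kernel_width), (0, pad_w), rng),
                _nn.ReLU(),
                # duplex free energy is (approximately) additive over
                # positions, so pool local features across the length
                # before the scalar head rather than flattening
                _nn.GlobalAvgPoolW(),
                _nn.Linear(c.conv2_channels, 1, rng),
            ]
        )
        self.trained = False
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (n, 2, 4, L) -> yields (n,) in (0, 1)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (2, 4, self.config.length):
            raise ValueError(f"expected (n, 2, 4, {self.config.length}), got {x.shape}")
        z = self.net.forward(x)[:, 0]
        y = 1.0 / (1.0 + np.exp(-z))
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the (n, 2, 4, L) input, given dLoss/dyield."""
        dz = (dy * self._y * (1.0 - self._y))[:, None]
        return self.net.backward(dz)

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Pre-sigmoid scores; margin losses on this scale keep their
        gradient even where the yield saturates at 0 or 1."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        return self.net.forward(x)[:, 0]

    def backward_logits(self, dz: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the input, given dLoss/dlogit."""
        return self.net.backward(np.asarray(dz)[:, None])

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.net.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state_dict(state)
        self.trained = True

    def checksum(self) -> float:
        return self.net.checksum()


def build_predictor(config: PredictorConfig | None = None) -> YieldPredictor:
    return YieldPredictor(config)


def make_predictor_input(first, second) -> np.ndarray:
    """Stack a pair into the (2, 4, L) predictor input.

    Arguments may be sequences (one-hot encoded) or soft 4xL base matrices
    (the encoder's output during stage 3).  The second channel is the
    reverse complement of the second argument; for soft matrices that is
    the continuous extension (reverse columns, swap A/T and C/G rows),
    which coincides with the discrete operation on one-hot input and is an
    involution.
    """
    m1 = one_hot(first) if isinstance(first, str) else np.asarray(first, dtype=np.float64)
    m2 = one_hot(second) if isinstance(second, str) else np.asarray(second, dtype=np.float64)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != 4:
        raise ValueError(f"incompatible base matrices: {m1.shape} vs {m2.shape}")
    return np.stack([m1, soft_reverse_complement(m2)])


def make_input_batch(pairs) -> np.ndarray:
    """(n, 2, 4, L) tensor from a list of YieldLabeledPair or (a, b) tuples."""
    rows = []
    for p in pairs:
        a, b = (p.first, p.second) if hasattr(p, "first") else (p[0], p[1])
        rows.append(make_predictor_input(a, b))
    return np.stack(rows)


def predict(model: YieldPredictor, first, second) -> float:
    """Estimated yield for one pair; in [0, 1] by construction."""
    import logging

    if not model.trained:
        logging.getLogger(__name__).warning("predicting with an untrained model")
    return float(model.forward(make_predictor_input(first, second)[None])[0])


def train_predictor(
    model: YieldPredictor,
    pairs,
    config: PredictorTrainConfig | None = None,
) -> dict:
    """Minimize MSE between predicted and labeled yields.

    Returns a history dict with the loss trace, the held-out MSE and the
    held-out (prediction, label) arrays for downstream diagnostics.
    """
    cfg = config or PredictorTrainConfig()
    if len(pairs) == 0:
        raise ValueError("empty pair corpus")
    rng = np.random.default_rng(cfg.seed)
    x = make_input_batch(pairs)
    y = np.array([p.yield_label for p in pairs])
    order = rng.permutation(len(pairs))
    n_hold = max(1, int(round(cfg.holdout_fraction * len(pairs))))
    hold_idx, train_idx = order[:n_hold], order[n_hold:]
    if len(train_idx) == 0:
        train_idx = hold_idx
    xt, yt = x[train_idx], y[train_idx]
    opt = _nn.Adam(model.net.params, model.net.grads, lr=cfg.learning_rate)
    loss_trace: list[float] = []
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(len(xt))
        total, n_batches = 0.0, 0
        for start in range(0, len(xt), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            pred = model.forward(xt[idx])
            err = pred - yt[idx]
            loss = float(np.mean(err**2))
            model.backward(2.0 * err / len(idx))
            opt.step()
            total += loss
            n_batches += 1
        loss_trace.append(total / n_batches)
    model.trained = True
    hold_pred = _predict_batches(model, x[hold_idx])
    holdout_mse = float(np.mean((hold_pred - y[hold_idx]) ** 2))
    return {
        "loss_trace": loss_trace,
        "holdout_mse": holdout_mse,
        "holdout_pred": hold_pred,
        "holdout_label": y[hold_idx],
    }


def _predict_batches(model: YieldPredictor, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
    out = np.empty(len(x))
    for start in range(0, len(x), batch_size):
        out[start : start + batch_size] = model.forward(x[start : start + batch_size])
    return out


def save_checkpoint(model: YieldPredictor, path) -> None:
    np.savez(path, kind="yield_predictor", version=1, **model.state_dict())


def load_checkpoint(path, config: PredictorConfig | None = None) -> YieldPredictor:
    state = np.load(path, allow_pickle=False)
    if str(state["kind"]) != "yield_predictor":
        raise ValueError(f"not a predictor checkpoint: {path}")
    model = YieldPredictor(config)
    model.load_state_dict({k: state[k] for k in state.files if k not in ("kind", "version")})
    return model
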