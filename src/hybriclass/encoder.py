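"""Feature-to-sequence encoder and its training objective.

The encoder maps a 50-D image feature vector to a soft 4x59 base matrix
(two linear layers, column-wise softmax); decoding the per-column argmax
gives the image's 59-nt DNA sequence.  Stage 3 trains it, with the
feature extractor and yield predictor frozen, against two goals:

* **encoding loss** — ambiguous columns (softmax maximum below 0.5) pay a
  cross-entropy against the one-hot indicator of their own argmax, which
  sharpens them; confident columns pay nothing, avoiding over-penalization.
* **sequence loss** — pairs of images that are close in feature space
  (Euclidean distance E below a threshold T1) and share a class label
  should map to high-yield sequence pairs (yield at least T2); pairs that
  are far apart with different labels should map to low-yield pairs.  The
  literal form of this rule is a 0/1 truth table over (E vs T1, Y vs T2,
  label equality); the default training mode replaces the two unit-loss
  branches with hinges (``max(0, T2 - Y)`` and ``max(0, Y - t_low)``).

How the hinges are descended matters more than their values.  Three
findings from developing this stage shaped the implementation (the
methods note discusses each):

* **branch gating uses the thermodynamic backend, not the neural
  surrogate.**  Descending against the frozen predictor lets the encoder
  drift into the surrogate's blind spots: sequence layouts where the
  predictor reports a low yield while the actual equilibrium yield is 1.
  The backend's two-state yield of the *decoded* pair is cheap to
  evaluate and cannot be gamed, so it decides whether a pair still needs
  pushing.  (The predictor's estimate remains the Y of the recorded loss
  and of all diagnostics.)
* **the descent direction is the base-agreement score.**  The
  classification duplex pairs an instance sequence with the reverse
  complement of the query's, so two images hybridize strongly exactly
  when their soft matrices agree column-wise; the inner product
  ``sum_j <p1_j, p2_j>`` is the differentiable leading term of the duplex
  stability, and its gradient (the partner's soft matrix) monotonically
  drives the true yield, unlike the predictor's input gradient, whose
  wrinkled level sets gradient descent exploits adversarially.
* **the low-yield margin is far below T2.**  The two-state melting
  transition is so sharp that a pair just below T2 in predicted yield is
  still on the fully-bound side of the cliff; repulsion therefore runs
  until the yield falls below ``t_low`` (default 0.05).

A differentiable homopolymer penalty keeps outputs inside the
homopolymer-free sequence space that the predictor was calibrated on and
that synthesis prefers; outputs are never filtered, and the realized
homopolymer rate is reported as a statistic.  The encoding loss joins
only after a warmup phase: it is a sharpening regularizer (argmax
decoding does not depend on it), and applying it from the start freezes
the softmax columns before the sequence forces have organized the
layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _nn, thermo
from .features import FEATURE_DIM, FeatureExtractor, extract_features
from .nucleic import decode_base_matrix, reverse_complement, soft_reverse_complement
from .predictor import YieldPredictor

logger = logging.getLogger(__name__)

SEQ_LEN = 59


@dataclass
class LossConfig:
    """Thresholds and weights of the encoder objective.

    ``t1`` is in raw feature-distance units (16 matches the MNIST feature
    geometry; for other corpora calibrate it from the feature-distance
    distribution, e.g. via ``synthetic_data.corpus_confusability_report``).
    ``t2`` is the yield threshold of the truth table; ``t_low`` is the
    stricter margin the surrogate pushes dissimilar pairs down to.
    ``attraction_weight``/``repulsion_weight`` scale the two sequence
    forces; ``homopolymer_weight`` scales the on-manifold regularizer.
    """

    t1: float = 16.0
    t2: float = 0.8
    t_low: float = 0.05
    confidence_threshold: float = 0.5
    mode: str = "surrogate"
    attraction_weight: float = 1.0
    repulsion_weight: float = 1.0
    homopolymer_weight: float = 0.5

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise ValueError("t1 must be positive")
        if not 0.0 < self.t2 < 1.0:
            raise ValueError("t2 must be in (0, 1)")
        if not 0.0 < self.t_low < self.t2:
            raise ValueError("t_low must be in (0, t2)")
        if self.mode not in ("literal", "surrogate"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class PairContext:
    """Per-pair quantities entering the sequence loss."""

    E: float  # Euclidean distance of the two feature vectors
    Y: float  # predictor-estimated yield of the sequence pair
    L1: int
    L2: int

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("E must be non-negative")
        if not 0.0 <= self.Y <= 1.0:
            raise ValueError("Y must be in [0, 1]")


@dataclass
class EncoderConfig:
    seed: int = 0
    hidden_width: int = 256
    length: int = SEQ_LEN


@dataclass
class EncoderTrainConfig:
    epochs: int = 35
    pairs_per_epoch: int = 4096
    batch_size: int = 64
    learning_rate: float = 1e-3
    same_label_rate: float = 0.5
    #: fraction of training during which the encoding loss stays off
    encoding_warmup_fraction: float = 0.7
    seed: int = 0


class Encoder:
    """Two linear layers, 50 -> hidden -> 4x59, column-wise softmax."""

    def __init__(self, config: EncoderConfig | None = None) -> None:
        self.config = config or EncoderConfig()
        c = self.config
        rng = np.random.default_rng(c.seed)
        self.net = _nn.Sequential(
            [
                _nn.Linear(FEATURE_DIM, c.hidden_width, rng),
                _nn.ReLU(),
                _nn.Linear(c.hidden_width, 4 * c.length, rng),
            ]
        )
        self.trained = False
        self._probs: np.ndarray | None = None

    def forward(self, feats: np.ndarray) -> np.ndarray:
        """(n, 50) features -> (n, 4, L) soft base matrices."""
        feats = np.asarray(feats, dtype=np.float64)
        single = feats.ndim == 1
        if single:
            feats = feats[None]
        z = self.net.forward(feats).reshape(-1, 4, self.config.length)
        p = _nn.softmax(z, axis=1)
        self._probs = p
        return p[0] if single else p

    def backward(self, dp: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the softmax output."""
        p = self._probs
        dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
        self.net.backward(dz.reshape(len(p), -1))

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.net.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state_dict(state)
        self.trained = True

    def checksum(self) -> float:
        return self.net.checksum()


def build_encoder(config: EncoderConfig | None = None) -> Encoder:
    return Encoder(config)


# ---------------------------------------------------------------------------
# Losses

def _check_soft_matrix(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != 4:
        raise ValueError(f"expected a 4xL soft matrix, got shape {m.shape}")
    if np.any(m < -1e-9) or np.any(np.abs(m.sum(axis=0) - 1.0) > 1e-6):
        raise ValueError("columns must be non-negative and sum to 1")
    return m


def encoding_loss(output: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Sum over columns of CE(Y_i, onehot(argmax Y_i)) where max(Y_i) is
    below the confidence threshold, else 0.

    Since the target is the column's own argmax indicator, each ambiguous
    column contributes exactly -ln(max(Y_i)).
    """
    cfg = cfg or LossConfig()
    m = _check_soft_matrix(output)
    col_max = m.max(axis=0)
    ambiguous = col_max < cfg.confidence_threshold
    return float(-np.log(col_max[ambiguous]).sum())


def sequence_loss(ctx: PairContext, cfg: LossConfig | None = None) -> float:
    """Similarity-to-yield supervision for one image pair.

    Literal mode is the 0/1 truth table over (E vs T1, Y vs T2, label
    equality); the combination "close features, low yield, different
    labels" is assigned 0 (low yield for different-label pairs is
    desirable regardless of distance).  Surrogate mode replaces the
    close-and-same-label branch with the hinge ``max(0, T2 - Y)`` and the
    far-and-different-label branch with ``max(0, Y - t_low)``; the two
    remaining (unconstrained) branches are 0.
    """
    cfg = cfg or LossConfig()
    close = ctx.E < cfg.t1
    same = ctx.L1 == ctx.L2
    if cfg.mode == "literal":
        high = ctx.Y >= cfg.t2
        if (close and not high and same) or (not close and high and not same):
            return 1.0
        return 0.0
    if close and same:
        return float(max(0.0, cfg.t2 - ctx.Y))
    if not close and not same:
        return float(max(0.0, ctx.Y - cfg.t_low))
    return 0.0


def encoder_loss(
    output_pair: tuple[np.ndarray, np.ndarray],
    ctx: PairContext,
    cfg: LossConfig | None = None,
) -> float:
    """Total objective for one pair: encoding loss of both encoder outputs
    plus the sequence loss of their pairing."""
    cfg = cfg or LossConfig()
    out1, out2 = output_pair
    return encoding_loss(out1, cfg) + encoding_loss(out2, cfg) + sequence_loss(ctx, cfg)


def homopolymer_penalty(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Differentiable surrogate of the homopolymer count of an (n, 4, L)
    soft batch: the sum over bases and 3-column windows of the product of
    the base's probabilities.  On one-hot matrices this counts windows of
    three identical consecutive bases.  Returns (per-item penalty, grad)."""
    a, b, c = p[:, :, :-2], p[:, :, 1:-1], p[:, :, 2:]
    pen = (a * b * c).sum(axis=(1, 2))
    g = np.zeros_like(p)
    g[:, :, :-2] += b * c
    g[:, :, 1:-1] += a * c
    g[:, :, 2:] += a * b
    return pen, g


def _harden(p: np.ndarray) -> np.ndarray:
    """One-hot argmax of each column of an (n, 4, L) batch."""
    h = np.zeros_like(p)
    idx = p.argmax(axis=1)
    n, _, length = p.shape
    h[np.arange(n)[:, None], idx, np.arange(length)[None, :]] = 1.0
    return h


# ---------------------------------------------------------------------------
# Stage-3 training

def _sample_pair_indices(
    labels: np.ndarray, n_pairs: int, same_label_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random pairs with a forced fraction of same-label pairs."""
    n = len(labels)
    idx1 = rng.integers(0, n, size=n_pairs)
    idx2 = rng.integers(0, n, size=n_pairs)
    force = rng.random(n_pairs) < same_label_rate
    by_label = {lab: np.flatnonzero(labels == lab) for lab in np.unique(labels)}
    for i in np.flatnonzero(force):
        pool = by_label[labels[idx1[i]]]
        idx2[i] = pool[rng.integers(0, len(pool))]
    return idx1, idx2


def train_encoder(
    feature_model: FeatureExtractor,
    predictor_model: YieldPredictor,
    images: np.ndarray,
    labels: np.ndarray,
    encoder_model: Encoder | None = None,
    loss_cfg: LossConfig | None = None,
    train_cfg: EncoderTrainConfig | None = None,
    conditions: "thermo.HybridizationConditions | None" = None,
) -> tuple[Encoder, dict]:
    """Train the encoder with the extractor and predictor frozen.

    Image features are computed once up front (the extractor is frozen,
    so this is exact).  Each step samples image pairs and calls the
    shared encoder on both members (one concatenated forward realizes
    the double call).  For every pair, E, the labels, the predictor's
    estimated yield of the hardened pair, and the thermodynamic backend's
    yield of the decoded pair are computed; the backend's yield gates the
    surrogate branches, and active pairs receive the base-agreement
    gradient (see the module docstring for why).  Only encoder
    parameters are updated; the history records the surrogate loss and
    the mean predictor yield per epoch.
    """
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or EncoderTrainConfig()
    conditions = conditions or thermo.HybridizationConditions()
    if not feature_model.trained:
        raise ValueError("feature extractor must be trained (and frozen) before stage 3")
    if not predictor_model.trained:
        raise ValueError("yield predictor must be trained (and frozen) before stage 3")
    if loss_cfg.mode == "literal":
        logger.warning(
            "literal sequence loss is piecewise-constant; only the encoding "
            "and homopolymer terms contribute gradients in this mode"
        )
    enc = encoder_model or Encoder(EncoderConfig(seed=train_cfg.seed))
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(train_cfg.seed)
    feats = extract_features(feature_model, images)
    opt = _nn.Adam(enc.net.params, enc.net.grads, lr=train_cfg.learning_rate)
    warmup_epochs = train_cfg.encoding_warmup_fraction * train_cfg.epochs
    loss_trace: list[float] = []
    predicted_yield_trace: list[float] = []
    for epoch in range(train_cfg.epochs):
        encoding_on = epoch >= warmup_epochs
        idx1, idx2 = _sample_pair_indices(
            labels, train_cfg.pairs_per_epoch, train_cfg.same_label_rate, rng
        )
        epoch_loss, epoch_y, n_batches = 0.0, 0.0, 0
        for start in range(0, len(idx1), train_cfg.batch_size):
            i1 = idx1[start : start + train_cfg.batch_size]
            i2 = idx2[start : start + train_cfg.batch_size]
            nb = len(i1)
            f1, f2 = feats[i1], feats[i2]
            p = enc.forward(np.concatenate([f1, f2], axis=0))
            p1, p2 = p[:nb], p[nb:]
            hard = _harden(p)
            seq1 = [decode_base_matrix(m) for m in hard[:nb]]
            seq2 = [decode_base_matrix(m) for m in hard[nb:]]
            y_true = thermo.pair_yields(
                seq1, [reverse_complement(s) for s in seq2], conditions
            )
            y_pred = predictor_model.forward(
                np.stack([hard[:nb], soft_reverse_complement(hard[nb:])], axis=1)
            )
            e = np.linalg.norm(f1 - f2, axis=1)
            same = labels[i1] == labels[i2]
            close = e < loss_cfg.t1
            want_high = close & same
            want_low = ~close & ~same
            seq_loss = np.where(
                want_high,
                np.maximum(0.0, loss_cfg.t2 - y_true),
                np.where(want_low, np.maximum(0.0, y_true - loss_cfg.t_low), 0.0),
            )
            if loss_cfg.mode == "literal":
                seq_loss = (
                    (want_high & (y_true < loss_cfg.t2))
                    | (want_low & (y_true >= loss_cfg.t2))
                ).astype(float)
                w = np.zeros(nb)
            else:
                attract = want_high & (y_true < loss_cfg.t2)
                repel = want_low & (y_true > loss_cfg.t_low)
                w = np.where(
                    attract,
                    -loss_cfg.attraction_weight,
                    np.where(repel, loss_cfg.repulsion_weight, 0.0),
                )
            # agreement-score gradient: each member is pushed along (or
            # against) its partner's soft matrix
            wc = w[:, None, None]
            dp = np.concatenate([wc * p2, wc * p1], axis=0) / nb
            if encoding_on:
                col_max = p.max(axis=1)
                arg = p.argmax(axis=1)
                active = col_max < loss_cfg.confidence_threshold
                n_i, l_i = np.nonzero(active)
                denc = np.zeros_like(p)
                denc[n_i, arg[n_i, l_i], l_i] = -1.0 / col_max[n_i, l_i]
                dp += denc / nb
                epoch_loss += float(-np.log(col_max[active]).sum() / nb)
            hp_pen, hp_grad = homopolymer_penalty(p)
            dp += loss_cfg.homopolymer_weight * hp_grad / nb
            enc.backward(dp)
            opt.step()
            epoch_loss += float(
                seq_loss.mean() + loss_cfg.homopolymer_weight * hp_pen.mean()
            )
            epoch_y += float(y_pred.mean())
            n_batches += 1
        loss_trace.append(epoch_loss / n_batches)
        predicted_yield_trace.append(epoch_y / n_batches)
    enc.trained = True
    return enc, {
        "loss_trace": loss_trace,
        "predicted_yield_trace": predicted_yield_trace,
    }


def encode_image(
    feature_model: FeatureExtractor, encoder_model: Encoder, image: np.ndarray
) -> str:
    """Image -> features -> soft base matrix -> argmax-decoded 59-nt sequence."""
    feats = extract_features(feature_model, np.asarray(image))
    return decode_base_matrix(encoder_model.forward(feats[0]))


def encode_images(
    feature_model: FeatureExtractor,
    encoder_model: Encoder,
    images: np.ndarray,
    batch_size: int = 256,
) -> list[str]:
    feats = extract_features(feature_model, images)
    out: list[str] = []
    for start in range(0, len(feats), batch_size):
        probs = encoder_model.forward(feats[start : start + batch_size])
        out.extend(decode_base_matrix(m) for m in probs)
    return out


def save_checkpoint(model: Encoder, path) -> None:
    np.savez(path, kind="encoder", version=1, **model.state_dict())


def load_checkpoint(path, config: EncoderConfig | None = None) -> Encoder:
    state = np.load(path, allow_pickle=False)
    if str(state["kind"]) != "encoder":
        raise ValueError(f"not an encoder checkpoint: {path}")
    model = Encoder(config)
    model.load_state_dict({k: state[k] for k in state.files if k not in ("kind", "version")})
    return model
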