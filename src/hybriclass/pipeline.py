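"""End-to-end orchestration of the three training stages and evaluation.

One global seed fans out to per-stage seeds through
:class:`numpy.random.SeedSequence`, so every stage is independently
re-runnable and the whole run is reproducible.  The default problem sizes
are the package's scaled-down study conditions: a synthetic glyph corpus
of 10 classes x 200 training images, 100 queries (10 per class), and a
yield-balanced corpus of up to 20,000 predictor pairs drawn from 60,000
raw candidates.  The full-scale protocol (60,000 MNIST instances, 300,000
pairs, 1,000 queries) is the same code with larger numbers and, if
desired, an external yield adapter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import classifier, encoder, features, pairset, predictor, synthetic_data, thermo

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    # corpus
    n_train_per_class: int = 200
    n_test_per_class: int = 10
    # predictor corpus
    n_raw_pairs: int = 200_000
    pairs_per_bin: int = 2_000
    n_bins: int = 10
    seq_length: int = 59
    # stage hyperparameters
    backbone: features.TrainConfig = field(default_factory=features.TrainConfig)
    predictor_train: predictor.PredictorTrainConfig = field(
        default_factory=predictor.PredictorTrainConfig
    )
    encoder_train: encoder.EncoderTrainConfig = field(
        default_factory=encoder.EncoderTrainConfig
    )
    # loss thresholds; t1=None means "calibrate from the corpus"
    t1: float | None = None
    t2: float = 0.8
    loss_mode: str = "surrogate"
    t1_percentile: float = 8.0
    conditions: thermo.HybridizationConditions = field(
        default_factory=thermo.HybridizationConditions
    )


def derive_seeds(seed: int, n: int = 8) -> list[int]:
    """Stable fan-out of one global seed into per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def make_corpus(cfg: PipelineConfig) -> dict:
    s = derive_seeds(cfg.seed)
    train_x, train_y, test_x, test_y = synthetic_data.generate_splits(
        cfg.n_train_per_class, cfg.n_test_per_class, seed=s[0]
    )
    return {"train_x": train_x, "train_y": train_y, "test_x": test_x, "test_y": test_y}


def stage1_backbone(cfg: PipelineConfig, corpus: dict) -> tuple[features.FeatureExtractor, dict]:
    s = derive_seeds(cfg.seed)
    model = features.build_feature_extractor(features.FeatureExtractorConfig(seed=s[1]))
    train_cfg = features.TrainConfig(
        epochs=cfg.backbone.epochs,
        batch_size=cfg.backbone.batch_size,
        learning_rate=cfg.backbone.learning_rate,
        seed=s[1],
    )
    history = features.train_feature_extractor(
        model, corpus["train_x"], corpus["train_y"], train_cfg
    )
    logger.info("stage 1: validation accuracy %.3f", history["val_accuracy"])
    return model, history


def make_pair_corpus(cfg: PipelineConfig) -> list[pairset.YieldLabeledPair]:
    s = derive_seeds(cfg.seed)
    balanced = pairset.generate_balanced_pairs(
        per_bin=cfg.pairs_per_bin,
        n_bins=cfg.n_bins,
        length=cfg.seq_length,
        conditions=cfg.conditions,
        seed=s[2],
        max_factor=cfg.n_raw_pairs / (cfg.n_bins * cfg.pairs_per_bin),
    )
    logger.info("pair corpus: %d balanced pairs", len(balanced))
    return balanced


def stage2_predictor(
    cfg: PipelineConfig, pairs: list[pairset.YieldLabeledPair]
) -> tuple[predictor.YieldPredictor, dict]:
    s = derive_seeds(cfg.seed)
    model = predictor.build_predictor(
        predictor.PredictorConfig(seed=s[3], length=cfg.seq_length)
    )
    train_cfg = predictor.PredictorTrainConfig(
        epochs=cfg.predictor_train.epochs,
        batch_size=cfg.predictor_train.batch_size,
        learning_rate=cfg.predictor_train.learning_rate,
        holdout_fraction=cfg.predictor_train.holdout_fraction,
        seed=s[3],
    )
    history = predictor.train_predictor(model, pairs, train_cfg)
    logger.info("stage 2: held-out MSE %.4f", history["holdout_mse"])
    return model, history


def stage3_encoder(
    cfg: PipelineConfig,
    feature_model: features.FeatureExtractor,
    predictor_model: predictor.YieldPredictor,
    corpus: dict,
) -> tuple[encoder.Encoder, encoder.LossConfig, dict]:
    s = derive_seeds(cfg.seed)
    if cfg.t1 is None:
        report = synthetic_data.corpus_confusability_report(
            corpus["train_x"],
            corpus["train_y"],
            feature_model,
            t1_percentile=cfg.t1_percentile,
            seed=s[4],
        )
        t1 = report["t1_calibrated"]
        logger.info("stage 3: calibrated T1 = %.3f", t1)
    else:
        t1 = cfg.t1
    loss_cfg = encoder.LossConfig(t1=t1, t2=cfg.t2, mode=cfg.loss_mode)
    train_cfg = encoder.EncoderTrainConfig(
        epochs=cfg.encoder_train.epochs,
        pairs_per_epoch=cfg.encoder_train.pairs_per_epoch,
        batch_size=cfg.encoder_train.batch_size,
        learning_rate=cfg.encoder_train.learning_rate,
        same_label_rate=cfg.encoder_train.same_label_rate,
        encoding_warmup_fraction=cfg.encoder_train.encoding_warmup_fraction,
        seed=s[4],
    )
    enc, history = encoder.train_encoder(
        feature_model, predictor_model, corpus["train_x"], corpus["train_y"],
        loss_cfg=loss_cfg, train_cfg=train_cfg, conditions=cfg.conditions,
    )
    return enc, loss_cfg, history


def intra_inter_yield_stats(
    feature_model: features.FeatureExtractor,
    encoder_model: encoder.Encoder,
    images: np.ndarray,
    labels: np.ndarray,
    conditions: thermo.HybridizationConditions,
    n_pairs: int = 500,
    seed: int = 0,
) -> dict:
    """Mean thermodynamic yield over sampled same-class and different-class
    image pairs (sequence of the first image vs the reverse complement of
    the second's — the quantity the classifier sums)."""
    from .nucleic import reverse_complement

    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    seqs = encoder.encode_images(feature_model, encoder_model, images)
    by_label = {lab: np.flatnonzero(labels == lab) for lab in np.unique(labels)}
    intra_a, intra_b, inter_a, inter_b = [], [], [], []
    for _ in range(n_pairs):
        lab = rng.choice(list(by_label))
        i, j = rng.choice(by_label[lab], size=2, replace=True)
        intra_a.append(seqs[i])
        intra_b.append(reverse_complement(seqs[j]))
        i = rng.integers(0, len(labels))
        j = rng.integers(0, len(labels))
        while labels[j] == labels[i]:
            j = rng.integers(0, len(labels))
        inter_a.append(seqs[i])
        inter_b.append(reverse_complement(seqs[j]))
    intra = thermo.pair_yields(intra_a, intra_b, conditions)
    inter = thermo.pair_yields(inter_a, inter_b, conditions)
    return {
        "mean_intra_yield": float(intra.mean()),
        "mean_inter_yield": float(inter.mean()),
        "median_intra_yield": float(np.median(intra)),
        "median_inter_yield": float(np.median(inter)),
    }


def homopolymer_rate(seqs: list[str]) -> float:
    """Fraction of encoded sequences containing a homopolymer run (>= 3).

    Encoder outputs are not constrained to be homopolymer-free; this
    statistic is reported so users can judge synthesis realism."""
    from .nucleic import has_homopolymer

    return float(np.mean([has_homopolymer(s) for s in seqs]))


def run_full(cfg: PipelineConfig | None = None) -> dict:
    """Run all stages and evaluation; returns every artifact in memory."""
    cfg = cfg or PipelineConfig()
    s = derive_seeds(cfg.seed)
    corpus = make_corpus(cfg)
    feature_model, backbone_history = stage1_backbone(cfg, corpus)
    pairs = make_pair_corpus(cfg)
    predictor_model, predictor_history = stage2_predictor(cfg, pairs)
    upstream_checksums_before = {
        "features": feature_model.checksum(),
        "predictor": predictor_model.checksum(),
    }
    enc, loss_cfg, encoder_history = stage3_encoder(
        cfg, feature_model, predictor_model, corpus
    )
    upstream_checksums_after = {
        "features": feature_model.checksum(),
        "predictor": predictor_model.checksum(),
    }
    library = classifier.build_library(
        corpus["train_x"], corpus["train_y"], feature_model, enc
    )
    evaluation = classifier.evaluate(
        corpus["test_x"], corpus["test_y"], library, feature_model, enc, cfg.conditions
    )
    yields = intra_inter_yield_stats(
        feature_model, enc, corpus["test_x"], corpus["test_y"], cfg.conditions, seed=s[5]
    )
    instance_seqs, _ = library.flat()
    return {
        "config": cfg,
        "corpus": corpus,
        "feature_model": feature_model,
        "backbone_history": backbone_history,
        "pairs": pairs,
        "predictor_model": predictor_model,
        "predictor_history": predictor_history,
        "encoder_model": enc,
        "loss_cfg": loss_cfg,
        "encoder_history": encoder_history,
        "upstream_checksums_before_stage3": upstream_checksums_before,
        "upstream_checksums_after_stage3": upstream_checksums_after,
        "library": library,
        "evaluation": evaluation,
        "yield_stats": yields,
        "homopolymer_rate": homopolymer_rate(instance_seqs),
    }
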