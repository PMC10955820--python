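"""The DNA instance-based classifier.

Every labeled image is encoded to a 59-nt instance sequence and stored in
the "tube" of its class — an in-silico stand-in for a physical tube of
synthesized strands.  To classify a query image, its encoded sequence's
reverse complement is used as the probe; the equilibrium hybridization
yield of the probe against every instance is computed pairwise at the
stated reaction conditions, yields are summed per tube, and the class
with the largest sum wins.  Classification-time yields come from the
thermodynamic backend (or a registered external adapter) — the neural
yield predictor plays no role after training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoder import Encoder, encode_image, encode_images
from .features import FeatureExtractor
from .nucleic import (
    format_record_id,
    parse_record_id,
    read_fasta,
    reverse_complement,
    validate_sequence,
    write_fasta,
)
from .thermo import HybridizationConditions, yield_matrix

logger = logging.getLogger(__name__)


@dataclass
class TubeLibrary:
    """Mapping class label -> ordered list of instance sequences."""

    tubes: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for seqs in self.tubes.values() for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"instance sequences have mixed lengths {sorted(lengths)}")
        for seqs in self.tubes.values():
            for s in seqs:
                validate_sequence(s)

    @property
    def labels(self) -> list[int]:
        return sorted(self.tubes)

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.tubes.values())

    def flat(self) -> tuple[list[str], np.ndarray]:
        """All instances pooled across tubes (label-sorted, stable order)
        with their class labels."""
        seqs: list[str] = []
        labels: list[int] = []
        for lab in self.labels:
            seqs.extend(self.tubes[lab])
            labels.extend([lab] * len(self.tubes[lab]))
        return seqs, np.array(labels)

    def to_fasta(self, path) -> None:
        records = []
        for lab in self.labels:
            for i, seq in enumerate(self.tubes[lab]):
                records.append((format_record_id(lab, i), seq))
        write_fasta(records, path)

    @classmethod
    def from_fasta(cls, path) -> "TubeLibrary":
        tubes: dict[int, list[str]] = {}
        for rid, seq in read_fasta(path):
            lab, _ = parse_record_id(rid)
            tubes.setdefault(lab, []).append(seq)
        return cls(tubes=tubes)


@dataclass
class ClassificationResult:
    predicted_label: int
    per_class_yield_sum: dict[int, float]
    query_sequence: str


def build_library(
    images: np.ndarray,
    labels: np.ndarray,
    feature_model: FeatureExtractor,
    encoder_model: Encoder,
) -> TubeLibrary:
    """Encode every image and group the sequences by label, preserving
    input order within each tube (duplicates are kept: a tube is a
    multiset of strands)."""
    labels = np.asarray(labels, dtype=np.int64)
    seqs = encode_images(feature_model, encoder_model, images)
    tubes: dict[int, list[str]] = {}
    for seq, lab in zip(seqs, labels):
        tubes.setdefault(int(lab), []).append(seq)
    for lab, members in tubes.items():
        if not members:
            logger.warning("class %d has no instances", lab)
    return TubeLibrary(tubes=tubes)


def classify_sequence(
    query_sequence: str,
    library: TubeLibrary,
    conditions: HybridizationConditions | None = None,
) -> ClassificationResult:
    """Classify an already-encoded query sequence by the yield-sum rule."""
    if not library.tubes:
        raise ValueError("empty library")
    conditions = conditions or HybridizationConditions()
    probe = reverse_complement(query_sequence)
    seqs, labs = library.flat()
    if len(seqs[0]) != len(probe):
        raise ValueError(
            f"probe length {len(probe)} != instance length {len(seqs[0])}"
        )
    yields = yield_matrix([probe], seqs, conditions)[0]
    sums = {int(lab): float(yields[labs == lab].sum()) for lab in library.labels}
    best = max(sums.values())
    winners = [lab for lab in sorted(sums) if sums[lab] == best]
    if len(winners) > 1:
        logger.warning(
            "yield-sum tie between classes %s; returning smallest label", winners
        )
    return ClassificationResult(
        predicted_label=winners[0], per_class_yield_sum=sums, query_sequence=query_sequence
    )


def classify(
    query_image: np.ndarray,
    library: TubeLibrary,
    feature_model: FeatureExtractor,
    encoder_model: Encoder,
    conditions: HybridizationConditions | None = None,
) -> ClassificationResult:
    """Encode a query image and classify it against the tube library."""
    seq = encode_image(feature_model, encoder_model, query_image)
    return classify_sequence(seq, library, conditions)


@dataclass
class EvaluationResult:
    overall_accuracy: float
    per_class_accuracy: dict[int, float]
    confusion_matrix: pd.DataFrame  # rows: true label, columns: predicted
    results: list[ClassificationResult]
    misclassified: pd.DataFrame

    def to_tsv(self, path) -> None:
        rows = []
        for i, (res, true_lab) in enumerate(zip(self.results, self._true_labels)):
            row = {"query": i, "true_label": true_lab, "predicted_label": res.predicted_label}
            row.update({f"yield_sum_{lab}": s for lab, s in res.per_class_yield_sum.items()})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    _true_labels: np.ndarray = field(default_factory=lambda: np.array([]))


def evaluate(
    query_images: np.ndarray,
    true_labels: np.ndarray,
    library: TubeLibrary,
    feature_model: FeatureExtractor,
    encoder_model: Encoder,
    conditions: HybridizationConditions | None = None,
) -> EvaluationResult:
    """Classify each query and report accuracy, per-class accuracy, the
    confusion matrix and the misclassified queries with their yield sums."""
    true_labels = np.asarray(true_labels, dtype=np.int64)
    if len(query_images) != len(true_labels):
        raise ValueError("queries and labels differ in length")
    conditions = conditions or HybridizationConditions()
    query_seqs = encode_images(feature_model, encoder_model, query_images)
    seqs, labs = library.flat()
    probes = [reverse_complement(q) for q in query_seqs]
    ym = yield_matrix(probes, seqs, conditions)
    class_labels = library.labels
    sums = np.stack([ym[:, labs == lab].sum(axis=1) for lab in class_labels], axis=1)
    pred_idx = np.argmax(sums, axis=1)  # first maximum = smallest label on ties
    predicted = np.array([class_labels[i] for i in pred_idx])
    results = [
        ClassificationResult(
            predicted_label=int(p),
            per_class_yield_sum={lab: float(s) for lab, s in zip(class_labels, row)},
            query_sequence=q,
        )
        for p, row, q in zip(predicted, sums, query_seqs)
    ]
    correct = predicted == true_labels
    per_class = {
        int(lab): float(np.mean(correct[true_labels == lab]))
        for lab in np.unique(true_labels)
    }
    cm = pd.crosstab(
        pd.Series(true_labels, name="true"),
        pd.Series(predicted, name="predicted"),
        dropna=False,
    ).reindex(index=class_labels, columns=class_labels, fill_value=0)
    mis_rows = []
    for i in np.flatnonzero(~correct):
        row = {
            "query": int(i),
            "true_label": int(true_labels[i]),
            "predicted_label": int(predicted[i]),
        }
        row.update({f"yield_sum_{lab}": results[i].per_class_yield_sum[lab] for lab in class_labels})
        mis_rows.append(row)
    out = EvaluationResult(
        overall_accuracy=float(np.mean(correct)),
        per_class_accuracy=per_class,
        confusion_matrix=cm,
        results=results,
        misclassified=pd.DataFrame(mis_rows),
    )
    out._true_labels = true_labels
    return out


def top_k_neighbors(
    query_image: np.ndarray,
    library: TubeLibrary,
    k: int,
    feature_model: FeatureExtractor,
    encoder_model: Encoder,
    conditions: HybridizationConditions | None = None,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Rank all instances by hybridization yield with the query's probe.

    Returns the top-k table (instance id, class, yield; stable sort, ties
    broken by pooled instance order) and the class-composition fractions
    of the retrieved set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = encode_image(feature_model, encoder_model, query_image)
    probe = reverse_complement(seq)
    seqs, labs = library.flat()
    if k > len(seqs):
        warnings.warn(f"k={k} exceeds library size {len(seqs)}; returning all")
        k = len(seqs)
    yields = yield_matrix([probe], seqs, conditions or HybridizationConditions())[0]
    order = np.argsort(-yields, kind="stable")[:k]
    ids = []
    counters: dict[int, int] = {}
    for lab in labs:
        counters[lab] = counters.get(lab, 0)
    # reconstruct per-tube instance indices in pooled order
    per_tube_index = []
    seen: dict[int, int] = {}
    for lab in labs:
        per_tube_index.append(seen.get(lab, 0))
        seen[lab] = seen.get(lab, 0) + 1
    for i in order:
        ids.append(format_record_id(int(labs[i]), per_tube_index[i]))
    table = pd.DataFrame(
        {
            "instance_id": ids,
            "class": labs[order],
            "yield": yields[order],
        }
    )
    composition = {
        int(lab): float(np.mean(labs[order] == lab)) for lab in np.unique(labs[order])
    }
    return table, composition
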