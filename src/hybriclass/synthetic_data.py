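"""Synthetic 10-class digit-glyph image corpus and MNIST IDX file I/O.

The generator renders ten hand-designed stroke templates, loosely shaped
like the digits 0-9, onto a 28x28 single-channel canvas with per-image
affine jitter (rotation, translation, scale), randomized stroke width and
additive clipped Gaussian noise.  Classes 4 and 9 share a similar layout
on purpose so that the corpus has a genuinely confusable class pair, not
just separable blobs.  Rendering is done at 4x resolution and downsampled
for antialiased strokes.

Real MNIST IDX files (big-endian, magic 2051/2049) are read by
:func:`read_idx` when available; the writer exists for round-trip tests.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

_SUPER = 4  # supersampling factor for rendering
_SIZE = 28


def _ellipse(cx: float, cy: float, rx: float, ry: float, n: int = 24) -> list[tuple[float, float]]:
    t = np.linspace(0.0, 2.0 * np.pi, n + 1)
    return list(zip(cx + rx * np.cos(t), cy + ry * np.sin(t)))


#: Stroke templates per class: a list of polylines in 28x28 coordinates.
TEMPLATES: dict[int, list[list[tuple[float, float]]]] = {
    0: [_ellipse(14, 14, 6, 9)],
    1: [[(11, 8), (14, 5), (14, 23)]],
    2: [[(8, 9), (9, 6), (13, 4.5), (17, 6), (19, 10), (16, 14), (11, 18), (8, 22), (20, 22)]],
    3: [[(8, 6), (13, 4), (17, 6), (18, 9), (14, 13), (18, 17), (17, 20), (12, 23), (8, 21)]],
    4: [[(14, 4), (6, 16), (21, 16)], [(16, 6), (16, 24)]],
    5: [[(19, 5), (9, 5), (9, 13), (15, 12), (19, 15), (18, 20), (12, 23), (8, 21)]],
    6: [[(17, 4), (11, 9), (8, 15), (9, 20), (14, 23), (18, 20), (18, 15), (13, 13), (9, 16)]],
    7: [[(7, 5), (20, 5), (13, 23)], [(10, 14), (17, 14)]],
    8: [_ellipse(14, 8.5, 4.5, 4.5), _ellipse(14, 18, 5.5, 5.5)],
    # 9 deliberately echoes 4: a closed head with a long right-hand tail.
    9: [_ellipse(13.5, 9, 5, 5), [(18.5, 9), (17, 24)]],
}


@dataclass
class GlyphSpec:
    """Rendering specification for one class."""

    class_id: int
    template: list[list[tuple[float, float]]]
    rotation_deg: float = 15.0
    translation_px: float = 2.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    stroke_width_range: tuple[float, float] = (1.5, 2.5)
    noise_sd: float = 0.05


def default_specs(**overrides) -> list[GlyphSpec]:
    return [GlyphSpec(class_id=c, template=TEMPLATES[c], **overrides) for c in range(10)]


def render_glyph(spec: GlyphSpec, rng: np.random.Generator) -> np.ndarray:
    """Render one jittered instance of a glyph as a 28x28 array in [0, 1]."""
    theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    scale = rng.uniform(*spec.scale_range)
    tx = rng.uniform(-spec.translation_px, spec.translation_px)
    ty = rng.uniform(-spec.translation_px, spec.translation_px)
    width = rng.uniform(*spec.stroke_width_range)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    canvas = Image.new("L", (_SIZE * _SUPER, _SIZE * _SUPER), 0)
    draw = ImageDraw.Draw(canvas)
    for stroke in spec.template:
        pts = []
        for x, y in stroke:
            # rotate+scale about the canvas center, then translate
            xr = scale * (cos_t * (x - 14) - sin_t * (y - 14)) + 14 + tx
            yr = scale * (sin_t * (x - 14) + cos_t * (y - 14)) + 14 + ty
            pts.append((xr * _SUPER, yr * _SUPER))
        draw.line(pts, fill=255, width=max(1, round(width * _SUPER)), joint="curve")
    img = canvas.resize((_SIZE, _SIZE), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float64) / 255.0
    if spec.noise_sd > 0:
        arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
    return np.clip(arr, 0.0, 1.0)


def generate_glyph_dataset(
    n_per_class: int,
    seed: int | np.random.Generator = 0,
    **spec_overrides,
) -> tuple[np.ndarray, np.ndarray]:
    """Render ``n_per_class`` jittered instances of each of the 10 classes.

    Returns ``(images, labels)`` with images of shape (10*n_per_class, 28, 28)
    in [0, 1], grouped by class in label order.  Deterministic given seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    specs = default_specs(**spec_overrides)
    images = np.empty((10 * n_per_class, _SIZE, _SIZE))
    labels = np.empty(10 * n_per_class, dtype=np.int64)
    i = 0
    for spec in specs:
        for _ in range(n_per_class):
            images[i] = render_glyph(spec, rng)
            labels[i] = spec.class_id
            i += 1
    return images, labels


def generate_splits(
    n_train_per_class: int,
    n_test_per_class: int,
    seed: int = 0,
    **spec_overrides,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint train/test corpora (independent jitter draws, derived seeds)."""
    root = np.random.SeedSequence(seed)
    train_seed, test_seed = root.spawn(2)
    train = generate_glyph_dataset(n_train_per_class, np.random.default_rng(train_seed), **spec_overrides)
    test = generate_glyph_dataset(n_test_per_class, np.random.default_rng(test_seed), **spec_overrides)
    return train[0], train[1], test[0], test[1]


# ---------------------------------------------------------------------------
# IDX (MNIST dialect) I/O

_IMAGE_MAGIC = 2051
_LABEL_MAGIC = 2049


def read_idx(images_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an MNIST-style IDX image/label file pair.

    Images are scaled to [0, 1]; image and label counts must agree.
    """
    with open(images_path, "rb") as fh:
        magic, count, rows, cols = struct.unpack(">iiii", fh.read(16))
        if magic != _IMAGE_MAGIC:
            raise ValueError(f"bad image-file magic {magic} (expected {_IMAGE_MAGIC})")
        data = np.frombuffer(fh.read(count * rows * cols), dtype=np.uint8)
        if data.size != count * rows * cols:
            raise ValueError("image file truncated")
        images = data.reshape(count, rows, cols).astype(np.float64) / 255.0
    with open(labels_path, "rb") as fh:
        magic, n_labels = struct.unpack(">ii", fh.read(8))
        if magic != _LABEL_MAGIC:
            raise ValueError(f"bad label-file magic {magic} (expected {_LABEL_MAGIC})")
        labels = np.frombuffer(fh.read(n_labels), dtype=np.uint8).astype(np.int64)
        if labels.size != n_labels:
            raise ValueError("label file truncated")
    if count != n_labels:
        raise ValueError(f"image count {count} != label count {n_labels}")
    return images, labels


def write_idx(images: np.ndarray, labels: np.ndarray, images_path, labels_path) -> None:
    """Write images in [0, 1] and integer labels as an IDX file pair
    (used for round-trip tests and for exporting synthetic corpora)."""
    images = np.asarray(images)
    labels = np.asarray(labels)
    if images.shape[0] != labels.shape[0]:
        raise ValueError("image and label counts differ")
    n, rows, cols = images.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">iiii", _IMAGE_MAGIC, n, rows, cols))
        fh.write((np.clip(images, 0, 1) * 255.0).round().astype(np.uint8).tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">ii", _LABEL_MAGIC, n))
        fh.write(labels.astype(np.uint8).tobytes())


def corpus_confusability_report(
    images: np.ndarray,
    labels: np.ndarray,
    feature_model,
    sample_size: int = 400,
    t1_percentile: float = 8.0,
    seed: int = 0,
) -> dict:
    """Intra-/inter-class feature-distance summary and the calibrated
    distance threshold (the given percentile of all pairwise distances on
    a calibration sample).  Used to set the encoder's similarity threshold
    on corpora whose feature geometry differs from MNIST's."""
    from .features import extract_features

    rng = np.random.default_rng(seed)
    n = len(labels)
    idx = rng.permutation(n)[: min(sample_size, n)]
    feats = extract_features(feature_model, images[idx])
    labs = np.asarray(labels)[idx]
    diff = feats[:, None, :] - feats[None, :, :]
    dmat = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(idx), k=1)
    dists = dmat[iu]
    same = labs[iu[0]] == labs[iu[1]]
    report = {
        "n_sampled": int(len(idx)),
        "intra_mean": float(dists[same].mean()) if same.any() else float("nan"),
        "inter_mean": float(dists[~same].mean()) if (~same).any() else float("nan"),
        "intra_median": float(np.median(dists[same])) if same.any() else float("nan"),
        "inter_median": float(np.median(dists[~same])) if (~same).any() else float("nan"),
        "t1_calibrated": float(np.percentile(dists, t1_percentile)),
        "t1_percentile": float(t1_percentile),
    }
    return report
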