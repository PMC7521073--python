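"""Synthetic handwritten-glyph data, plus an IDX reader/writer.

The experiments need balanced sets of 28x28 grayscale glyph images — ten
digit classes and twenty-six uppercase letter classes — that a small
convolutional classifier can learn well above chance.  The generator
renders a fixed stroke skeleton per class (polylines and sampled arcs on
the unit square) into a 28x28 intensity image, then applies seeded
random variability emulating handwriting: an affine jitter (rotation,
translation, isotropic scale), stroke-thickness variation, optional
Gaussian blur, and additive pixel noise.  Generation is a pure function
of (classes, n, params, seed).

An optional loader for the IDX binary format used by the public EMNIST
distribution is included so the same experiments can be run on real
handwriting; nothing in the package requires it.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GlyphGenParams",
    "GlyphDataset",
    "DIGITS",
    "UPPERCASE",
    "generate_glyph",
    "generate_dataset",
    "load_idx",
    "save_idx",
]

DIGITS = [str(d) for d in range(10)]
UPPERCASE = [chr(c) for c in range(ord("A"), ord("Z") + 1)]

IMAGE_SIZE = 28


class FormatError(ValueError):
    """Raised for malformed IDX files."""


@dataclass(frozen=True)
class GlyphGenParams:
    """Variability knobs for the glyph renderer.

    Ranges are half-widths of uniform jitter distributions: rotation in
    degrees, translation in pixels, scale as a fraction of 1, stroke
    half-width variation in pixels.  ``noise_sd`` is the standard
    deviation of additive Gaussian pixel noise (intensity units, image in
    [0, 1]); ``blur_sd`` the Gaussian blur radius in pixels.
    """

    rotation_range: float = 25.0
    translation_range: float = 3.0
    scale_range: float = 0.25
    stroke_width: float = 1.0
    stroke_width_range: float = 0.5
    noise_sd: float = 0.15
    blur_sd: float = 0.6

    def __post_init__(self) -> None:
        for name in ("rotation_range", "translation_range", "scale_range",
                     "stroke_width_range", "noise_sd", "blur_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.stroke_width <= 0:
            raise ValueError("stroke_width must be positive")


@dataclass
class GlyphDataset:
    """Labeled batch of 28x28 single-channel glyph images."""

    images: np.ndarray  # (n, 28, 28, 1), float64 in [0, 1]
    labels: np.ndarray  # (n,) integer class indices
    class_names: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def __len__(self) -> int:
        return self.images.shape[0]


# ---------------------------------------------------------------------------
# class prototypes: stroke skeletons on the unit square (x right, y down)


def _arc(cx, cy, rx, ry, a0, a1, n=24):
    """Sampled elliptical arc; angles in degrees, 0 = +x, 90 = down."""
    th = np.radians(np.linspace(a0, a1, n))
    return np.column_stack([cx + rx * np.cos(th), cy + ry * np.sin(th)])


def _line(*pts):
    return np.asarray(pts, dtype=float)


def _build_prototypes() -> dict[str, list[np.ndarray]]:
    P = {}
    # digits
    P["0"] = [_arc(0.5, 0.5, 0.26, 0.34, 0, 360)]
    P["1"] = [_line((0.34, 0.30), (0.52, 0.15), (0.52, 0.85)),
              _line((0.36, 0.85), (0.68, 0.85))]
    P["2"] = [_arc(0.5, 0.36, 0.25, 0.20, 180, 355),
              _line((0.74, 0.40), (0.24, 0.85)),
              _line((0.24, 0.85), (0.78, 0.85))]
    P["3"] = [_arc(0.47, 0.33, 0.24, 0.18, -150, 90),
              _arc(0.47, 0.67, 0.26, 0.18, -90, 150)]
    P["4"] = [_line((0.68, 0.15), (0.22, 0.60)),
              _line((0.22, 0.60), (0.82, 0.60)),
              _line((0.68, 0.15), (0.68, 0.85))]
    P["5"] = [_line((0.74, 0.15), (0.28, 0.15)),
              _line((0.28, 0.15), (0.28, 0.47)),
              _arc(0.47, 0.64, 0.26, 0.20, -95, 150)]
    P["6"] = [_line((0.62, 0.15), (0.40, 0.42), (0.31, 0.62)),
              _arc(0.49, 0.66, 0.19, 0.18, 0, 360)]
    P["7"] = [_line((0.22, 0.15), (0.78, 0.15)),
              _line((0.78, 0.15), (0.40, 0.85))]
    P["8"] = [_arc(0.5, 0.32, 0.18, 0.16, 0, 360),
              _arc(0.5, 0.67, 0.22, 0.18, 0, 360)]
    P["9"] = [_arc(0.5, 0.35, 0.20, 0.19, 0, 360),
              _line((0.70, 0.38), (0.66, 0.62), (0.54, 0.85))]
    # uppercase letters
    P["A"] = [_line((0.50, 0.15), (0.22, 0.85)),
              _line((0.50, 0.15), (0.78, 0.85)),
              _line((0.33, 0.58), (0.67, 0.58))]
    P["B"] = [_line((0.26, 0.15), (0.26, 0.85)),
              _arc(0.26, 0.33, 0.29, 0.18, -90, 90),
              _arc(0.26, 0.67, 0.33, 0.18, -90, 90)]
    P["C"] = [_arc(0.55, 0.50, 0.30, 0.35, 55, 305)]
    P["D"] = [_line((0.26, 0.15), (0.26, 0.85)),
              _arc(0.26, 0.50, 0.42, 0.35, -90, 90)]
    P["E"] = [_line((0.26, 0.15), (0.26, 0.85)),
              _line((0.26, 0.15), (0.76, 0.15)),
              _line((0.26, 0.50), (0.66, 0.50)),
              _line((0.26, 0.85), (0.76, 0.85))]
    P["F"] = [_line((0.26, 0.15), (0.26, 0.85)),
              _line((0.26, 0.15), (0.76, 0.15)),
              _line((0.26, 0.50), (0.64, 0.50))]
    P["G"] = [_arc(0.52, 0.50, 0.30, 0.35, 40, 320),
              _line((0.52, 0.52), (0.80, 0.52), (0.80, 0.70))]
    P["H"] = [_line((0.25, 0.15), (0.25, 0.85)),
              _line((0.75, 0.15), (0.75, 0.85)),
              _line((0.25, 0.50), (0.75, 0.50))]
    P["I"] = [_line((0.50, 0.15), (0.50, 0.85)),
              _line((0.32, 0.15), (0.68, 0.15)),
              _line((0.32, 0.85), (0.68, 0.85))]
    P["J"] = [_line((0.40, 0.15), (0.78, 0.15)),
              _line((0.64, 0.15), (0.64, 0.64)),
              _arc(0.45, 0.64, 0.19, 0.18, 0, 180)]
    P["K"] = [_line((0.26, 0.15), (0.26, 0.85)),
              _line((0.72, 0.15), (0.26, 0.53)),
              _line((0.40, 0.42), (0.76, 0.85))]
    P["L"] = [_line((0.28, 0.15), (0.28, 0.85)),
              _line((0.28, 0.85), (0.76, 0.85))]
    P["M"] = [_line((0.20, 0.85), (0.20, 0.15)),
              _line((0.20, 0.15), (0.50, 0.62)),
              _line((0.50, 0.62), (0.80, 0.15)),
              _line((0.80, 0.15), (0.80, 0.85))]
    P["N"] = [_line((0.25, 0.85), (0.25, 0.15)),
              _line((0.25, 0.15), (0.75, 0.85)),
              _line((0.75, 0.85), (0.75, 0.15))]
    P["O"] = [_arc(0.5, 0.5, 0.28, 0.35, 0, 360)]
    P["P"] = [_line((0.27, 0.15), (0.27, 0.85)),
              _arc(0.27, 0.34, 0.31, 0.19, -90, 90)]
    P["Q"] = [_arc(0.5, 0.48, 0.27, 0.33, 0, 360),
              _line((0.58, 0.60), (0.82, 0.88))]
    P["R"] = [_line((0.27, 0.15), (0.27, 0.85)),
              _arc(0.27, 0.34, 0.31, 0.19, -90, 90),
              _line((0.32, 0.53), (0.76, 0.85))]
    P["S"] = [_arc(0.50, 0.33, 0.23, 0.18, -30, -270),
              _arc(0.50, 0.67, 0.23, 0.18, -90, 150)]
    P["T"] = [_line((0.22, 0.15), (0.78, 0.15)),
              _line((0.50, 0.15), (0.50, 0.85))]
    P["U"] = [_line((0.25, 0.15), (0.25, 0.60)),
              _arc(0.50, 0.60, 0.25, 0.25, 180, 0),
              _line((0.75, 0.60), (0.75, 0.15))]
    P["V"] = [_line((0.22, 0.15), (0.50, 0.85)),
              _line((0.50, 0.85), (0.78, 0.15))]
    P["W"] = [_line((0.18, 0.15), (0.32, 0.85)),
              _line((0.32, 0.85), (0.50, 0.40)),
              _line((0.50, 0.40), (0.68, 0.85)),
              _line((0.68, 0.85), (0.82, 0.15))]
    P["X"] = [_line((0.24, 0.15), (0.76, 0.85)),
              _line((0.76, 0.15), (0.24, 0.85))]
    P["Y"] = [_line((0.22, 0.15), (0.50, 0.50)),
              _line((0.78, 0.15), (0.50, 0.50)),
              _line((0.50, 0.50), (0.50, 0.85))]
    P["Z"] = [_line((0.24, 0.15), (0.76, 0.15)),
              _line((0.76, 0.15), (0.24, 0.85)),
              _line((0.24, 0.85), (0.76, 0.85))]
    return P


PROTOTYPES = _build_prototypes()

# pixel-centre grid, reused by every render
_GRID = np.stack(np.meshgrid(
    (np.arange(IMAGE_SIZE) + 0.5) / IMAGE_SIZE,
    (np.arange(IMAGE_SIZE) + 0.5) / IMAGE_SIZE,
    indexing="xy"), axis=-1).reshape(-1, 2)  # (784, 2) as (x, y)


def _distance_field(strokes: list[np.ndarray]) -> np.ndarray:
    """Min distance (unit-square units) from each pixel centre to strokes."""
    d = np.full(_GRID.shape[0], np.inf)
    for poly in strokes:
        a = poly[:-1]
        b = poly[1:]
        ab = b - a  # (s, 2)
        denom = (ab * ab).sum(axis=1)
        denom[denom == 0] = 1e-12
        ap = _GRID[:, None, :] - a[None, :, :]  # (784, s, 2)
        t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom, 0.0, 1.0)
        proj = a[None, :, :] + t[..., None] * ab[None, :, :]
        dist = np.sqrt(((proj - _GRID[:, None, :]) ** 2).sum(axis=2))
        d = np.minimum(d, dist.min(axis=1))
    return d


def generate_glyph(class_name: str, params: GlyphGenParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Render one 28x28 glyph image with seeded variability.

    Deterministic given the RNG state; with all ranges and noise zero the
    undistorted prototype rendering is returned.
    """
    if class_name not in PROTOTYPES:
        raise ValueError(f"unknown glyph class {class_name!r}")
    strokes = PROTOTYPES[class_name]

    angle = np.radians(rng.uniform(-1, 1) * params.rotation_range)
    scale = 1.0 + rng.uniform(-1, 1) * params.scale_range
    shift = rng.uniform(-1, 1, size=2) * params.translation_range / IMAGE_SIZE
    half_w = max(
        0.2, params.stroke_width + rng.uniform(-1, 1) * params.stroke_width_range
    ) / IMAGE_SIZE
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    centre = np.array([0.5, 0.5])
    moved = [ (poly - centre) @ (scale * rot.T) + centre + shift
              for poly in strokes ]

    d = _distance_field(moved)
    # smooth-edged stroke: full intensity inside the half-width, soft rim
    img = np.exp(-np.maximum(d - half_w, 0.0) ** 2 / (2 * (0.6 / IMAGE_SIZE) ** 2))
    img = img.reshape(IMAGE_SIZE, IMAGE_SIZE)
    if params.blur_sd > 0:
        img = gaussian_filter(img, params.blur_sd)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(classes: Sequence[str], n: int,
                     params: GlyphGenParams | None = None,
                     seed: int = 0, balanced: bool = True) -> GlyphDataset:
    """Generate ``n`` labeled glyphs over ``classes``.

    Balanced mode assigns per-class counts differing by at most one
    (``n`` mod ``len(classes)`` classes get the extra image), then
    shuffles the order.  Disjoint train/test sets are obtained by calling
    with distinct seeds.
    """
    classes = list(classes)
    params = params or GlyphGenParams()
    if balanced and n < len(classes):
        raise ValueError(
            f"balanced dataset needs n >= {len(classes)} classes, got n={n}"
        )
    rng = np.random.default_rng(seed)
    if balanced:
        base, extra = divmod(n, len(classes))
        counts = [base + (i < extra) for i in range(len(classes))]
        labels = np.repeat(np.arange(len(classes)), counts)
    else:
        labels = rng.integers(0, len(classes), size=n)
    rng.shuffle(labels)
    images = np.empty((n, IMAGE_SIZE, IMAGE_SIZE, 1))
    for i, lab in enumerate(labels):
        images[i, :, :, 0] = generate_glyph(classes[lab], params, rng)
    return GlyphDataset(
        images=images,
        labels=labels.astype(np.int64),
        class_names=classes,
        provenance={"kind": "synthetic", "seed": seed, "n": n,
                    "balanced": balanced, "params": vars(params) | {}},
    )


# ---------------------------------------------------------------------------
# IDX format (big-endian; magic 0x803 for image tensors, 0x801 for labels)

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


def _open_maybe_gzip(path, mode="rb"):
    with open(path, "rb") as fh:
        gz = fh.read(2) == b"\x1f\x8b"
    return gzip.open(path, mode) if gz else open(path, mode)


def load_idx(images_path: str, labels_path: str,
             class_names: Sequence[str] | None = None,
             transpose: bool = True) -> GlyphDataset:
    """Read an IDX image/label file pair into a :class:`GlyphDataset`.

    Pixel bytes are rescaled to [0, 1].  ``transpose=True`` (default)
    swaps each image's row/column axes: the public EMNIST files store
    images transposed relative to the usual visual orientation.  Set it
    to False for files written by :func:`save_idx`, which uses the
    conventional orientation.
    """
    with _open_maybe_gzip(images_path) as fh:
        header = fh.read(16)
        if len(header) < 16:
            raise FormatError(f"{images_path}: truncated IDX header")
        magic, n, rows, cols = struct.unpack(">IIII", header)
        if magic != _IDX_IMAGES_MAGIC:
            raise FormatError(f"{images_path}: bad IDX magic {magic:#010x}")
        payload = fh.read(n * rows * cols)
        if len(payload) != n * rows * cols:
            raise FormatError(f"{images_path}: truncated IDX payload")
        images = np.frombuffer(payload, dtype=np.uint8).reshape(n, rows, cols)
    with _open_maybe_gzip(labels_path) as fh:
        header = fh.read(8)
        if len(header) < 8:
            raise FormatError(f"{labels_path}: truncated IDX header")
        magic, n_lab = struct.unpack(">II", header)
        if magic != _IDX_LABELS_MAGIC:
            raise FormatError(f"{labels_path}: bad IDX magic {magic:#010x}")
        payload = fh.read(n_lab)
        if len(payload) != n_lab:
            raise FormatError(f"{labels_path}: truncated IDX payload")
        labels = np.frombuffer(payload, dtype=np.uint8).astype(np.int64)
    if n != n_lab:
        raise FormatError(
            f"{images_path}: {n} images but {labels_path} has {n_lab} labels"
        )
    if transpose:
        images = images.transpose(0, 2, 1)
    pixels = images.astype(np.float64)[..., None] / 255.0
    if class_names is None:
        class_names = [str(c) for c in range(int(labels.max()) + 1 if n else 0)]
    return GlyphDataset(
        images=pixels, labels=labels, class_names=list(class_names),
        provenance={"kind": "idx", "images_path": str(images_path),
                    "labels_path": str(labels_path)},
    )


def save_idx(dataset: GlyphDataset, images_path: str,
             labels_path: str) -> None:
    """Write a dataset as an IDX image/label file pair (uncompressed)."""
    imgs = np.clip(dataset.images[..., 0] * 255.0, 0, 255).round()
    imgs = imgs.astype(np.uint8)
    n, rows, cols = imgs.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(imgs.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS_MAGIC, n))
        fh.write(dataset.labels.astype(np.uint8).tobytes())
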