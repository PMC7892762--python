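"""Synthetic images and datasets, plus IDX/PGM loaders.

The toy generator emulates the stroke structure the Hough input layers
detect in handwritten digits: straight strokes of a given orientation and
circular strokes of a given radius.  Classes of
:func:`make_toy_dataset` differ in their Hough signature — line classes by
orientation (and hence theta cell), the circle class by centre/radius
cells — so the full modular + Hough pipeline is exercised end to end
without any external download.  All images are 28x28 floats in [0, 1].
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ToyShapeSpec",
    "make_shape_image",
    "make_toy_dataset",
    "TOY_CLASSES",
    "load_idx",
    "load_pgm",
    "save_pgm",
]

TOY_CLASSES = ("vline", "hline", "diag", "circle")


@dataclass
class ToyShapeSpec:
    """A single synthetic stroke image.

    shape : one of vline, hline, diag, circle, composite.
    params : geometry — vline: {"x"}; hline: {"y"}; diag: {"offset"}
             (the line y = x + offset); circle: {"cx", "cy", "r",
             "rasterize": "ring"|"strict"}; composite: {"parts": [specs]}.
    pixel_jitter : fraction in [0, 1]; stroke pixels are dropped with
             probability ``0.3 * pixel_jitter`` and background speckle is
             added with probability ``0.02 * pixel_jitter`` per pixel.
    """

    shape: str
    params: dict = field(default_factory=dict)
    intensity: float = 1.0
    pixel_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("vline", "hline", "diag", "circle", "composite"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not 0 <= self.pixel_jitter <= 1:
            raise ValueError("pixel_jitter must lie in [0, 1]")


def _draw(spec: ToyShapeSpec, dims: tuple[int, int]) -> np.ndarray:
    h, w = dims
    img = np.zeros(dims)
    p = spec.params
    if spec.shape == "vline":
        x = int(p.get("x", w // 2))
        if not 0 <= x < w:
            raise ValueError("vline column out of bounds")
        img[:, x] = spec.intensity
    elif spec.shape == "hline":
        y = int(p.get("y", h // 2))
        if not 0 <= y < h:
            raise ValueError("hline row out of bounds")
        img[y, :] = spec.intensity
    elif spec.shape == "diag":
        off = int(p.get("offset", 0))
        xs = np.arange(w)
        ys = xs + off
        ok = (ys >= 0) & (ys < h)
        if not ok.any():
            raise ValueError("diagonal entirely out of bounds")
        img[ys[ok], xs[ok]] = spec.intensity
    elif spec.shape == "circle":
        cx, cy = float(p.get("cx", 13)), float(p.get("cy", 13))
        r = float(p.get("r", 6))
        if r < 0 or not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("circle geometry out of bounds")
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
        if p.get("rasterize", "ring") == "strict":
            on = np.abs(d**2 - r**2) < 1e-9
        else:
            on = np.abs(d - r) <= 0.5
        img[on] = spec.intensity
    else:  # composite
        for part in p.get("parts", []):
            img = np.maximum(img, _draw(part, dims))
    return img


def make_shape_image(spec: ToyShapeSpec, dims: tuple[int, int] = (28, 28)) -> np.ndarray:
    """Render a deterministic stroke image; same spec (incl. seed) ->
    identical image."""
    img = _draw(spec, dims)
    if spec.pixel_jitter > 0:
        rng = np.random.default_rng(spec.seed)
        drop = rng.random(dims) < 0.3 * spec.pixel_jitter
        img = np.where(drop, 0.0, img)
        speckle = rng.random(dims) < 0.02 * spec.pixel_jitter
        img = np.maximum(img, np.where(speckle, spec.intensity, 0.0))
    return img


def make_toy_dataset(
    n_classes: int,
    n_per_class: int,
    jitter: float = 0.0,
    seed: int | None = None,
    dims: tuple[int, int] = (28, 28),
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labelled dataset of jittered strokes.

    Classes (in order): vertical line, horizontal line, diagonal line,
    circle.  ``jitter`` in [0, 1] scales the within-class geometric
    variability — stroke position / diagonal offset vary by up to
    ``round(9 * jitter)`` px and the circle radius by up to
    ``round(3 * jitter)`` px — plus mild pixel dropout/speckle.  At
    jitter 0 every image of a class is identical (the canonical shape).

    Returns ``(images, labels)`` with images of shape
    (n_classes * n_per_class, *dims), grouped by class; labels are a
    deterministic function of the seed and stable under relabelling of
    sample order within the generator.
    """
    if not 1 <= n_classes <= len(TOY_CLASSES):
        raise ValueError(f"n_classes must be 1..{len(TOY_CLASSES)}")
    if n_per_class < 1:
        raise ValueError("n_per_class must be positive")
    if not 0 <= jitter <= 1:
        raise ValueError("jitter must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pos_range = round(9 * jitter)
    rad_range = round(3 * jitter)
    h, w = dims
    cx0, cy0 = (w - 1) // 2, (h - 1) // 2
    images, labels = [], []
    for label, cls in enumerate(TOY_CLASSES[:n_classes]):
        for k in range(n_per_class):
            dp = int(rng.integers(-pos_range, pos_range + 1)) if pos_range else 0
            dr = int(rng.integers(-rad_range, rad_range + 1)) if rad_range else 0
            sub_seed = int(rng.integers(2**31)) if jitter > 0 else 0
            if cls == "vline":
                params = {"x": np.clip(cx0 + dp, 0, w - 1)}
            elif cls == "hline":
                params = {"y": np.clip(cy0 + dp, 0, h - 1)}
            elif cls == "diag":
                params = {"offset": dp}
            else:
                params = {
                    "cx": np.clip(cx0 + dp // 2, 6, w - 7),
                    "cy": np.clip(cy0 - dp // 2, 6, h - 7),
                    "r": max(3, 6 + dr),
                }
            spec = ToyShapeSpec(
                cls, params, pixel_jitter=0.3 * jitter if jitter > 0 else 0.0,
                seed=sub_seed,
            )
            images.append(make_shape_image(spec, dims))
            labels.append(label)
    return np.stack(images), np.array(labels, dtype=np.int64)


# ---------------------------------------------------------------------------
# IDX (big-endian image/label containers)
# ---------------------------------------------------------------------------
def _read_idx(path: Path) -> np.ndarray:
    data = path.read_bytes()
    if len(data) < 4:
        raise ValueError(f"{path}: truncated IDX header")
    zero1, zero2, dtype_code, n_dims = struct.unpack(">BBBB", data[:4])
    if zero1 != 0 or zero2 != 0:
        raise ValueError(f"{path}: bad IDX magic at offset 0: {data[:4]!r}")
    if dtype_code != 0x08:
        raise ValueError(f"{path}: unsupported IDX dtype code 0x{dtype_code:02x}")
    header_len = 4 + 4 * n_dims
    if len(data) < header_len:
        raise ValueError(f"{path}: truncated IDX dimension block")
    dims = struct.unpack(f">{n_dims}I", data[4:header_len])
    expected = int(np.prod(dims))
    payload = data[header_len:]
    if len(payload) != expected:
        raise ValueError(
            f"{path}: payload has {len(payload)} bytes, header promises {expected}"
        )
    return np.frombuffer(payload, dtype=np.uint8).reshape(dims)


def load_idx(images_path: str | Path, labels_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load an IDX image/label pair (idx3-ubyte / idx1-ubyte).

    Magic numbers and payload sizes are validated; intensities are scaled
    to [0, 1].  Raises on truncation, a bad magic number, or an
    image/label count mismatch — never returns partial data.
    """
    images = _read_idx(Path(images_path))
    labels = _read_idx(Path(labels_path))
    if images.ndim != 3:
        raise ValueError(f"{images_path}: expected a rank-3 image container")
    if labels.ndim != 1:
        raise ValueError(f"{labels_path}: expected a rank-1 label container")
    if images.shape[0] != labels.shape[0]:
        raise ValueError(
            f"image/label count mismatch: {images.shape[0]} vs {labels.shape[0]}"
        )
    return images.astype(np.float64) / 255.0, labels.astype(np.int64)


# ---------------------------------------------------------------------------
# PGM
# ---------------------------------------------------------------------------
def load_pgm(path: str | Path) -> np.ndarray:
    """Read a PGM image (ASCII P2 or binary P5), normalised to [0, 1]."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im, dtype=np.float64)
    return arr / 255.0


def save_pgm(image: np.ndarray, path: str | Path) -> None:
    """Write an intensity image in [0, 1] as ASCII PGM (P2)."""
    arr = np.clip(np.asarray(image) * 255.0, 0, 255).round().astype(int)
    h, w = arr.shape
    lines = [f"P2", f"{w} {h}", "255"]
    lines += [" ".join(str(v) for v in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")
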