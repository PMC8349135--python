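"""Reading, converting and augmenting thermal images.

Inputs are 8/16-bit PNG/TIFF/JPEG frames or plain-text temperature
matrices (whitespace-delimited °C values, one row per line, as exported
from radiometric captures).  Records resize to the 299x299 network
geometry, convert between color and grayscale, and pass through a seeded
augmentation pipeline: random mirror across the vertical (left-right)
axis, integer translation up to ±30 pixels per axis, and up-to-10%
per-axis upscaling — each draw taken from a single seeded generator so a
(seed, policy) pair reproduces the augmented stream exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageRecord",
    "AugmentationPolicy",
    "FormatError",
    "StratificationError",
    "load_image",
    "load_temperature_matrix",
    "write_temperature_matrix",
    "to_grayscale",
    "resize_to_network",
    "augment",
    "translate",
    "split_dataset",
]

#: Standard luminance weights for RGB -> grayscale.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

TEXT_SUFFIXES = {".txt", ".dat", ".tsv"}
IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


class FormatError(ValueError):
    """Unreadable or malformed thermal input."""


class StratificationError(ValueError):
    """A label class required for a stratified split is empty."""


@dataclass
class ImageRecord:
    """A pixel array with its label and provenance.

    ``pixels`` is (H, W) or (H, W, 3); grayscale records are 2-D.
    ``label`` is ``"healthy"``/``"sick"`` for training records and may be
    ``None`` for inference inputs.
    """

    pixels: np.ndarray
    label: str | None
    source_id: str
    color_mode: str  # "color" | "grayscale"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(f"bad pixel array shape {px.shape} for {self.source_id!r}")
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise FormatError(f"expected 1 or 3 channels, got {px.shape[2]}")
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if self.color_mode not in ("color", "grayscale"):
            raise ValueError(f"bad color_mode {self.color_mode!r}")
        if self.color_mode == "grayscale" and px.ndim == 3:
            raise FormatError("grayscale records must have a single channel")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def load_temperature_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace-delimited temperature matrix (°C) as float64."""
    path = Path(path)
    try:
        mat = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse temperature matrix {path}: {exc}") from exc
    if mat.size == 0:
        raise FormatError(f"empty temperature matrix {path}")
    return mat


def write_temperature_matrix(path: str | Path, temps: np.ndarray) -> None:
    np.savetxt(path, np.asarray(temps, dtype=np.float64), fmt="%.6f")


def scale_to_uint16(values: np.ndarray) -> np.ndarray:
    """Min-max scale an arbitrary real-valued field onto the full 16-bit
    range (a constant field maps to zero)."""
    values = np.asarray(values, dtype=np.float64)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros(values.shape, dtype=np.uint16)
    return np.round((values - lo) / (hi - lo) * 65535.0).astype(np.uint16)


def load_image(
    path: str | Path, declared_mode: str | None = None, label: str | None = None
) -> ImageRecord:
    """Load a thermal input, preserving bit depth.

    Text matrices are min-max scaled onto the 16-bit range and loaded as
    grayscale.  Image files keep their native 8- or 16-bit values.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in TEXT_SUFFIXES:
        pixels = scale_to_uint16(load_temperature_matrix(path))
        mode = "grayscale"
    elif suffix in IMAGE_SUFFIXES:
        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except OSError as exc:
            raise FormatError(f"cannot read image {path}: {exc}") from exc
        if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.dtype == np.int32:  # PIL mode "I" for 16-bit PNGs
            arr = np.clip(arr, 0, 65535).astype(np.uint16)
        pixels = arr
        mode = "color" if arr.ndim == 3 else "grayscale"
    else:
        raise FormatError(f"unsupported input format {suffix!r} for {path}")
    if declared_mode is not None and declared_mode != mode:
        if declared_mode == "grayscale" and mode == "color":
            return to_grayscale(
                ImageRecord(pixels, label, str(path), "color")
            )
        raise FormatError(
            f"{path}: declared mode {declared_mode!r} but file reads as {mode!r}"
        )
    return ImageRecord(pixels, label, str(path), mode)


def to_grayscale(record: ImageRecord) -> ImageRecord:
    """Collapse RGB to one channel with fixed luminance weights
    (0.299, 0.587, 0.114); already-gray input passes through unchanged."""
    px = record.pixels
    if px.ndim == 2:
        return replace(record, pixels=px.copy(), color_mode="grayscale")
    weights = np.asarray(LUMINANCE_WEIGHTS, dtype=np.float64)
    gray = px.astype(np.float64) @ weights
    if np.issubdtype(px.dtype, np.integer):
        gray = np.round(gray).astype(px.dtype)
    else:
        gray = gray.astype(px.dtype)
    return replace(record, pixels=gray, color_mode="grayscale")


def resize_to_network(record: ImageRecord, side: int = 299) -> ImageRecord:
    """Resize to side x side and replicate single-channel input to three
    channels for network ingestion (bilinear, range-preserving)."""
    if side < 1:
        raise ValueError("side must be positive")
    px = record.pixels
    if px.shape[:2] == (side, side):
        out = px.astype(np.float64)
    else:
        out = _sk_resize(
            px.astype(np.float64), (side, side), order=1,
            preserve_range=True, anti_aliasing=False,
        )
    if out.ndim == 2:
        out = np.repeat(out[:, :, None], 3, axis=2)
    if np.issubdtype(px.dtype, np.integer):
        info = np.iinfo(px.dtype)
        out = np.clip(np.round(out), info.min, info.max).astype(px.dtype)
    else:
        out = out.astype(px.dtype)
    if out.shape != (side, side, 3):
        raise AssertionError(f"resize contract violated: {out.shape}")
    # network-ready records are always 3-channel; replicated grayscale is
    # recorded as color so the 1-channel grayscale invariant stays intact
    return replace(record, pixels=out, color_mode="color")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Training-time augmentation ranges.

    ``flip_vertical_axis`` mirrors left-right with probability 0.5 — the
    anatomically meaningful reading for bilateral breast symmetry; set
    ``flip_axis="vertical"`` for the up-down reading.  Translation is an
    integer offset drawn uniformly in [-max_translation, +max_translation]
    per axis with edge-replication fill; scaling is a per-axis factor
    drawn uniformly in [1, 1 + max_scale_fraction].
    """

    flip_vertical_axis: bool = True
    max_translation: int = 30
    max_scale_fraction: float = 0.10
    seed: int = 0
    flip_axis: str = "horizontal"  # mirror left-right by default

    def __post_init__(self):
        if self.max_translation < 0:
            raise ValueError("max_translation must be >= 0")
        if not (0.0 <= self.max_scale_fraction < 1.0):
            raise ValueError("max_scale_fraction must be in [0, 1)")
        if self.flip_axis not in ("horizontal", "vertical"):
            raise ValueError("flip_axis must be 'horizontal' or 'vertical'")

    def make_rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def translate(pixels: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Shift content by (rows, cols) with edge-replication fill; output
    dims unchanged.  Positive offsets move content down/right."""
    h, w = pixels.shape[:2]
    ar, ac = abs(int(rows)), abs(int(cols))
    if ar >= h or ac >= w:
        raise ValueError("translation exceeds image size")
    pad = [(ar, ar), (ac, ac)] + [(0, 0)] * (pixels.ndim - 2)
    padded = np.pad(pixels, pad, mode="edge")
    r0 = ar - int(rows)
    c0 = ac - int(cols)
    return padded[r0 : r0 + h, c0 : c0 + w, ...]


def _rescale(pixels: np.ndarray, sy: float, sx: float) -> np.ndarray:
    """Upscale per-axis then center-crop back to the original dims."""
    if sy == 1.0 and sx == 1.0:
        return pixels
    h, w = pixels.shape[:2]
    nh, nw = max(h, int(round(h * sy))), max(w, int(round(w * sx)))
    out = _sk_resize(
        pixels.astype(np.float64), (nh, nw) + pixels.shape[2:], order=1,
        preserve_range=True, anti_aliasing=False,
    )
    r0, c0 = (nh - h) // 2, (nw - w) // 2
    out = out[r0 : r0 + h, c0 : c0 + w, ...]
    if np.issubdtype(pixels.dtype, np.integer):
        info = np.iinfo(pixels.dtype)
        out = np.clip(np.round(out), info.min, info.max)
    return out.astype(pixels.dtype)


def augment(
    record: ImageRecord,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> ImageRecord:
    """Apply one random flip/translate/scale draw from ``rng``.

    All draws come from the one generator passed in, in a fixed order, so
    identical seeds yield bit-identical outputs; zero-range policies are
    the identity.
    """
    px = record.pixels
    if policy.flip_vertical_axis and rng.random() < 0.5:
        px = px[:, ::-1, ...] if policy.flip_axis == "horizontal" else px[::-1, :, ...]
    if policy.max_translation > 0:
        dr = int(rng.integers(-policy.max_translation, policy.max_translation + 1))
        dc = int(rng.integers(-policy.max_translation, policy.max_translation + 1))
        px = translate(px, dr, dc)
    if policy.max_scale_fraction > 0:
        sy = float(rng.uniform(1.0, 1.0 + policy.max_scale_fraction))
        sx = float(rng.uniform(1.0, 1.0 + policy.max_scale_fraction))
        px = _rescale(px, sy, sx)
    return replace(record, pixels=np.ascontiguousarray(px))


def split_dataset(
    records: Sequence[ImageRecord], train_fraction: float, seed: int
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Stratified train/test partition.

    Per class, ``floor(train_fraction * n)`` records go to the training
    set after a seeded shuffle; the partition is exact (no overlap, union
    equals the input) and label proportions in each part are within one
    record of the requested fraction.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    groups: dict[str, list[ImageRecord]] = {}
    for rec in records:
        if rec.label is None:
            raise StratificationError(f"record {rec.source_id!r} has no label")
        groups.setdefault(rec.label, []).append(rec)
    if len(groups) < 2:
        raise StratificationError(
            f"stratified split needs at least two classes, found {sorted(groups)}"
        )
    rng = np.random.default_rng(seed)
    train: list[ImageRecord] = []
    test: list[ImageRecord] = []
    for label in sorted(groups):
        members = groups[label]
        order = rng.permutation(len(members))
        n_train = math.floor(train_fraction * len(members))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test
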