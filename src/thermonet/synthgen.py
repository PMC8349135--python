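"""Synthetic breast thermograms.

The generator emulates the statistical structure a thermography classifier
relies on, not the biophysics: a frontal-torso temperature field that is
*bilaterally symmetric and smooth* for healthy subjects, plus one or more
*localized asymmetric hot spots* (tumour-associated hyperthermia, 1-3 °C
above the surrounding skin) for sick subjects, over a FLIR-SC-620-like
480x640 16-bit frame acquired at 18-25 °C room temperature.

Healthy frames are mirror-symmetric about the midline column by
construction (before sensor noise); sick frames add a Gaussian temperature
bump centered inside one breast.  Fields are quantized to 16 bits over a
configurable rendering window (default 22-38 °C, physiological contrast
rather than the camera's full -40..500 °C span) and rendered either as
16-bit grayscale or through a fixed rainbow palette.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .thermal_io import ImageRecord

__all__ = [
    "LesionSpec",
    "SimulationConfig",
    "LesionPlacementError",
    "generate_thermogram",
    "generate_records",
    "generate_dataset",
    "separability_report",
    "asymmetry_statistic",
    "rainbow_palette",
]


class LesionPlacementError(RuntimeError):
    """No valid lesion position found within the breast mask."""


@dataclass(frozen=True)
class LesionSpec:
    """One simulated hyperthermic lesion.

    ``delta_t`` is the peak temperature elevation in °C at the lesion
    center; the bump is Gaussian with standard deviation ``radius / 2``,
    truncated to zero beyond three standard deviations so the elevation is
    strictly local.  Placement guarantees the truncation disc never
    reaches the mirrored contralateral position, which keeps the
    left-right asymmetry of a noise-free sick frame exactly ``delta_t``.
    """

    center: tuple[int, int]  # (row, col)
    radius: float            # pixels
    delta_t: float           # °C
    side: str                # "left" | "right" (image-left / image-right)

    def __post_init__(self):
        if self.radius <= 0 or self.delta_t <= 0:
            raise ValueError("lesion radius and delta_t must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition-emulation parameters (temperatures in °C)."""

    frame_height: int = 480
    frame_width: int = 640
    baseline_temp: float = 33.0
    ambient_temp: float = 20.0
    # normal smooth skin-temperature variation is well under 1 °C; tumour
    # hotspots run 1-3 °C over a broad vascularized region
    gradient_amplitude: float = 0.5   # amplitude of the smooth physiological field
    noise_sd: float = 0.2             # sensor noise
    min_lesions: int = 1
    max_lesions: int = 1
    delta_t_range: tuple[float, float] = (1.0, 3.0)
    lesion_radius_frac: tuple[float, float] = (0.10, 0.16)  # of frame height
    render_window: tuple[float, float] = (22.0, 38.0)
    seed: int = 0

    def __post_init__(self):
        if self.frame_height < 8 or self.frame_width < 8 or self.frame_width % 2:
            raise ValueError("frame must be at least 8x8 with an even width")
        if not (18.0 <= self.ambient_temp <= 25.0):
            raise ValueError("ambient_temp must lie in [18, 25] °C")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.min_lesions <= self.max_lesions):
            raise ValueError("need 1 <= min_lesions <= max_lesions")
        lo, hi = self.delta_t_range
        if not (0 < lo <= hi):
            raise ValueError("delta_t_range must be positive and ordered")
        w0, w1 = self.render_window
        if not w0 < w1:
            raise ValueError("render_window must be increasing")

    @property
    def quantization_step(self) -> float:
        w0, w1 = self.render_window
        return (w1 - w0) / 65535.0


# ---------------------------------------------------------------------------
# geometry


def _masks(h: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Torso ellipse plus left/right breast discs, all symmetric about the
    midline (cached per frame shape)."""
    key = (h, w)
    cached = _masks._cache.get(key)
    if cached is not None:
        return cached
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    cy, cx = 0.52 * h, (w - 1) / 2.0
    torso = ((rows - cy) / (0.46 * h)) ** 2 + ((cols - cx) / (0.40 * w)) ** 2 <= 1.0
    br = 0.16 * min(h, w)
    bcy = 0.58 * h
    left_cx = cx - 0.17 * w
    right_cx = cx + 0.17 * w
    left = (rows - bcy) ** 2 + (cols - left_cx) ** 2 <= br**2
    right = (rows - bcy) ** 2 + (cols - right_cx) ** 2 <= br**2
    result = (torso, torso & left, torso & right)
    _masks._cache[key] = result
    return result


_masks._cache = {}


def _smooth_symmetric_field(
    h: int, w: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-frequency field, exactly mirror-symmetric about the midline:
    coarse Gaussian grid upsampled over the left half, then mirrored."""
    coarse = rng.normal(0.0, 1.0, size=(6, 4))
    half = _sk_resize(coarse, (h, w // 2), order=3, mode="edge",
                      preserve_range=True, anti_aliasing=False)
    return amplitude * np.concatenate([half, half[:, ::-1]], axis=1)


def _place_lesion(
    config: SimulationConfig, rng: np.random.Generator, max_attempts: int = 100
) -> LesionSpec:
    h, w = config.frame_height, config.frame_width
    _, left, right = _masks(h, w)
    side = "left" if rng.random() < 0.5 else "right"
    mask = left if side == "left" else right
    radius = float(rng.uniform(*config.lesion_radius_frac) * h)
    delta_t = float(rng.uniform(*config.delta_t_range))
    sigma = radius / 2.0
    midline = (w - 1) / 2.0
    for _ in range(max_attempts):
        r = int(rng.integers(0, h))
        c = int(rng.integers(0, w))
        # the truncated bump (3 sigma) must not touch the mirrored position
        if mask[r, c] and 2.0 * abs(c - midline) > 3.0 * sigma + 1.0:
            return LesionSpec(center=(r, c), radius=radius, delta_t=delta_t, side=side)
    raise LesionPlacementError(
        f"no valid lesion position found in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# rendering


def rainbow_palette() -> np.ndarray:
    """Fixed 256-entry rainbow LUT (uint8 RGB), documented and
    reproducible: piecewise-linear blue -> cyan -> green -> yellow -> red."""
    x = np.linspace(0.0, 1.0, 256)
    r = np.clip(np.minimum(4 * x - 1.5, -4 * x + 4.5), 0, 1)
    g = np.clip(np.minimum(4 * x - 0.5, -4 * x + 3.5), 0, 1)
    b = np.clip(np.minimum(4 * x + 0.5, -4 * x + 2.5), 0, 1)
    return np.round(np.stack([r, g, b], axis=1) * 255).astype(np.uint8)


_PALETTE = rainbow_palette()


def quantize_temperatures(temps: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Clip to the rendering window and quantize to uint16; the implied
    temperature error is at most (window span)/65535."""
    w0, w1 = window
    clipped = np.clip(temps, w0, w1)
    return np.round((clipped - w0) / (w1 - w0) * 65535.0).astype(np.uint16)


def render(temps: np.ndarray, window: tuple[float, float], color_mode: str) -> np.ndarray:
    u16 = quantize_temperatures(temps, window)
    if color_mode == "grayscale":
        return u16
    if color_mode == "color":
        return _PALETTE[(u16 >> 8).astype(np.uint8)]
    raise ValueError(f"bad color_mode {color_mode!r}")


def implied_temperatures(u16: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    w0, w1 = window
    return w0 + u16.astype(np.float64) / 65535.0 * (w1 - w0)


# ---------------------------------------------------------------------------
# generation


def generate_thermogram(
    config: SimulationConfig,
    label: str,
    rng: np.random.Generator | int | None = None,
    color_mode: str = "grayscale",
    source_id: str = "synthetic",
) -> tuple[np.ndarray, ImageRecord, list[LesionSpec]]:
    """Simulate one frame.

    Returns the continuous temperature field (°C, float64), the rendered
    :class:`~thermonet.thermal_io.ImageRecord`, and the lesion list (empty
    for healthy frames).  With ``noise_sd = 0`` a healthy field is exactly
    mirror-symmetric about the midline column.
    """
    if label not in ("healthy", "sick"):
        raise ValueError("label must be 'healthy' or 'sick'")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(config.seed if rng is None else int(rng))
    h, w = config.frame_height, config.frame_width
    torso, _, _ = _masks(h, w)
    temps = np.full((h, w), config.ambient_temp, dtype=np.float64)
    body = config.baseline_temp + _smooth_symmetric_field(
        h, w, config.gradient_amplitude, rng
    )
    temps[torso] = body[torso]
    lesions: list[LesionSpec] = []
    if label == "sick":
        n = int(rng.integers(config.min_lesions, config.max_lesions + 1))
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        for _ in range(n):
            lesion = _place_lesion(config, rng)
            sigma = lesion.radius / 2.0
            d2 = (rows - lesion.center[0]) ** 2 + (cols - lesion.center[1]) ** 2
            bump = lesion.delta_t * np.exp(-d2 / (2.0 * sigma**2))
            bump[d2 > (3.0 * sigma) ** 2] = 0.0  # strictly local elevation
            temps += bump
            lesions.append(lesion)
    if config.noise_sd > 0:
        temps = temps + rng.normal(0.0, config.noise_sd, size=(h, w))
    record = ImageRecord(
        pixels=render(temps, config.render_window, color_mode),
        label=label,
        source_id=source_id,
        color_mode=color_mode,
    )
    return temps, record, lesions


def _record_seed(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(index,)))


def generate_records(
    n_healthy: int,
    n_sick: int,
    config: SimulationConfig | None = None,
    color_mode: str = "grayscale",
    master_seed: int | None = None,
) -> list[tuple[ImageRecord, list[LesionSpec]]]:
    """In-memory dataset: ``n_healthy`` healthy then ``n_sick`` sick
    records, each generated from a seed derived from the master seed so
    any single record is reproducible on its own."""
    config = config or SimulationConfig()
    if n_healthy < 0 or n_sick < 0:
        raise ValueError("class counts must be >= 0")
    master = config.seed if master_seed is None else master_seed
    out = []
    labels = ["healthy"] * n_healthy + ["sick"] * n_sick
    for i, label in enumerate(labels):
        _, record, lesions = generate_thermogram(
            config, label, _record_seed(master, i), color_mode,
            source_id=f"{label}_{i:05d}",
        )
        out.append((record, lesions))
    return out


def generate_dataset(
    n_healthy: int,
    n_sick: int,
    config: SimulationConfig | None = None,
    out_dir: str | Path = "synthetic_data",
    color_mode: str = "grayscale",
    master_seed: int | None = None,
) -> Path:
    """Write PNG frames plus a CSV manifest; returns the manifest path.

    The manifest columns are (path, label, side, center_row, center_col,
    radius, delta_t, record_index); regeneration with the same master
    seed is byte-identical.
    """
    config = config or SimulationConfig()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    for i, (record, lesions) in enumerate(
        generate_records(n_healthy, n_sick, config, color_mode, master_seed)
    ):
        fname = f"{record.source_id}.png"
        px = record.pixels
        if color_mode == "grayscale":
            Image.fromarray(px).save(out_dir / fname)  # uint16 -> 16-bit PNG
        else:
            Image.fromarray(px, mode="RGB").save(out_dir / fname)
        lesion = lesions[0] if lesions else None
        rows.append(
            {
                "path": fname,
                "label": record.label,
                "side": lesion.side if lesion else "",
                "center_row": lesion.center[0] if lesion else "",
                "center_col": lesion.center[1] if lesion else "",
                "radius": f"{lesion.radius:.3f}" if lesion else "",
                "delta_t": f"{lesion.delta_t:.3f}" if lesion else "",
                "record_index": i,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    with open(out_dir / "config.json", "w") as fh:
        json.dump({"config": asdict(config), "color_mode": color_mode,
                   "master_seed": config.seed if master_seed is None else master_seed,
                   "n_healthy": n_healthy, "n_sick": n_sick}, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# separability


def asymmetry_statistic(record: ImageRecord, window: tuple[float, float]) -> float:
    """Left-right maximum-temperature asymmetry of a grayscale frame:
    the maximum over pixels of ``|T - mirror(T)|`` in °C, where the mirror
    is taken about the midline column.  Zero for a noise-free healthy
    frame; exactly the peak lesion elevation for a noise-free sick one."""
    px = record.pixels
    if px.ndim == 3:
        raise ValueError("asymmetry statistic requires a grayscale record")
    temps = implied_temperatures(px, window)
    return float(np.abs(temps - temps[:, ::-1]).max())


def separability_report(
    records: Iterable[ImageRecord],
    config: SimulationConfig | None = None,
) -> dict:
    """Class-conditional distribution of the asymmetry statistic.

    Returns per-class n/mean/sd/min/max plus whether the class ranges
    overlap; with ``delta_t`` well above the noise level the healthy and
    sick ranges separate completely.
    """
    config = config or SimulationConfig()
    stats: dict[str, list[float]] = {}
    for rec in records:
        if rec.label is None:
            continue
        stats.setdefault(rec.label, []).append(
            asymmetry_statistic(rec, config.render_window)
        )
    if any(len(v) < 2 for v in stats.values()) or len(stats) < 2:
        raise ValueError("separability report needs at least 2 records per class")
    out: dict = {}
    for label, values in sorted(stats.items()):
        arr = np.asarray(values)
        out[label] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    out["ranges_overlap"] = not (
        out["healthy"]["max"] < out["sick"]["min"]
        or out["sick"]["max"] < out["healthy"]["min"]
    )
    return out
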