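"""Render scalograms as fixed-size RGB images for CNN input.

The rendering chain is: min-max normalize the magnitude matrix to [0, 1],
map values through a 64-entry jet-like lookup table (linear interpolation
between entries), and bilinearly resize to the target size (224 x 224 for
large backbones, 28 x 28 for the small CNN). The chain is deterministic,
and because of the min-max step it is invariant to the beat's overall
amplitude gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import map_coordinates

from .morse import Scalogram


def _jet_table(n: int = 64) -> np.ndarray:
    """Jet-like colormap table: blue -> cyan -> yellow -> red ramps."""
    x = np.linspace(0.0, 1.0, n)
    r = np.clip(1.5 - np.abs(4.0 * x - 3.0), 0.0, 1.0)
    g = np.clip(1.5 - np.abs(4.0 * x - 2.0), 0.0, 1.0)
    b = np.clip(1.5 - np.abs(4.0 * x - 1.0), 0.0, 1.0)
    return np.column_stack([r, g, b])


JET64 = _jet_table(64)


@dataclass
class ScalogramImage:
    """H x W x 3 float image with channel values in [0, 1]."""

    pixels: np.ndarray
    subject_id: str = ""
    r_index: int = -1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if np.any(self.pixels < 0) or np.any(self.pixels > 1):
            raise ValueError("channel values must lie in [0, 1]")

    @property
    def size(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def normalize_magnitude(scalo: Scalogram | np.ndarray) -> np.ndarray:
    """Min-max normalize a magnitude matrix to the unit interval.

    A constant matrix maps to all zeros (tie rule).
    """
    mag = scalo.magnitude if isinstance(scalo, Scalogram) else np.asarray(scalo)
    if not np.all(np.isfinite(mag)):
        raise ValueError("magnitude must be finite")
    lo, hi = float(np.min(mag)), float(np.max(mag))
    if hi == lo:
        return np.zeros_like(mag, dtype=np.float64)
    return (mag - lo) / (hi - lo)


def apply_colormap(normalized: np.ndarray,
                   table: np.ndarray = JET64) -> np.ndarray:
    """Map unit-interval values through a color lookup table.

    Values between adjacent table entries are linearly interpolated;
    0 maps exactly to the first entry and 1 to the last.
    """
    normalized = np.asarray(normalized, dtype=np.float64)
    if np.any(normalized < 0) or np.any(normalized > 1) \
            or not np.all(np.isfinite(normalized)):
        raise ValueError("colormap input must lie in [0, 1]")
    pos = normalized * (table.shape[0] - 1)
    lo = np.floor(pos).astype(np.intp)
    hi = np.minimum(lo + 1, table.shape[0] - 1)
    frac = (pos - lo)[..., None]
    return (1.0 - frac) * table[lo] + frac * table[hi]


def grayscale_channels(normalized: np.ndarray) -> np.ndarray:
    """Replicate a unit-interval matrix across three channels."""
    normalized = np.asarray(normalized, dtype=np.float64)
    if np.any(normalized < 0) or np.any(normalized > 1):
        raise ValueError("input must lie in [0, 1]")
    return np.repeat(normalized[..., None], 3, axis=2)


def resize_image(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Corner-aligned bilinear resize of an H x W x 3 array.

    Resizing to the source's own size is the identity; values stay
    within the convex hull of the source values, hence within [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    h_src, w_src = image.shape[:2]
    h_t, w_t = int(target[0]), int(target[1])
    if h_src < 2 or w_src < 2:
        raise ValueError("source image must be at least 2 x 2")
    if h_t < 1 or w_t < 1:
        raise ValueError("target size must be positive")
    if (h_t, w_t) == (h_src, w_src):
        return image.copy()
    rows = (np.linspace(0.0, h_src - 1.0, h_t) if h_t > 1
            else np.array([(h_src - 1) / 2.0]))
    cols = (np.linspace(0.0, w_src - 1.0, w_t) if w_t > 1
            else np.array([(w_src - 1) / 2.0]))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty((h_t, w_t, image.shape[2]), dtype=np.float64)
    for c in range(image.shape[2]):
        out[..., c] = map_coordinates(image[..., c], [rr, cc], order=1,
                                      mode="nearest")
    return out


def render(scalo: Scalogram, size: tuple[int, int] = (224, 224),
           colormap: str = "jet", log_scale: bool = False,
           high_freq_top: bool = True,
           subject_id: str = "", r_index: int = -1) -> ScalogramImage:
    """Full scalogram -> image chain.

    ``high_freq_top`` keeps the smallest scale (highest frequency) at the
    top row of the image; ``log_scale`` applies log1p compression before
    normalization (off by default — magnitudes are mapped linearly).
    """
    mag = scalo.magnitude
    if log_scale:
        mag = np.log1p(mag)
    norm = normalize_magnitude(mag)
    if not high_freq_top:
        norm = norm[::-1]
    if colormap == "jet":
        rgb = apply_colormap(norm)
    elif colormap == "gray":
        rgb = grayscale_channels(norm)
    else:
        raise ValueError(f"unknown colormap {colormap!r}")
    pixels = resize_image(rgb, size)
    # bilinear interpolation of in-range values can only stay in range,
    # up to rounding
    pixels = np.clip(pixels, 0.0, 1.0)
    return ScalogramImage(pixels=pixels, subject_id=subject_id,
                          r_index=r_index)


def to_uint8(image: ScalogramImage | np.ndarray) -> np.ndarray:
    pixels = image.pixels if isinstance(image, ScalogramImage) else image
    return np.round(np.asarray(pixels) * 255.0).astype(np.uint8)


def save_png(image: ScalogramImage, path) -> None:
    """Write an 8-bit-per-channel PNG."""
    Image.fromarray(to_uint8(image), mode="RGB").save(path, format="PNG")


def load_png(path) -> np.ndarray:
    """Read a PNG back to a float H x W x 3 array in [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"), dtype=np.float64)
    return arr / 255.0
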