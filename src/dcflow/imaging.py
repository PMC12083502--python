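"""Post-processing of the reconstructed rBFI volume into a classification image.

The chain mirrors the visualization pipeline the flow images go through
before classification: take the 16 x 16 slice at the second depth layer
(0.5-1.0 cm, where reconstruction accuracy peaks), upsample to 150 x 150 by
nearest neighbor, map through the diverging "Cool to Warm" colormap into
RGB, write/read 8-bit TIFF, and resize to 224 x 224 (cubic, antialiased) —
yielding the 3 x 224 x 224 tensor consumed by image classifiers.
"""

from __future__ import annotations

import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

from .nldct import RBFIMap

__all__ = [
    "take_slice",
    "upsample_nn",
    "cool_to_warm",
    "cool_to_warm_table",
    "resize_rgb",
    "write_tiff",
    "read_tiff",
    "render_classification_image",
]

# Diverging cool-warm control points (low / mid / high), the standard table
# shipped by the visualization tools that popularized the name.
_CW_LOW = (0.231, 0.298, 0.753)
_CW_MID = (0.865, 0.865, 0.865)
_CW_HIGH = (0.706, 0.016, 0.150)


def take_slice(rbfi: RBFIMap, layer: int = 2) -> np.ndarray:
    """Depth slice of the volume; ``layer`` is 1-based (layer 2 = 0.5-1.0 cm)."""
    if not (1 <= layer <= rbfi.grid.nz):
        raise ValueError(f"layer must lie in [1, {rbfi.grid.nz}]")
    return rbfi.as_volume()[layer - 1]


def upsample_nn(img: np.ndarray, target: int = 150) -> np.ndarray:
    """Nearest-neighbor upsampling to target x target.

    Output pixel (r, c) takes input pixel (floor((r+.5)*n/target),
    floor((c+.5)*n/target)); no new values are invented.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("expected a square 2-D image")
    n = img.shape[0]
    src = np.minimum((np.arange(target) + 0.5) * n // target, n - 1).astype(int)
    return img[np.ix_(src, src)]


def cool_to_warm_table(n_entries: int = 256) -> np.ndarray:
    """(n_entries, 3) RGB lookup table linearly interpolating the diverging
    cool-warm control points (blue -> near-white -> red)."""
    x = np.linspace(0.0, 1.0, n_entries)
    table = np.empty((n_entries, 3))
    for ch in range(3):
        table[:, ch] = np.interp(
            x, [0.0, 0.5, 1.0], [_CW_LOW[ch], _CW_MID[ch], _CW_HIGH[ch]]
        )
    return table


def cool_to_warm(img: np.ndarray) -> np.ndarray:
    """Min-max scale a grayscale image and map through the cool-warm table.

    Returns (H, W, 3) floats in [0, 1].  A constant image maps wholly to the
    low (cool) endpoint.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    table = cool_to_warm_table()
    idx = np.clip((scaled * (len(table) - 1)).round().astype(int), 0, len(table) - 1)
    return table[idx]


def resize_rgb(img: np.ndarray, target: int = 224) -> np.ndarray:
    """Cubic antialiased resize of an (H, W, 3) RGB image to target x target."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    out = _sk_resize(
        img, (target, target, 3), order=3, anti_aliasing=True, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0)


def write_tiff(path, rgb: np.ndarray) -> None:
    """Write an RGB float image in [0, 1] as 8-bit TIFF."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    try:
        tifffile.imwrite(path, (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8))
    except OSError as exc:
        raise OSError(f"failed to write TIFF {path}: {exc}") from exc


def read_tiff(path) -> np.ndarray:
    """Read an 8-bit RGB TIFF back to floats in [0, 1]."""
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"failed to read TIFF {path}: {exc}") from exc
    return data.astype(float) / 255.0


def render_classification_image(
    rbfi: RBFIMap, layer: int = 2, tiff_path=None
) -> tuple[np.ndarray, np.ndarray]:
    """Full chain 16x16 -> 150x150 -> RGB -> (optional TIFF) -> 3x224x224.

    Returns ``(gray_slice, chw)`` where ``gray_slice`` is the 16 x 16 rBFI
    slice (the input to feature extraction) and ``chw`` the channels-first
    3 x 224 x 224 RGB tensor.
    """
    gray = take_slice(rbfi, layer)
    up = upsample_nn(gray, 150)
    rgb = cool_to_warm(up)
    if tiff_path is not None:
        write_tiff(tiff_path, rgb)
        rgb = read_tiff(tiff_path)
    out = resize_rgb(rgb, 224)
    return gray, np.moveaxis(out, -1, 0)
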