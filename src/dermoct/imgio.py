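"""Reading and writing of B-scans, AC maps and masks.

Single-channel TIFF or PNG input; 8- and 16-bit integer images are
rescaled to [0, 1] by dividing by the type maximum, float images are used
as-is.  AC maps are written as 32-bit float TIFF with an optional 8-bit
min-max-scaled preview PNG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .ac import ACMap, BScan

__all__ = [
    "read_image",
    "read_bscan",
    "read_mask",
    "write_bscan",
    "write_float_tiff",
    "write_ac_map",
    "write_mask",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a single-channel image as float64 in [0, 1] (integer inputs)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] not in (1, 3, 4):
            raise ValueError(f"{path}: expected a single-channel image")
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return arr.astype(float)


def read_bscan(
    path: str | Path,
    axial_pitch: float = 10.0,
    lateral_pitch: float = 7.5,
    mask_path: str | Path | None = None,
) -> BScan:
    """Load an OCT B-scan, optionally applying an artifact mask file."""
    pixels = read_image(path)
    invalid = None
    if mask_path is not None:
        mask = read_mask(mask_path)
        if mask.shape != pixels.shape:
            raise ValueError(
                f"mask {mask_path} shape {mask.shape} does not match image {pixels.shape}"
            )
        invalid = mask
    return BScan(
        pixels=pixels,
        axial_pitch=axial_pitch,
        lateral_pitch=lateral_pitch,
        invalid=invalid,
        source_id=Path(path).stem,
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Binary artifact mask: nonzero pixels are excluded from analysis."""
    arr = iio.imread(path) if Path(path).suffix.lower() == ".png" else tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr != 0


def write_bscan(path: str | Path, bscan: BScan) -> None:
    """Write intensities as 16-bit TIFF, min-max scaled to the dtype range."""
    pix = bscan.pixels
    top = pix.max()
    scaled = np.zeros_like(pix) if top == 0 else pix / top
    tifffile.imwrite(Path(path), (scaled * 65535).astype(np.uint16))


def write_float_tiff(path: str | Path, values: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def write_ac_map(path: str | Path, acmap: ACMap, preview: str | Path | None = None) -> None:
    """Write an AC map as float32 TIFF; invalid pixels hold NaN.

    With ``preview`` set, also writes an 8-bit min-max scaled PNG.
    """
    vals = np.where(acmap.valid, acmap.values, np.nan).astype(np.float32)
    tifffile.imwrite(Path(path), vals)
    if preview is not None:
        finite = vals[np.isfinite(vals)]
        if finite.size and np.ptp(finite) > 0:
            lo, hi = finite.min(), finite.max()
            scaled = np.clip((vals - lo) / (hi - lo), 0, 1)
        else:
            scaled = np.zeros_like(vals)
        scaled = np.where(np.isfinite(scaled), scaled, 0.0)
        iio.imwrite(Path(preview), (scaled * 255).astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))
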