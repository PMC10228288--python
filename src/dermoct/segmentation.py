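"""Skin-surface detection, artifact masking and ROI extraction.

The skin entrance (stratum corneum) appears as a bright line across the
B-scan and must be excluded from attenuation fits: including it would skew
estimates upward.  The AC map shows strong surface contrast, so the surface
is located per column by a high-gradient rule with an adaptive (Otsu)
threshold, then regularised laterally with a median filter.

ROIs are fixed-geometry vertical patches, 10 pixels wide and 150 deep,
anchored just below the detected surface.  Non-overlapping strips tile the
image left to right; the outermost strip on each side is dropped by default
because replicate-padded AC values there are less reliable (an 800-column
scan then yields at most 78 ROIs).  Regions covered by an artifact mask
(hair shafts, follicles, dust shadows) are excluded from fits and feature
pooling, and ROIs with too few valid pixels are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter
from skimage.filters import threshold_otsu

from .ac import ACMap, BScan

__all__ = [
    "SurfaceProfile",
    "ROI",
    "SurfaceNotFoundError",
    "detect_surface",
    "apply_artifact_mask",
    "extract_rois",
]

logger = logging.getLogger(__name__)

ROI_WIDTH = 10
ROI_HEIGHT = 150


class SurfaceNotFoundError(RuntimeError):
    """Raised when no column shows a gradient crossing the threshold."""


@dataclass
class SurfaceProfile:
    """Per-column row index of the skin entrance.

    ``confidence`` holds the vertical gradient magnitude at the detected
    row (0 where a column was filled in from its neighbours).
    """

    row_index: np.ndarray
    confidence: np.ndarray

    def __len__(self) -> int:
        return self.row_index.size


@dataclass
class ROI:
    """A 10-wide by 150-deep analysis patch anchored below the surface.

    Coordinates are 0-based with row 0 at the top (shallowest depth);
    column intervals are half-open: ``[column_start, column_start+width)``.
    """

    column_start: int
    top_row: int
    valid_mask: np.ndarray
    source_id: str = ""
    width: int = ROI_WIDTH
    height: int = ROI_HEIGHT

    @property
    def valid_fraction(self) -> float:
        return float(self.valid_mask.mean())

    @property
    def row_slice(self) -> slice:
        return slice(self.top_row, self.top_row + self.height)

    @property
    def col_slice(self) -> slice:
        return slice(self.column_start, self.column_start + self.width)


def detect_surface(
    acmap: ACMap,
    smooth_sigma: float = 1.0,
    median_width: int = 9,
) -> SurfaceProfile:
    """Locate the skin entrance per column by high-gradient detection.

    Works on the magnitude of the AC map (invalid pixels treated as 0),
    laterally smoothed.  Per column, the candidate surface is the topmost
    row whose downward gradient exceeds an Otsu threshold computed from the
    image's positive-gradient distribution.  Because a sliding vertical fit
    window turns valid a few rows before it fully enters tissue, the
    candidate is shifted down by the map's ``surface_lead_rows``.  Columns
    with no crossing (e.g. artifact shadows) are filled from their nearest
    detected neighbour, and the result is median-filtered laterally
    (window ``median_width``) to enforce continuity.

    Raises
    ------
    SurfaceNotFoundError
        If no column in the image crosses the threshold.
    """
    vals = np.abs(np.where(acmap.valid, acmap.values, 0.0))
    vals = np.where(np.isfinite(vals), vals, 0.0)
    if smooth_sigma > 0:
        vals = gaussian_filter1d(vals, smooth_sigma, axis=1, mode="nearest")

    grad = np.diff(vals, axis=0)  # grad[r] = vals[r+1] - vals[r]
    pos = grad[grad > 0]
    if pos.size == 0:
        raise SurfaceNotFoundError(
            f"no positive vertical gradient in columns 0..{vals.shape[1] - 1}"
        )
    if np.ptp(pos) == 0:
        thr = pos[0] / 2.0
    else:
        thr = threshold_otsu(pos)

    n_rows, n_cols = vals.shape
    rows = np.full(n_cols, -1, dtype=int)
    conf = np.zeros(n_cols)
    crossing = grad > thr
    for c in range(n_cols):
        idx = np.flatnonzero(crossing[:, c])
        if idx.size:
            rows[c] = idx[0] + 1 + acmap.surface_lead_rows
            conf[c] = grad[idx[0], c]
    found = rows >= 0
    if not found.any():
        raise SurfaceNotFoundError(
            f"no column crossed the gradient threshold in columns 0..{n_cols - 1}"
        )
    if not found.all():
        # fill gaps from the nearest detected column
        det_cols = np.flatnonzero(found)
        missing = np.flatnonzero(~found)
        nearest = det_cols[np.argmin(np.abs(missing[:, None] - det_cols[None, :]), axis=1)]
        rows[missing] = rows[nearest]
    if median_width > 1:
        rows = median_filter(rows, size=median_width, mode="nearest")
    rows = np.clip(rows, 0, n_rows - 1)
    return SurfaceProfile(row_index=rows, confidence=conf)


def apply_artifact_mask(image: BScan, mask: np.ndarray) -> BScan:
    """Flag mask-covered pixels invalid for all downstream analysis.

    ``mask`` is binary with nonzero meaning excluded; intensities are left
    unchanged.  Any invalid pixels already present on the scan are kept.
    """
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    invalid = mask != 0
    if image.invalid is not None:
        invalid = invalid | image.invalid
    return BScan(
        pixels=image.pixels,
        axial_pitch=image.axial_pitch,
        lateral_pitch=image.lateral_pitch,
        invalid=invalid,
        source_id=image.source_id,
    )


def extract_rois(
    image: BScan,
    surface: SurfaceProfile,
    entrance_band: int = 8,
    acmap: ACMap | None = None,
    roi_width: int = ROI_WIDTH,
    roi_height: int = ROI_HEIGHT,
    stride: int | None = None,
    border_trim: int = 1,
    min_valid_fraction: float = 0.7,
) -> list[ROI]:
    """Tile the scan into fixed-geometry ROIs anchored below the surface.

    Strips of ``roi_width`` columns tile the image left to right with the
    given ``stride`` (default: the width, i.e. non-overlapping);
    ``border_trim`` strips are dropped from each side.  Each surviving
    strip's ROI starts ``entrance_band`` rows below the deepest surface row
    within the strip, skipping the bright entrance signal.  Strips whose
    ROI would run off the bottom, or whose valid-pixel fraction falls below
    ``min_valid_fraction``, are dropped.  Pixel validity combines the
    artifact mask on the scan with the AC map's fit-validity mask when one
    is supplied.  Ordering is left to right and stable; an empty result is
    returned (with a warning) rather than raised.
    """
    rows, cols = image.shape
    if len(surface) != cols:
        raise ValueError("surface profile length must equal image columns")
    if stride is None:
        stride = roi_width
    if stride < 1 or roi_width < 1 or roi_height < 1:
        raise ValueError("stride and ROI dimensions must be positive")

    validity = np.ones(image.shape, dtype=bool)
    if image.invalid is not None:
        validity &= ~image.invalid
    if acmap is not None:
        if acmap.shape != image.shape:
            raise ValueError("AC map shape must match image shape")
        validity &= acmap.valid

    starts = list(range(0, cols - roi_width + 1, stride))
    if border_trim > 0:
        starts = starts[border_trim:len(starts) - border_trim]

    out: list[ROI] = []
    n_deep, n_sparse = 0, 0
    for c0 in starts:
        strip = slice(c0, c0 + roi_width)
        top = int(surface.row_index[strip].max()) + entrance_band
        if top + roi_height > rows:
            n_deep += 1
            continue
        vm = validity[top:top + roi_height, strip]
        roi = ROI(
            column_start=c0,
            top_row=top,
            valid_mask=vm,
            source_id=image.source_id,
            width=roi_width,
            height=roi_height,
        )
        if roi.valid_fraction < min_valid_fraction:
            n_sparse += 1
            continue
        out.append(roi)
    if not out:
        logger.warning(
            "no ROIs survived extraction for %s (%d too deep, %d too sparse)",
            image.source_id or "<image>", n_deep, n_sparse,
        )
    else:
        logger.info(
            "%s: %d ROIs extracted, %d rejected (depth), %d rejected (validity)",
            image.source_id or "<image>", len(out), n_deep, n_sparse,
        )
    return out
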