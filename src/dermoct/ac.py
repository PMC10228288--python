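"""Depth-resolved attenuation-coefficient (AC) estimation for OCT B-scans.

The detected OCT intensity in a weakly scattering medium follows the
single-scattering Beer-Lambert model

    I(x) = I0 * rho * exp(-2 * mu * x)

where ``x`` is the depth below the tissue surface, ``mu`` the attenuation
coefficient (mm^-1), ``rho`` the local backscatter fraction and the factor 2
accounts for the round trip to the detector.  Only the product ``I0 * rho``
is identifiable from a single depth profile; it is reported as the fit
amplitude.

This module fits that model to depth profiles (log-linear least squares),
builds per-pixel AC maps by sliding-kernel estimation, and summarises ROI AC
patches as seven-layer depth profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "BScan",
    "DecayFit",
    "ACMap",
    "DepthProfile",
    "DegenerateProfileError",
    "LAYER_NAMES",
    "LAYER_BAND_SIZES",
    "fit_decay",
    "ac_map",
    "depth_profile",
    "band_slices",
]

#: Anatomic names of the seven ROI depth bands, shallowest first.
LAYER_NAMES = (
    "epidermis",
    "dermal-epidermal junction",
    "superficial papillary dermis",
    "mid papillary dermis (upper)",
    "mid papillary dermis (lower)",
    "deep papillary dermis",
    "superficial reticular dermis",
)

#: Fixed partition of the 150-row ROI into seven contiguous bands
#: (top to bottom).  The anatomic extremes get the two larger bands.
LAYER_BAND_SIZES = (22, 22, 21, 21, 21, 21, 22)


class DegenerateProfileError(ValueError):
    """Raised when a depth profile has too few positive samples to fit."""


@dataclass
class BScan:
    """A single OCT cross-sectional image.

    Parameters
    ----------
    pixels
        2-D non-negative intensity array; rows run along depth (row 0 is the
        shallowest), columns along the lateral scan direction.
    axial_pitch
        Physical length of one row, micrometres (default 10).
    lateral_pitch
        Physical length of one column, micrometres (default 7.5).
    invalid
        Optional boolean array of the same shape; ``True`` marks pixels
        excluded from all fits and feature pooling (artifact regions).
    source_id
        Identifier carried through to ROI tables and reports.
    """

    pixels: np.ndarray
    axial_pitch: float = 10.0
    lateral_pitch: float = 7.5
    invalid: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("BScan pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("BScan intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("BScan intensities must be non-negative")
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.invalid is not None:
            self.invalid = np.asarray(self.invalid, dtype=bool)
            if self.invalid.shape != self.pixels.shape:
                raise ValueError("invalid mask shape must match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DecayFit:
    """Result of a single-scattering exponential fit.

    ``mu`` is the attenuation coefficient (mm^-1), ``amplitude`` the fitted
    ``I0*rho`` product and ``residual`` the sum of squared log-domain
    residuals.  ``mu`` may be negative for increasing profiles; no clamping
    is applied.
    """

    mu: float
    amplitude: float
    residual: float
    n_samples: int


@dataclass
class ACMap:
    """Per-pixel attenuation-coefficient image.

    ``values`` has the same dimensions as the source B-scan; ``valid`` marks
    pixels where a fit with enough positive samples was obtained.  The fit
    geometry is retained because it sets the axial localisation of the map:
    axial smoothing spreads signal ``smooth_window // 2`` rows upward and a
    centred ``fit_depth``-row window turns valid once ``min_samples`` of its
    lower half reach tissue, so the valid band leads a dark-to-bright edge
    by a fixed, computable number of rows that surface detection
    compensates for.
    """

    values: np.ndarray
    valid: np.ndarray
    axial_pitch: float = 10.0
    lateral_pitch: float = 7.5
    fit_depth: int = 15
    min_samples: int = 4
    smooth_window: int = 5

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def surface_lead_rows(self) -> int:
        """Rows by which the valid band leads a dark-to-bright edge."""
        lead = self.fit_depth // 2 + self.smooth_window // 2 - (self.min_samples - 1)
        return max(0, lead)


@dataclass(frozen=True)
class DepthProfile:
    """Mean AC of the seven ROI depth bands, shallowest first.

    Bands with no valid pixel hold ``nan`` in ``layer_means`` and are
    flagged in ``missing``.
    """

    layer_means: tuple[float, ...]
    missing: tuple[bool, ...]
    layer_labels: tuple[str, ...] = LAYER_NAMES


def _moving_average(profile: np.ndarray, window: int) -> tuple[np.ndarray, int]:
    """Centred moving average, full-window (valid) region only.

    Returns the smoothed profile and the index offset of its first sample.
    A pure exponential stays a pure exponential under this operation (the
    window average contributes a constant factor), so smoothing does not
    bias the decay rate.
    """
    if window <= 1 or profile.size < window:
        return profile, 0
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(profile, kernel, mode="valid")
    return smoothed, (window - 1) // 2


def fit_decay(
    profile: np.ndarray,
    axial_pitch: float,
    smooth_window: int | None = 5,
) -> DecayFit:
    """Fit the single-scattering decay model to one depth profile.

    Ordinary least squares of ``log I`` against depth; the slope is
    ``-2*mu``.  Depth is physical: ``x = index * axial_pitch / 1000`` mm.
    Samples that are non-positive after smoothing are excluded (log
    undefined); fewer than four usable samples raises
    :class:`DegenerateProfileError`.

    Parameters
    ----------
    profile
        1-D intensity sequence ordered by increasing depth.
    axial_pitch
        Sample spacing, micrometres.
    smooth_window
        Moving-average window applied before the fit; ``None`` or ``1``
        disables smoothing.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1:
        raise ValueError("profile must be 1-D")
    if p.size < 4:
        raise DegenerateProfileError(
            f"profile has {p.size} samples; at least 4 required"
        )
    if smooth_window:
        p, offset = _moving_average(p, int(smooth_window))
    else:
        offset = 0
    x = (offset + np.arange(p.size)) * (axial_pitch / 1000.0)
    pos = p > 0
    n = int(pos.sum())
    if n < 4:
        raise DegenerateProfileError(
            f"only {n} positive samples after smoothing; at least 4 required"
        )
    xs = x[pos]
    ys = np.log(p[pos])
    # Intensity weighting (residuals scaled by I, i.e. weights I^2 in the
    # SSE) makes the log-domain fit approximate the linear-domain fit and
    # stops near-noise-floor tail samples from dominating the slope.
    slope, intercept = np.polyfit(xs, ys, 1, w=p[pos])
    resid = float(np.sum((ys - (intercept + slope * xs)) ** 2))
    return DecayFit(
        mu=float(-slope / 2.0),
        amplitude=float(np.exp(intercept)),
        residual=resid,
        n_samples=n,
    )


def _nanmean_last(w: np.ndarray) -> np.ndarray:
    """Mean over the last axis ignoring NaNs; all-NaN slices give NaN
    without the RuntimeWarning nanmean would emit."""
    finite = np.isfinite(w)
    count = finite.sum(axis=-1)
    total = np.where(finite, w, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def _nan_uniform_rows(a: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware centred moving average along axis 0 with edge replication."""
    if window <= 1:
        return a
    h = window // 2
    padded = np.pad(a, ((h, h), (0, 0)), mode="edge")
    w = sliding_window_view(padded, window, axis=0)
    return _nanmean_last(w)


def ac_map(
    image: BScan,
    kernel: int = 5,
    fit_depth: int = 15,
    smooth_window: int = 5,
    min_samples: int = 4,
) -> ACMap:
    """Build an AC map by sliding-kernel estimation, one fit per pixel.

    The estimation kernel shifts pixel by pixel over the whole image.  Its
    ``kernel`` columns are averaged laterally (artifact pixels excluded) and
    the decay fit runs over a ``fit_depth``-row vertical extent centred on
    the pixel; a 5-wide kernel alone offers too few depth samples for a
    stable exponential fit, so the vertical fit extent is decoupled from the
    lateral averaging width.  Rows and columns are replicate-padded so the
    output has exactly the source dimensions.  Pixels whose window holds
    fewer than ``min_samples`` positive samples are marked invalid rather
    than raising.
    """
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be odd and >= 3, got {kernel}")
    if fit_depth % 2 == 0 or fit_depth < 5:
        raise ValueError(f"fit_depth must be odd and >= 5, got {fit_depth}")
    rows, cols = image.shape
    if rows <= kernel or cols < kernel:
        raise ValueError(
            f"image {rows}x{cols} too small for a {kernel}-wide kernel"
        )
    if fit_depth > rows:
        raise ValueError(f"fit_depth {fit_depth} exceeds image rows {rows}")

    pix = image.pixels.astype(float, copy=True)
    if image.invalid is not None:
        pix[image.invalid] = np.nan

    # Lateral (column) averaging over the kernel width, NaN-aware.
    hc = kernel // 2
    padded = np.pad(pix, ((0, 0), (hc, hc)), mode="edge")
    win = sliding_window_view(padded, kernel, axis=1)
    lat = _nanmean_last(win)

    lat = _nan_uniform_rows(lat, smooth_window)

    # Vertical sliding windows of fit_depth rows, replicate-padded.
    hr = fit_depth // 2
    lat_pad = np.pad(lat, ((hr, hr), (0, 0)), mode="edge")
    v = sliding_window_view(lat_pad, fit_depth, axis=0)  # rows x cols x fit_depth

    usable = np.isfinite(v) & (v > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        logv = np.where(usable, np.log(np.where(usable, v, 1.0)), 0.0)

    dx = image.axial_pitch / 1000.0  # mm per row
    x = np.arange(fit_depth, dtype=float) * dx

    # Weighted least squares with weights I^2, matching fit_decay.
    w = np.where(usable, v * v, 0.0)
    n = usable.sum(axis=-1, dtype=float)
    sw = w.sum(axis=-1)
    swx = (w * x).sum(axis=-1)
    swy = (w * logv).sum(axis=-1)
    swxx = (w * x * x).sum(axis=-1)
    swxy = (w * logv * x).sum(axis=-1)

    denom = sw * swxx - swx * swx
    valid = (n >= min_samples) & (denom > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(
            valid, (sw * swxy - swx * swy) / np.where(denom == 0, 1.0, denom), np.nan
        )
    mu = -slope / 2.0
    return ACMap(
        values=mu,
        valid=valid,
        axial_pitch=image.axial_pitch,
        lateral_pitch=image.lateral_pitch,
        fit_depth=fit_depth,
        min_samples=min_samples,
        smooth_window=smooth_window,
    )


def band_slices(n_rows: int = 150) -> list[slice]:
    """Row slices of the seven depth bands of a 150-row ROI."""
    if n_rows != sum(LAYER_BAND_SIZES):
        raise ValueError(
            f"ROI must have {sum(LAYER_BAND_SIZES)} rows, got {n_rows}"
        )
    out, start = [], 0
    for size in LAYER_BAND_SIZES:
        out.append(slice(start, start + size))
        start += size
    return out


def depth_profile(roi_ac: np.ndarray, valid: np.ndarray | None = None) -> DepthProfile:
    """Mean AC of seven contiguous horizontal bands of a 150-row ROI patch.

    The bands span 22,22,21,21,21,21,22 rows top to bottom and are labelled
    epidermis through superficial reticular dermis.  Means are taken over
    valid pixels only; an all-invalid band yields ``nan`` and a missing
    flag.
    """
    a = np.asarray(roi_ac, dtype=float)
    if a.ndim != 2 or a.shape[0] != sum(LAYER_BAND_SIZES):
        raise ValueError(
            f"ROI AC patch must have {sum(LAYER_BAND_SIZES)} rows, got shape {a.shape}"
        )
    if valid is None:
        v = np.isfinite(a)
    else:
        v = np.asarray(valid, dtype=bool) & np.isfinite(a)
        if v.shape != a.shape:
            raise ValueError("valid mask shape must match the AC patch")
    means, missing = [], []
    for sl in band_slices(a.shape[0]):
        band_vals = a[sl][v[sl]]
        if band_vals.size == 0:
            means.append(float("nan"))
            missing.append(True)
        else:
            means.append(float(band_vals.mean()))
            missing.append(False)
    return DepthProfile(layer_means=tuple(means), missing=tuple(missing))
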