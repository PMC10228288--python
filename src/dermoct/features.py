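"""Gabor wavelet filter bank and per-ROI texture features.

A Gabor wavelet is a Gaussian-windowed complex sinusoid,

    g(x, y) = 1/(2*pi*sx*sy) * exp(-x'^2/(2*sx^2) - y'^2/(2*sy^2)
                                   + j*2*pi*f*x')

with (x', y') the image coordinates rotated by the filter orientation,
``f`` the modulation frequency (cycles/pixel) and ``sx``, ``sy`` the
Gaussian major and minor widths.  Each filter in the bank captures image
energy at one spatial frequency and orientation; pooled magnitude
statistics of the filter responses over a ROI form its texture feature
vector, optionally augmented with the seven-layer attenuation means.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.signal import fftconvolve

from .ac import DepthProfile

__all__ = [
    "GaborBank",
    "FeatureVector",
    "FeatureExtractionError",
    "gabor_kernel",
    "extract_features",
    "feature_names",
]

#: Default modulation frequencies, cycles/pixel.
DEFAULT_FREQUENCIES = (0.05, 0.1, 0.2, 0.3)
#: Default orientations: 6 angles evenly spaced over [0, pi).
DEFAULT_ORIENTATIONS = tuple(k * np.pi / 6 for k in range(6))
#: One-octave bandwidth convention: sigma = BANDWIDTH_FACTOR / f.
BANDWIDTH_FACTOR = 0.56


class FeatureExtractionError(RuntimeError):
    """Raised when a ROI has no valid pixels to pool over."""


def gabor_kernel(
    f: float,
    theta: float,
    sigma_x: float,
    sigma_y: float,
) -> np.ndarray:
    """Complex Gabor kernel on an odd-sized grid truncated at +/- 3 sigma.

    At ``theta = 0`` the carrier modulates the lateral (x / column) axis;
    the real part at the origin is ``1/(2*pi*sigma_x*sigma_y)``.
    """
    if f <= 0:
        raise ValueError(f"modulation frequency must be positive, got {f}")
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("Gaussian widths must be positive")
    half = int(np.ceil(3.0 * max(sigma_x, sigma_y)))
    y, x = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-(xr**2) / (2 * sigma_x**2) - (yr**2) / (2 * sigma_y**2))
    carrier = np.exp(2j * np.pi * f * xr)
    return envelope * carrier / (2 * np.pi * sigma_x * sigma_y)


@dataclass(frozen=True)
class GaborBank:
    """A grid of Gabor filters over frequencies x orientations.

    When ``sigma_x``/``sigma_y`` are ``None`` the widths follow the
    one-octave bandwidth convention ``sigma = 0.56 / f``, so low-frequency
    filters get proportionally wider envelopes.
    """

    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    sigma_x: float | None = None
    sigma_y: float | None = None

    def __post_init__(self) -> None:
        if not self.frequencies or not self.orientations:
            raise ValueError("bank must have at least one frequency and orientation")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")
        if any(not (0 <= t < np.pi) for t in self.orientations):
            raise ValueError("orientations must lie in [0, pi)")
        if self.sigma_x is not None and self.sigma_x <= 0:
            raise ValueError("sigma_x must be positive")
        if self.sigma_y is not None and self.sigma_y <= 0:
            raise ValueError("sigma_y must be positive")

    def sigmas(self, f: float) -> tuple[float, float]:
        sx = self.sigma_x if self.sigma_x is not None else BANDWIDTH_FACTOR / f
        sy = self.sigma_y if self.sigma_y is not None else BANDWIDTH_FACTOR / f
        return sx, sy

    def __len__(self) -> int:
        return len(self.frequencies) * len(self.orientations)

    @cached_property
    def kernels(self) -> list[tuple[float, float, np.ndarray]]:
        """All (frequency, orientation, kernel) triples, in feature order."""
        out = []
        for f in self.frequencies:
            sx, sy = self.sigmas(f)
            for t in self.orientations:
                out.append((f, t, gabor_kernel(f, t, sx, sy)))
        return out


@dataclass(frozen=True)
class FeatureVector:
    """Ordered texture statistics for one ROI.

    Per filter: mean and standard deviation of the complex-response
    magnitude over valid pixels, ordered by (frequency index, orientation
    index, statistic); optionally followed by the seven depth-band AC
    means.
    """

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("feature values and names must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def feature_names(bank: GaborBank, with_ac: bool = False) -> tuple[str, ...]:
    """Column-order manifest for feature matrices built from ``bank``."""
    names = []
    for i, f in enumerate(bank.frequencies):
        for j, t in enumerate(bank.orientations):
            stem = f"gabor_f{i}_o{j}"
            names.append(f"{stem}_mag_mean")
            names.append(f"{stem}_mag_sd")
    if with_ac:
        names.extend(f"ac_depth{k + 1}_mean" for k in range(7))
    return tuple(names)


def _replicate_convolve(patch: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size convolution with replicate (edge) padding."""
    ph, pw = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(patch, ((ph, ph), (pw, pw)), mode="edge")
    return fftconvolve(padded, kernel, mode="valid")


def extract_features(
    roi_pixels: np.ndarray,
    valid_mask: np.ndarray | None,
    bank: GaborBank,
    ac_profile: DepthProfile | None = None,
) -> FeatureVector:
    """Texture feature vector of one ROI patch.

    The patch is z-scored over its valid pixels (so a constant patch yields
    zero texture energy), invalid pixels are filled with the mean, and each
    bank kernel is applied with replicate padding.  Response magnitudes are
    pooled (mean, sd) over valid pixels.  When ``ac_profile`` is given its
    seven layer means are appended; a missing band is imputed with the mean
    of the available bands.
    """
    patch = np.asarray(roi_pixels, dtype=float)
    if patch.ndim != 2:
        raise ValueError("ROI patch must be 2-D")
    if valid_mask is None:
        vm = np.ones(patch.shape, dtype=bool)
    else:
        vm = np.asarray(valid_mask, dtype=bool)
        if vm.shape != patch.shape:
            raise ValueError("valid mask shape must match the patch")
    if not vm.any():
        raise FeatureExtractionError("ROI has no valid pixels")

    vals = patch[vm]
    mean, sd = vals.mean(), vals.std()
    if sd > 0:
        z = (patch - mean) / sd
    else:
        z = np.zeros_like(patch)
    z = np.where(vm, z, 0.0)

    out: list[float] = []
    for _f, _t, kernel in bank.kernels:
        mag = np.abs(_replicate_convolve(z, kernel))[vm]
        out.append(float(mag.mean()))
        out.append(float(mag.std()))

    if ac_profile is not None:
        means = np.asarray(ac_profile.layer_means, dtype=float)
        if np.isnan(means).all():
            means = np.zeros_like(means)
        elif np.isnan(means).any():
            means = np.where(np.isnan(means), np.nanmean(means), means)
        out.extend(float(m) for m in means)

    return FeatureVector(
        values=np.asarray(out),
        names=feature_names(bank, with_ac=ac_profile is not None),
    )
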