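"""Synthetic skin-OCT phantom generator with ground truth.

Renders labelled B-scans that emulate the qualitative appearance of
pigmented lesions in swept-source OCT:

* a dark (signal-free) region above the tissue,
* a bright 2-row skin-entrance line at the surface (the stratum corneum's
  hyper-reflective signature),
* layered tissue below it whose intensity follows cumulative Beer-Lambert
  decay, ``I = rho * exp(-2 * integral(mu) dz)``, with per-layer
  attenuation ``mu`` and backscatter ``rho`` steps,
* undulating rete-ridge layer boundaries (benign-nevus preset) or an
  architecture blended toward a single homogeneous, weakly attenuating
  layer (melanoma preset, controlled by an effacement factor),
* unit-mean log-normal multiplicative speckle, and
* optional hypo-reflective hair-shaft artifact bands.

Every render returns the image together with its ground truth (surface
rows, per-pixel attenuation map, artifact mask, class label), so each
pipeline stage can be validated without clinical data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .ac import BScan

__all__ = [
    "Layer",
    "PhantomSpec",
    "Phantom",
    "render",
    "benign_spec",
    "melanoma_spec",
    "make_dataset",
]


@dataclass(frozen=True)
class Layer:
    """One tissue layer: thickness in rows, attenuation mu (mm^-1),
    relative backscatter rho."""

    thickness: int
    mu: float
    rho: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic B-scan.

    The surface sits at ``surface_row`` plus an optional lateral sinusoid;
    internal layer boundaries undulate with the rete-ridge amplitude/period
    (benign architecture).  ``effacement`` in [0, 1] blends the layered
    attenuation/backscatter maps toward their depth-homogeneous average
    (1 = fully effaced, the melanoma architecture).  Speckle is unit-mean
    log-normal with standard deviation ``speckle_sigma`` of the underlying
    normal.  ``artifacts`` lists (column_start, width) hair-shaft bands
    whose signal is suppressed to a small fraction.
    """

    width: int = 120
    depth: int = 220
    axial_pitch: float = 10.0
    lateral_pitch: float = 7.5
    surface_row: int = 40
    surface_amplitude: float = 0.0
    surface_period: float = 100.0
    layers: tuple[Layer, ...] = (Layer(45, 4.0, 1.0), Layer(175, 2.5, 0.7))
    rete_amplitude: float = 0.0
    rete_period: float = 60.0
    rete_phase: float = 0.0
    effacement: float = 0.0
    speckle_sigma: float = 0.2
    entrance_rows: int = 2
    entrance_gain: float = 3.0
    artifacts: tuple[tuple[int, int], ...] = ()
    artifact_attenuation: float = 0.02
    class_label: str = "benign"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 10 or self.depth < 160:
            raise ValueError("phantom must be at least 10 wide and 160 deep")
        if not self.layers:
            raise ValueError("at least one tissue layer is required")
        if any(l.thickness <= 0 or l.mu < 0 or l.rho <= 0 for l in self.layers):
            raise ValueError("layer thicknesses/rho must be positive and mu >= 0")
        if sum(l.thickness for l in self.layers) > self.depth:
            raise ValueError("layer thicknesses exceed the phantom depth")
        if not 0.0 <= self.effacement <= 1.0:
            raise ValueError("effacement must lie in [0, 1]")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be non-negative")
        if self.surface_row < 0 or self.surface_row >= self.depth:
            raise ValueError("surface_row must lie inside the image")
        if self.class_label not in ("benign", "melanoma"):
            raise ValueError("class_label must be 'benign' or 'melanoma'")


@dataclass
class Phantom:
    """A rendered B-scan with its ground truth."""

    bscan: BScan
    surface_rows: np.ndarray
    mu_map: np.ndarray
    artifact_mask: np.ndarray
    label: str
    spec: PhantomSpec


def _surface_rows(spec: PhantomSpec) -> np.ndarray:
    cols = np.arange(spec.width)
    rows = spec.surface_row + spec.surface_amplitude * np.sin(
        2 * np.pi * cols / spec.surface_period
    )
    return np.clip(np.round(rows).astype(int), 0, spec.depth - 1)


def _material_maps(spec: PhantomSpec, surface: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mu (mm^-1) and rho below the surface; mu = 0 above."""
    rows = np.arange(spec.depth)[:, None]
    cols = np.arange(spec.width)[None, :]
    tissue_depth = rows - surface[None, :]  # rows below the entrance

    mus = np.array([l.mu for l in spec.layers])
    rhos = np.array([l.rho for l in spec.layers])
    cum = np.cumsum([l.thickness for l in spec.layers]).astype(float)

    # Internal boundaries undulate (rete ridges); the deepest boundary is
    # open so the last layer extends to the image bottom.
    idx = np.zeros((spec.depth, spec.width), dtype=int)
    for b, bound in enumerate(cum[:-1]):
        wobble = spec.rete_amplitude * np.sin(
            2 * np.pi * cols / spec.rete_period + spec.rete_phase + b * np.pi / 3
        )
        idx += tissue_depth >= (bound + wobble)
    idx = np.clip(idx, 0, len(spec.layers) - 1)

    mu = mus[idx]
    rho = rhos[idx]
    if spec.effacement > 0:
        weights = np.array([l.thickness for l in spec.layers], dtype=float)
        weights /= weights.sum()
        mu_h = float(weights @ mus)
        rho_h = float(weights @ rhos)
        mu = (1 - spec.effacement) * mu + spec.effacement * mu_h
        rho = (1 - spec.effacement) * rho + spec.effacement * rho_h

    above = tissue_depth < 0
    mu = np.where(above, 0.0, mu)
    rho = np.where(above, 0.0, rho)
    return mu, rho


def render(spec: PhantomSpec) -> Phantom:
    """Render one phantom B-scan with its ground truth.

    Below the entrance, the noiseless intensity of a column at tissue depth
    ``x`` is ``rho(x) * exp(-2 * integral_0^x mu dz)`` with the integral
    accumulated through the layer stack (exclusive of the current row, so a
    single-layer column reads exactly ``rho * exp(-2*mu*x)``).  The
    entrance band is set to ``entrance_gain`` times the first sub-entrance
    value; speckle multiplies the whole image; artifact bands suppress the
    signal to ``artifact_attenuation`` of its value.  Output is
    bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    surface = _surface_rows(spec)
    mu, rho = _material_maps(spec, surface)

    dz = spec.axial_pitch / 1000.0  # mm per row
    # Optical depth accumulated from the surface, exclusive of current row.
    tau = np.cumsum(mu, axis=0) * dz - mu * dz
    intensity = rho * np.exp(-2.0 * tau)

    cols = np.arange(spec.width)
    sub = np.clip(surface + spec.entrance_rows, 0, spec.depth - 1)
    entrance_value = spec.entrance_gain * intensity[sub, cols]
    for k in range(spec.entrance_rows):
        r = np.clip(surface + k, 0, spec.depth - 1)
        intensity[r, cols] = entrance_value

    if spec.speckle_sigma > 0:
        s = spec.speckle_sigma
        speckle = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=intensity.shape)
        intensity = intensity * speckle

    artifact_mask = np.zeros(intensity.shape, dtype=bool)
    for c0, w in spec.artifacts:
        band = slice(max(0, c0), min(spec.width, c0 + w))
        intensity[:, band] *= spec.artifact_attenuation
        artifact_mask[:, band] = True

    bscan = BScan(
        pixels=intensity,
        axial_pitch=spec.axial_pitch,
        lateral_pitch=spec.lateral_pitch,
        source_id=f"{spec.class_label}-{spec.seed}",
    )
    return Phantom(
        bscan=bscan,
        surface_rows=surface,
        mu_map=mu,
        artifact_mask=artifact_mask,
        label=spec.class_label,
        spec=spec,
    )


def benign_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Benign-nevus preset: preserved layering with a well-delineated
    junction, undulating rete ridges and relatively high attenuation
    (epidermis mu = 4, dermis mu = 2.5 mm^-1)."""
    base = dict(
        layers=(Layer(45, 4.0, 1.0), Layer(175, 2.5, 0.7)),
        rete_amplitude=6.0,
        rete_period=60.0,
        effacement=0.0,
        class_label="benign",
        seed=seed,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def melanoma_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Melanoma preset: architectural disarray rendered as strong
    effacement toward a homogeneous, weakly attenuating medium
    (mu ~ 1.2 mm^-1, effacement 0.9, no rete ridges)."""
    base = dict(
        layers=(Layer(45, 1.4, 0.9), Layer(175, 1.15, 0.8)),
        rete_amplitude=0.0,
        effacement=0.9,
        class_label="melanoma",
        seed=seed,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def _jittered(preset, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Randomise nuisance parameters so dataset images are not clones.

    Attenuations move +/-10%, the surface base row over 35..45, ridge
    phase freely, and effacement (melanoma) over 0.8..0.95.
    """
    spec = preset(seed=seed)
    scale = rng.uniform(0.9, 1.1)
    layers = tuple(
        Layer(l.thickness, l.mu * scale * rng.uniform(0.95, 1.05), l.rho)
        for l in spec.layers
    )
    updates: dict = {
        "layers": layers,
        "surface_row": int(rng.integers(35, 46)),
        "rete_phase": float(rng.uniform(0, 2 * np.pi)),
    }
    if spec.rete_amplitude > 0:
        updates["rete_amplitude"] = float(rng.uniform(4.0, 8.0))
    if spec.effacement > 0:
        updates["effacement"] = float(rng.uniform(0.8, 0.95))
    return replace(spec, **updates)


def make_dataset(
    n_benign: int,
    n_melanoma: int,
    seed: int = 0,
    out_dir: str | Path | None = None,
    jitter: bool = True,
    **spec_overrides,
) -> tuple[list[Phantom], list[dict]]:
    """Generate a labelled phantom image set with a manifest.

    Returns the rendered phantoms and a manifest (one record per image:
    ``image_id``, ``label``, ``seed``).  With ``out_dir`` set, images are
    written as 16-bit TIFF, ground truth as float TIFF (mu map) + CSV
    (surface rows) + PNG (artifact mask), plus ``manifest.csv``.  The
    manifest is identical across runs with the same seed.
    """
    if n_benign < 1 or n_melanoma < 1:
        raise ValueError("need at least one image per class")
    rng = np.random.default_rng(seed)
    phantoms: list[Phantom] = []
    manifest: list[dict] = []
    presets = [(benign_spec, "benign")] * n_benign + [(melanoma_spec, "melanoma")] * n_melanoma
    for i, (preset, label) in enumerate(presets):
        img_seed = int(rng.integers(0, 2**31 - 1))
        if jitter:
            spec = _jittered(preset, rng, img_seed)
        else:
            spec = preset(seed=img_seed)
        if spec_overrides:
            spec = replace(spec, **spec_overrides)
        image_id = f"{label}_{i:03d}"
        phantom = render(spec)
        phantom.bscan.source_id = image_id
        phantoms.append(phantom)
        manifest.append({"image_id": image_id, "label": label, "seed": img_seed})

    if out_dir is not None:
        from . import imgio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for phantom, rec in zip(phantoms, manifest):
            stem = rec["image_id"]
            imgio.write_bscan(out / f"{stem}.tif", phantom.bscan)
            imgio.write_float_tiff(out / f"{stem}_mu.tif", phantom.mu_map)
            imgio.write_mask(out / f"{stem}_mask.png", phantom.artifact_mask)
            with open(out / f"{stem}_surface.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["column", "surface_row"])
                w.writerows(enumerate(phantom.surface_rows.tolist()))
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["image_id", "label", "seed"])
            w.writeheader()
            w.writerows(manifest)
    return phantoms, manifest
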