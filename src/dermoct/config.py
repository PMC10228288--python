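"""Pipeline configuration: every tunable, its frozen default, and flat
``key = value`` file round-tripping.

Unknown keys are rejected so a typo cannot silently fall back to a
default.  ``config_hash`` fingerprints the resolved configuration for run
records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables with their defaults.

    Geometry is in pixels unless stated; pitches in micrometres;
    attenuation in mm^-1.
    """

    # image geometry
    axial_pitch: float = 10.0
    lateral_pitch: float = 7.5
    # AC map estimation
    ac_kernel: int = 5
    fit_depth: int = 15
    smooth_window: int = 5
    min_fit_samples: int = 4
    # surface detection
    surface_smooth_sigma: float = 1.0
    surface_median_width: int = 9
    # ROI extraction
    entrance_band: int = 8
    roi_width: int = 10
    roi_height: int = 150
    roi_stride: int = 10
    border_trim: int = 1
    min_valid_fraction: float = 0.7
    # Gabor bank
    gabor_frequencies: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3)
    gabor_orientations: int = 6
    use_ac_features: bool = True
    # classifier
    svm_c: float = 1.0
    svm_gamma: str = "scale"
    tie_break: str = "melanoma"
    # randomness
    seed: int = 0

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        overrides: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            overrides[key] = val
        return cls().with_overrides(**overrides)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        """Apply string or native overrides, rejecting unknown keys."""
        known = {f.name: f for f in fields(self)}
        parsed: dict = {}
        for key, val in overrides.items():
            if key not in known:
                raise KeyError(f"unknown configuration key: {key!r}")
            current = getattr(self, key)
            if isinstance(val, str):
                val = _parse(val, current)
            parsed[key] = val
        return replace(self, **parsed)


def _parse(text: str, current):
    if isinstance(current, bool):
        low = text.lower()
        if low in ("true", "1", "yes", "on"):
            return True
        if low in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"cannot parse boolean from {text!r}")
    if isinstance(current, int):
        return int(text)
    if isinstance(current, float):
        return float(text)
    if isinstance(current, tuple):
        return tuple(float(x) for x in text.split(",") if x.strip())
    return text
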