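"""Run configuration: tunable parameters, validation, YAML round trip.

Precedence is CLI flag > config file > built-in default; the defaults for
``sigma``, ``k`` and ``r`` are the values used for every segmentation in the
source study.  A resolved copy of the configuration is written next to every
output for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]

_RANGES = {
    "sigma": (0.0, 50.0),
    "k": (0.0, 100.0),
    "r": (3, 501),
    "shrink_factor": (0.0, 1.0),
    "slice_spacing": (0.0, 100.0),
    "n_points": (16, 100000),
}


@dataclass
class RunConfig:
    """All user-tunable parameters of the pipeline with their defaults."""

    sigma: float = 4.0            # Gaussian smoothing std, semi-axial pixels
    k: float = 1.0                # edge-preservation exponent
    r: int = 29                   # radial search length, pixels
    shrink_factor: float = 0.5    # boundary concavity, 0 = convex hull
    slice_spacing: float | None = None  # mm; None -> 2x voxel spacing
    n_points: int = 180           # contour samples per slice
    model_path: str | None = None  # axis-model JSON; None -> shipped default
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            value = getattr(self, name)
            if value is None:
                continue
            if not lo < value <= hi and not (name == "r" and lo <= value <= hi):
                raise ValueError(f"{name}={value} outside valid range ({lo}, {hi}]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (CLI flag precedence)."""
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
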