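"""Run configuration with model defaults.

All architectural constants live here: a 400x400 px input canvas at
32 px/deg, V4 receptive fields of 4 deg (128 px), 12 orientation channels
in (0, pi), 4 filter scales giving 8 signed-curvature maps, and a 3x3 grid
of Gaussian pooling kernels giving 72-dimensional part vectors.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence


class ConfigError(ValueError):
    """A configuration invariant is violated; message names the field."""


@dataclass(frozen=True)
class RunConfig:
    # canvas / geometry
    canvas_px: int = 400
    px_per_deg: int = 32
    rf_deg: int = 4
    # stimulus scaling: max contour extent from the RF center, as a
    # fraction of the RF side length
    stimulus_extent_frac: float = 0.75
    antialias: bool = False

    # V1 front end
    n_orientations: int = 12
    n_scales: int = 4
    min_wavelength_px: float = 4.0
    gabor_aspect: float = 0.5
    gabor_bandwidth: float = 1.0  # octaves; sets envelope sigma from wavelength

    # endstopping: flank displacement = flank_frac * filter half-width
    flank_frac: float = 1.0
    # border ownership: smoothing of the signed distance field (px)
    bo_smooth_px: float = 2.0

    # V4 pooling grid
    grid_side: int = 3
    kernel_sigma_frac: float = 1.0 / 6.0  # of RF side

    # fitting
    train_frac: float = 0.6
    n_strata: int = 4
    cv_folds: int = 5
    n_alphas: int = 13
    alpha_decades: float = 6.0
    rho_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    max_iter: int = 100_000
    tol: float = 1e-6
    nonzero_eps: float = 1e-8
    seed: int = 0

    # ---- derived ----
    @property
    def rf_px(self) -> int:
        return self.rf_deg * self.px_per_deg

    @property
    def n_maps(self) -> int:
        return self.n_scales * 2

    @property
    def part_vector_len(self) -> int:
        return self.n_maps * self.grid_side**2

    @property
    def wavelengths(self) -> tuple:
        """Octave-spaced Gabor wavelengths, smallest first."""
        return tuple(self.min_wavelength_px * 2.0**s for s in range(self.n_scales))

    def __post_init__(self) -> None:
        if self.rf_px != self.rf_deg * self.px_per_deg:  # pragma: no cover
            raise ConfigError("rf_px must equal rf_deg * px_per_deg")
        if self.rf_px > self.canvas_px:
            raise ConfigError(f"rf_deg*px_per_deg={self.rf_px} exceeds canvas_px={self.canvas_px}")
        if self.n_orientations < 2:
            raise ConfigError("n_orientations must be >= 2")
        if self.n_scales < 1:
            raise ConfigError("n_scales must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ConfigError("train_frac must lie in (0, 1)")
        if not 0 < self.stimulus_extent_frac:
            raise ConfigError("stimulus_extent_frac must be positive")
        for r in self.rho_grid:
            if not 0 <= r <= 1:
                raise ConfigError(f"rho_grid entry {r} outside [0, 1]")

    # ---- (de)serialization ----
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rho_grid"] = list(self.rho_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "rho_grid" in d:
            d = dict(d, rho_grid=tuple(d["rho_grid"]))
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_CONFIG = RunConfig()
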