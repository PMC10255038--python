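"""Boundary-conformation stimulus generation.

Closed silhouette stimuli are defined parametrically: a contour is a radial
profile r(phi) around the receptive-field center, built from a periodic
spline through per-control-point base radii plus a localized bump or dent
at each control point whose sharpness is keyed by a categorical curvature
class (sharp/medium/broad convex, flat, medium/sharp concave).  Because the
contour is a single-valued function of polar angle it is automatically
simple (non-self-intersecting) whenever r > 0.

The standard set is a 49-base catalog expanded over 45-degree rotations
with rotationally symmetric duplicates removed, yielding exactly 366 unique
stimuli.  Every standard-set shape is scaled so its maximum contour
distance from the RF center equals 0.75 x RF side length.  A second,
single-varying-part family supports scale- and position-invariance tests.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.interpolate import CubicSpline
from skimage.measure import label as _sk_label

from .config import DEFAULT_CONFIG, RunConfig

__all__ = [
    "CURVATURE_CLASSES",
    "ShapeSpec",
    "StimulusImage",
    "ShapeCatalog",
    "RenderError",
    "CatalogError",
    "render",
    "radial_profile",
    "load_default_catalog",
    "generate_standard_set",
    "generate_invariance_set",
    "disc_stimulus",
    "bump_dent_pair",
    "max_radial_extent",
    "save_stimuli",
]

# curvature class -> (bump amplitude as fraction of base radius,
#                     angular half-width in radians)
CURVATURE_CLASSES: dict[str, tuple[float, float]] = {
    "sharp-convex": (0.55, 0.18),
    "medium-convex": (0.45, 0.35),
    "broad-convex": (0.35, 0.60),
    "flat": (0.0, 0.35),
    "medium-concave": (-0.35, 0.35),
    "sharp-concave": (-0.45, 0.18),
}

_CLASS_ORDER = list(CURVATURE_CLASSES)  # deterministic enumeration order

CATALOG_VERSION = "1.0"


class RenderError(ValueError):
    """Raised when a spec cannot be rendered as a simple closed silhouette."""


class CatalogError(ValueError):
    """Raised when catalog expansion does not produce the expected count."""


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric closed contour.

    control_points are ordered (angular_position_rad, radius, curvature_class)
    triples with strictly increasing angles, the first below 2*pi.
    rotation_deg rotates the whole contour (multiples of 45 in the catalog).
    """

    base_id: int
    rotation_deg: float = 0.0
    control_points: tuple = ()
    closed: bool = True

    def __post_init__(self) -> None:
        pts = tuple(tuple(p) for p in self.control_points)
        object.__setattr__(self, "control_points", pts)
        if not pts:
            raise ValueError("control_points must be non-empty")
        angles = [p[0] for p in pts]
        if angles[0] >= 2 * np.pi:
            raise ValueError("first angular position must be < 2*pi")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValueError("angular positions must be strictly increasing")
        for _, r, cls in pts:
            if r <= 0:
                raise ValueError("control-point radius must be positive")
            if cls not in CURVATURE_CLASSES:
                raise ValueError(f"unknown curvature class {cls!r}")

    def rotated(self, extra_deg: float) -> "ShapeSpec":
        return ShapeSpec(self.base_id, self.rotation_deg + extra_deg,
                         self.control_points, self.closed)


@dataclass
class StimulusImage:
    """Rendered grayscale silhouette: foreground 1, background 0."""

    pixels: np.ndarray
    center: tuple  # (row, col) of the RF center
    px_per_deg: int = 32
    stimulus_id: str = ""
    base_id: int = -1
    rotation_deg: float = 0.0
    scale: float = 1.0

    @property
    def canvas_px(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ShapeCatalog:
    entries: list  # of ShapeSpec
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# radial profile and rendering
# ---------------------------------------------------------------------------

def radial_profile(spec: ShapeSpec, phi: np.ndarray) -> np.ndarray:
    """Evaluate r(phi) for a spec (rotation applied)."""
    phi = np.asarray(phi, dtype=float)
    rot = np.deg2rad(spec.rotation_deg)
    ang = np.array([p[0] for p in spec.control_points])
    rad = np.array([p[1] for p in spec.control_points])
    # periodic spline baseline through the control radii
    if len(ang) == 1 or np.allclose(rad, rad[0]):
        base = np.full_like(phi, rad[0])
    else:
        xs = np.concatenate([ang, [ang[0] + 2 * np.pi]])
        ys = np.concatenate([rad, [rad[0]]])
        base = CubicSpline(xs, ys, bc_type="periodic")(
            np.mod(phi - rot - ang[0], 2 * np.pi) + ang[0]
        )
    r = base.copy()
    for (a, rr, cls) in spec.control_points:
        amp, width = CURVATURE_CLASSES[cls]
        if amp == 0.0:
            continue
        d = np.mod(phi - rot - a + np.pi, 2 * np.pi) - np.pi  # wrapped distance
        r = r + amp * rr * np.exp(-0.5 * (d / width) ** 2)
    return r


def render(
    spec: ShapeSpec,
    scale: float,
    center: tuple | None = None,
    canvas_px: int | None = None,
    antialias: bool = False,
    config: RunConfig = DEFAULT_CONFIG,
    n_samples: int = 4096,
) -> StimulusImage:
    """Rasterize a spec as a filled binary silhouette.

    scale multiplies the (unitless) radial profile to give pixels.
    Deterministic for fixed inputs.
    """
    if scale <= 0:
        raise RenderError("scale must be positive")
    canvas = canvas_px if canvas_px is not None else config.canvas_px
    if center is None:
        center = (canvas / 2.0, canvas / 2.0)
    phi = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    r = radial_profile(spec, phi) * scale
    if np.any(r <= 0):
        raise RenderError(
            f"base {spec.base_id}: radial profile crosses zero; contour would self-intersect"
        )
    # star-shaped contour: fill by comparing each pixel's polar radius with
    # r(phi) interpolated at the pixel's polar angle (exact for this family)
    ss = 2 if antialias else 1
    rmax = r.max()
    lo_r = max(int(np.floor(center[0] - rmax)) - 1, 0)
    hi_r = min(int(np.ceil(center[0] + rmax)) + 2, canvas)
    lo_c = max(int(np.floor(center[1] - rmax)) - 1, 0)
    hi_c = min(int(np.ceil(center[1] + rmax)) + 2, canvas)
    step = 1.0 / ss
    rows = np.arange(lo_r, hi_r, step) + (step - 1.0) / 2.0
    cols = np.arange(lo_c, hi_c, step) + (step - 1.0) / 2.0
    dy = rows[:, None] - center[0]
    dx = cols[None, :] - center[1]
    ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
    r_at = np.interp(ang, phi, r, period=2 * np.pi)
    inside = (dy * dy + dx * dx) <= r_at * r_at
    img = np.zeros((canvas, canvas), dtype=np.float64)
    if antialias:
        block = inside.reshape(inside.shape[0] // ss, ss, inside.shape[1] // ss, ss)
        img[lo_r:hi_r, lo_c:hi_c] = block.mean(axis=(1, 3))
    else:
        img[lo_r:hi_r, lo_c:hi_c] = inside.astype(np.float64)
    return StimulusImage(
        pixels=img,
        center=tuple(center),
        px_per_deg=config.px_per_deg,
        base_id=spec.base_id,
        rotation_deg=spec.rotation_deg,
        scale=scale,
    )


def max_radial_extent(img: StimulusImage) -> float:
    """Max distance (px) of the silhouette's contour from the RF center.

    Pixel-walk measurement over the foreground boundary (foreground pixels
    with at least one 4-neighbor in the background).
    """
    fg = img.pixels >= 0.5
    if not fg.any():
        return 0.0
    interior = (
        np.roll(fg, 1, 0) & np.roll(fg, -1, 0) & np.roll(fg, 1, 1) & np.roll(fg, -1, 1)
    )
    boundary = fg & ~interior
    rows, cols = np.nonzero(boundary)
    d = np.hypot(rows - img.center[0], cols - img.center[1])
    return float(d.max())


def n_foreground_components(img: StimulusImage) -> int:
    return int(_sk_label(img.pixels >= 0.5, connectivity=1).max())


# ---------------------------------------------------------------------------
# default catalog: 49 bases -> 366 unique rotations
# ---------------------------------------------------------------------------

_CARDINAL = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


def _spec_from_classes(base_id: int, classes: Sequence[str]) -> ShapeSpec:
    pts = tuple((a, 1.0, c) for a, c in zip(_CARDINAL, classes))
    return ShapeSpec(base_id=base_id, rotation_deg=0.0, control_points=pts)


def _canonical_aperiodic_sequences(n_classes: int, length: int) -> Iterable[tuple]:
    """Class-index sequences that are lexicographically minimal among their
    cyclic shifts and have no cyclic symmetry (full rotation period)."""
    for seq in itertools.product(range(n_classes), repeat=length):
        shifts = {seq[i:] + seq[:i] for i in range(length)}
        if len(shifts) == length and seq == min(shifts):
            yield seq


def _construct_default_bases() -> list[ShapeSpec]:
    """49 base shapes: 3 with 90-deg symmetry, 2 with 180-deg symmetry,
    44 asymmetric.  Expansion over 45-deg rotations gives
    3*2 + 2*4 + 44*8 = 366 unique stimuli."""
    bases: list[ShapeSpec] = []
    # 90-deg symmetric (2 unique rotations each)
    for cls in ("sharp-convex", "medium-convex", "broad-convex"):
        bases.append(_spec_from_classes(len(bases), (cls,) * 4))
    # 180-deg symmetric (4 unique rotations each)
    bases.append(_spec_from_classes(
        len(bases), ("sharp-convex", "broad-convex", "sharp-convex", "broad-convex")))
    bases.append(_spec_from_classes(
        len(bases), ("medium-convex", "sharp-concave", "medium-convex", "sharp-concave")))
    # asymmetric (8 unique rotations each)
    need = 44
    for seq in _canonical_aperiodic_sequences(len(_CLASS_ORDER), 4):
        classes = tuple(_CLASS_ORDER[i] for i in seq)
        bases.append(_spec_from_classes(len(bases), classes))
        if len(bases) == 49:
            break
    assert len(bases) == 49
    return bases


def rotation_period(spec: ShapeSpec, n_steps: int = 8, n_samples: int = 720,
                    tol: float = 1e-9) -> int:
    """Smallest p such that rotating by p*(360/n_steps) degrees leaves the
    contour unchanged; the number of distinct 45-degree rotations."""
    phi = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    r = radial_profile(spec, phi)
    step = n_samples // n_steps
    for p in (1, 2, 4, 8):
        if p == n_steps:
            return n_steps
        if np.max(np.abs(r - np.roll(r, p * step))) < tol:
            return p
    return n_steps


def expand_catalog(bases: Sequence[ShapeSpec], rotation_step_deg: float = 45.0) -> ShapeCatalog:
    """Expand bases over rotations, dropping rotationally symmetric duplicates."""
    entries = []
    for b in bases:
        p = rotation_period(b)
        for k in range(p):
            entries.append(b.rotated(k * rotation_step_deg))
    return ShapeCatalog(entries=entries,
                        provenance=f"default catalog v{CATALOG_VERSION}")


# -- catalog (de)serialization ------------------------------------------------

def catalog_to_json(bases: Sequence[ShapeSpec]) -> dict:
    return {
        "version": CATALOG_VERSION,
        "rotation_step_deg": 45.0,
        "bases": [
            {
                "base_id": b.base_id,
                "control_points": [
                    {"angle_rad": a, "radius": r, "curvature_class": c}
                    for a, r, c in b.control_points
                ],
            }
            for b in bases
        ],
    }


def catalog_from_json(d: dict) -> list[ShapeSpec]:
    return [
        ShapeSpec(
            base_id=b["base_id"],
            rotation_deg=0.0,
            control_points=tuple(
                (p["angle_rad"], p["radius"], p["curvature_class"])
                for p in b["control_points"]
            ),
        )
        for b in d["bases"]
    ]


def load_default_catalog() -> list[ShapeSpec]:
    """Base shapes from the versioned JSON shipped with the package."""
    with resources.files("sparseshape.data").joinpath("catalog.json").open() as fh:
        return catalog_from_json(json.load(fh))


# ---------------------------------------------------------------------------
# standard and invariance sets
# ---------------------------------------------------------------------------

def generate_standard_set(
    rf_size_px: int | None = None,
    config: RunConfig = DEFAULT_CONFIG,
    bases: Sequence[ShapeSpec] | None = None,
    expected_count: int = 366,
) -> tuple[ShapeCatalog, list[StimulusImage]]:
    """Render the standard boundary-conformation set.

    Each shape is scaled so its maximum radial contour extent from the RF
    center equals ``stimulus_extent_frac * rf_size_px`` (default 0.75 x RF).
    """
    rf = rf_size_px if rf_size_px is not None else config.rf_px
    if rf % 2 != 0 or rf > config.canvas_px:
        raise ValueError("rf_size_px must be even and no larger than the canvas")
    if bases is None:
        bases = load_default_catalog()
    catalog = expand_catalog(bases)
    if expected_count is not None and len(catalog) != expected_count:
        counts: dict[int, int] = {}
        for e in catalog.entries:
            counts[e.base_id] = counts.get(e.base_id, 0) + 1
        raise CatalogError(
            f"catalog expansion yielded {len(catalog)} != {expected_count} stimuli; "
            f"per-base rotation counts: {counts}"
        )
    target = config.stimulus_extent_frac * rf
    phi = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
    images = []
    for i, spec in enumerate(catalog.entries):
        scale = target / radial_profile(spec, phi).max()
        img = render(spec, scale, config=config, antialias=config.antialias)
        img.stimulus_id = f"std-{i:03d}"
        images.append(img)
    return catalog, images


_INVARIANCE_LEVELS = (
    "sharp-concave", "medium-concave", "flat", "medium-convex", "sharp-convex",
)


def generate_invariance_set(
    part_curvatures: Sequence[str] = _INVARIANCE_LEVELS,
    scales: Sequence[float] = (0.75, 1.0, 1.25),
    positions: Sequence[tuple] = ((0, 0),),
    config: RunConfig = DEFAULT_CONFIG,
    base_scale: float | None = None,
) -> list[StimulusImage]:
    """Single-varying-part stimuli: one contour part sweeps curvature level
    while the rest of the shape is fixed; the whole shape varies in scale
    or in position within the RF.  Full factorial over
    (curvature, scale, position).
    """
    if len(part_curvatures) < 3 or len(scales) < 3 and len(positions) < 3:
        # at least one series must have >=3 points alongside >=3 curvatures
        pass
    if len(part_curvatures) < 3:
        raise ValueError("need >= 3 curvature levels")
    for c in part_curvatures:
        if c not in CURVATURE_CLASSES:
            raise ValueError(f"unknown curvature class {c!r}")
    if base_scale is None:
        base_scale = config.stimulus_extent_frac * config.rf_px / 1.55
    half = config.canvas_px / 2.0
    images = []
    for ci, cls in enumerate(part_curvatures):
        pts = (
            (0.0, 1.0, cls),
            (np.pi / 2, 1.0, "medium-convex"),
            (np.pi, 1.0, "medium-convex"),
            (3 * np.pi / 2, 1.0, "medium-convex"),
        )
        spec = ShapeSpec(base_id=1000 + ci, control_points=pts)
        rmax = radial_profile(spec, np.linspace(0, 2 * np.pi, 2048, endpoint=False)).max()
        for si, s in enumerate(scales):
            for pi, (dr, dc) in enumerate(positions):
                extent = rmax * base_scale * s
                if extent + max(abs(dr), abs(dc)) > half:
                    raise ValueError(
                        f"scale {s} at position {(dr, dc)} exceeds the canvas"
                    )
                center = (half + dr, half + dc)
                img = render(spec, base_scale * s, center=center, config=config)
                img.stimulus_id = f"inv-c{ci}-s{si}-p{pi}"
                images.append(img)
    return images


# ---------------------------------------------------------------------------
# demonstration stimuli (masks built directly, not via ShapeSpec)
# ---------------------------------------------------------------------------

def _blank(config: RunConfig) -> np.ndarray:
    return np.zeros((config.canvas_px, config.canvas_px), dtype=np.float64)


def disc_stimulus(radius: float, center: tuple | None = None,
                  config: RunConfig = DEFAULT_CONFIG) -> StimulusImage:
    """Filled circle; convex everywhere."""
    n = config.canvas_px
    if center is None:
        center = (n / 2.0, n / 2.0)
    rr, cc = np.mgrid[0:n, 0:n]
    px = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2).astype(float)
    return StimulusImage(px, center=center, px_per_deg=config.px_per_deg,
                         stimulus_id=f"disc-r{radius:g}")


def bump_dent_pair(arc_radius: float = 40.0, config: RunConfig = DEFAULT_CONFIG
                   ) -> tuple[StimulusImage, StimulusImage, tuple]:
    """Two silhouettes sharing an identical circular-arc segment.

    The 'bump' is a disc: the arc bounds it from outside (convex part).
    The 'dent' is a larger disc with a bite taken by the same small circle:
    the arc bounds a concave indentation.  At the shared apex, curvature
    direction (the side the contour bends toward) is identical, while
    curvature sign differs — the motivating failure case for direction-only
    curvature cells.  Returns (bump, dent, apex_rowcol).
    """
    n = config.canvas_px
    c = n / 2.0
    small_c = (c - 40.0, c)            # small circle center, above canvas center
    apex = (small_c[0] + arc_radius, c)  # bottom of the small circle
    rr, cc = np.mgrid[0:n, 0:n]
    small = (rr - small_c[0]) ** 2 + (cc - small_c[1]) ** 2 <= arc_radius**2
    bump = StimulusImage(small.astype(float), center=(c, c),
                         px_per_deg=config.px_per_deg, stimulus_id="demo-bump")
    big_c = (c + 50.0, c)
    big_r = 130.0
    big = (rr - big_c[0]) ** 2 + (cc - big_c[1]) ** 2 <= big_r**2
    dent_px = (big & ~small).astype(float)
    dent = StimulusImage(dent_px, center=(c, c), px_per_deg=config.px_per_deg,
                         stimulus_id="demo-dent")
    return bump, dent, apex


# ---------------------------------------------------------------------------
# stimulus IO
# ---------------------------------------------------------------------------

def save_stimuli(images: Iterable[StimulusImage], out_dir) -> "pd.DataFrame":
    """Write 8-bit grayscale PNGs plus a CSV manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        name = f"{img.stimulus_id or 'stim'}.png"
        arr = np.clip(img.pixels * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / name)
        rows.append({
            "stimulus_id": img.stimulus_id,
            "base_id": img.base_id,
            "rotation_deg": img.rotation_deg,
            "scale": img.scale,
            "center_row": img.center[0],
            "center_col": img.center[1],
            "file": name,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
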