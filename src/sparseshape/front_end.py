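"""Model V1: oriented simple cells and phase-invariant complex cells.

A bank of quadrature Gabor pairs at 12 orientations theta_j = (j-1)*pi/12
spanning (0, pi) and 4 octave-spaced scales (smallest wavelength 4 px,
aspect ratio 0.5).  Simple-cell responses are half-wave rectified filter
outputs; complex cells take the quadrature energy sqrt(odd^2 + even^2),
which is invariant to contrast polarity.  Responses are normalized so the
peak energy per image is 1.

Kernels for orientations >= 90 deg are 90-deg array rotations of the first
six, so rotating an image by 90 deg shifts the orientation index by
exactly 6 channels (up to border effects from the reflect padding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as _fft

from .config import DEFAULT_CONFIG, RunConfig
from .shapes import StimulusImage

__all__ = ["OrientedStack", "GaborBank", "simple_cells", "complex_cells"]


@dataclass
class OrientedStack:
    """Per-location responses indexed (scale, orientation-or-direction, y, x).

    ``extras`` carries auxiliary signed maps (e.g. raw odd/even filter
    outputs) used by downstream stages; ``valid_margin`` is the border
    width (px) within which responses are influenced by padding.
    """

    data: np.ndarray
    orientations: np.ndarray
    scales: tuple
    extras: dict = field(default_factory=dict)
    valid_margin: int = 0

    @property
    def n_scales(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def _gabor_pair(wavelength: float, theta: float, aspect: float,
                bandwidth: float) -> tuple[np.ndarray, np.ndarray]:
    """Even/odd Gabor kernels for a contour oriented at ``theta``.

    The carrier runs perpendicular to the contour orientation, so an edge
    or bar oriented at theta drives this pair maximally.
    """
    sigma = wavelength / np.pi * np.sqrt(np.log(2) / 2) * (2**bandwidth + 1) / (2**bandwidth - 1)
    radius = int(np.ceil(3.0 * sigma))
    c = np.arange(-radius, radius + 1, dtype=np.float64)
    x, y = np.meshgrid(c, c)  # x: col, y: row (down)
    nx, ny = np.cos(theta + np.pi / 2), np.sin(theta + np.pi / 2)
    u = x * nx + y * ny          # across the contour
    v = -x * ny + y * nx         # along the contour
    env = np.exp(-(u**2 + (aspect * v) ** 2) / (2 * sigma**2))
    arg = 2 * np.pi * u / wavelength
    even = env * np.cos(arg)
    odd = env * np.sin(arg)
    even -= env * (even.sum() / env.sum())  # zero-mean (odd already is)
    norm = np.sqrt((even**2).sum())
    return even / norm, odd / np.sqrt((odd**2).sum())


class GaborBank:
    """Precomputed Gabor filter bank with FFT-domain kernels for one canvas.

    Construction is deterministic; instances are cached per
    (canvas size, filter configuration) by :func:`get_bank`.
    """

    def __init__(self, canvas_px: int, config: RunConfig = DEFAULT_CONFIG):
        self.config = config
        self.canvas_px = canvas_px
        self.orientations = np.array(
            [j * np.pi / config.n_orientations for j in range(config.n_orientations)]
        )
        self.wavelengths = config.wavelengths
        n_half = config.n_orientations // 2
        kernels: list[list[tuple]] = []
        for lam in self.wavelengths:
            per_scale = []
            for j in range(n_half):
                per_scale.append(_gabor_pair(lam, self.orientations[j],
                                             config.gabor_aspect, config.gabor_bandwidth))
            for j in range(n_half):
                ev, od = per_scale[j]
                # exact 90-deg rotation keeps the lattice equivariant
                per_scale.append((np.rot90(ev, 1), np.rot90(od, 1)))
            kernels.append(per_scale)
        self.kernels = kernels
        self.max_radius = max(k[0][0].shape[0] // 2 for k in kernels)
        self.pad = self.max_radius
        self._padded = _fft.next_fast_len(canvas_px + 2 * self.pad)
        # one complex kernel per pair (even + i*odd): a single inverse FFT
        # yields even responses in the real part and odd in the imaginary
        self._kfft = [
            [
                _fft.fft2(self._embed(ev) + 1j * self._embed(od),
                          s=(self._padded, self._padded)).astype(np.complex64)
                for ev, od in per_scale
            ]
            for per_scale in kernels
        ]

    def _embed(self, k: np.ndarray) -> np.ndarray:
        """Center the kernel at the origin of the padded frame (circular)."""
        P = self._padded
        out = np.zeros((P, P))
        r = k.shape[0] // 2
        out[: r + 1, : r + 1] = k[r:, r:]
        out[: r + 1, -r:] = k[r:, :r]
        out[-r:, : r + 1] = k[:r, r:]
        out[-r:, -r:] = k[:r, :r]
        return out

    def respond(self, pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Raw (signed) odd/even responses, shape (S, O, H, W), float32."""
        n = self.canvas_px
        if pixels.shape != (n, n):
            raise ValueError(f"expected {(n, n)} image, got {pixels.shape}")
        padded = np.pad(pixels.astype(np.float32), self.pad, mode="reflect")
        extra = self._padded - padded.shape[0]
        padded = np.pad(padded, ((0, extra), (0, extra)), mode="reflect")
        F = _fft.fft2(padded)
        S, O = len(self.wavelengths), len(self.orientations)
        even = np.empty((S, O, n, n), dtype=np.float32)
        odd = np.empty((S, O, n, n), dtype=np.float32)
        sl = slice(self.pad, self.pad + n)
        for s in range(S):
            for j in range(O):
                resp = _fft.ifft2(F * self._kfft[s][j])[sl, sl]
                even[s, j] = resp.real
                odd[s, j] = resp.imag
        return odd, even


_BANK_CACHE: dict = {}


def get_bank(canvas_px: int, config: RunConfig = DEFAULT_CONFIG) -> GaborBank:
    key = (canvas_px, config.n_orientations, config.n_scales,
           config.min_wavelength_px, config.gabor_aspect, config.gabor_bandwidth)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = GaborBank(canvas_px, config)
    return _BANK_CACHE[key]


def simple_cells(img: StimulusImage, config: RunConfig = DEFAULT_CONFIG) -> OrientedStack:
    """Half-wave rectified oriented simple-cell responses.

    ``data`` holds, per scale/orientation, the strongest of the four
    rectified phase units, i.e. max(|odd|, |even|); the signed odd/even
    maps are kept in ``extras`` for the complex-cell energy stage.
    Responses are scaled so the maximum quadrature energy in the image
    is 1 (blank images stay identically zero).
    """
    bank = get_bank(img.canvas_px, config)
    odd, even = bank.respond(img.pixels)
    energy_max = float(np.sqrt(odd.astype(np.float64) ** 2 + even.astype(np.float64) ** 2).max())
    if energy_max > 0:
        odd = odd / energy_max
        even = even / energy_max
    data = np.maximum(np.abs(odd), np.abs(even))
    return OrientedStack(
        data=data,
        orientations=bank.orientations.copy(),
        scales=bank.wavelengths,
        extras={"odd": odd, "even": even},
        valid_margin=bank.max_radius,
    )


def complex_cells(simple: OrientedStack) -> OrientedStack:
    """Phase-invariant oriented energy sqrt(odd^2 + even^2)."""
    if "odd" not in simple.extras or "even" not in simple.extras:
        raise ValueError("simple stack is missing odd/even phase maps")
    odd, even = simple.extras["odd"], simple.extras["even"]
    data = np.sqrt(odd**2 + even**2)
    return OrientedStack(
        data=data,
        orientations=simple.orientations.copy(),
        scales=simple.scales,
        valid_margin=simple.valid_margin,
    )
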