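"""Endstopped cells: curvature degree (EsDeg) and curvature direction (EsDir).

Curvature degree cells receive a facilitatory signal from a simple cell and
inhibition from two complex cells displaced along the preferred orientation;
on a straight contour the flanks cancel the center exactly (the inhibition
weight is calibrated once per configuration on a rendered straight edge), so
the rectified response encodes deviation from a straight line.  Four scales
give four levels of curvature acuteness.

Curvature direction cells pair a simple cell with displaced complex cells at
+/-45 deg orientations.  For each contour orientation theta two opposed
channels (theta + pi/2, theta - pi/2) compete; each channel's flanks are
displaced toward the opposite side, so contour energy on the side the curve
bends away from suppresses that channel and the channel pointing toward the
bend (the direction of the tangent derivative) wins.  Both +/-45 deg flank
orientations contribute at each flank position, keeping the configuration
mirror-symmetric: straight contours tie by construction.

Direction selectivity is necessarily scale-local: a fine-scale flank pair
cannot see a gentle bend.  The per-scale channel stacks are kept, and the
curvature-sign stage decides winners from the scale-pooled channel
difference, where coarse scales supply the sign for gentle curvature and
fine scales for sharp curvature.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import DEFAULT_CONFIG, RunConfig
from .front_end import OrientedStack, complex_cells, simple_cells
from .shapes import StimulusImage

__all__ = ["EsDegStack", "EsDirStack", "curvature_degree", "curvature_direction",
           "gabor_sigma", "straight_edge_weights"]


class EsDegStack(OrientedStack):
    """Curvature-magnitude responses, (scale, orientation, y, x), >= 0."""


class EsDirStack(OrientedStack):
    """Curvature-direction responses, (scale, 2*n_orient, y, x); channels d
    and d + n_orient are the opposing (theta + pi/2, theta - pi/2) pair."""


def gabor_sigma(wavelength: float, bandwidth: float = 1.0) -> float:
    """Envelope std of the front-end Gabor at the given wavelength."""
    return (wavelength / np.pi * np.sqrt(np.log(2) / 2)
            * (2**bandwidth + 1) / (2**bandwidth - 1))


def _flank_displacement(config: RunConfig, s: int) -> int:
    sg = gabor_sigma(config.wavelengths[s], config.gabor_bandwidth)
    return max(1, round(config.flank_frac * sg))


def _shifted(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """a sampled at (y + dy, x + dx) (circular; margins are flagged)."""
    return np.roll(a, (-dy, -dx), axis=(0, 1))


_W_CACHE: dict = {}


def straight_edge_weights(config: RunConfig = DEFAULT_CONFIG) -> tuple:
    """Per-scale inhibition weights w_s such that an infinite straight edge
    yields zero curvature-degree response; calibrated once on a rendered
    vertical step edge and cached per filter configuration."""
    key = (config.n_orientations, config.n_scales, config.min_wavelength_px,
           config.gabor_aspect, config.gabor_bandwidth, config.flank_frac)
    if key in _W_CACHE:
        return _W_CACHE[key]
    side = 4 * int(np.ceil(3 * gabor_sigma(max(config.wavelengths),
                                           config.gabor_bandwidth))) + 64
    px = np.zeros((side, side))
    px[:, side // 2:] = 1.0
    edge = StimulusImage(px, center=(side / 2.0, side / 2.0))
    st = simple_cells(edge, config)
    cx = complex_cells(st)
    j_vert = config.n_orientations // 2  # theta = pi/2
    y, x = side // 2, side // 2  # first foreground column: on the edge
    ws = []
    for s in range(config.n_scales):
        d = _flank_displacement(config, s)
        flanks = cx.data[s, j_vert, y + d, x] + cx.data[s, j_vert, y - d, x]
        ws.append(float(st.data[s, j_vert, y, x] / flanks))
    ws = tuple(ws)
    _W_CACHE[key] = ws
    return ws


def curvature_degree(simple: OrientedStack, cx: OrientedStack,
                     config: RunConfig = DEFAULT_CONFIG) -> EsDegStack:
    """rectify(simple(theta) - w_s * [complex(theta) at +/- Delta along theta])."""
    if simple.data.shape != cx.data.shape:
        raise ValueError("simple and complex stacks are not aligned")
    ws = straight_edge_weights(config)
    S, O = simple.n_scales, len(simple.orientations)
    out = np.empty_like(simple.data)
    for s in range(S):
        d = _flank_displacement(config, s)
        for j, th in enumerate(simple.orientations):
            dy, dx = round(d * np.sin(th)), round(d * np.cos(th))
            fl = _shifted(cx.data[s, j], dy, dx) + _shifted(cx.data[s, j], -dy, -dx)
            out[s, j] = np.maximum(simple.data[s, j] - ws[s] * fl, 0.0)
    return EsDegStack(data=out, orientations=simple.orientations.copy(),
                      scales=simple.scales,
                      valid_margin=simple.valid_margin + _flank_displacement(config, S - 1))


# EsDir flank geometry, in units of the per-scale Gabor envelope sigma:
# flank centers at +/- X0*sigma along the tangent and Y0*sigma toward the
# opposite side; complex maps pooled with an isotropic Gaussian of SM*sigma.
_ESDIR_X0 = 2.0
_ESDIR_Y0 = 1.0
_ESDIR_SMOOTH = 1.0
_ESDIR_W = 0.5


def curvature_direction(simple: OrientedStack, cx: OrientedStack,
                        config: RunConfig = DEFAULT_CONFIG) -> EsDirStack:
    """Opposed direction channels per orientation; the channel on the side
    toward which the contour bends is facilitated, the other inhibited."""
    if simple.data.shape != cx.data.shape:
        raise ValueError("simple and complex stacks are not aligned")
    S, O = simple.n_scales, len(simple.orientations)
    q = O // 4  # 45 deg in channel units
    H, W = simple.data.shape[2:]
    out = np.empty((S, 2 * O, H, W), dtype=simple.data.dtype)
    max_off = 0
    for s in range(S):
        sg = gabor_sigma(config.wavelengths[s], config.gabor_bandwidth)
        x0, y0 = _ESDIR_X0 * sg, _ESDIR_Y0 * sg
        max_off = max(max_off, int(np.ceil(np.hypot(x0, y0) + 2 * _ESDIR_SMOOTH * sg)))
        sm = [gaussian_filter(cx.data[s, j], _ESDIR_SMOOTH * sg, truncate=2.0)
              for j in range(O)]
        for j, th in enumerate(simple.orientations):
            ty, tx = np.sin(th), np.cos(th)
            pair = 0.5 * (sm[(j + q) % O] + sm[(j - q) % O])
            for half, sign in ((0, +1), (1, -1)):
                psi = th + sign * np.pi / 2
                uy, ux = np.sin(psi), np.cos(psi)
                fp = _shifted(pair, round(x0 * ty - y0 * uy), round(x0 * tx - y0 * ux))
                fm = _shifted(pair, round(-x0 * ty - y0 * uy), round(-x0 * tx - y0 * ux))
                out[s, j + half * O] = np.maximum(
                    simple.data[s, j] - _ESDIR_W * (fp + fm), 0.0)
    return EsDirStack(data=out, orientations=simple.orientations.copy(),
                      scales=simple.scales,
                      valid_margin=simple.valid_margin + max_off)
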