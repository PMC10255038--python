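"""Curvature-sign cells and signed local-curvature maps — the model's core.

A contour segment of a simple closed shape is convex when it bends toward
the shape interior.  Two signals decide this at every boundary point: the
curvature direction (which side the contour bends toward, from endstopped
EsDir cells) and the inside-outside direction (from border-ownership
cells).  When the winning directions agree the segment is convex, otherwise
concave:

    convex  = rectify( (EsDir(theta+pi/2) - EsDir(theta-pi/2))
                     * (BO(theta+pi/2)   - BO(theta-pi/2)) )
    concave = rectify( -same product )

so at any location and orientation at most one of the pair is positive.

Signed local-curvature maps then combine curvature magnitude (EsDeg) with
the sign comparison, per scale:

    pos(x, y) = max_j EsDeg(x, y, theta_j) * [convex > concave at theta_j]
    neg(x, y) = max_j EsDeg(x, y, theta_j) * [convex < concave at theta_j]

The max over orientations marginalizes orientation and keeps curvature.
With 4 scales and 2 signs the output is 8 maps: four levels of acuteness
for convexities and concavities.  Ties in the strict comparisons zero both
maps, so straight segments vanish by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .border_ownership import BOStack
from .config import DEFAULT_CONFIG, RunConfig
from .endstopping import EsDegStack, EsDirStack

__all__ = ["SignStack", "CurvatureMaps", "rectify", "curvature_sign",
           "local_curvature", "channel_legend"]


def rectify(v):
    """Half-wave rectification: negative responses go to zero."""
    return np.maximum(v, 0)


@dataclass
class SignStack:
    """Curvature-sign responses: convex/concave, each (scale, orient, y, x)."""

    convex: np.ndarray
    concave: np.ndarray
    orientations: np.ndarray
    valid_margin: int = 0


@dataclass
class CurvatureMaps:
    """Signed local-curvature maps, (8, y, x): channel 2s is the positive
    (convex) map at scale s, channel 2s+1 the negative (concave) map."""

    data: np.ndarray
    scales: tuple = ()
    valid_margin: int = 0

    @property
    def n_maps(self) -> int:
        return self.data.shape[0]

    def pos(self, s: int) -> np.ndarray:
        return self.data[2 * s]

    def neg(self, s: int) -> np.ndarray:
        return self.data[2 * s + 1]


def channel_legend(n_scales: int = 4) -> list[str]:
    """Human-readable names for the map channels, finest scale first."""
    return [f"scale{s + 1}-{sign}" for s in range(n_scales) for sign in ("pos", "neg")]


def curvature_sign(esdir: EsDirStack, bo: BOStack,
                   config: RunConfig = DEFAULT_CONFIG) -> SignStack:
    """Combine direction and inside-outside winners into convex/concave cells.

    The EsDir channel difference is pooled over scales before the product:
    direction selectivity is scale-local (a fine flank pair cannot see a
    gentle bend), so the pooled difference lets whichever scales carry the
    direction signal decide, while the border-ownership difference — and
    hence the response magnitude — stays scale-matched.
    """
    S, D = esdir.data.shape[:2]
    O = D // 2
    if bo.data.shape != esdir.data.shape:
        raise ValueError("EsDir and BO stacks are not aligned")
    d_dir = (esdir.data[:, :O] - esdir.data[:, O:]).sum(axis=0)  # (O, H, W)
    d_bo = bo.data[:, :O] - bo.data[:, O:]                       # (S, O, H, W)
    prod = d_dir[None] * d_bo
    return SignStack(convex=rectify(prod), concave=rectify(-prod),
                     orientations=esdir.orientations.copy(),
                     valid_margin=max(esdir.valid_margin, bo.valid_margin))


def local_curvature(esdeg: EsDegStack, sign: SignStack,
                    config: RunConfig = DEFAULT_CONFIG) -> CurvatureMaps:
    """Per scale, gate curvature magnitude by the strict sign comparison and
    take the max over orientations."""
    S, O = esdeg.data.shape[:2]
    if sign.convex.shape != esdeg.data.shape:
        raise ValueError("EsDeg and sign stacks are not aligned")
    H, W = esdeg.data.shape[2:]
    maps = np.zeros((2 * S, H, W), dtype=esdeg.data.dtype)
    for s in range(S):
        conv_wins = sign.convex[s] > sign.concave[s]
        conc_wins = sign.convex[s] < sign.concave[s]
        pos = (esdeg.data[s] * conv_wins).max(axis=0)
        neg = (esdeg.data[s] * conc_wins).max(axis=0)
        # the pos/neg cells at a location form a competing pair: different
        # orientations can disagree about the sign (numerical residue off
        # the contour), so the weaker of the two is silenced to keep the
        # maps mutually exclusive at every pixel
        maps[2 * s] = np.where(pos >= neg, pos, 0.0)
        maps[2 * s + 1] = np.where(neg > pos, neg, 0.0)
    return CurvatureMaps(data=maps, scales=esdeg.scales,
                         valid_margin=max(esdeg.valid_margin, sign.valid_margin))
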