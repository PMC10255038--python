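"""Signed curvature from the hierarchy: why direction cells are not enough.

Runs two silhouettes that share an identical circular-arc segment — once
as a convex bump (a disc) and once as a concave dent (a bite taken out
of a larger disc) — through the full hierarchy, and prints what the
curvature-direction cells and the signed-curvature maps see at the
shared apex.
"""

import numpy as np

from sparseshape.endstopping import curvature_direction
from sparseshape.front_end import complex_cells, simple_cells
from sparseshape.pipeline import compute_curvature_maps
from sparseshape.shapes import bump_dent_pair

bump, dent, apex = bump_dent_pair()
ay, ax = int(apex[0]), int(apex[1])

for name, img in (("bump (convex)", bump), ("dent (concave)", dent)):
    st = simple_cells(img)
    cx = complex_cells(st)
    es = curvature_direction(st, cx)
    pooled = (es.data[:, :12] - es.data[:, 12:]).sum(axis=0)
    direction = "up" if pooled[0, ay + 1, ax] < 0 else "down"

    maps = compute_curvature_maps(img)
    sl = (slice(ay - 5, ay + 6), slice(ax - 5, ax + 6))
    pos = sum(float(maps.pos(s)[sl].max()) for s in range(4))
    neg = sum(float(maps.neg(s)[sl].max()) for s in range(4))
    print(f"{name:16s} direction winner at apex: {direction:4s}   "
          f"map energy: pos {pos:.3f}  neg {neg:.3f}")

# Both shapes give the same direction winner (the arc bends the same way
# in both), so curvature-direction cells alone cannot distinguish them.
# The signed maps — which combine direction with the inside-outside
# signal — put the bump's energy in the positive (convex) channels and
# the dent's in the negative (concave) channels.
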