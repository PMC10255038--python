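"""End-to-end feedforward pass: stimulus image -> signed-curvature maps.

Convenience orchestration over the front_end, border_ownership,
endstopping and curvature modules, plus optional array dumps
(compressed ``.npz`` with a JSON sidecar describing axes).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .border_ownership import inside_outside
from .config import DEFAULT_CONFIG, RunConfig
from .curvature import CurvatureMaps, channel_legend, curvature_sign, local_curvature
from .endstopping import curvature_degree, curvature_direction
from .front_end import complex_cells, simple_cells
from .shapes import StimulusImage

__all__ = ["compute_curvature_maps", "batch_curvature_maps", "dump_stack"]


def compute_curvature_maps(img: StimulusImage,
                           config: RunConfig = DEFAULT_CONFIG) -> CurvatureMaps:
    """Run the full hierarchy on one stimulus."""
    st = simple_cells(img, config)
    cx = complex_cells(st)
    bo = inside_outside(img, cx, config)
    esdeg = curvature_degree(st, cx, config)
    esdir = curvature_direction(st, cx, config)
    sign = curvature_sign(esdir, bo, config)
    return local_curvature(esdeg, sign, config)


def batch_curvature_maps(images, config: RunConfig = DEFAULT_CONFIG,
                         progress: bool = False):
    """Yield (image, CurvatureMaps) pairs; filter banks are reused."""
    for i, img in enumerate(images):
        if progress and i % 25 == 0:
            print(f"  maps {i}/{len(images)}", flush=True)
        yield img, compute_curvature_maps(img, config)


def dump_stack(data: np.ndarray, path, axes: list[str],
               channels: list[str] | None = None) -> None:
    """Save an array with a JSON sidecar describing its axes."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=data)
    sidecar = {"axes": axes, "shape": list(data.shape)}
    if channels is not None:
        sidecar["channels"] = channels
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
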