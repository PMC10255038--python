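"""Population analyses of learned V4 codes.

Covers receptive-field visualization (signed part-weighted images),
sparsity of convex vs concave weights, facilitatory/inhibitory
contribution sums, the maximum pairwise distance between contributing
parts, tuning-centroid invariance slopes for scale/position series, and
prediction metrics (Pearson r, MAE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .config import DEFAULT_CONFIG, RunConfig
from .v4_fit import GaussianGrid, SparseCode, predict

__all__ = [
    "LearnedRF", "NeuronStats",
    "find_best_segments", "visualize_rf", "save_rf_png",
    "sparsity_stats", "contribution_stats", "max_part_distance",
    "tuning_centroids", "centroid_slope", "invariance_test", "evaluate",
    "convex_mask",
]


def convex_mask(config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Boolean mask over the 72 weights marking convex-map entries."""
    g = config.grid_side**2
    m = np.zeros(config.part_vector_len, dtype=bool)
    for k in range(0, config.n_maps, 2):
        m[k * g:(k + 1) * g] = True
    return m


@dataclass
class LearnedRF:
    """Signed RF image (facilitatory > 0, inhibitory < 0) plus the
    per-(map, cell) component images it sums; linear in gamma."""

    image: np.ndarray
    components: np.ndarray  # (72, rf, rf)
    neuron_id: str = ""


@dataclass
class NeuronStats:
    neuron_id: str
    convex_sparsity: float
    concave_sparsity: float
    facilitatory_convex: float
    inhibitory_convex: float
    facilitatory_concave: float
    inhibitory_concave: float
    max_part_distance: float


# ---------------------------------------------------------------------------
# RF visualization
# ---------------------------------------------------------------------------

def find_best_segments(map_list, images, grid: GaussianGrid,
                       config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Per curvature map, the contour fragment that drives it hardest.

    Scans the supplied stimuli, finds for each map k the location of the
    strongest summed response within one grid-cell window, and cuts that
    window from the map itself (the map is contour-localized, so the cut
    is an isolated segment response).  Returns (n_maps, win, win).
    """
    win = grid.rf_px // config.grid_side
    K = map_list[0].data.shape[0]
    best_val = np.full(K, -1.0)
    best_seg = np.zeros((K, win, win))
    for m in map_list:
        H, W = m.data.shape[1:]
        for k in range(K):
            a = m.data[k]
            # coarse scan over win/2-strided windows
            step = max(win // 2, 1)
            for r0 in range(0, H - win + 1, step):
                for c0 in range(0, W - win + 1, step):
                    v = a[r0:r0 + win, c0:c0 + win].sum()
                    if v > best_val[k]:
                        best_val[k] = v
                        best_seg[k] = a[r0:r0 + win, c0:c0 + win]
    return best_seg


def visualize_rf(code: SparseCode | np.ndarray, grid: GaussianGrid,
                 segments: np.ndarray,
                 config: RunConfig = DEFAULT_CONFIG) -> LearnedRF:
    """Render the learned code as a signed RF image.

    For each map, an auxiliary map tiles that map's best-driving segment at
    the 9 grid cells; it is windowed by each Gaussian kernel, weighted by
    the corresponding gamma entry and summed.  The result is linear in
    gamma: facilitatory parts are positive, inhibitory negative.
    """
    gamma = code.gamma if isinstance(code, SparseCode) else np.asarray(code)
    rf = grid.rf_px
    K = segments.shape[0]
    win = segments.shape[1]
    aux = np.zeros((K, rf, rf))
    for j, (cy, cx) in enumerate(grid.centers):
        r0 = int(round(cy - win / 2))
        c0 = int(round(cx - win / 2))
        r0, c0 = max(r0, 0), max(c0, 0)
        aux[:, r0:r0 + win, c0:c0 + win] = np.maximum(
            aux[:, r0:r0 + win, c0:c0 + win], segments)
    kern = grid.kernel_images()
    kern = kern / kern.max(axis=(1, 2), keepdims=True)  # windowing profile
    components = np.empty((K * grid.n_kernels, rf, rf))
    for k in range(K):
        for j in range(grid.n_kernels):
            components[k * grid.n_kernels + j] = aux[k] * kern[j]
    image = np.tensordot(gamma, components, axes=1)
    return LearnedRF(image=image, components=components)


def save_rf_png(rf: LearnedRF, path) -> None:
    """Diverging rendering: facilitatory red, inhibitory blue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vmax = np.abs(rf.image).max() or 1.0
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rf.image, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def sparsity_stats(gamma: np.ndarray, config: RunConfig = DEFAULT_CONFIG
                   ) -> tuple[float, float]:
    """Fractions of nonzero entries among the 36 convex-map and 36
    concave-map weights (nonzero means |gamma_i| > solver tolerance)."""
    gamma = np.asarray(gamma)
    m = convex_mask(config)
    nz = np.abs(gamma) > config.nonzero_eps
    return (float(nz[m].mean()), float(nz[~m].mean()))


def contribution_stats(gamma: np.ndarray, config: RunConfig = DEFAULT_CONFIG
                       ) -> dict:
    """Facilitatory and inhibitory weight sums, convex/concave split.

    gamma is first normalized so its maximum absolute entry is 1 (the
    max-|.| convention keeps inhibition-dominated neurons sensible); the
    all-zero vector yields all-zero sums.
    """
    gamma = np.asarray(gamma, dtype=float)
    peak = np.abs(gamma).max()
    g = gamma / peak if peak > 0 else gamma
    m = convex_mask(config)
    out = {}
    for name, sel in (("convex", m), ("concave", ~m)):
        part = g[sel]
        out[f"facilitatory_{name}"] = float(part[part > 0].sum())
        out[f"inhibitory_{name}"] = float(-part[part < 0].sum())
    out["facilitatory"] = out["facilitatory_convex"] + out["facilitatory_concave"]
    out["inhibitory"] = out["inhibitory_convex"] + out["inhibitory_concave"]
    return out


def max_part_distance(gamma: np.ndarray, grid: GaussianGrid,
                      config: RunConfig = DEFAULT_CONFIG) -> float:
    """Max Euclidean distance between grid-cell centers of contributing
    (nonzero) parts, as a fraction of the RF side; 0 with < 2 parts.
    Depends only on grid cells, not on which map a part belongs to."""
    gamma = np.asarray(gamma)
    nz = np.abs(gamma) > config.nonzero_eps
    cells = np.unique(np.nonzero(nz)[0] % grid.n_kernels)
    if len(cells) < 2:
        return 0.0
    pts = np.array([grid.centers[j] for j in cells])
    d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()) / grid.rf_px)


# ---------------------------------------------------------------------------
# invariance
# ---------------------------------------------------------------------------

def tuning_centroids(resp: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Response-weighted mean curvature level, one centroid per series row.

    Rows are scale (or position) conditions, columns curvature levels.
    Responses are rectified before weighting (weights must be
    nonnegative); an all-zero row yields NaN.
    """
    resp = np.maximum(np.asarray(resp, dtype=float), 0.0)
    levels = np.asarray(levels, dtype=float)
    tot = resp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (resp * levels[None]) .sum(axis=1) / tot
    c[tot == 0] = np.nan
    return c


def centroid_slope(centroids: np.ndarray, conditions: np.ndarray) -> float:
    """Least-squares slope of tuning centroid against the condition value
    (scale or position); NaN if any centroid is undefined."""
    centroids = np.asarray(centroids, dtype=float)
    conditions = np.asarray(conditions, dtype=float)
    if np.isnan(centroids).any():
        return float("nan")
    if np.ptp(centroids) == 0:  # identical tuning -> exactly zero slope
        return 0.0
    A = np.vstack([conditions, np.ones_like(conditions)]).T
    slope, _ = np.linalg.lstsq(A, centroids, rcond=None)[0]
    return float(slope)


def invariance_test(codes: dict, D_inv: np.ndarray, levels: np.ndarray,
                    conditions: np.ndarray) -> pd.DataFrame:
    """Tuning-centroid slopes for a population over an invariance series.

    D_inv is (n_conditions, n_levels, 72): part vectors of the
    single-varying-part stimuli, one row per scale (or position) step.
    Neurons whose tuning curve is all zero at any condition are flagged
    and excluded from the slope histogram (slope NaN).
    """
    rows = []
    for nid, code in codes.items():
        resp = predict(code, D_inv.reshape(-1, D_inv.shape[-1]))
        resp = resp.reshape(D_inv.shape[:2])
        cent = tuning_centroids(resp, levels)
        rows.append({"neuron_id": nid,
                     "slope": centroid_slope(cent, conditions),
                     "flagged": bool(np.isnan(cent).any())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate(predictions: np.ndarray, observations: np.ndarray
             ) -> tuple[float, float]:
    """(Pearson r, mean absolute error); r is NaN for constant observations."""
    predictions = np.asarray(predictions, dtype=float)
    observations = np.asarray(observations, dtype=float)
    if predictions.shape != observations.shape or len(predictions) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    mae = float(np.mean(np.abs(predictions - observations)))
    if np.std(observations) == 0 or np.std(predictions) == 0:
        return float("nan"), mae
    r = float(_stats.pearsonr(predictions, observations).statistic)
    return r, mae


def neuron_stats(code: SparseCode, grid: GaussianGrid,
                 config: RunConfig = DEFAULT_CONFIG) -> NeuronStats:
    conv_s, conc_s = sparsity_stats(code.gamma, config)
    c = contribution_stats(code.gamma, config)
    return NeuronStats(
        neuron_id=code.neuron_id,
        convex_sparsity=conv_s, concave_sparsity=conc_s,
        facilitatory_convex=c["facilitatory_convex"],
        inhibitory_convex=c["inhibitory_convex"],
        facilitatory_concave=c["facilitatory_concave"],
        inhibitory_concave=c["inhibitory_concave"],
        max_part_distance=max_part_distance(code.gamma, grid, config),
    )
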