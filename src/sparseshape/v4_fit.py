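"""Supervised sparse coding of V4 receptive fields.

Each model V4 cell sees the 8 signed-curvature maps through a fixed 3x3
grid of Gaussian pooling kernels covering its RF, giving a 72-dimensional
part-based vector d_t per stimulus t:

    d_t(i) = sum_{x,y} C(x, y, t, k) * G(x, y, j; mu_j, Sigma_j),
    i = (k - 1) * 9 + j

The signed weight vector gamma over these parts is learned per neuron by
minimizing the elastic-net objective

    min_gamma  sum_t 1/2 ||R_t - d_t^T gamma||^2
             + alpha * rho * ||gamma||_1
             + alpha * (1 - rho) / 2 * ||gamma||_2^2

(the residual term carries 1/2 and no 1/tau factor; solver penalties are
rescaled so this literal objective is minimized).  alpha and rho are set by
k-fold cross-validation on a stratified 60/40 train/test split, followed by
a refit on the full training set.  Predicted responses are the unrectified
inner products R = d^T gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .config import DEFAULT_CONFIG, RunConfig
from .curvature import CurvatureMaps

__all__ = [
    "GaussianGrid", "SparseCode", "FitError",
    "build_part_vector", "part_vector_matrix",
    "fit_neuron", "predict", "stratified_split", "cross_validate",
    "fit_population", "alpha_max",
    "load_responses", "save_responses",
]


class FitError(RuntimeError):
    """Solver failed to converge; carries diagnostics in the message."""


# ---------------------------------------------------------------------------
# Gaussian pooling grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianGrid:
    """3x3 grid of identical isotropic Gaussian kernels over the RF square.

    Centers sit at fractions {1/6, 1/2, 5/6} of the RF side; sigma is
    RF_side/6 so each kernel's std spans half a grid cell.  Kernels are
    normalized to unit sum over the RF window and are fixed, not learned.
    """

    rf_px: int
    sigma: float
    centers: tuple  # ((row, col), ...) relative to the RF window, row-major

    @classmethod
    def default(cls, config: RunConfig = DEFAULT_CONFIG) -> "GaussianGrid":
        rf = config.rf_px
        g = config.grid_side
        fr = [(2 * i + 1) / (2 * g) for i in range(g)]
        centers = tuple((rf * fy, rf * fx) for fy in fr for fx in fr)
        return cls(rf_px=rf, sigma=config.kernel_sigma_frac * rf, centers=centers)

    @property
    def n_kernels(self) -> int:
        return len(self.centers)

    def kernel_images(self) -> np.ndarray:
        """(9, rf, rf) unit-sum kernel rasters."""
        yy, xx = np.mgrid[0:self.rf_px, 0:self.rf_px].astype(float) + 0.5
        out = np.empty((self.n_kernels, self.rf_px, self.rf_px))
        for j, (cy, cx) in enumerate(self.centers):
            g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * self.sigma**2))
            out[j] = g / g.sum()
        return out


_KERNEL_CACHE: dict = {}


def _kernels(grid: GaussianGrid) -> np.ndarray:
    key = (grid.rf_px, grid.sigma, grid.centers)
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = grid.kernel_images()
    return _KERNEL_CACHE[key]


def build_part_vector(maps: CurvatureMaps, grid: GaussianGrid,
                      rf_center: tuple | None = None) -> np.ndarray:
    """Pool each curvature map through each grid kernel: 72-vector with
    index i = k * 9 + j (map k, grid cell j, both 0-based)."""
    K, H, W = maps.data.shape
    rf = grid.rf_px
    if rf_center is None:
        rf_center = (H / 2.0, W / 2.0)
    r0 = int(round(rf_center[0] - rf / 2))
    c0 = int(round(rf_center[1] - rf / 2))
    if r0 < 0 or c0 < 0 or r0 + rf > H or c0 + rf > W:
        raise ValueError("RF window exceeds curvature-map extent")
    window = maps.data[:, r0:r0 + rf, c0:c0 + rf]
    kern = _kernels(grid)
    # (K, rf*rf) @ (rf*rf, 9) -> (K, 9) -> flat 72
    d = window.reshape(K, -1) @ kern.reshape(grid.n_kernels, -1).T
    return np.asarray(d, dtype=np.float64).ravel()


def part_vector_matrix(map_list, grid: GaussianGrid) -> np.ndarray:
    """Stack part vectors for a list of CurvatureMaps: (n_stimuli, 72)."""
    return np.vstack([build_part_vector(m, grid) for m in map_list])


def standardize_parts(D: np.ndarray) -> np.ndarray:
    """Scale part-vector columns to unit RMS (no centering).

    Raw pooled-curvature features differ in scale by orders of magnitude
    across maps, which makes the L1/L2 penalties weigh parts inequitably;
    penalized fits are therefore run on RMS-scaled features (the usual
    convention for penalized regression).  Support and signs of the
    weights are unchanged by column scaling.
    """
    D = np.asarray(D, dtype=np.float64)
    s = np.sqrt((D**2).mean(axis=0))
    s[s == 0] = 1.0
    return D / s


# ---------------------------------------------------------------------------
# elastic net (Eq. objective above, literal scaling)
# ---------------------------------------------------------------------------

@dataclass
class SparseCode:
    """Learned signed weights plus fit metadata."""

    gamma: np.ndarray
    alpha: float
    rho: float
    n_iter: int = 0
    train_r: float = np.nan
    train_mae: float = np.nan
    test_r: float = np.nan
    test_mae: float = np.nan
    train_ids: np.ndarray | None = None
    test_ids: np.ndarray | None = None
    neuron_id: str = ""


def objective(D: np.ndarray, R: np.ndarray, gamma: np.ndarray,
              alpha: float, rho: float) -> float:
    """The literal elastic-net objective value."""
    resid = R - D @ gamma
    return float(0.5 * resid @ resid
                 + alpha * rho * np.abs(gamma).sum()
                 + 0.5 * alpha * (1 - rho) * gamma @ gamma)


def alpha_max(D: np.ndarray, R: np.ndarray, rho: float) -> float:
    """Smallest alpha for which the elastic-net solution is exactly zero."""
    rho = max(rho, 1e-3)
    return float(np.max(np.abs(D.T @ R)) / rho)


def fit_neuron(D: np.ndarray, R: np.ndarray, alpha: float, rho: float,
               positive: bool = False,
               config: RunConfig = DEFAULT_CONFIG,
               fast: bool = False) -> SparseCode:
    """Minimize the elastic-net objective for one neuron.

    D is (tau, 72); R is (tau,).  ``positive`` restricts gamma to
    facilitatory (nonnegative) weights for the ablation analysis.
    The sklearn coordinate-descent solver minimizes the per-sample-scaled
    objective, so its alpha is ours divided by tau.

    ``fast`` relaxes the solver tolerance and skips the exact refinement;
    it is used inside cross-validation scoring, where hyperparameter
    ranking does not need machine-precision solutions.  Final fits always
    run at full precision.
    """
    D = np.asarray(D, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    tau = D.shape[0]
    if tau < 2:
        raise ValueError("need at least 2 stimuli to fit")
    if alpha < 0 or not 0 <= rho <= 1:
        raise ValueError("alpha must be >= 0 and rho in [0, 1]")
    if alpha == 0:
        if positive:
            from scipy.optimize import nnls
            gamma, _ = nnls(D, R)
        else:
            gamma, *_ = np.linalg.lstsq(D, R, rcond=None)
        return SparseCode(gamma=gamma, alpha=0.0, rho=rho, n_iter=0)
    import warnings
    model = ElasticNet(alpha=alpha / tau, l1_ratio=rho, fit_intercept=False,
                       positive=positive, precompute=tau > D.shape[1],
                       max_iter=5000 if fast else config.max_iter,
                       tol=1e-6 if fast else config.tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(D, R)
    n_iter = int(np.max(model.n_iter_)) if np.ndim(model.n_iter_) else int(model.n_iter_)
    if fast:
        return SparseCode(gamma=model.coef_.copy(), alpha=alpha, rho=rho,
                          n_iter=n_iter)
    gamma = _active_set_polish(D, R, alpha, rho, model.coef_.copy(), positive)
    if _kkt_violation(D, R, alpha, rho, gamma, positive) > 1e-7 * max(alpha * rho, 1e-12):
        # degenerate active set (e.g. pure lasso with support == tau);
        # fall back to the exact homotopy solver
        gamma2 = _lars_enet(D, R, alpha, rho, positive, config)
        if objective(D, R, gamma2, alpha, rho) < objective(D, R, gamma, alpha, rho):
            gamma = gamma2
        viol = _kkt_violation(D, R, alpha, rho, gamma, positive)
        if viol > 1e-3 * max(alpha * rho, 1.0):  # pragma: no cover
            raise FitError(
                f"elastic net failed to converge (alpha={alpha}, rho={rho}, "
                f"tau={tau}): stationarity violation {viol:.3e} after "
                f"{n_iter} coordinate-descent iterations and homotopy fallback")
    return SparseCode(gamma=gamma, alpha=alpha, rho=rho, n_iter=n_iter)


def _kkt_violation(D: np.ndarray, R: np.ndarray, alpha: float, rho: float,
                   gamma: np.ndarray, positive: bool) -> float:
    """Worst violation of the elastic-net stationarity conditions."""
    corr = D.T @ (R - D @ gamma) - alpha * (1 - rho) * gamma
    l1 = alpha * rho
    act = gamma != 0
    v_act = np.abs(corr[act] - l1 * np.sign(gamma[act])).max() if act.any() else 0.0
    if positive:
        v_in = max(float(corr[~act].max(initial=0.0) - l1), 0.0)
    else:
        v_in = max(float(np.abs(corr[~act]).max(initial=0.0) - l1), 0.0)
    return max(float(v_act), v_in)


def _lars_enet(D: np.ndarray, R: np.ndarray, alpha: float, rho: float,
               positive: bool, config: RunConfig) -> np.ndarray:
    """Exact elastic-net solution via LARS on the ridge-augmented system."""
    from sklearn.linear_model import LassoLars

    tau, P = D.shape
    if rho < 1:
        X = np.vstack([D, np.sqrt(alpha * (1 - rho)) * np.eye(P)])
        y = np.concatenate([R, np.zeros(P)])
    else:
        X, y = D, R
    model = LassoLars(alpha=alpha * rho / X.shape[0], fit_intercept=False,
                      positive=positive, max_iter=5000)
    model.fit(X, y)
    return model.coef_.copy()


def _active_set_polish(D: np.ndarray, R: np.ndarray, alpha: float, rho: float,
                       gamma: np.ndarray, positive: bool,
                       max_rounds: int = 100) -> np.ndarray:
    """Refine a coordinate-descent solution to near machine precision.

    Active-set Newton refinement: on a fixed-sign active set the
    elastic-net stationarity condition is a linear system.  Solve it
    exactly, drop entries whose sign flips, add the worst violator of the
    subgradient optimality condition, and iterate.  The polished vector is
    kept only if it does not raise the literal objective.
    """
    best = gamma
    best_obj = objective(D, R, gamma, alpha, rho)
    g = gamma.copy()
    l1 = alpha * rho
    for _ in range(max_rounds):
        A = g != 0
        s = np.sign(g[A])
        if A.any():
            DA = D[:, A]
            M = DA.T @ DA + alpha * (1 - rho) * np.eye(int(A.sum()))
            b = DA.T @ R - l1 * s
            # lstsq handles the singular pure-lasso case (support > tau);
            # an inconsistent system means the support is too large
            x = np.linalg.lstsq(M, b, rcond=None)[0]
            if np.linalg.norm(M @ x - b) > 1e-10 * max(np.linalg.norm(b), 1.0):
                drop = int(np.argmin(np.abs(x)))
                idx = np.nonzero(A)[0]
                g[idx[drop]] = 0.0
                continue
            flipped = np.sign(x) != s
            if positive:
                flipped |= x < 0
            x[flipped] = 0.0
            g = np.zeros_like(g)
            g[A] = x
            if flipped.any():
                continue  # re-solve on the shrunken set first
        # subgradient optimality for inactive coordinates
        corr = D.T @ (R - D @ g)
        corr[g != 0] = 0.0
        if positive:
            viol = corr - l1
        else:
            viol = np.abs(corr) - l1
        i = int(np.argmax(viol))
        if viol[i] <= l1 * 1e-12 + 1e-14:
            obj = objective(D, R, g, alpha, rho)
            if obj <= best_obj:
                best, best_obj = g, obj
            break
        g[i] = np.sign(corr[i]) * 1e-30  # admit violator with its sign
        obj = objective(D, R, g, alpha, rho)
        if obj < best_obj:
            best, best_obj = g.copy(), obj
    return best


def predict(code: SparseCode | np.ndarray, d: np.ndarray) -> np.ndarray | float:
    """Unrectified response D_s^T gamma; linear in both arguments."""
    gamma = code.gamma if isinstance(code, SparseCode) else np.asarray(code)
    d = np.asarray(d)
    if d.shape[-1] != gamma.shape[0]:
        raise ValueError(f"dimension mismatch: {d.shape[-1]} vs {gamma.shape[0]}")
    return d @ gamma


# ---------------------------------------------------------------------------
# splitting and cross-validation
# ---------------------------------------------------------------------------

def stratified_split(R: np.ndarray, frac_train: float = 0.6, seed: int = 0,
                     n_strata: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of stimulus indices.

    Stimuli are binned by response quantile (default quartiles) so both
    splits sample the neuron's full response range; each bin is split at
    frac_train.  Deterministic given the seed.
    """
    if not 0 < frac_train < 1:
        raise ValueError("frac_train must lie in (0, 1)")
    R = np.asarray(R, dtype=float)
    n = len(R)
    edges = np.quantile(R, np.linspace(0, 1, n_strata + 1)[1:-1])
    bins = np.searchsorted(edges, R, side="right")
    # merge undersized strata (can happen with heavily tied responses)
    for b in range(n_strata):
        if 0 < (bins == b).sum() < 2:
            bins[bins == b] = min(b + 1, n_strata - 1)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for b in np.unique(bins):
        idx = np.nonzero(bins == b)[0]
        rng.shuffle(idx)
        k = int(round(frac_train * len(idx)))
        train.extend(idx[:k])
        test.extend(idx[k:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def _alpha_grid(D: np.ndarray, R: np.ndarray, rho_grid, config: RunConfig) -> np.ndarray:
    amax = max(alpha_max(D, R, max(rho_grid)), 1e-12)
    return np.logspace(np.log10(amax) - config.alpha_decades, np.log10(amax),
                       config.n_alphas)


def cross_validate(D: np.ndarray, R: np.ndarray,
                   alpha_grid: np.ndarray | None = None,
                   rho_grid=None, k_folds: int | None = None,
                   seed: int = 0, positive: bool = False,
                   config: RunConfig = DEFAULT_CONFIG) -> tuple[float, float]:
    """Pick (alpha, rho) minimizing mean held-out squared error over k folds.

    Ties break toward the smallest alpha (least shrinkage), then the
    largest rho (sparsest penalty mix).
    """
    if rho_grid is None:
        rho_grid = config.rho_grid
    if alpha_grid is None:
        alpha_grid = _alpha_grid(D, R, rho_grid, config)
    if k_folds is None:
        k_folds = config.cv_folds
    n = len(R)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    scores = np.zeros((len(alpha_grid), len(rho_grid)))
    for f in folds:
        mask = np.ones(n, dtype=bool)
        mask[f] = False
        Dtr, Rtr, Dte, Rte = D[mask], R[mask], D[~mask], R[~mask]
        for ai, a in enumerate(alpha_grid):
            for ri, r in enumerate(rho_grid):
                code = fit_neuron(Dtr, Rtr, a, r, positive=positive,
                                  config=config, fast=True)
                err = Rte - predict(code, Dte)
                scores[ai, ri] += err @ err
    scores /= n
    best = None
    for ai, a in enumerate(alpha_grid):        # ascending alpha
        for ri in range(len(rho_grid) - 1, -1, -1):  # descending rho
            if best is None or scores[ai, ri] < scores[best] - 1e-12:
                best = (ai, ri)
    return float(alpha_grid[best[0]]), float(rho_grid[best[1]])


# ---------------------------------------------------------------------------
# population fitting
# ---------------------------------------------------------------------------

def _pearson_mae(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    mae = float(np.mean(np.abs(pred - obs)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        return np.nan, mae
    return float(np.corrcoef(pred, obs)[0, 1]), mae


def fit_population(D: np.ndarray, responses: pd.DataFrame,
                   config: RunConfig = DEFAULT_CONFIG,
                   seed: int = 0, positive: bool = False,
                   stimulus_ids=None) -> tuple[dict, pd.DataFrame]:
    """Split -> cross-validate -> refit -> evaluate, per neuron.

    D is the (n_stimuli, 72) part-vector matrix in stimulus order;
    ``responses`` has columns (neuron_id, stimulus_id, response) with
    stimulus_id an integer row index into D unless ``stimulus_ids`` maps
    ids to rows.  Neurons with constant responses are skipped (Pearson r
    undefined) with a log entry in the metrics table.

    Returns ({neuron_id: SparseCode}, metrics DataFrame).
    """
    id_to_row = None
    if stimulus_ids is not None:
        id_to_row = {sid: i for i, sid in enumerate(stimulus_ids)}
    codes: dict = {}
    rows = []
    for g, (nid, df) in enumerate(responses.groupby("neuron_id", sort=True)):
        if id_to_row is not None:
            idx = df["stimulus_id"].map(id_to_row).to_numpy()
        else:
            idx = df["stimulus_id"].to_numpy(dtype=int)
        R = df["response"].to_numpy(dtype=float)
        if np.all(R == R[0]):
            rows.append({"neuron_id": nid, "skipped": True,
                         "reason": "constant responses"})
            continue
        nseed = (seed * 1_000_003 + g) % (2**31)
        tr, te = stratified_split(R, config.train_frac, seed=nseed,
                                  n_strata=config.n_strata)
        Dtr, Rtr = D[idx[tr]], R[tr]
        a, r = cross_validate(Dtr, Rtr, seed=nseed, positive=positive,
                              config=config)
        code = fit_neuron(Dtr, Rtr, a, r, positive=positive, config=config)
        code.neuron_id = str(nid)
        code.train_ids, code.test_ids = idx[tr], idx[te]
        code.train_r, code.train_mae = _pearson_mae(predict(code, Dtr), Rtr)
        pred_te = predict(code, D[idx[te]])
        code.test_r, code.test_mae = _pearson_mae(pred_te, R[te])
        codes[nid] = code
        rows.append({"neuron_id": nid, "skipped": False, "alpha": a, "rho": r,
                     "n_nonzero": int((np.abs(code.gamma) > config.nonzero_eps).sum()),
                     "train_r": code.train_r, "train_mae": code.train_mae,
                     "test_r": code.test_r, "test_mae": code.test_mae})
    return codes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response-table IO
# ---------------------------------------------------------------------------

def load_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"neuron_id", "stimulus_id", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response table is missing columns: {sorted(missing)}")
    if not np.isfinite(df["response"].to_numpy(dtype=float)).all():
        raise ValueError("responses must be finite")
    if df.duplicated(["neuron_id", "stimulus_id"]).any():
        raise ValueError("duplicate neuron/stimulus pairs in response table")
    return df


def save_responses(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
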