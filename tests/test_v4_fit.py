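"""Sparse-coding machinery: Gaussian grid, part vectors, elastic-net
solutions vs an independent convex oracle, splitting, cross-validation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from sparseshape.curvature import CurvatureMaps
from sparseshape.v4_fit import (GaussianGrid, alpha_max, build_part_vector,
                                cross_validate, fit_neuron, objective, predict,
                                standardize_parts, stratified_split)


def enet_oracle(D, R, alpha, rho):
    """General-purpose convex solver for the elastic-net objective: split
    gamma into positive/negative parts, making the problem smooth and
    box-constrained (independent of the coordinate-descent path)."""
    tau, P = D.shape

    def f(z):
        g = z[:P] - z[P:]
        resid = R - D @ g
        return (0.5 * resid @ resid + alpha * rho * z.sum()
                + 0.5 * alpha * (1 - rho) * g @ g)

    def grad(z):
        g = z[:P] - z[P:]
        gr = -(D.T @ (R - D @ g)) + alpha * (1 - rho) * g
        return np.concatenate([gr + alpha * rho, -gr + alpha * rho])

    res = minimize(f, np.zeros(2 * P), jac=grad, bounds=[(0, None)] * 2 * P,
                   method="L-BFGS-B",
                   options=dict(maxiter=100000, maxfun=1000000,
                                ftol=1e-18, gtol=1e-14))
    return res.x[:P] - res.x[P:], res.fun


class TestGaussianGrid:
    def test_default_geometry(self, config):
        grid = GaussianGrid.default(config)
        assert grid.n_kernels == 9
        fr = np.array([1 / 6, 1 / 2, 5 / 6]) * 128
        centers = np.array(grid.centers)
        np.testing.assert_allclose(sorted(set(centers[:, 0])), fr)
        assert grid.sigma == pytest.approx(128 / 6)

    def test_kernels_unit_sum_and_translated(self, config):
        grid = GaussianGrid.default(config)
        k = grid.kernel_images()
        np.testing.assert_allclose(k.sum(axis=(1, 2)), 1.0, atol=1e-9)
        # center kernel is symmetric under the grid's translations
        assert k.shape == (9, 128, 128)


class TestPartVector:
    def test_zero_maps_give_zero_vector(self, config):
        maps = CurvatureMaps(data=np.zeros((8, 400, 400)))
        grid = GaussianGrid.default(config)
        d = build_part_vector(maps, grid)
        assert d.shape == (72,)
        assert np.all(d == 0)

    def test_impulse_at_kernel_center(self, config):
        grid = GaussianGrid.default(config)
        data = np.zeros((8, 400, 400))
        # grid cell 5 (0-based index 4 = center cell) of map k=0
        cy, cx = grid.centers[4]
        r0, c0 = 200 - 64, 200 - 64
        data[0, int(r0 + cy), int(c0 + cx)] = 1.0
        d = build_part_vector(CurvatureMaps(data=data), grid)
        kern = grid.kernel_images()
        # entry (k=0, j=4): kernel value at its own center (its peak)
        assert d[4] == pytest.approx(kern[4].max(), rel=1e-6)
        # other entries equal that kernel tail at the impulse location
        assert d[0] == pytest.approx(kern[0][int(cy + 0.0), int(cx)], rel=1e-4)
        assert np.all(d[9:] == 0)

    def test_rf_window_out_of_bounds(self, config):
        maps = CurvatureMaps(data=np.zeros((8, 100, 100)))
        with pytest.raises(ValueError, match="RF window"):
            build_part_vector(maps, GaussianGrid.default(config))


class TestElasticNet:
    @pytest.mark.parametrize("alpha,rho", [(0.01, 0.5), (0.01, 1.0),
                                           (0.1, 0.5), (0.1, 1.0)])
    def test_matches_convex_oracle(self, alpha, rho):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(5):
            D = rng.normal(size=(30, 72))
            R = rng.normal(size=30)
            code = fit_neuron(D, R, alpha, rho)
            mine = objective(D, R, code.gamma, alpha, rho)
            _, ref = enet_oracle(D, R, alpha, rho)
            worst = max(worst, (mine - ref) / abs(ref))
        assert worst < 1e-6

    def test_alpha_zero_is_least_squares(self):
        rng = np.random.default_rng(1)
        D = rng.normal(size=(100, 72))
        R = rng.normal(size=100)
        code = fit_neuron(D, R, 0.0, 0.5)
        ls, *_ = np.linalg.lstsq(D, R, rcond=None)
        np.testing.assert_allclose(code.gamma, ls, atol=1e-10)

    def test_large_alpha_gives_exact_zero(self):
        rng = np.random.default_rng(2)
        D = rng.normal(size=(50, 72))
        R = rng.normal(size=50)
        code = fit_neuron(D, R, alpha_max(D, R, 0.7) * 1.001, 0.7)
        assert np.all(code.gamma == 0)

    def test_positive_mode_is_nonnegative(self):
        rng = np.random.default_rng(3)
        D = rng.normal(size=(80, 72))
        g = np.zeros(72)
        g[[3, 40]] = [1.0, -0.8]
        R = D @ g
        code = fit_neuron(D, R, 0.1, 0.5, positive=True)
        assert np.all(code.gamma >= 0)

    def test_monotone_regularization_path(self):
        """Nonzero count is non-increasing in alpha at fixed rho."""
        rng = np.random.default_rng(4)
        D = rng.normal(size=(150, 72))
        g = np.zeros(72)
        g[rng.choice(72, 8, replace=False)] = rng.uniform(0.5, 1, 8)
        R = D @ g + 0.05 * rng.normal(size=150)
        amax = alpha_max(D, R, 1.0)
        nnz = []
        for a in np.logspace(np.log10(amax) - 4, np.log10(amax), 20):
            code = fit_neuron(D, R, a, 1.0)
            nnz.append(int((np.abs(code.gamma) > 1e-8).sum()))
        assert all(b <= a + 1 for a, b in zip(nnz, nnz[1:]))  # allow 1-step jitter
        assert nnz[-1] == 0

    def test_invalid_hyperparameters(self):
        D = np.zeros((5, 72))
        with pytest.raises(ValueError):
            fit_neuron(D, np.zeros(5), -1.0, 0.5)
        with pytest.raises(ValueError):
            fit_neuron(D, np.zeros(5), 1.0, 1.5)
        with pytest.raises(ValueError):
            fit_neuron(np.zeros((1, 72)), np.zeros(1), 1.0, 0.5)


class TestPredict:
    def test_linear_in_gamma(self):
        rng = np.random.default_rng(0)
        d = rng.random(72)
        g = rng.normal(size=72)
        assert predict(2 * g, d) == pytest.approx(2 * predict(g, d))
        assert predict(np.zeros(72), d) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            predict(np.zeros(72), np.zeros(10))


class TestStratifiedSplit:
    def test_partition_sizes(self):
        rng = np.random.default_rng(0)
        R = rng.random(366)
        tr, te = stratified_split(R, 0.6, seed=1)
        assert len(tr) + len(te) == 366
        assert len(tr) in (219, 220)
        assert len(np.intersect1d(tr, te)) == 0

    def test_deterministic(self):
        R = np.random.default_rng(0).random(366)
        a = stratified_split(R, 0.6, seed=5)
        b = stratified_split(R, 0.6, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_quartiles_proportionally_represented(self):
        R = np.random.default_rng(3).random(366)
        edges = np.quantile(R, [0.25, 0.5, 0.75])
        bins = np.searchsorted(edges, R)
        for seed in range(100):
            tr, _ = stratified_split(R, 0.6, seed=seed)
            for b in range(4):
                n_bin = (bins == b).sum()
                n_tr = (bins[tr] == b).sum()
                assert abs(n_tr - 0.6 * n_bin) <= 1

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            stratified_split(np.arange(10.0), 1.2, seed=0)


class TestCrossValidate:
    def test_single_point_grid(self):
        rng = np.random.default_rng(0)
        D = rng.normal(size=(40, 72))
        R = rng.normal(size=40)
        a, r = cross_validate(D, R, alpha_grid=np.array([0.5]), rho_grid=[0.7],
                              seed=0)
        assert (a, r) == (0.5, 0.7)

    def test_noiseless_data_selects_smallest_alpha(self):
        rng = np.random.default_rng(1)
        D = rng.normal(size=(200, 72))
        g = np.zeros(72)
        g[rng.choice(72, 5, replace=False)] = rng.uniform(0.5, 1.0, 5)
        R = D @ g  # exact linear responses, no noise
        grid = np.array([1e-4, 1e-2, 1.0, 100.0])
        a, _ = cross_validate(D, R, alpha_grid=grid, rho_grid=[0.5], seed=2)
        assert a == grid[0]

    def test_selected_point_minimizes_score(self):
        """Exhaustive re-evaluation: no grid point scores better than the
        selected one."""
        rng = np.random.default_rng(5)
        D = rng.normal(size=(60, 72))
        g = np.zeros(72)
        g[:4] = 1.0
        R = D @ g + 0.3 * rng.normal(size=60)
        agrid = np.array([0.01, 0.1, 1.0])
        rgrid = [0.5, 1.0]

        def score(alpha, rho, seed=9, k=5):
            n = len(R)
            order = np.random.default_rng(seed).permutation(n)
            folds = np.array_split(order, k)
            total = 0.0
            for f in folds:
                mask = np.ones(n, bool)
                mask[f] = False
                code = fit_neuron(D[mask], R[mask], alpha, rho, fast=True)
                err = R[~mask] - predict(code, D[~mask])
                total += err @ err
            return total / n

        a, r = cross_validate(D, R, alpha_grid=agrid, rho_grid=rgrid, seed=9)
        best = min(score(ai, ri) for ai in agrid for ri in rgrid)
        assert score(a, r) <= best + 1e-9


def test_standardize_parts_unit_rms():
    rng = np.random.default_rng(0)
    D = rng.random((50, 72)) * np.logspace(-4, 0, 72)
    Ds = standardize_parts(D)
    np.testing.assert_allclose(np.sqrt((Ds**2).mean(axis=0)), 1.0, atol=1e-12)
    assert np.all(np.sign(Ds) == np.sign(D))


class TestFitPopulation:
    def test_noiseless_neurons_recover_predictions(self):
        """Noiseless linear neurons: held-out r is essentially perfect."""
        import pandas as pd
        from sparseshape.synthetic_v4 import make_population, simulate_responses
        from sparseshape.v4_fit import fit_population

        rng = np.random.default_rng(0)
        D = rng.random((366, 72))
        frames = [simulate_responses(n, D)
                  for n in make_population(5, K=5, noise_sigma=0.0, seed=2)]
        codes, metrics = fit_population(D, pd.concat(frames), seed=1)
        assert len(codes) == 5
        assert (metrics["test_r"] >= 0.99).all()

    def test_constant_response_neuron_skipped(self):
        import pandas as pd
        from sparseshape.v4_fit import fit_population

        rng = np.random.default_rng(1)
        D = rng.random((50, 72))
        resp = pd.DataFrame({
            "neuron_id": ["flat"] * 50,
            "stimulus_id": np.arange(50),
            "response": np.ones(50),
        })
        codes, metrics = fit_population(D, resp, seed=0)
        assert codes == {}
        assert bool(metrics.loc[0, "skipped"])
        assert "constant" in metrics.loc[0, "reason"]
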