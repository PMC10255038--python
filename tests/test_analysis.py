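"""Analysis suite: RF visualization linearity, sparsity and contribution
statistics, part distances, invariance slopes, prediction metrics."""

import numpy as np
import pytest

from sparseshape.analysis import (centroid_slope, contribution_stats, evaluate,
                                  invariance_test, max_part_distance,
                                  sparsity_stats, tuning_centroids, visualize_rf)
from sparseshape.v4_fit import GaussianGrid


@pytest.fixture(scope="module")
def grid(config):
    return GaussianGrid.default(config)


@pytest.fixture(scope="module")
def segments(grid):
    """Synthetic per-map motifs (a small oriented blob per map) standing in
    for the standard-set best-driving contour fragments."""
    rng = np.random.default_rng(0)
    win = grid.rf_px // 3
    yy, xx = np.mgrid[0:win, 0:win]
    segs = np.empty((8, win, win))
    for k in range(8):
        cy, cx = rng.uniform(10, win - 10, 2)
        segs[k] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 30.0)
    return segs


class TestVisualizeRF:
    def test_zero_code_gives_blank(self, grid, segments):
        rf = visualize_rf(np.zeros(72), grid, segments)
        assert np.all(rf.image == 0)

    def test_single_entry_localizes_to_cell(self, grid, segments):
        gamma = np.zeros(72)
        gamma[0] = 1.0  # map k=0, grid cell j=0 (top-left)
        rf = visualize_rf(gamma, grid, segments)
        assert np.all(rf.image >= 0)
        half = grid.rf_px // 2
        assert rf.image[:half, :half].sum() > rf.image[half:, half:].sum()

    def test_linear_in_gamma(self, grid, segments):
        rng = np.random.default_rng(1)
        g1, g2 = rng.normal(size=72), rng.normal(size=72)
        lhs = visualize_rf(g1 + g2, grid, segments).image
        rhs = (visualize_rf(g1, grid, segments).image
               + visualize_rf(g2, grid, segments).image)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestSparsity:
    def test_half_nonzero(self, config):
        gamma = np.zeros(72)
        conv_idx = [k * 9 + j for k in (0, 2, 4, 6) for j in range(9)]
        gamma[conv_idx[:18]] = 1.0
        conv, conc = sparsity_stats(gamma, config)
        assert conv == 0.5 and conc == 0.0

    def test_zero_vector(self, config):
        assert sparsity_stats(np.zeros(72), config) == (0.0, 0.0)

    def test_convexity_biased_population(self, config):
        """Generating with a convex bias should show up as higher median
        convex than concave sparsity across neurons."""
        from sparseshape.synthetic_v4 import make_population

        pop = make_population(30, K=12, convex_bias=0.8, seed=3)
        conv = np.median([sparsity_stats(n.true_gamma, config)[0] for n in pop])
        conc = np.median([sparsity_stats(n.true_gamma, config)[1] for n in pop])
        assert conv > conc


class TestContributions:
    def test_example_sums(self, config):
        gamma = np.zeros(72)
        gamma[0], gamma[1] = 1.0, -0.5  # both in convex map k=0
        c = contribution_stats(gamma, config)
        assert c["facilitatory_convex"] == pytest.approx(1.0)
        assert c["inhibitory_convex"] == pytest.approx(0.5)
        assert c["facilitatory_concave"] == 0.0

    def test_sign_flip_swaps_sums(self, config):
        rng = np.random.default_rng(2)
        gamma = rng.normal(size=72)
        a = contribution_stats(gamma, config)
        b = contribution_stats(-gamma, config)
        assert a["facilitatory"] == pytest.approx(b["inhibitory"])
        assert a["inhibitory"] == pytest.approx(b["facilitatory"])

    def test_matches_naive_loop(self, config):
        rng = np.random.default_rng(3)
        gamma = rng.normal(size=72)
        c = contribution_stats(gamma, config)
        g = gamma / np.abs(gamma).max()
        fac = sum(v for v in g if v > 0)
        inh = sum(-v for v in g if v < 0)
        assert c["facilitatory"] == pytest.approx(fac)
        assert c["inhibitory"] == pytest.approx(inh)

    def test_all_zero_defined(self, config):
        c = contribution_stats(np.zeros(72), config)
        assert all(v == 0 for v in c.values())


class TestMaxPartDistance:
    def test_single_part_is_zero(self, grid, config):
        gamma = np.zeros(72)
        gamma[30] = 1.0
        assert max_part_distance(gamma, grid, config) == 0.0

    def test_diagonal_corners(self, grid, config):
        gamma = np.zeros(72)
        gamma[0], gamma[8] = 1.0, -1.0  # cells j=0 and j=8
        d = max_part_distance(gamma, grid, config)
        assert d == pytest.approx(2 * np.sqrt(2) / 3, rel=1e-9)

    def test_monotone_under_added_parts(self, grid, config):
        rng = np.random.default_rng(4)
        gamma = np.zeros(72)
        prev = 0.0
        for idx in rng.permutation(72)[:20]:
            gamma[idx] = 1.0
            d = max_part_distance(gamma, grid, config)
            assert d >= prev - 1e-12
            prev = d

    def test_map_permutation_invariant(self, grid, config):
        gamma = np.zeros(72)
        gamma[[2, 40]] = 1.0
        moved = np.zeros(72)
        moved[[9 * 3 + 2, 9 * 5 + 4]] = 1.0  # same cells (2, 4), other maps
        assert (max_part_distance(gamma, grid, config)
                == max_part_distance(moved, grid, config))


class TestInvariance:
    def test_identical_curves_slope_zero(self):
        levels = np.arange(5.0)
        resp = np.tile([0.1, 0.4, 1.0, 0.4, 0.1], (3, 1))
        cent = tuning_centroids(resp, levels)
        assert centroid_slope(cent, np.array([1.0, 2.0, 3.0])) == 0.0

    def test_symmetric_curve_centroid_is_center(self):
        levels = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        cent = tuning_centroids(np.array([[0.2, 0.7, 1.0, 0.7, 0.2]]), levels)
        assert cent[0] == pytest.approx(0.0, abs=1e-12)

    def test_one_level_per_step_gives_unit_slope(self):
        levels = np.arange(5.0)
        resp = np.zeros((3, 5))
        for i in range(3):
            resp[i, i + 1] = 1.0  # centroid shifts one level per condition
        cent = tuning_centroids(resp, levels)
        slope = centroid_slope(cent, np.arange(3.0))
        assert slope == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_row_flagged(self):
        from sparseshape.v4_fit import SparseCode

        D_inv = np.zeros((3, 5, 72))
        D_inv[0, :, 0] = [1, 2, 3, 2, 1]
        # rows 1, 2 are zero -> tuning curve all zero there
        codes = {"n0": SparseCode(gamma=np.eye(72)[0], alpha=0.1, rho=0.5)}
        df = invariance_test(codes, D_inv, np.arange(5.0), np.arange(3.0))
        assert bool(df.loc[0, "flagged"])
        assert np.isnan(df.loc[0, "slope"])


class TestEvaluate:
    def test_perfect_prediction(self):
        v = np.array([0.1, 0.5, 0.9, 0.3])
        r, mae = evaluate(v, v)
        assert r == pytest.approx(1.0)
        assert mae == 0.0

    def test_anticorrelated(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = evaluate(-v, v)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=50), rng.normal(size=50)
        r, mae = evaluate(a, b)
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        assert r == pytest.approx(float((za * zb).mean()), abs=1e-12)
        assert mae == pytest.approx(float(np.abs(a - b).mean()), abs=1e-12)

    def test_constant_observations_give_nan_r(self):
        r, mae = evaluate(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))
        assert np.isnan(r)
        assert mae == pytest.approx(3.0)
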