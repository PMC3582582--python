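"""PCA, Gaussian fits and the Hellinger distance against independent oracles."""

import numpy as np
import pytest

from betasignal import seqspace
from betasignal.seqspace import (
    DistanceMatrix,
    SequenceSpace,
    bhattacharyya_coefficient,
    choose_n_components,
    distances_to_weights,
    fit_gaussian,
    fit_pca,
    hellinger,
    hellinger_1d,
    pairwise_distances,
)


def gaussian_space(entity_id, mu, sigma, n=100):
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    return SequenceSpace(entity_id=entity_id, n_peptides=n, mu=mu, sigma=sigma)


# ---------------------------------------------------------------------------
# numerical-integration oracle for the Bhattacharyya coefficient


def bc_numeric_1d(mu1, s1, mu2, s2, n_grid=8001):
    lo = min(mu1 - 9 * s1, mu2 - 9 * s2)
    hi = max(mu1 + 9 * s1, mu2 + 9 * s2)
    x = np.linspace(lo, hi, n_grid)
    p = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    q = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    return np.trapezoid(np.sqrt(p * q), x)


def bc_numeric_2d(mu1, S1, mu2, S2, n_grid=401):
    from scipy.stats import multivariate_normal

    sd = np.sqrt(max(np.max(np.diag(S1)), np.max(np.diag(S2))))
    lo = np.minimum(mu1, mu2) - 8 * sd
    hi = np.maximum(mu1, mu2) + 8 * sd
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    grid = np.dstack([X, Y])
    p = multivariate_normal(mu1, S1).pdf(grid)
    q = multivariate_normal(mu2, S2).pdf(grid)
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    return float(np.sqrt(p * q).sum() * dx * dy)


def random_spd(rng, d):
    A = rng.normal(size=(d, d))
    return A @ A.T + 0.3 * np.eye(d)


class TestPca:
    def test_exact_two_dim_subspace_fully_explained(self, rng):
        basis = rng.normal(size=(2, 50))
        coords = rng.normal(size=(200, 2))
        X = coords @ basis + rng.normal(size=50)  # affine offset
        model = fit_pca(X, k=2)
        assert model.cumulative_explained == pytest.approx(1.0, abs=1e-9)

    def test_explained_variance_non_increasing(self, rng):
        X = rng.normal(size=(120, 50))
        model = fit_pca(X, k=12)
        assert np.all(np.diff(model.explained_variance_fraction) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(500, 50)) @ np.diag(np.linspace(3, 0.3, 50))
        model = fit_pca(X, k=12)
        # independent oracle: eigendecomposition of the sample covariance
        C = np.cov(X, rowvar=False)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1][:12]
        proj_oracle = (X - X.mean(axis=0)) @ V[:, order]
        proj_model = model.project(X)
        for j in range(12):
            # eigenvector signs are arbitrary: compare up to sign per axis
            err_same = np.abs(proj_model[:, j] - proj_oracle[:, j]).max()
            err_flip = np.abs(proj_model[:, j] + proj_oracle[:, j]).max()
            assert min(err_same, err_flip) < 1e-8

    def test_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(80, 50))
        a = fit_pca(X, k=5)
        b = fit_pca(X.copy(), k=5)
        np.testing.assert_allclose(a.components, b.components)
        for row in a.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_projection_of_training_mean_is_zero(self, rng):
        X = rng.normal(size=(60, 50))
        model = fit_pca(X, k=4)
        np.testing.assert_allclose(model.project(X.mean(axis=0)), 0.0, atol=1e-10)

    def test_k_beyond_rank_rejected(self, rng):
        basis = rng.normal(size=(3, 50))
        X = rng.normal(size=(40, 3)) @ basis
        with pytest.raises(ValueError, match="rank"):
            fit_pca(X, k=5)

    def test_choose_n_components_targets_variance(self, rng):
        X = rng.normal(size=(300, 50)) @ np.diag(np.linspace(4, 0.1, 50))
        k = choose_n_components(X, evr_target=0.69, max_k=20)
        model = fit_pca(X, k=k)
        assert model.cumulative_explained >= 0.69
        if k > 1:
            assert fit_pca(X, k=k - 1).cumulative_explained < 0.69


class TestFitGaussian:
    def test_identical_rows_without_ridge_is_singular(self):
        rows = np.ones((5, 3))
        with pytest.raises(ValueError, match="singular"):
            fit_gaussian("e", rows, regularization=0.0)

    def test_two_point_hand_case_uses_unbiased_divisor(self):
        rows = np.array([[0.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="singular"):
            fit_gaussian("e", rows, regularization=0.0)
        space = fit_gaussian("e", rows, regularization=1e-6)
        np.testing.assert_allclose(space.mu, [1.0, 0.0])
        assert space.sigma[0, 0] == pytest.approx(2.0, rel=1e-5)  # (n-1) divisor

    def test_mean_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(7)
        d, n = 12, 66
        mu = rng.normal(size=d)
        sd = 1.5
        rows = rng.normal(loc=mu, scale=sd, size=(n, d))
        space = fit_gaussian("ecoli", rows)
        se = sd / np.sqrt(n)
        assert np.all(np.abs(space.mu - mu) < 3 * se + 3 * se)  # 3 SE + slack per coord

    def test_shrinkage_blends_toward_target(self, rng):
        rows = rng.normal(size=(30, 4))
        target = np.eye(4)
        full = fit_gaussian("e", rows, shrinkage=1.0, shrinkage_target=target)
        np.testing.assert_allclose(full.sigma, target, atol=1e-5)
        with pytest.raises(ValueError, match="shrinkage_target"):
            fit_gaussian("e", rows, shrinkage=0.5)


class TestHellinger:
    def test_identical_distributions_give_zero(self):
        a = gaussian_space("a", [0.0], [[1.0]])
        assert hellinger(a, a) == 0.0
        b = gaussian_space("b", np.zeros(12), np.eye(12))
        assert hellinger(b, b) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "mu1,s1,mu2,s2,expected",
        [
            (0.0, 1.0, 0.0, 1.0, 0.0),
            # closed form: BC = sqrt(2*1*5/26), D = sqrt(1-sqrt(10/26))
            (0.0, 1.0, 0.0, 5.0, np.sqrt(1 - np.sqrt(10 / 26))),
            # closed form: BC = exp(-25/8)
            (0.0, 1.0, 5.0, 1.0, np.sqrt(1 - np.exp(-25 / 8))),
        ],
    )
    def test_one_dimensional_closed_forms(self, mu1, s1, mu2, s2, expected):
        assert hellinger_1d(mu1, s1, mu2, s2) == pytest.approx(expected, abs=1e-12)

    def test_scalar_and_matrix_paths_agree(self, rng):
        for _ in range(20):
            mu1, mu2 = rng.normal(scale=3, size=2)
            s1, s2 = rng.uniform(0.3, 3, size=2)
            a = gaussian_space("a", [mu1], [[s1**2]])
            b = gaussian_space("b", [mu2], [[s2**2]])
            assert hellinger(a, b) == pytest.approx(hellinger_1d(mu1, s1, mu2, s2), abs=1e-12)

    def test_matches_numerical_integration_d1(self, rng):
        for _ in range(25):
            mu1, mu2 = rng.uniform(-3, 3, size=2)
            s1, s2 = rng.uniform(0.5, 2.0, size=2)
            bc = bc_numeric_1d(mu1, s1, mu2, s2)
            a = gaussian_space("a", [mu1], [[s1**2]])
            b = gaussian_space("b", [mu2], [[s2**2]])
            assert bhattacharyya_coefficient(a, b) == pytest.approx(bc, abs=1e-4)

    def test_matches_numerical_integration_d2(self, rng):
        for _ in range(25):
            mu1 = rng.uniform(-2, 2, size=2)
            mu2 = rng.uniform(-2, 2, size=2)
            S1 = random_spd(rng, 2)
            S2 = random_spd(rng, 2)
            bc = bc_numeric_2d(mu1, S1, mu2, S2)
            a = gaussian_space("a", mu1, S1)
            b = gaussian_space("b", mu2, S2)
            assert bhattacharyya_coefficient(a, b) == pytest.approx(bc, abs=1e-4)

    def test_distance_saturates_for_distant_means(self):
        a = gaussian_space("a", np.zeros(3), np.eye(3))
        prev = 0.0
        for shift in (1.0, 5.0, 20.0, 100.0):
            b = gaussian_space("b", np.full(3, shift), np.eye(3))
            d = hellinger(a, b)
            assert d >= prev
            prev = d
        assert prev == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        # transforming both peptide clouds by one affine map leaves D_H fixed
        X = rng.normal(size=(200, 5)) + 1.0
        Y = rng.normal(size=(150, 5)) * 1.3
        A = rng.normal(size=(5, 5)) + np.eye(5) * 2
        b = rng.normal(size=5)
        d_orig = hellinger(fit_gaussian("x", X, 0), fit_gaussian("y", Y, 0))
        d_mapped = hellinger(fit_gaussian("x", X @ A.T + b, 0),
                             fit_gaussian("y", Y @ A.T + b, 0))
        assert d_mapped == pytest.approx(d_orig, abs=1e-8)

    def test_dimension_mismatch_rejected(self):
        a = gaussian_space("a", [0.0], [[1.0]])
        b = gaussian_space("b", np.zeros(2), np.eye(2))
        with pytest.raises(ValueError, match="dimension"):
            hellinger(a, b)

    def test_debias_reduces_distance_and_floors_at_zero(self):
        a = gaussian_space("a", np.zeros(4), np.eye(4), n=10)
        b = gaussian_space("b", np.full(4, 0.1), np.eye(4), n=10)
        assert hellinger(a, b, debias=True) < hellinger(a, b)
        assert hellinger(a, b, debias=True) == 0.0  # correction exceeds mahal


class TestPairwiseDistances:
    def test_symmetric_zero_diagonal_and_duplicates(self, rng):
        a = gaussian_space("a", np.zeros(2), np.eye(2))
        b = gaussian_space("b", np.ones(2), 2 * np.eye(2))
        dm = pairwise_distances([a, b, a])
        np.testing.assert_allclose(dm.values, dm.values.T)
        np.testing.assert_allclose(np.diag(dm.values), 0.0)
        assert dm.values[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert np.all((dm.values >= 0) & (dm.values <= 1))

    def test_well_separated_entities_near_one(self, rng):
        # means 50 sigma apart -> all off-diagonal distances > 0.9
        spaces = [
            fit_gaussian(f"org{i}", rng.normal(loc=50.0 * i, scale=1.0, size=(40, 3)))
            for i in range(3)
        ]
        dm = pairwise_distances(spaces)
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.all(off > 0.9)

    def test_tsv_round_trip(self, tmp_path):
        a = gaussian_space("a", np.zeros(2), np.eye(2))
        b = gaussian_space("b", np.ones(2), np.eye(2))
        dm = pairwise_distances([a, b])
        path = tmp_path / "dh.tsv"
        dm.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.entity_ids == dm.entity_ids
        np.testing.assert_allclose(back.values, dm.values, atol=1e-12)


class TestWeights:
    def test_endpoint_and_bc_identity(self):
        ids = ("a", "b", "c")
        d = np.sqrt(1 - np.sqrt(10 / 26))
        values = np.array([[0.0, 1.0, d], [1.0, 0.0, 0.0], [d, 0.0, 0.0]])
        dm = DistanceMatrix(entity_ids=ids, values=values)
        w = distances_to_weights(dm)
        assert w.loc["b", "a"] == pytest.approx(0.0)
        assert w.loc["c", "a"] == pytest.approx(np.sqrt(10 / 26), abs=1e-12)
        assert w.loc["a", "a"] == 0.0

    def test_contrast_rescale_preserves_order(self, rng):
        vals = np.array([[0, 0.3, 0.5], [0.3, 0, 0.8], [0.5, 0.8, 0]])
        dm = DistanceMatrix(entity_ids=("a", "b", "c"), values=vals)
        raw = distances_to_weights(dm)
        scaled = distances_to_weights(dm, contrast=True)
        mask = ~np.eye(3, dtype=bool)
        order_raw = np.argsort(raw.to_numpy()[mask])
        order_scaled = np.argsort(scaled.to_numpy()[mask])
        np.testing.assert_array_equal(order_raw, order_scaled)
        assert scaled.to_numpy()[mask].min() == pytest.approx(0.0)
        assert scaled.to_numpy()[mask].max() == pytest.approx(1.0)
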