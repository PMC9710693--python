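import numpy as np
import pytest

from cscd.covtransform import (
    lw_shrink,
    moments,
    multivariate_transform,
    sym_inv_root,
    sym_root,
    univariate_transform,
)
from cscd.io_core import BulkDataset, ExpressionMatrix
from cscd.reference import PseudoBulk


def lw_intensity_oracle(values: np.ndarray) -> float:
    """Hand-coded Ledoit-Wolf (2004) plug-in intensity, population moments."""
    G, n = values.shape
    Xc = values - values.mean(1, keepdims=True)
    S = Xc @ Xc.T / n
    mu = np.trace(S) / G
    d2 = ((S - mu * np.eye(G)) ** 2).sum()
    b2 = sum(((np.outer(x, x) - S) ** 2).sum() for x in Xc.T) / n**2
    b2 = min(b2, d2)
    return b2 / d2 if d2 > 0 else 0.0


def bulk_of(values) -> BulkDataset:
    values = np.asarray(values, dtype=float)
    return BulkDataset(
        ExpressionMatrix(
            values,
            tuple(f"g{i}" for i in range(values.shape[0])),
            tuple(f"s{i}" for i in range(values.shape[1])),
        )
    )


def pb_of(values) -> PseudoBulk:
    values = np.asarray(values, dtype=float)
    return PseudoBulk(
        values,
        tuple(f"g{i}" for i in range(values.shape[0])),
        tuple(f"j{i}" for i in range(values.shape[1])),
    )


class TestMoments:
    def test_divisor_is_n(self):
        m = moments(np.array([[0.0, 2.0]]))
        assert m.mean[0] == pytest.approx(1.0)
        assert m.cov[0, 0] == pytest.approx(1.0)  # ((0-1)^2 + (2-1)^2)/2

    def test_identical_columns_zero_cov(self):
        m = moments(np.tile([[3.0], [1.0]], (1, 5)))
        np.testing.assert_allclose(m.cov, 0.0)

    def test_column_permutation_invariance(self, rng):
        X = rng.normal(size=(4, 9))
        np.testing.assert_allclose(
            moments(X).cov, moments(X[:, rng.permutation(9)]).cov
        )

    def test_needs_two_columns(self):
        with pytest.raises(ValueError, match="at least 2"):
            moments(np.ones((3, 1)))


class TestLwShrink:
    def test_target_coincides_with_sample_cov(self):
        # columns chosen so the sample covariance is exactly 0.5 * I
        X = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        s = moments(X)
        out = lw_shrink(X, s)
        np.testing.assert_allclose(out.matrix, s.cov, atol=1e-12)

    def test_singular_sample_cov_becomes_positive_definite(self, rng):
        X = rng.normal(size=(50, 10))
        out = lw_shrink(X)
        assert 0 < out.intensity <= 1
        assert np.linalg.eigvalsh(out.matrix).min() > 0

    def test_monte_carlo_consistency(self):
        rng = np.random.default_rng(2024)
        true = np.array([[1.0, 0.3], [0.3, 0.5]])
        X = rng.multivariate_normal([0, 0], true, size=100_000).T
        out = lw_shrink(X)
        assert np.linalg.norm(out.matrix - true) < 0.05
        assert out.intensity < 0.05

    @pytest.mark.parametrize("shape", [(5, 20), (50, 10), (2, 500), (1, 10)])
    def test_intensity_matches_plugin_formula(self, rng, shape):
        X = rng.lognormal(0.5, 0.8, shape)
        out = lw_shrink(X)
        assert out.intensity == pytest.approx(lw_intensity_oracle(X), abs=1e-10)

    def test_structure_identity(self, rng):
        X = rng.normal(size=(6, 12))
        s = moments(X)
        out = lw_shrink(X, s)
        expected = (1 - out.intensity) * s.cov + out.intensity * out.target_scale * np.eye(6)
        np.testing.assert_allclose(out.matrix, expected, atol=1e-10)

    def test_all_zero_covariance_errors(self):
        with pytest.raises(ValueError, match="all-zero covariance"):
            lw_shrink(np.ones((3, 5)))

    def test_shrinkage_never_worsens_conditioning(self, rng):
        X = rng.lognormal(0, 1, (4, 100))
        s = moments(X)
        out = lw_shrink(X, s)
        assert np.linalg.cond(out.matrix) <= np.linalg.cond(s.cov) * (1 + 1e-10)


class TestSymRoots:
    def test_diagonal_case(self):
        c = np.diag([4.0, 9.0])
        np.testing.assert_allclose(sym_root(c), np.diag([2.0, 3.0]), atol=1e-12)
        np.testing.assert_allclose(sym_inv_root(c), np.diag([0.5, 1 / 3]), atol=1e-12)

    def test_defining_identities(self, rng):
        A = rng.normal(size=(5, 5))
        c = A @ A.T + 5 * np.eye(5)  # well-conditioned SPD
        R = sym_root(c)
        np.testing.assert_allclose(R @ R, c, atol=1e-8)
        Ri = sym_inv_root(c)
        np.testing.assert_allclose(Ri @ c @ Ri, np.eye(5), atol=1e-8)
        np.testing.assert_allclose(Ri @ R, np.eye(5), atol=1e-8)

    def test_non_symmetric_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            sym_root(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_eigenvalue_floor_handles_singularity(self):
        c = np.diag([1.0, 0.0])
        out = sym_inv_root(c, floor=1e-4)
        assert np.all(np.isfinite(out))


class TestUnivariateTransform:
    def test_hand_evaluated_value(self):
        # Ybar=10, s_Y=4 (J=3); Xbar=5, s_X=1 (I=2); X=6 -> 10 + sqrt(3/4)*2*1
        a = np.sqrt(6.0)
        Y = pb_of([[10 - a, 10.0, 10 + a]])
        X = bulk_of([[4.0, 6.0]])
        out = univariate_transform(X, Y)
        assert out.Xm[0, 1] == pytest.approx(11.7320508, abs=1e-6)

    def test_centered_point_maps_to_target_mean(self):
        Y = pb_of([[1.0, 3.0]])
        X = bulk_of([[2.0, 4.0, 3.0]])  # mean 3: middle deviation for s3 is 0
        out = univariate_transform(X, Y)
        assert out.Xm[0, 2] == pytest.approx(2.0)  # Ybar = 2

    def test_transformed_variance_identity(self, rng):
        G, J, I = 4, 6, 30
        Y = pb_of(rng.lognormal(1, 0.4, (G, J)))
        X = bulk_of(rng.lognormal(1, 0.6, (G, I)))
        out = univariate_transform(X, Y)
        sy = np.diag(moments(Y).cov)
        var_t = out.Xm.var(axis=1)  # divisor I, matching the moment convention
        np.testing.assert_allclose(var_t, J / (J + 1) * sy, rtol=1e-10)

    def test_zero_bulk_variance_names_gene(self):
        Y = pb_of([[1.0, 2.0], [1.0, 3.0]])
        X = bulk_of([[1.0, 2.0], [5.0, 5.0]])
        with pytest.raises(ValueError, match="g1"):
            univariate_transform(X, Y)


class TestMultivariateTransform:
    def test_constant_bulk_maps_to_pseudo_bulk_mean(self, rng):
        Y = pb_of(rng.lognormal(1, 0.5, (3, 4)))
        X = bulk_of(np.tile([[2.0], [3.0], [4.0]], (1, 5)))
        out = multivariate_transform(X, Y)
        ybar = Y.Y.mean(axis=1)
        for i in range(5):
            np.testing.assert_allclose(out.Xm[:, i], ybar, atol=1e-12)

    def test_whitening_recoloring_identity_intensity_zero(self, rng):
        G, J, I = 3, 50, 200
        Y = pb_of(rng.lognormal(1, 0.3, (G, J)))
        X = bulk_of(rng.lognormal(1, 0.5, (G, I)))
        out = multivariate_transform(X, Y, force_intensity=0.0)
        sy = moments(Y).cov
        cov_t = moments(out.Xm).cov
        np.testing.assert_allclose(cov_t, J / (J + 1) * sy, rtol=1e-6, atol=1e-6)

    def test_single_gene_agrees_with_univariate(self, rng):
        # in one dimension the shrinkage target equals the variance itself,
        # so the multivariate map reduces exactly to the univariate one
        Y = pb_of(rng.lognormal(1, 0.4, (1, 5)))
        X = bulk_of(rng.lognormal(1, 0.6, (1, 7)))
        mv = multivariate_transform(X, Y)
        uv = univariate_transform(X, Y)
        np.testing.assert_allclose(mv.Xm, uv.Xm, rtol=1e-9)

    def test_roots_cancel_when_cov_and_mean_match(self, rng):
        vals = rng.lognormal(1, 0.5, (4, 6))
        Y = pb_of(vals)
        X = bulk_of(vals)
        J = 6
        out = multivariate_transform(X, Y)
        expected = vals.mean(1, keepdims=True) + np.sqrt(J / (J + 1)) * (
            vals - vals.mean(1, keepdims=True)
        )
        np.testing.assert_allclose(out.Xm, expected, rtol=1e-7, atol=1e-7)

    def test_output_mean_is_pseudo_bulk_mean(self, rng):
        Y = pb_of(rng.lognormal(1, 0.4, (3, 5)))
        X = bulk_of(rng.lognormal(1, 0.6, (3, 9)))
        out = multivariate_transform(X, Y)
        np.testing.assert_allclose(out.Xm.mean(axis=1), Y.Y.mean(axis=1), rtol=1e-9)

    def test_gene_mismatch_errors(self, rng):
        Y = PseudoBulk(rng.lognormal(1, 0.4, (2, 4)), ("gA", "gB"), ("j0", "j1", "j2", "j3"))
        X = bulk_of(rng.lognormal(1, 0.4, (2, 4)))
        with pytest.raises(ValueError, match="same genes"):
            multivariate_transform(X, Y)
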