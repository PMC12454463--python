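import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import least_squares

from pancdwi import (
    DiffusionTensorModel,
    DwiDataset,
    GradientScheme,
    build_design_matrix,
    compute_dti_maps,
    eigendecompose,
)
from pancdwi.core import TensorField, ValidationError
from pancdwi.dti import fractional_anisotropy

from conftest import scheme_two_shell, tensor_signals


def _field_from_matrix(M):
    D = np.array([M[0, 0], M[1, 1], M[2, 2], M[0, 1], M[0, 2], M[1, 2]])
    return TensorField(log_s0=np.zeros((1,)), D=D[None, :])


class TestDesignMatrix:
    def test_axis_direction_row(self):
        s = GradientScheme(np.array([1000.0] * 7 + [200.0] * 7),
                           np.tile(scheme_two_shell(7).bvecs[:7], (2, 1)),
                           np.ones(14, int))
        X = build_design_matrix(s)
        # substitute a pure-axis row analytically
        sx = GradientScheme(np.array([1000.0]), np.array([[1.0, 0, 0]]), [1])
        row = np.column_stack([np.ones(1), -1000 * np.ones(1), [0], [0], [0], [0], [0]])
        # single rows cannot pass the rank check; verify via the formula on
        # the first matrix built above instead
        b, g = s.bvals[0], s.bvecs[0]
        expected = [1, -b * g[0] ** 2, -b * g[1] ** 2, -b * g[2] ** 2,
                    -2 * b * g[0] * g[1], -2 * b * g[0] * g[2], -2 * b * g[1] * g[2]]
        assert np.allclose(X[0], expected)
        assert np.allclose(row[0][:2], [1, -1000])

    def test_six_directions_two_shells_full_rank(self):
        X = build_design_matrix(scheme_two_shell(6))
        assert X.shape == (12, 7)
        assert np.linalg.matrix_rank(X) == 7

    def test_underdetermined_rejected(self):
        dirs = np.eye(3)
        s = GradientScheme(np.full(3, 1000.0), dirs, np.ones(3, int))
        with pytest.raises(ValidationError, match="insufficient directions"):
            build_design_matrix(s)

    def test_b0_volume_rejected(self):
        s = GradientScheme(np.array([0.0] + [1000.0] * 6),
                           np.vstack([[0, 0, 0], scheme_two_shell(6).bvecs[:6]]),
                           np.ones(7, int))
        with pytest.raises(ValidationError):
            build_design_matrix(s)


class TestEigendecompose:
    def test_diagonal(self):
        f = eigendecompose(_field_from_matrix(np.diag([3e-3, 2e-3, 1e-3])))
        assert np.allclose(f.eigvals[0], [3e-3, 2e-3, 1e-3])

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        D = np.diag([1.5e-3, 0.5e-3, 0.5e-3])
        f1 = eigendecompose(_field_from_matrix(D))
        f2 = eigendecompose(_field_from_matrix(Q @ D @ Q.T))
        assert np.allclose(f1.eigvals, f2.eigvals, rtol=1e-10)

    def test_matches_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            A = rng.normal(size=(3, 3))
            M = (A + A.T) / 2
            f = eigendecompose(_field_from_matrix(M))
            # independent oracle: roots of det(M - x I)
            c2 = -np.trace(M)
            c1 = 0.5 * (np.trace(M) ** 2 - np.trace(M @ M))
            c0 = -np.linalg.det(M)
            roots = np.sort(np.roots([1.0, c2, c1, c0]).real)[::-1]
            assert np.allclose(f.eigvals[0], roots, atol=1e-10)

    def test_orthonormal_and_reconstructs(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3))
        M = (A + A.T) / 2
        f = eigendecompose(_field_from_matrix(M))
        V = f.eigvecs[0]
        assert np.allclose(V.T @ V, np.eye(3), atol=1e-6)
        assert np.allclose(V @ np.diag(f.eigvals[0]) @ V.T, M, atol=1e-9)

    def test_nonfinite_gives_nan(self):
        f = eigendecompose(_field_from_matrix(np.full((3, 3), np.nan)))
        assert np.all(np.isnan(f.eigvals))


class TestScalarMaps:
    def test_isotropic(self):
        fa = fractional_anisotropy(np.array([1e-3, 1e-3, 1e-3]))
        assert fa == pytest.approx(0.0, abs=1e-12)

    def test_stick_limit(self):
        assert fractional_anisotropy(np.array([1.0, 0.0, 0.0])) == pytest.approx(1.0)

    def test_reported_pancreas_eigenvalues(self):
        # median AD/RD for the short protocol give FA ~ 0.2374
        lam = np.array([1.343e-3, 0.903e-3, 0.903e-3])
        md = lam.mean()
        oracle = np.sqrt(1.5 * np.sum((lam - md) ** 2) / np.sum(lam**2))
        assert fractional_anisotropy(lam) == pytest.approx(oracle, rel=1e-12)
        assert fractional_anisotropy(lam) == pytest.approx(0.2374, abs=5e-4)

    def test_all_zero_eigenvalues_give_nan_fa(self):
        assert np.isnan(fractional_anisotropy(np.zeros(3)))

    @given(st.lists(st.floats(1e-4, 3e-3), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50)
    def test_md_identity(self, lam):
        f = eigendecompose(_field_from_matrix(np.diag(sorted(lam, reverse=True))))
        maps = compute_dti_maps(f)
        assert maps.md[0] == pytest.approx((maps.ad[0] + 2 * maps.rd[0]) / 3,
                                           rel=1e-12)

    @given(st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=30)
    def test_fa_scale_invariance(self, c):
        lam = np.array([1.3e-3, 0.9e-3, 0.6e-3])
        assert fractional_anisotropy(c * lam) == pytest.approx(
            fractional_anisotropy(lam), rel=1e-9
        )


class TestWlsFit:
    def test_noiseless_recovery_exact(self):
        D = np.diag([1.3e-3, 0.85e-3, 0.85e-3])
        ds = tensor_signals(scheme_two_shell(6), D)
        res = DiffusionTensorModel(ds).fit()
        Dxx = res.tensor_field.D[0, 0, 0]
        assert np.allclose(Dxx, [1.3e-3, 0.85e-3, 0.85e-3, 0, 0, 0], atol=1e-12)
        assert res.tensor_field.eigvals[0, 0, 0, 0] == pytest.approx(1.3e-3, rel=1e-9)
        assert res.tensor_field.log_s0[0, 0, 0] == pytest.approx(np.log(1000.0))

    def test_isotropic_decay(self):
        ds = tensor_signals(scheme_two_shell(6), np.eye(3) * 1e-3)
        res = DiffusionTensorModel(ds).fit()
        assert np.allclose(res.tensor_field.eigvals[0, 0, 0], 1e-3, rtol=1e-9)

    def test_zero_passes_equals_ols(self):
        rng = np.random.default_rng(8)
        scheme = scheme_two_shell(6)
        D = np.diag([1.2e-3, 0.9e-3, 0.7e-3])
        ds = tensor_signals(scheme, D, shape=(1, 1, 1))
        noisy = ds.signal * np.exp(rng.normal(scale=0.02, size=ds.signal.shape))
        ds_noisy = DwiDataset(signal=noisy, scheme=scheme)
        model = DiffusionTensorModel(ds_noisy, n_reweight=0)
        res = model.fit()
        beta_ols = np.linalg.lstsq(model.design, np.log(noisy[0, 0, 0]),
                                   rcond=None)[0]
        got = np.concatenate([[res.tensor_field.log_s0[0, 0, 0]],
                              res.tensor_field.D[0, 0, 0]])
        assert np.allclose(got, beta_ols, rtol=1e-9)

    def test_all_zero_voxel_is_nan_not_failure(self):
        scheme = scheme_two_shell(6)
        sig = np.zeros((1, 2, 1, 12))
        sig[0, 1, 0] = tensor_signals(scheme, np.eye(3) * 1e-3).signal[0, 0, 0]
        res = DiffusionTensorModel(DwiDataset(signal=sig, scheme=scheme)).fit()
        assert np.all(np.isnan(res.tensor_field.D[0, 0, 0]))
        assert np.all(np.isfinite(res.tensor_field.D[0, 1, 0]))

    def test_matches_nonlinear_least_squares_oracle(self):
        rng = np.random.default_rng(9)
        scheme = scheme_two_shell(6)
        X = build_design_matrix(scheme)
        for _ in range(100):
            A = rng.normal(scale=0.6e-3, size=(3, 3))
            D = A @ A.T + 0.3e-3 * np.eye(3)  # positive definite
            ds = tensor_signals(scheme, D, s0=500.0, shape=(1, 1, 1))
            res = DiffusionTensorModel(ds).fit()
            y = ds.signal[0, 0, 0]

            def resid(beta):
                return np.exp(X @ beta) - y

            beta0 = np.zeros(7)
            beta0[0] = np.log(y.max())
            oracle = least_squares(resid, beta0, method="lm", xtol=1e-15,
                                   ftol=1e-15).x
            got = np.concatenate([[res.tensor_field.log_s0[0, 0, 0]],
                                  res.tensor_field.D[0, 0, 0]])
            assert np.allclose(got, oracle, rtol=1e-6, atol=1e-10)

    def test_perfusion_suppressed_range_removes_ivim_bias(self):
        # IVIM component f=0.1, D*=20e-3: fitting b>=200 keeps MD within 2%,
        # a naive log-linear fit including b=0 shifts MD by > 5%
        scheme = scheme_two_shell(6)
        f, dstar = 0.1, 20e-3
        D = np.eye(3) * 1e-3
        dapp = np.einsum("ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs)
        s = 1000 * ((1 - f) * np.exp(-scheme.bvals * dapp)
                    + f * np.exp(-scheme.bvals * dstar))
        ds = DwiDataset(signal=np.broadcast_to(s, (1, 1, 1, len(s))).copy(),
                        scheme=scheme)
        res = DiffusionTensorModel(ds).fit()
        md = res.md[0, 0, 0]
        assert abs(md - 1e-3) / 1e-3 < 0.02

        # naive signal^2-weighted fit with a b=0 row, written out directly
        bv = np.concatenate([[0.0], scheme.bvals])
        sig0 = np.concatenate([[1000.0], s])
        gx = np.vstack([[0, 0, 0], scheme.bvecs])
        Xn = np.column_stack([
            np.ones_like(bv), -bv * gx[:, 0] ** 2, -bv * gx[:, 1] ** 2,
            -bv * gx[:, 2] ** 2, -2 * bv * gx[:, 0] * gx[:, 1],
            -2 * bv * gx[:, 0] * gx[:, 2], -2 * bv * gx[:, 1] * gx[:, 2],
        ])
        w = sig0**2
        for _ in range(3):
            A = Xn.T @ (w[:, None] * Xn)
            beta = np.linalg.solve(A, Xn.T @ (w * np.log(sig0)))
            w = np.exp(2 * Xn @ beta)
        md_naive = beta[1:4].mean()
        assert abs(md_naive - 1e-3) / 1e-3 > 0.05
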