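import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pancdwi import (
    DiffusionTensorModel,
    DwiDataset,
    GradientScheme,
    MeanSignalDKIModel,
    compute_adc,
    directional_average,
    fit_msdki_signals,
)
from pancdwi.core import ValidationError
from pancdwi.phantom import make_direction_set

from conftest import scheme_two_shell

SHELLS = np.array([200.0, 1000.0, 1700.0])


def _ms(s0, md, mk, b=SHELLS):
    return s0 * np.exp(-b * md + (b * md) ** 2 * mk / 6.0)


def _three_shell_scheme(n_dirs=6, averages=(2, 4, 5)):
    dirs = make_direction_set(n_dirs)
    bvals = np.repeat(SHELLS, n_dirs)
    bvecs = np.tile(dirs, (3, 1))
    avg = np.repeat(averages, n_dirs)
    return GradientScheme(bvals, bvecs, avg)


class TestDirectionalAverage:
    def test_identical_volumes(self):
        s = GradientScheme(np.full(6, 1000.0), make_direction_set(6), np.ones(6, int))
        ds = DwiDataset(signal=np.full((2, 2, 1, 6), 100.0), scheme=s)
        b, ms, counts = directional_average(ds)
        assert np.allclose(ms, 100.0)
        assert counts[0] == 6

    def test_mean_of_two(self):
        s = GradientScheme(np.full(2, 1000.0),
                           make_direction_set(6)[:2], np.ones(2, int))
        sig = np.zeros((1, 1, 1, 2))
        sig[..., 0], sig[..., 1] = 90.0, 110.0
        _, ms, _ = directional_average(DwiDataset(signal=sig, scheme=s))
        assert ms[0, 0, 0, 0] == pytest.approx(100.0)

    def test_matches_dense_spherical_quadrature(self):
        # 16 evenly spread directions approximate the orientation average
        # of an anisotropic tensor signal to within 1%
        D = np.diag([1.5e-3, 0.5e-3, 0.5e-3])
        b = 1000.0
        dirs = make_direction_set(16)
        ms16 = np.mean(np.exp(-b * np.einsum("ni,ij,nj->n", dirs, D, dirs)))
        # dense quadrature oracle: 10^4 quasi-uniform sphere points
        k = np.arange(10_000)
        z = 1 - 2 * (k + 0.5) / 10_000
        phi = np.pi * (1 + np.sqrt(5)) * k
        g = np.column_stack([np.sqrt(1 - z**2) * np.cos(phi),
                             np.sqrt(1 - z**2) * np.sin(phi), z])
        dense = np.mean(np.exp(-b * np.einsum("ni,ij,nj->n", g, D, g)))
        assert abs(ms16 - dense) / dense < 0.01


class TestMsdkiFit:
    def test_exact_recovery_from_closed_form(self):
        ms = _ms(1000.0, 1.0e-3, 0.66)
        assert np.allclose(ms, [822.3, 410.7, 251.1], atol=0.05)
        md, mk, s0 = fit_msdki_signals(SHELLS, ms[None, :], np.array([2, 4, 5]))
        assert md[0] == pytest.approx(1.0e-3, rel=1e-12)
        assert mk[0] == pytest.approx(0.66, rel=1e-12)
        assert s0[0] == pytest.approx(1000.0, rel=1e-12)

    def test_monoexponential_gives_zero_kurtosis(self):
        ms = 500.0 * np.exp(-SHELLS * 1e-3)
        md, mk, _ = fit_msdki_signals(SHELLS, ms[None, :])
        assert md[0] == pytest.approx(1e-3, rel=1e-12)
        assert abs(mk[0]) < 1e-9

    def test_increasing_signal_flags_nan_mk(self):
        ms = np.array([100.0, 150.0, 300.0])
        md, mk, _ = fit_msdki_signals(SHELLS, ms[None, :])
        assert md[0] < 0
        assert np.isnan(mk[0])

    def test_nonpositive_signal_gives_nan_voxel(self):
        ms = np.array([100.0, 0.0, 10.0])
        md, mk, s0 = fit_msdki_signals(SHELLS, ms[None, :])
        assert np.isnan(md[0]) and np.isnan(mk[0]) and np.isnan(s0[0])

    def test_fewer_than_three_shells_rejected(self):
        with pytest.raises(ValidationError):
            fit_msdki_signals(SHELLS[:2], np.ones((1, 2)))

    @given(st.floats(0.1, 50.0))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, c):
        ms = _ms(800.0, 1.2e-3, 0.8)
        md1, mk1, s01 = fit_msdki_signals(SHELLS, ms[None, :])
        md2, mk2, s02 = fit_msdki_signals(SHELLS, c * ms[None, :])
        assert md2[0] == pytest.approx(md1[0], rel=1e-9)
        assert mk2[0] == pytest.approx(mk1[0], rel=1e-9)
        assert s02[0] == pytest.approx(c * s01[0], rel=1e-9)

    def test_four_shell_weighted_fit_recovers_noiseless_truth(self):
        b4 = np.array([200.0, 700.0, 1200.0, 1700.0])
        ms = _ms(1000.0, 1.0e-3, 0.5, b=b4)
        md, mk, _ = fit_msdki_signals(b4, ms[None, :], np.array([2, 3, 4, 5]))
        assert md[0] == pytest.approx(1e-3, rel=1e-9)
        assert mk[0] == pytest.approx(0.5, rel=1e-9)

    def test_mk_error_scales_inversely_with_snr(self):
        # sd(MK) * SNR should be constant within 10% across SNR 20/30/50
        rng = np.random.default_rng(11)
        ms_true = _ms(1.0, 1.0e-3, 0.66)
        products = []
        for snr in (20.0, 30.0, 50.0):
            sigma = 1.0 / snr
            ms = np.empty((8000, 3))
            for k, navg in enumerate((2, 4, 5)):
                n = navg * 6  # directions x averages, as acquired
                re = ms_true[k] + rng.normal(scale=sigma, size=(8000, n))
                im = rng.normal(scale=sigma, size=(8000, n))
                ms[:, k] = np.hypot(re, im).mean(axis=1)
            _, mk, _ = fit_msdki_signals(SHELLS, ms, np.array([2, 4, 5]))
            products.append(np.std(mk[np.isfinite(mk)]) * snr)
        assert max(products) / min(products) < 1.10


class TestAdc:
    def test_two_point_formula(self):
        s = scheme_two_shell(6)
        sig = np.empty((1, 1, 1, 12))
        sig[..., :6] = 800.0
        sig[..., 6:] = 310.0
        adc = compute_adc(DwiDataset(signal=sig, scheme=s))
        assert adc[0, 0, 0] == pytest.approx(np.log(800 / 310) / 800, rel=1e-12)
        assert adc[0, 0, 0] == pytest.approx(1.185e-3, abs=1e-6)

    def test_equal_signals_give_zero(self):
        s = scheme_two_shell(6)
        adc = compute_adc(DwiDataset(signal=np.full((1, 1, 1, 12), 5.0), scheme=s))
        assert adc[0, 0, 0] == 0.0

    def test_monoexponential_self_consistency(self):
        s = scheme_two_shell(6)
        sig = 1000.0 * np.exp(-s.bvals * 1.2e-3)
        ds = DwiDataset(signal=np.broadcast_to(sig, (1, 1, 1, 12)).copy(), scheme=s)
        assert compute_adc(ds)[0, 0, 0] == pytest.approx(1.2e-3, rel=1e-12)

    def test_nonpositive_signal_gives_nan(self):
        s = scheme_two_shell(6)
        sig = np.full((1, 1, 1, 12), 5.0)
        sig[0, 0, 0, 0] = 0.0
        assert np.isnan(compute_adc(DwiDataset(signal=sig, scheme=s))[0, 0, 0])

    def test_missing_direction_rejected(self):
        s = scheme_two_shell(6)
        ds = DwiDataset(signal=np.full((1, 1, 1, 12), 5.0), scheme=s)
        with pytest.raises(ValidationError):
            compute_adc(ds, direction_index=6)


class TestModelConsistency:
    def test_isotropic_noiseless_md_agreement(self):
        # isotropic, kurtosis-free: DTI-MD, msdki-MD and ADC all equal D
        dirs = make_direction_set(6)
        bvals = np.concatenate([np.repeat(SHELLS, 6)])
        bvecs = np.tile(dirs, (3, 1))
        scheme = GradientScheme(bvals, bvecs, np.repeat([2, 4, 5], 6))
        sig = 1000.0 * np.exp(-bvals * 1.0e-3)
        ds = DwiDataset(signal=np.broadcast_to(sig, (2, 2, 1, len(bvals))).copy(),
                        scheme=scheme)
        dti = DiffusionTensorModel(ds).fit()
        dki = MeanSignalDKIModel(ds).fit()
        assert dti.md[0, 0, 0] == pytest.approx(1e-3, rel=1e-9)
        assert dki.md[0, 0, 0] == pytest.approx(1e-3, rel=1e-9)
        assert dki.adc[0, 0, 0] == pytest.approx(1e-3, rel=1e-9)
        assert abs(dki.mk[0, 0, 0]) < 1e-9

    def test_three_shell_requirement(self):
        ds_two = DwiDataset(signal=np.full((1, 1, 1, 12), 5.0),
                            scheme=scheme_two_shell(6))
        with pytest.raises(ValidationError):
            MeanSignalDKIModel(ds_two)
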