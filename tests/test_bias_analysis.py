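"""Per-shell covariances and the signal/noise/bias variance decomposition."""

import numpy as np
import pytest

import crefdenoise as cd
from crefdenoise.bias_analysis import (
    decompose_denoised,
    decompose_noisy,
    ratio_curves,
    shell_covariance,
    shrinkage_diagnostic,
)
from crefdenoise.grid import GeometryError
from crefdenoise.synthetic_data import _shaped_noise


@pytest.fixture(scope="module")
def p64():
    return cd.build_shell_partition((64,) * 3, 1.0)


@pytest.fixture(scope="module")
def p16():
    return cd.build_shell_partition((16,) * 3, 1.0)


class TestShellCovariance:
    def test_self_covariance_is_mean_shell_power(self, rng, p16):
        x = rng.standard_normal((16,) * 3)
        v = cd.VolumeGrid(x)
        cov = shell_covariance(v, v, p16)
        f = np.fft.fftn(x, norm="ortho")
        power = p16.shell_sum(np.abs(f) ** 2) / p16.n_per_shell
        assert np.allclose(cov[1:], power[1:])
        assert cov[0] == pytest.approx(x.var())
        assert np.all(cov >= 0)

    def test_bilinearity_under_negation(self, rng, p16):
        x = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        neg = x.with_values(-x.values)
        assert np.allclose(
            shell_covariance(x, neg, p16), -shell_covariance(x, x, p16)
        )

    def test_independent_fields_decorrelate(self, p64):
        rng = np.random.default_rng(1)
        a = cd.VolumeGrid(rng.standard_normal((64,) * 3))
        b = cd.VolumeGrid(rng.standard_normal((64,) * 3))
        cov = shell_covariance(a, b, p64)
        var_a = shell_covariance(a, a, p64)
        var_b = shell_covariance(b, b, p64)
        big = p64.n_per_shell >= 100
        bound = 4.0 * np.sqrt(var_a * var_b / p64.n_per_shell)
        assert np.all(np.abs(cov[big]) <= bound[big])

    def test_shape_mismatch_rejected(self, rng, p16):
        a = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        b = cd.VolumeGrid(rng.standard_normal((32,) * 3))
        with pytest.raises(GeometryError):
            shell_covariance(a, b, p16)


class TestDecomposeNoisy:
    def test_identical_half_maps(self, rng, p16):
        x = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        var_s, var_n = decompose_noisy(x, x, p16)
        assert np.allclose(var_n, 0.0, atol=1e-12)
        assert np.allclose(var_s, shell_covariance(x, x, p16))

    def test_recovers_known_flat_spectra(self, p64):
        # S and N_i all shell-shaped: var_S = 4, var_N = 1 per shell.
        # Per-shell tolerances are 4 sigma of the estimators' sampling
        # spread, calibrated once by resampling: for this (4, 1) spectrum
        # std(var_S_hat) ~= 6.0/sqrt(n_s) and std(var_N_hat) ~= 1.4/sqrt(n_s).
        rng = np.random.default_rng(5)
        flat4 = np.full(p64.n_shells, 4.0)
        flat1 = np.ones(p64.n_shells)
        s = _shaped_noise(rng, flat4, p64)
        m1 = cd.VolumeGrid(s + _shaped_noise(rng, flat1, p64))
        m2 = cd.VolumeGrid(s + _shaped_noise(rng, flat1, p64))
        var_s, var_n = decompose_noisy(m1, m2, p64)
        big = p64.n_per_shell >= 500
        root_n = np.sqrt(p64.n_per_shell[big])
        assert np.all(np.abs(var_s[big] - 4.0) < 4 * 6.0 / root_n)
        assert np.all(np.abs(var_n[big] - 1.0) < 4 * 1.4 / root_n)

    def test_pure_noise_has_no_signal(self, p64):
        rng = np.random.default_rng(6)
        m1 = cd.VolumeGrid(rng.standard_normal((64,) * 3))
        m2 = cd.VolumeGrid(rng.standard_normal((64,) * 3))
        var_s, var_n = decompose_noisy(m1, m2, p64)
        big = p64.n_per_shell >= 100
        bound = 4.0 * var_n / np.sqrt(p64.n_per_shell)
        assert np.all(np.abs(var_s[big]) <= bound[big])

    def test_reconstruction_closure(self, rng, p16):
        # var_S + var_N == mean auto-power, exactly, for ANY inputs
        m1 = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        m2 = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        var_s, var_n = decompose_noisy(m1, m2, p16)
        half_power = 0.5 * (
            shell_covariance(m1, m1, p16) + shell_covariance(m2, m2, p16)
        )
        assert np.allclose(var_s + var_n, half_power, atol=1e-12)


class TestDecomposeDenoised:
    def test_identity_denoiser_is_exact(self, synth64):
        v = decompose_denoised(
            synth64.m1, synth64.m2, synth64.m1, synth64.m2, synth64.partition
        )
        var_s, var_n = decompose_noisy(synth64.m1, synth64.m2, synth64.partition)
        assert np.all(v.raw_B == 0.0)  # four-term combination cancels exactly
        assert np.allclose(v.raw_Nd, var_n)
        assert "assumptions" in v.metadata

    def test_perfect_denoiser_removes_noise_and_bias(self, synth64):
        v = decompose_denoised(
            synth64.m1,
            synth64.m2,
            synth64.truth,
            synth64.truth,
            synth64.partition,
        )
        p = synth64.partition
        big = p.n_per_shell >= 500
        var_s = synth64.spectra["var_S"]
        var_n = synth64.spectra["var_N_target"]
        tol = 4.0 * np.sqrt(var_s * var_n + var_n**2)[big] / np.sqrt(
            p.n_per_shell[big]
        )
        assert np.all(np.abs(v.raw_B[big]) <= tol)
        assert np.all(np.abs(v.raw_Nd[big]) <= tol)

    def test_recovers_injected_bias_and_leftover_noise(self, bias64):
        v = decompose_denoised(
            bias64.m1, bias64.m2, bias64.d1, bias64.d2, bias64.partition
        )
        p = bias64.partition
        big = p.n_per_shell >= 500
        ratio_b = v.raw_B[big] / v.raw_S[big]
        assert np.all(np.abs(ratio_b - 0.25) < 0.15 * 0.25)
        var_n = bias64.spectra["var_N_target"]
        ratio_nd = v.raw_Nd[big] / var_n[big]
        assert np.all(np.abs(ratio_nd - 0.25) < 0.15 * 0.25)

    def test_cross_terms_cancel_even_with_correlated_bias(self, p64):
        # B deliberately correlated with S: the four-covariance combination
        # must still recover var(B) (cov(S, B) cancels algebraically)
        rng = np.random.default_rng(9)
        flat = np.ones(p64.n_shells)
        s = _shaped_noise(rng, 4.0 * flat, p64)
        b_indep = _shaped_noise(rng, 0.75 * flat, p64)
        b = 0.5 * s + b_indep  # var_B = 0.25*4*... per shell: 1 + 0.75 = 1.75
        n1 = _shaped_noise(rng, flat, p64)
        n2 = _shaped_noise(rng, flat, p64)
        a = 0.5
        m1 = cd.VolumeGrid(s + n1)
        m2 = cd.VolumeGrid(s + n2)
        d1 = cd.VolumeGrid(s + b + a * n1)
        d2 = cd.VolumeGrid(s + b + a * n2)
        v = decompose_denoised(m1, m2, d1, d2, p64)
        pb = cd.shell_covariance(cd.VolumeGrid(b), cd.VolumeGrid(b), p64)
        big = p64.n_per_shell >= 500
        assert np.abs(v.raw_B[big] - pb[big]).max() < 0.15 * pb[big].max()


class TestRatioCurves:
    def test_unit_snr(self, p16):
        v = cd.VarianceSpectra(
            freq_axis=p16.freq_axis,
            raw_S=np.ones(p16.n_shells),
            raw_N=np.ones(p16.n_shells),
        )
        snr, s2b, flags = ratio_curves(v)
        assert np.allclose(snr, 1.0)
        assert s2b is None
        assert not flags["noise_floored"].any()

    def test_clamped_denominator_is_flagged(self, p16):
        n = p16.n_shells
        v = cd.VarianceSpectra(
            freq_axis=p16.freq_axis,
            raw_S=np.ones(n),
            raw_N=np.ones(n),
            raw_B=np.zeros(n),
            raw_Nd=np.ones(n),
        )
        floor = 1e-12
        snr, s2b, flags = ratio_curves(v, floor=floor)
        assert np.allclose(s2b, 1.0 / floor)
        assert flags["bias_floored"].all()

    def test_identity_denoiser_ratios(self, synth64):
        v = decompose_denoised(
            synth64.m1, synth64.m2, synth64.m1, synth64.m2, synth64.partition
        )
        snr, s2b, flags = ratio_curves(v)
        var_s, var_n = decompose_noisy(synth64.m1, synth64.m2, synth64.partition)
        noisy_snr = np.maximum(var_s, 0) / np.maximum(var_n, 1e-12)
        assert np.allclose(snr, noisy_snr)
        assert flags["bias_floored"].all()  # var_B = 0 everywhere


class TestShrinkageDiagnostic:
    @staticmethod
    def _shrink(v, factors, p):
        lab = p.shell_of_voxel.copy()
        lab[lab < 0] = p.n_shells - 1
        f = np.fft.fftn(v.values.astype(np.float64))
        f *= factors[lab]
        return v.with_values(np.fft.ifftn(f).real.astype(np.float32))

    def test_shared_shrinkage_trips_flag(self, synth64):
        p = synth64.partition
        factors = np.ones(p.n_shells)
        factors[p.n_shells // 2 :] = 0.5
        d1 = self._shrink(synth64.m1, factors, p)
        d2 = self._shrink(synth64.m2, factors, p)
        diag = shrinkage_diagnostic(synth64.m1, synth64.m2, d1, d2, p)
        assert diag.violated
        # flags concentrate on the shrunk shells
        assert diag.flags[p.n_shells // 2 :].sum() >= diag.flags.sum() * 0.9

    def test_genuine_denoiser_does_not_trip(self, bias64):
        diag = shrinkage_diagnostic(
            bias64.m1, bias64.m2, bias64.d1, bias64.d2, bias64.partition
        )
        assert not diag.violated

    def test_identity_denoiser_does_not_trip(self, synth64):
        diag = shrinkage_diagnostic(
            synth64.m1, synth64.m2, synth64.m1, synth64.m2, synth64.partition
        )
        assert not diag.violated
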