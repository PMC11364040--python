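"""Fourier-shell math: partition geometry, FSC, Cref and the training loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crefdenoise as cd
from crefdenoise.fourier_shell import CrefCurve, FSCCurve
from crefdenoise.grid import DegenerateInputError, GeometryError


def naive_fsc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Brute-force FSC oracle: visit every Fourier voxel one by one."""
    n = a.shape[0]
    f1 = np.fft.fftn(a.astype(np.float64))
    f2 = np.fft.fftn(b.astype(np.float64))
    n_shells = n // 2 + 1
    num = np.zeros(n_shells)
    p1 = np.zeros(n_shells)
    p2 = np.zeros(n_shells)
    freqs = (np.fft.fftfreq(n) * n).astype(np.float64)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                r = np.sqrt(freqs[i] ** 2 + freqs[j] ** 2 + freqs[k] ** 2)
                s = int(np.rint(r))
                if s >= n_shells:
                    continue
                num[s] += (f1[i, j, k] * np.conj(f2[i, j, k])).real
                p1[s] += abs(f1[i, j, k]) ** 2
                p2[s] += abs(f2[i, j, k]) ** 2
    with np.errstate(invalid="ignore"):
        out = np.where(p1 * p2 > 0, num / np.sqrt(p1 * p2), 0.0)
    return np.clip(out, -1.0, 1.0)


class TestShellPartition:
    def test_small_cube_shell_layout(self):
        p = cd.build_shell_partition((8, 8, 8), 1.0)
        assert p.n_shells == 5
        assert p.n_per_shell[0] == 1  # DC voxel alone
        assert p.shell_of_voxel[0, 0, 0] == 0

    def test_partition_conserves_in_band_voxels(self):
        for n in (8, 16, 32):
            p = cd.build_shell_partition((n,) * 3, 1.0)
            k = np.fft.fftfreq(n) * n
            kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
            in_band = np.rint(np.sqrt(kx**2 + ky**2 + kz**2)) <= n // 2
            assert p.n_per_shell.sum() == in_band.sum()
            # each in-band voxel labelled exactly once with a valid shell
            labels = p.shell_of_voxel[in_band]
            assert (labels >= 0).all() and (labels <= n // 2).all()
            assert (p.n_per_shell > 0).all()

    def test_nyquist_frequency(self):
        p = cd.build_shell_partition((32, 32, 32), 1.0)
        assert p.freq_axis[16] == pytest.approx(0.5)
        assert np.all(np.diff(p.freq_axis) > 0)

    def test_non_cubic_rejected_with_axes_named(self):
        with pytest.raises(GeometryError, match=r"\(16, 16, 32\)"):
            cd.build_shell_partition((16, 16, 32), 1.0)


class TestComputeFsc:
    def test_matches_naive_all_voxel_oracle(self, rng):
        for n in (16, 24):
            a = rng.standard_normal((n,) * 3)
            b = rng.standard_normal((n,) * 3)
            p = cd.build_shell_partition((n,) * 3, 1.0)
            fast = cd.compute_fsc(cd.VolumeGrid(a), cd.VolumeGrid(b), p)
            assert np.allclose(fast.values, naive_fsc(a, b), atol=1e-10)

    def test_self_opposite_and_scaled(self, rng):
        x = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        p = cd.build_shell_partition(x.shape, 1.0)
        assert np.allclose(cd.compute_fsc(x, x, p).values, 1.0)
        neg = x.with_values(-x.values)
        assert np.allclose(cd.compute_fsc(x, neg, p).values, -1.0)
        scaled = x.with_values(2.5 * x.values)
        assert np.allclose(cd.compute_fsc(x, scaled, p).values, 1.0)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        n = 64
        a = cd.VolumeGrid(rng.standard_normal((n,) * 3))
        b = cd.VolumeGrid(rng.standard_normal((n,) * 3))
        p = cd.build_shell_partition((n,) * 3, 1.0)
        fsc = cd.compute_fsc(a, b, p)
        big = p.n_per_shell >= 100
        bound = 4.0 / np.sqrt(p.n_per_shell[big])
        assert np.all(np.abs(fsc.values[big]) <= bound)

    def test_symmetry_between_arguments(self, rng):
        a = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        b = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        p = cd.build_shell_partition((16,) * 3, 1.0)
        assert np.allclose(
            cd.compute_fsc(a, b, p).values, cd.compute_fsc(b, a, p).values
        )

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 100))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        a = cd.VolumeGrid(rng.standard_normal((12,) * 3))
        b = cd.VolumeGrid(rng.standard_normal((12,) * 3))
        p = cd.build_shell_partition((12,) * 3, 1.0)
        ref = cd.compute_fsc(a, b, p).values
        got = cd.compute_fsc(a.with_values(scale * a.values), b, p).values
        assert np.allclose(ref, got, atol=1e-9)

    def test_zero_power_shells_report_zero(self):
        # a constant volume has exactly zero power off DC, so every non-DC
        # shell hits the zero-power sentinel
        n = 16
        p = cd.build_shell_partition((n,) * 3, 1.0)
        a = cd.VolumeGrid(np.full((n,) * 3, 2.0))
        fsc = cd.compute_fsc(a, a, p)
        assert fsc.values[0] == pytest.approx(1.0)
        assert np.all(fsc.values[1:] == 0.0)

    def test_all_zero_volumes_rejected(self):
        z = cd.VolumeGrid(np.zeros((16,) * 3))
        p = cd.build_shell_partition((16,) * 3, 1.0)
        with pytest.raises(DegenerateInputError):
            cd.compute_fsc(z, z, p)

    def test_shape_mismatch_rejected(self, rng):
        a = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        b = cd.VolumeGrid(rng.standard_normal((24,) * 3))
        p = cd.build_shell_partition((16,) * 3, 1.0)
        with pytest.raises(GeometryError):
            cd.compute_fsc(a, b, p)


class TestIntegrateFsc:
    @pytest.mark.parametrize(
        "values,expected",
        [
            (np.ones(49), 48.0),  # 48 non-DC shells of ones
            (np.zeros(49), 0.0),
            (np.full(17, 0.5), 8.0),  # 16 non-DC shells at 0.5
        ],
    )
    def test_sums_non_dc_shells(self, values, expected):
        curve = FSCCurve(values=values, freq_axis=np.linspace(0, 0.5, len(values)))
        assert cd.integrate_fsc(curve) == pytest.approx(expected)

    def test_empty_curve_rejected(self):
        curve = FSCCurve(values=np.array([]), freq_axis=np.array([]))
        with pytest.raises(ValueError):
            cd.integrate_fsc(curve)


class TestCref:
    def test_closed_form_values(self):
        curve = FSCCurve(
            values=np.array([1.0, 0.0, 1.0 / 7.0, -0.3]),
            freq_axis=np.arange(4) / 16.0,
        )
        cref = cd.cref_from_fsc_half(curve)
        assert cref.values[0] == pytest.approx(1.0)
        assert cref.values[1] == pytest.approx(0.0)
        assert cref.values[2] == pytest.approx(0.5)  # F = 1/7 exactly
        assert cref.values[3] == pytest.approx(0.0)  # negative F clamped

    def test_monotone_on_unit_interval(self):
        f = np.linspace(0.0, 1.0, 201)
        cref = cd.cref_from_fsc_half(FSCCurve(values=f, freq_axis=f))
        assert np.all(np.diff(cref.values) >= 0)
        assert np.all((cref.values >= 0) & (cref.values <= 1))


class TestCrefLoss:
    def test_zero_when_denoised_traces_cref(self, rng):
        x = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        p = cd.build_shell_partition((16,) * 3, 1.0)
        # identical half-maps: FSC_half = 1, Cref = 1, FSC_FD(mean, mean) = 1
        assert cd.cref_loss(x, x, x, x, p) == pytest.approx(0.0)

    def test_equals_mean_absolute_curve_difference(self, rng):
        s = rng.standard_normal((16,) * 3)
        a = cd.VolumeGrid(s + rng.standard_normal((16,) * 3))
        b = cd.VolumeGrid(s + rng.standard_normal((16,) * 3))
        mean = a.with_values(0.5 * (a.values + b.values))
        den = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        p = cd.build_shell_partition((16,) * 3, 1.0)
        cref = cd.cref_from_fsc_half(cd.compute_fsc(a, b, p))
        fsc_fd = cd.compute_fsc(mean, den, p)
        manual = float(np.mean(np.abs(cref.values[1:] - fsc_fd.values[1:])))
        assert cd.cref_loss(mean, den, a, b, p) == pytest.approx(manual, abs=1e-12)

    def test_constant_offset_gives_offset_loss(self):
        # pure curve algebra: FSC_FD = Cref - 0.1 everywhere -> loss 0.1
        freq = np.arange(9) / 16.0
        cref = np.linspace(1.0, 0.3, 9)
        fsc_fd = cref - 0.1
        manual = float(np.mean(np.abs(cref[1:] - fsc_fd[1:])))
        assert manual == pytest.approx(0.1)

    def test_mean_map_mismatch_rejected(self, rng):
        a = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        b = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        p = cd.build_shell_partition((16,) * 3, 1.0)
        with pytest.raises(ValueError, match="average"):
            cd.cref_loss(a, a, a, b, p)

    def test_gradient_matches_finite_differences(self, rng):
        n = 16
        s = rng.standard_normal((n,) * 3)
        a = cd.VolumeGrid(s + rng.standard_normal((n,) * 3))
        b = cd.VolumeGrid(s + rng.standard_normal((n,) * 3))
        mean = a.with_values(0.5 * (a.values + b.values))
        den = cd.VolumeGrid(rng.standard_normal((n,) * 3))
        p = cd.build_shell_partition((n,) * 3, 1.0)
        loss, grad = cd.cref_loss_with_grad(mean, den, a, b, p)
        eps = 1e-6
        for idx in [(0, 0, 0), (3, 5, 7), (8, 2, 11), (15, 15, 15)]:
            up = den.values.copy()
            up[idx] += eps
            down = den.values.copy()
            down[idx] -= eps
            fd = (
                cd.cref_loss(mean, cd.VolumeGrid(up), a, b, p)
                - cd.cref_loss(mean, cd.VolumeGrid(down), a, b, p)
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_external_cref_curve_override(self, rng):
        s = rng.standard_normal((16,) * 3)
        a = cd.VolumeGrid(s + rng.standard_normal((16,) * 3))
        b = cd.VolumeGrid(s + rng.standard_normal((16,) * 3))
        mean = a.with_values(0.5 * (a.values + b.values))
        den = cd.VolumeGrid(rng.standard_normal((16,) * 3))
        p = cd.build_shell_partition((16,) * 3, 1.0)
        override = CrefCurve(values=np.full(p.n_shells, 0.5), freq_axis=p.freq_axis)
        fsc_fd = cd.compute_fsc(mean, den, p)
        manual = float(np.mean(np.abs(0.5 - fsc_fd.values[1:])))
        got = cd.cref_loss(mean, den, a, b, p, cref_override=override)
        assert got == pytest.approx(manual, abs=1e-12)


class TestHalfMapRelations:
    def test_ssnr_relation_and_rosenthal_henderson_closure(self, synth64):
        """FSC_half tracks q/(1+q) and FSC(full, truth) tracks Cref."""
        p = synth64.partition
        big = p.n_per_shell >= 500
        fsc_half = cd.compute_fsc(synth64.m1, synth64.m2, p)
        assert np.abs(fsc_half.values[big] - 0.5).max() < 0.05
        mean = synth64.m1.with_values(
            0.5 * (synth64.m1.values + synth64.m2.values)
        )
        fsc_fd = cd.compute_fsc(mean, synth64.truth, p)
        cref = cd.cref_from_fsc_half(fsc_half)
        assert np.abs(fsc_fd.values[big] - cref.values[big]).max() < 0.05
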