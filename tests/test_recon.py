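import dataclasses

import numpy as np
import pytest

from utecine.phantom import rasterize
from utecine.recon import (
    CineFrameSet,
    GridParams,
    adjoint_ndft_oracle,
    beatty_beta,
    bin_spokes,
    density_weights,
    grid_and_reconstruct_frame,
    kb_fourier,
    kb_kernel,
    reconstruct_cine,
)
from utecine.selfgate import GatingResult
from utecine.sequencer import acquire


def random_spokes(seed, n=100, samples=16, fov=20.0):
    rng = np.random.default_rng(seed)
    ang = rng.uniform(0, 2 * np.pi, n)
    kr = np.arange(samples) / fov
    data = rng.standard_normal((n, samples)) + 1j * rng.standard_normal((n, samples))
    return data, ang, kr


def synthetic_gating(phases, accepted=None):
    phases = np.asarray(phases, dtype=float)
    acc = np.ones(len(phases), bool) if accepted is None else np.asarray(accepted)
    return GatingResult(cardiac_phase=phases, resp_phase=np.zeros_like(phases),
                        accepted=acc, cardiac_rate=8.0, resp_rate=1.0,
                        n_rejected_resp=int((~acc).sum()), n_rejected_edge=0)


class TestKernel:
    def test_unit_peak_and_compact_support(self):
        gp = GridParams(matrix=32)
        assert kb_kernel(0.0, gp) == pytest.approx(1.0)
        assert kb_kernel(gp.kernel_width / 2 + 1e-9, gp) == 0.0
        u = np.linspace(-3, 3, 61)
        np.testing.assert_allclose(kb_kernel(u, gp), kb_kernel(-u, gp))

    def test_beatty_beta_default(self):
        gp = GridParams(matrix=32)
        assert gp.beta == pytest.approx(beatty_beta(4, 2.0))
        assert beatty_beta(4, 2.0) == pytest.approx(np.pi * np.sqrt(8.2))

    def test_kernel_transform_pair(self):
        """kb_fourier is the numerical Fourier transform of kb_kernel."""
        gp = GridParams(matrix=32)
        u = np.linspace(-2, 2, 4001)
        du = u[1] - u[0]
        for xi in (0.0, 0.1, 0.25, 0.4):
            num = np.sum(kb_kernel(u, gp) * np.exp(2j * np.pi * u * xi)) * du
            assert kb_fourier(xi, gp.kernel_width, gp.beta) == pytest.approx(
                num.real, rel=1e-5, abs=1e-7)

    def test_invalid_grid_params(self):
        with pytest.raises(ValueError):
            GridParams(matrix=32, kernel_width=1)
        with pytest.raises(ValueError):
            GridParams(matrix=32, oversampling=1.0)


class TestBinning:
    def test_floor_rule(self):
        g = synthetic_gating([0.0, 0.999, 0.5])
        f = bin_spokes(g, 20)
        assert list(f) == [0, 19, 10]

    def test_rejected_unassigned(self):
        g = synthetic_gating([0.1, 0.2], accepted=[True, False])
        assert list(bin_spokes(g, 4)) == [0, -1]

    def test_uniform_phases_fill_frames_evenly(self):
        rng = np.random.default_rng(11)
        g = synthetic_gating(rng.uniform(0, 1, 49200))
        counts = np.bincount(bin_spokes(g, 16), minlength=16)
        expect = 49200 / 16
        sd = np.sqrt(expect * (1 - 1 / 16))
        assert np.all(np.abs(counts - expect) < 4 * sd)


class TestDensityWeights:
    def test_ramp_shape(self):
        kr = np.arange(16) / 20.0
        w = density_weights(kr, 10)
        assert np.all(w >= 0)
        assert np.all(np.diff(w[1:]) > 0)
        assert w[0] < w[1]

    def test_normalization_by_spoke_count(self):
        kr = np.arange(16) / 20.0
        np.testing.assert_allclose(density_weights(kr, 20), density_weights(kr, 10) / 2)

    def test_ramp_beats_uniform_on_static_disk(self, unit_disk, ute_1slice):
        p = dataclasses.replace(ute_1slice, n_projections=492, n_movie_cycles=1)
        sp = acquire(unit_disk, p, seed=0)
        truth = rasterize(unit_disk, 0.0, 0, 156, 20.0)
        gp = GridParams(matrix=156)
        w = density_weights(sp.k_radii, sp.n_spokes)
        img = grid_and_reconstruct_frame(sp.data, sp.angle, sp.k_radii, w, gp, 20.0)
        wu = np.full_like(sp.k_radii, w.mean())
        img_u = grid_and_reconstruct_frame(sp.data, sp.angle, sp.k_radii, wu, gp, 20.0)
        img_u *= truth.max() / img_u.max()
        err = np.linalg.norm(img - truth)
        err_u = np.linalg.norm(img_u - truth)
        assert err < err_u


class TestOracle:
    def test_dc_only_sample_gives_constant_image(self):
        img = adjoint_ndft_oracle(np.array([[2.0 + 0j]]), np.array([0.0]),
                                  np.array([0.0]), np.array([0.5]), 16, 20.0)
        np.testing.assert_allclose(img, 1.0 + 0j, atol=1e-12)

    def test_linearity(self):
        d1, ang, kr = random_spokes(1)
        d2, _, _ = random_spokes(2)
        w = density_weights(kr, len(ang))
        a, b = 2.3, -0.7 + 0.4j
        lhs = adjoint_ndft_oracle(a * d1 + b * d2, ang, kr, w, 24, 20.0)
        rhs = (a * adjoint_ndft_oracle(d1, ang, kr, w, 24, 20.0)
               + b * adjoint_ndft_oracle(d2, ang, kr, w, 24, 20.0))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10 * np.abs(rhs).max())

    def test_hermitian_data_gives_real_image(self):
        # data from a real-valued object: d(-k) = conj(d(k)); build by
        # pairing each spoke with its angular opposite
        rng = np.random.default_rng(5)
        n, samples = 40, 12
        ang_half = rng.uniform(0, np.pi, n // 2)
        kr = np.arange(samples) / 20.0
        d_half = rng.standard_normal((n // 2, samples)) + 1j * rng.standard_normal((n // 2, samples))
        d_half[:, 0] = d_half[:, 0].real  # k = 0 must be real
        ang = np.concatenate([ang_half, ang_half + np.pi])
        data = np.concatenate([d_half, np.conj(d_half)])
        w = density_weights(kr, n)
        img = adjoint_ndft_oracle(data, ang, kr, w, 24, 20.0)
        assert np.linalg.norm(img.imag) < 1e-10 * np.linalg.norm(img.real)

    def test_matrix_cap(self):
        d, ang, kr = random_spokes(0)
        with pytest.raises(ValueError):
            adjoint_ndft_oracle(d, ang, kr, np.ones_like(kr), 128, 20.0)


class TestGridding:
    def test_matches_oracle(self):
        for seed in (0, 1, 2):
            data, ang, kr = random_spokes(seed)
            w = density_weights(kr, len(ang))
            gp = GridParams(matrix=32)
            img_g = grid_and_reconstruct_frame(data, ang, kr, w, gp, 20.0)
            img_o = np.abs(adjoint_ndft_oracle(data, ang, kr, w, 32, 20.0))
            nrmse = np.linalg.norm(img_g - img_o) / np.linalg.norm(img_o)
            assert nrmse < 0.02

    def test_dc_only_gives_flat_positive_image(self):
        # residual ripple bounded by the kernel's interpolation accuracy
        data = np.array([[3.0 + 0j]])
        gp = GridParams(matrix=32)
        img = grid_and_reconstruct_frame(data, np.array([0.0]), np.array([0.0]),
                                         np.array([1.0]), gp, 20.0)
        assert img.min() > 0
        assert np.ptp(img) < 0.02 * img.mean()

    def test_static_disk_full_sampling_near_gibbs_floor(self, unit_disk, ute_1slice):
        """Fully-sampled static disk reconstructs to within ~0.004 of the
        circular-truncation Gibbs floor (~0.053 at matrix 156)."""
        p = dataclasses.replace(ute_1slice, n_projections=492, n_movie_cycles=1)
        sp = acquire(unit_disk, p, seed=0)
        truth = rasterize(unit_disk, 0.0, 0, 156, 20.0)
        w = density_weights(sp.k_radii, sp.n_spokes)
        img = grid_and_reconstruct_frame(sp.data, sp.angle, sp.k_radii, w,
                                         GridParams(matrix=156), 20.0)
        nrmse = np.linalg.norm(img - truth) / np.linalg.norm(truth)
        assert nrmse < 0.06

    def test_full_sampling_beats_polar_undersampling(self, static_phantom1, ute_1slice):
        truth = rasterize(static_phantom1, 0.0, 0, 156, 20.0)
        errs = {}
        for nproj in (246, 492):
            p = dataclasses.replace(ute_1slice, n_projections=nproj, n_movie_cycles=1)
            sp = acquire(static_phantom1, p, seed=0)
            w = density_weights(sp.k_radii, sp.n_spokes)
            img = grid_and_reconstruct_frame(sp.data, sp.angle, sp.k_radii, w,
                                             GridParams(matrix=156), 20.0)
            errs[nproj] = np.linalg.norm(img - truth) / np.linalg.norm(truth)
        assert errs[492] < errs[246]

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            grid_and_reconstruct_frame(np.empty((0, 4), complex), np.empty(0),
                                       np.arange(4) / 20.0, np.ones(4),
                                       GridParams(matrix=32), 20.0)


@pytest.fixture(scope="module")
def static_sweeps(static_phantom1, ute_1slice):
    p = dataclasses.replace(ute_1slice, n_movie_cycles=40)
    return acquire(static_phantom1, p, seed=0)


class TestCine:
    def test_static_frames_mutually_consistent(self, static_sweeps):
        # phases follow the acquisition clock (as retrospective gating
        # produces), giving each frame near-uniform angular coverage
        phases = (static_sweeps.time / 0.125) % 1.0
        cine = reconstruct_cine(static_sweeps, synthetic_gating(phases), n_frames=4)
        f = cine.frames[0]
        for i in range(4):
            for j in range(i + 1, 4):
                nrmse = np.linalg.norm(f[i] - f[j]) / np.linalg.norm(f[j])
                assert nrmse < 0.02

    def test_amplitude_stable_across_spoke_counts(self, static_sweeps, static_phantom1):
        """Density normalization keeps tissue amplitude frame-count independent."""
        from utecine.phantom import compartment_mask
        rng = np.random.default_rng(4)
        # deliberately unbalanced frames: phases concentrated in frame 0
        phases = rng.uniform(0, 1, static_sweeps.n_spokes) ** 2
        g = synthetic_gating(phases)
        cine = reconstruct_cine(static_sweeps, g, n_frames=4)
        blood = compartment_mask(static_phantom1, 0.0, 0, "LV_blood", 156, 20.0)
        means = [cine.frames[0, i][blood].mean() for i in range(4)]
        assert cine.spokes_per_frame.max() > 2 * cine.spokes_per_frame.min()
        assert (max(means) - min(means)) / np.mean(means) < 0.05

    def test_deterministic(self, static_sweeps):
        g = synthetic_gating(np.linspace(0, 1, static_sweeps.n_spokes, endpoint=False))
        c1 = reconstruct_cine(static_sweeps, g, n_frames=4)
        c2 = reconstruct_cine(static_sweeps, g, n_frames=4)
        np.testing.assert_array_equal(c1.frames, c2.frames)

    def test_empty_frame_error_names_frame(self, static_sweeps):
        phases = np.full(static_sweeps.n_spokes, 0.1)  # everything in frame 0
        g = synthetic_gating(phases)
        with pytest.raises(ValueError, match="frame"):
            reconstruct_cine(static_sweeps, g, n_frames=4)

    def test_nifti_roundtrip(self, tmp_path, static_sweeps):
        g = synthetic_gating(np.linspace(0, 1, static_sweeps.n_spokes, endpoint=False))
        cine = reconstruct_cine(static_sweeps, g, n_frames=4)
        path = tmp_path / "cine.nii"
        cine.save_nifti(path)
        back = CineFrameSet.load_nifti(path)
        np.testing.assert_allclose(back.frames, cine.frames, rtol=1e-6)
        np.testing.assert_allclose(back.frame_phase_centers, cine.frame_phase_centers)
        assert back.pixel_size == pytest.approx(cine.pixel_size)
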