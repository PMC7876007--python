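import numpy as np
import pytest

from cochleafit import ctsim
from cochleafit.errors import FormatError, ParameterError
from cochleafit.volume import Volume


@pytest.fixture(scope="module")
def blob_volume():
    """Smooth synthetic volume: a bright ellipsoid blob in a dim background."""
    n = 48
    x, y, z = np.meshgrid(*[np.arange(n) * 0.1 - 2.35] * 3, indexing="ij")
    r2 = x ** 2 / 2.2 + y ** 2 / 1.5 + z ** 2
    data = 20.0 + 210.0 / (1.0 + np.exp((np.sqrt(r2) - 1.4) / 0.08))
    return Volume(data, 0.1)


def disc_image(n=64, radius=0.35):
    x, y = np.meshgrid(np.linspace(-0.5, 0.5, n), np.linspace(-0.5, 0.5, n),
                       indexing="ij")
    return (x ** 2 + y ** 2 < radius ** 2).astype(float)


class TestDownsample:
    def test_identity_spacing_returns_values_unchanged(self, blob_volume):
        out = ctsim.downsample(blob_volume, blob_volume.spacing)
        assert np.array_equal(out.data, blob_volume.data)

    def test_constant_volume_preserved(self):
        vol = Volume(np.full((12, 12, 12), 7.0), 0.1)
        out = ctsim.downsample(vol, 0.3)
        assert np.allclose(out.data, 7.0)

    def test_integer_factor_matches_block_mean_oracle(self, blob_volume):
        out = ctsim.downsample(blob_volume, 0.3)
        d = blob_volume.data
        oracle = d.reshape(16, 3, 16, 3, 16, 3).mean(axis=(1, 3, 5))
        assert np.allclose(out.data, oracle)
        assert abs(out.data.mean() - d.mean()) / d.mean() < 0.005

    def test_non_integer_factor_preserves_mean(self, blob_volume):
        out = ctsim.downsample(blob_volume, 0.25)
        assert abs(out.data.mean() - blob_volume.data.mean()) < 0.02 * np.ptp(
            blob_volume.data)

    def test_upsampling_rejected(self, blob_volume):
        with pytest.raises(ParameterError):
            ctsim.downsample(blob_volume, 0.05)

    def test_extent_preserved_within_one_voxel(self, blob_volume):
        out = ctsim.downsample(blob_volume, 0.3)
        assert np.all(np.abs(out.world_extent() - blob_volume.world_extent())
                      <= 0.3 + 1e-9)


class TestProjection:
    def test_zero_slice_gives_zero_sinogram(self):
        sino = ctsim.project_slice(np.zeros((32, 32)), 24)
        assert np.abs(sino.data).max() == 0.0

    def test_centered_disc_projections_identical(self):
        sino = ctsim.project_slice(disc_image(65, 0.3), 36)
        spread = np.ptp(sino.data, axis=1)
        assert spread.max() < 0.05 * sino.data.max()

    def test_point_mass_traces_sinusoid_of_its_radius(self):
        n = 129
        img = np.zeros((n, n))
        r_pix = 40
        img[n // 2 + r_pix, n // 2] = 1.0
        sino = ctsim.project_slice(img, 90)
        peaks = np.argmax(sino.data, axis=0) - (sino.data.shape[0] // 2)
        # geometry oracle: the peak detector offset follows a sinusoid in the
        # projection angle whose amplitude is the point's radius from center
        th = np.radians(sino.theta_deg)
        A = np.column_stack([np.cos(th), np.sin(th)])
        coef, *_ = np.linalg.lstsq(A, peaks, rcond=None)
        assert abs(np.hypot(*coef) - r_pix) <= 1.5
        assert np.sqrt(np.mean((peaks - A @ coef) ** 2)) <= 1.5

    def test_too_few_angles_rejected(self):
        with pytest.raises(ParameterError):
            ctsim.project_slice(np.ones((16, 16)), 1)


class TestNoise:
    def test_zero_sigma_returns_input(self):
        sino = ctsim.project_slice(disc_image(), 20)
        out = ctsim.add_detector_noise(sino, 0.0, seed=1)
        assert np.array_equal(out.data, sino.data)

    def test_sigma_scaling_and_determinism(self):
        sino = ctsim.project_slice(np.random.default_rng(0).random((350, 350)), 300)
        n1 = ctsim.add_detector_noise(sino, 0.01, seed=5).data - sino.data
        n2 = ctsim.add_detector_noise(sino, 0.02, seed=5).data - sino.data
        assert abs(n2.std() / n1.std() - 2.0) < 0.05
        n1b = ctsim.add_detector_noise(sino, 0.01, seed=5).data - sino.data
        assert np.array_equal(n1, n1b)

    def test_negative_sigma_rejected(self):
        sino = ctsim.project_slice(disc_image(), 20)
        with pytest.raises(ParameterError):
            ctsim.add_detector_noise(sino, -0.1, seed=0)


class TestReconstruction:
    def test_zero_sinogram_reconstructs_to_zero(self):
        sino = ctsim.project_slice(np.zeros((32, 32)), 24)
        assert np.abs(ctsim.reconstruct_slice(sino)).max() < 1e-12

    def test_round_trip_interior_rmse_below_two_percent(self):
        from scipy.ndimage import gaussian_filter
        # band-limited test phantom: FBP can only round-trip content below
        # the angular/detector Nyquist limit
        img = gaussian_filter(disc_image(64, 0.3) * 100.0, 1.5)
        n_angles = ctsim.nyquist_angles(64)
        rec = ctsim.reconstruct_slice(ctsim.project_slice(img, n_angles))
        x, y = np.meshgrid(np.linspace(-0.5, 0.5, 64), np.linspace(-0.5, 0.5, 64),
                           indexing="ij")
        interior = x ** 2 + y ** 2 < 0.45 ** 2
        rmse = np.sqrt(np.mean((rec[interior] - img[interior]) ** 2))
        assert rmse < 0.02 * np.ptp(img)

    def test_disc_boundary_recovered_within_one_pixel(self):
        img = disc_image(64, 0.3)
        rec = ctsim.reconstruct_slice(ctsim.project_slice(img, ctsim.nyquist_angles(64)))
        area_true = img.sum()
        area_rec = (rec > 0.5).sum()
        # one-pixel boundary tolerance: area difference below the perimeter
        perimeter = 2 * np.pi * 0.3 * 64
        assert abs(area_rec - area_true) < perimeter

    def test_angle_mismatch_rejected(self):
        sino = ctsim.project_slice(disc_image(), 20)
        with pytest.raises(FormatError):
            ctsim.reconstruct_slice(sino, theta_deg=np.linspace(0, 180, 21))


class TestDegradeVolume:
    def test_noiseless_same_spacing_round_trip(self, blob_volume):
        cfg = ctsim.DegradeConfig(target_spacing=0.1, noise_sigma=0.0)
        out = ctsim.degrade_volume(blob_volume, cfg)
        rmse = np.sqrt(np.mean((out.data - blob_volume.data) ** 2))
        assert rmse < 0.02 * np.ptp(blob_volume.data)

    def test_linearity_without_noise(self, blob_volume):
        cfg = ctsim.DegradeConfig(target_spacing=0.3, noise_sigma=0.0)
        one = ctsim.degrade_volume(blob_volume, cfg)
        two = ctsim.degrade_volume(
            Volume(2.0 * blob_volume.data, blob_volume.spacing,
                   blob_volume.origin), cfg)
        assert np.allclose(two.data, 2.0 * one.data, atol=1e-8)

    def test_noise_is_zero_mean_in_image_domain(self, blob_volume):
        clean = ctsim.degrade_volume(
            blob_volume, ctsim.DegradeConfig(target_spacing=0.3, noise_sigma=0.0))
        noisy = ctsim.degrade_volume(
            blob_volume, ctsim.DegradeConfig(target_spacing=0.3, noise_sigma=0.01,
                                             rng_seed=2))
        diff = noisy.data - clean.data
        se = diff.std() / np.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se + 1e-12

    def test_preset_noise_strictly_ordered(self, blob_volume):
        stds = []
        for name in ("cbct", "mdct", "poor_mdct"):
            cfg = ctsim.DegradeConfig.from_preset(name, rng_seed=9)
            noisy = ctsim.degrade_volume(blob_volume, cfg)
            clean = ctsim.degrade_volume(
                blob_volume, ctsim.DegradeConfig(
                    target_spacing=cfg.target_spacing, noise_sigma=0.0))
            stds.append(float((noisy.data - clean.data).std()))
        assert stds[0] < stds[1] < stds[2]

    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError):
            ctsim.DegradeConfig.from_preset("ultra")
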