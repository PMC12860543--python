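"""OSEM reconstruction, Butterworth post-filter and cardiac ROI extraction."""

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from ctless.projector import AcquisitionGeometry, SpectProjector
from ctless.recon import butterworth_filter, extract_cardiac_roi, osem

VOX = 0.68


@dataclass
class _Geom:
    n_views: int


class MatrixProjector:
    """Tiny explicit-matrix system: one 'view' per detector row."""

    def __init__(self, H):
        self.H = np.asarray(H, dtype=float)
        self.geometry = _Geom(n_views=self.H.shape[0])
        self.volume_shape = (self.H.shape[1],)

    def project(self, f, views):
        return f @ self.H[list(views)].T

    def backproject(self, g, views):
        return g @ self.H[list(views)]


def test_single_mlem_update_matches_hand_computation():
    """One iteration, one subset equals f * (H^T(g/Hf)) / (H^T 1)."""
    H = np.array([[1.0, 0.5], [0.3, 1.0]])
    g = np.array([2.0, 1.0])
    proj = MatrixProjector(H)
    f0 = np.ones(2)
    fwd = H @ f0
    expected = f0 * (H.T @ (g / fwd)) / (H.T @ np.ones(2))
    out = osem(g, proj, n_iterations=1, n_subsets=1)
    np.testing.assert_allclose(out, expected, rtol=1e-12)


def test_osem_one_subset_equals_mlem_iterates():
    H = np.array([[1.0, 0.2, 0.1], [0.1, 1.0, 0.4], [0.3, 0.2, 1.0], [0.5, 0.5, 0.5]])
    g = np.array([1.0, 2.0, 0.5, 1.5])
    proj = MatrixProjector(H)
    f = np.ones(3)
    for _ in range(7):
        f = f * (H.T @ (g / np.maximum(H @ f, 1e-12))) / (H.T @ np.ones(4))
        f = np.maximum(f, 0.0)
    out = osem(g, proj, n_iterations=7, n_subsets=1)
    np.testing.assert_allclose(out, f, rtol=1e-10)


def test_zero_projections_give_zero_image_after_one_update():
    H = np.eye(3)
    out = osem(np.zeros(3), MatrixProjector(H), n_iterations=1, n_subsets=1)
    np.testing.assert_allclose(out, 0.0)


def test_nonnegativity_and_subset_validation():
    H = np.abs(np.random.default_rng(0).normal(size=(6, 4))) + 0.1
    g = np.abs(np.random.default_rng(1).normal(size=6))
    out = osem(g, MatrixProjector(H), n_iterations=5, n_subsets=3)
    assert np.all(out >= 0)
    with pytest.raises(ValueError):
        osem(g, MatrixProjector(H), n_iterations=1, n_subsets=4)
    with pytest.raises(ValueError):
        osem(g - 10, MatrixProjector(H), n_iterations=1, n_subsets=1)


def test_osem_batch_matches_per_sample():
    H = np.abs(np.random.default_rng(3).normal(size=(6, 4))) + 0.1
    g = np.abs(np.random.default_rng(4).normal(size=(3, 6)))  # 3 samples
    proj = MatrixProjector(H)
    batch = osem(g, proj, n_iterations=4, n_subsets=2)
    singles = np.stack([osem(gi, proj, n_iterations=4, n_subsets=2) for gi in g])
    np.testing.assert_allclose(batch, singles, rtol=1e-12)


def test_noise_free_self_consistency_recovery():
    """Matched system model, noise-free data, 50 iterations: NRMSE < 5%."""
    n = 24
    geom = AcquisitionGeometry(n_views=30, n_bins=n)
    c = (np.arange(n) + 0.5 - n / 2) * VOX
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    act = np.where(x**2 + y**2 + z**2 <= 5.0**2, 1.0, 0.0)
    act += np.where((x - 1) ** 2 + y**2 + z**2 <= 2.0**2, 3.0, 0.0)
    mu = np.where(x**2 + y**2 <= 6.5**2, 0.15, 0.0)
    proj = SpectProjector(geom, n, VOX, mu=mu, model_cdr=True)
    g = proj.project(act)
    rec = osem(g, proj, n_iterations=50, n_subsets=6)
    nrmse = np.sqrt(np.mean((rec - act) ** 2)) / act.max()
    assert nrmse < 0.05


def test_osem_ac_recovers_deep_activity_better_than_nac():
    """Attenuated noise-free data: AC restores the center of a uniform
    cylinder that NAC suppresses (artifact-reduction property)."""
    n = 24
    geom = AcquisitionGeometry(n_views=30, n_bins=n)
    c = (np.arange(n) + 0.5 - n / 2) * VOX
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    inside = (x**2 + y**2 <= 6.0**2) & (np.abs(z) < 4)
    act = inside.astype(float)
    mu = np.where(x**2 + y**2 <= 6.5**2, 0.16, 0.0)
    proj_mu = SpectProjector(geom, n, VOX, mu=mu, model_cdr=False)
    proj_nac = SpectProjector(geom, n, VOX, mu=None, model_cdr=False)
    g = proj_mu.project(act)
    rec_ac = osem(g, proj_mu, 8, 6)
    rec_nac = osem(g, proj_nac, 8, 6)
    center = (x**2 + y**2 <= 2.0**2) & (np.abs(z) < 2)
    rim = inside & (x**2 + y**2 >= 4.5**2)
    # NAC shows the classic center depression; AC flattens the profile
    assert rec_nac[center].mean() / rec_nac[rim].mean() \
        < rec_ac[center].mean() / rec_ac[rim].mean()


# ---------------------------------------------------------------------------
# Butterworth
# ---------------------------------------------------------------------------

def test_butterworth_preserves_dc():
    img = np.full((16, 16, 16), 3.7)
    out = butterworth_filter(img, voxel_size_cm=VOX)
    np.testing.assert_allclose(out, img, rtol=1e-10)


def test_butterworth_gain_at_cutoff_is_half_sqrt2():
    """A sinusoid exactly at the cutoff frequency is attenuated by 1/sqrt(2)."""
    n, k = 40, 6
    fc = 0.44
    voxel = k / (n * fc)  # place fc exactly on DFT bin k
    xi = np.arange(n) * voxel
    img = np.cos(2 * np.pi * fc * xi)[:, None, None] * np.ones((1, n, n))
    out = butterworth_filter(img, order=5, cutoff_cycles_per_cm=fc, voxel_size_cm=voxel)
    gain = np.ptp(out) / np.ptp(img)
    assert abs(gain - 1 / np.sqrt(2)) < 1e-6


def test_butterworth_warns_at_nyquist():
    img = np.zeros((8, 8, 8))
    with pytest.warns(UserWarning):
        butterworth_filter(img, cutoff_cycles_per_cm=0.8, voxel_size_cm=VOX)


# ---------------------------------------------------------------------------
# cardiac ROI
# ---------------------------------------------------------------------------

def _volume_with_mask(n=48):
    img = np.zeros((n, n, n))
    mask = np.zeros((n, n, n), bool)
    mask[20:28, 20:28, 22:26] = True
    img[mask] = 10.0
    return img, mask


def test_roi_dimensions_and_mapping_endpoints():
    img, mask = _volume_with_mask()
    roi = extract_cardiac_roi(img, (24.0, 24.0, 24.0), mask)
    assert roi.pixels.shape == (32, 32)
    assert roi.x_lv == 10.0
    # voxels at the LV maximum map to 255, empty voxels to 0
    assert roi.pixels.max() == 255.0
    assert roi.pixels.min() == 0.0


def test_roi_clips_values_above_lv_maximum():
    img, mask = _volume_with_mask()
    img[24, 24, 24] = 0.0
    img[5, 5, 24] = 20.0  # hot spot outside the LV, twice x_LV
    roi = extract_cardiac_roi(img, (10.0, 10.0, 24.0), mask)
    # the hot voxel is clipped to x_LV, i.e. mapped to exactly 255
    assert roi.pixels.max() == 255.0


def test_roi_uniform_at_xlv_maps_to_255():
    img, mask = _volume_with_mask()
    img[:, :, 24] = 10.0
    roi = extract_cardiac_roi(img, (24.0, 24.0, 24.0), mask)
    np.testing.assert_allclose(roi.pixels, 255.0)


def test_roi_edge_padding_and_errors():
    img, mask = _volume_with_mask()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        roi = extract_cardiac_roi(img, (3.0, 3.0, 24.0), mask)
    assert roi.padded
    assert roi.pixels.shape == (32, 32)
    with pytest.raises(ValueError):
        extract_cardiac_roi(img, (24, 24, 24), np.zeros_like(mask))
    with pytest.raises(ValueError):
        extract_cardiac_roi(img, (24, 24, 480.0), mask)


def test_roi_slice_tie_breaks_toward_lower_index():
    img, mask = _volume_with_mask()
    img[:, :, 23] = 5.0
    roi = extract_cardiac_roi(img, (24.0, 24.0, 23.5), mask)
    assert roi.center_voxel[2] == 23
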