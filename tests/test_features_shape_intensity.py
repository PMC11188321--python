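"""Shape and first-order features: analytic solids, percentile oracles,
degenerate-VOI conventions, discretization rules."""

import numpy as np
import pytest

from petrad import LesionMask, PETVolume, PhantomSpec, discretize, make_phantom, sphere_lesion
from petrad.features.intensity import intensity_features
from petrad.features.shape import shape_features

from conftest import make_voi


def _shape(mask, spacing, intensity=None):
    out = shape_features(LesionMask(data=mask, spacing=spacing), spacing, intensity)
    return {k.split(".")[-1]: v for k, v in out.items()}


def _intensity(vol, mask, n_bins=16):
    m = LesionMask(data=mask, spacing=vol.spacing)
    voi = discretize(vol, m, n_bins=n_bins)
    out = intensity_features(vol, m, voi)
    return {k.split(".")[-1]: v for k, v in out.items()}


class TestShape:
    def test_cube_surface_and_volume_analytic(self):
        # 40 mm digital cube (40 voxels at 1 mm): V = 64000 mm^3, A = 9600 mm^2;
        # anti-aliased meshing rounds the corners, an O(h) effect within 5%
        mask = np.zeros((48, 48, 48), dtype=bool)
        mask[4:44, 4:44, 4:44] = True
        f = _shape(mask, (1.0, 1.0, 1.0))
        assert f["volume"] == pytest.approx(64000, rel=0.05)
        assert f["surface_area"] == pytest.approx(9600, rel=0.05)
        assert f["approximate_volume"] == pytest.approx(64000, rel=1e-12)

    def test_sphere_is_the_sphericity_optimum(self):
        spec = PhantomSpec(shape=(40, 40, 40),
                           lesions=[sphere_lesion((40.0, 40.0, 40.0), 30.0, peak_suv=5.0)],
                           spacing=(2.0, 2.0, 2.0))
        _, masks = make_phantom(spec)
        f = _shape(masks[0].data, (2.0, 2.0, 2.0))
        assert f["sphericity"] == pytest.approx(1.0, abs=0.02)
        assert f["spherical_disproportion"] == pytest.approx(1.0 / f["sphericity"], rel=1e-9)
        assert f["asphericity"] == pytest.approx(1.0 / f["sphericity"] - 1.0, abs=1e-9)
        assert f["compactness_2"] == pytest.approx(f["sphericity"] ** 3, rel=1e-9)

    def test_maximum_3d_diameter_of_a_line(self):
        mask = np.zeros((10, 4, 4), dtype=bool)
        mask[1:9, 1, 1] = True  # 8 voxels along x at 3 mm: centres span 21 mm
        f = _shape(mask, (3.0, 1.0, 1.0))
        assert f["maximum_3d_diameter"] == pytest.approx(21.0)

    def test_centre_of_mass_shift_and_integrated_intensity(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        uniform = np.ones((10, 10, 10))
        f0 = _shape(mask, (1.0, 1.0, 1.0), uniform)
        assert f0["centre_of_mass_shift"] == pytest.approx(0.0, abs=1e-9)
        assert f0["integrated_intensity"] == pytest.approx(f0["volume"])
        skewed = uniform.copy()
        skewed[2:5] = 10.0  # mass pulled toward low x
        f1 = _shape(mask, (1.0, 1.0, 1.0), skewed)
        assert f1["centre_of_mass_shift"] > 0.5

    def test_single_voxel_mask_finite(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        f = _shape(mask, (4.0, 4.0, 4.0))
        assert all(np.isfinite(v) for v in f.values())


class TestIntensity:
    def test_constant_voi_conventions(self):
        vol = PETVolume(data=np.full((6, 6, 6), 5.0), spacing=(4, 4, 4))
        mask = np.ones((6, 6, 6), dtype=bool)
        with pytest.warns(UserWarning, match="constant"):
            f = _intensity(vol, mask)
        assert f["mean"] == pytest.approx(5.0)
        assert f["variance"] == 0.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0
        assert f["range"] == 0.0
        assert f["coefficient_of_variation"] == 0.0

    def test_percentiles_match_numpy_oracle(self):
        rng = np.random.default_rng(11)
        data = rng.random((8, 8, 8)) * 100
        vol = PETVolume(data=data, spacing=(4, 4, 4))
        mask = np.ones((8, 8, 8), dtype=bool)
        f = _intensity(vol, mask)
        assert f["percentile_10"] == pytest.approx(np.percentile(data, 10))
        assert f["percentile_90"] == pytest.approx(np.percentile(data, 90))
        assert f["median"] == pytest.approx(np.median(data))
        assert f["energy"] == pytest.approx((data**2).sum())

    def test_uniform_histogram_maximum_entropy(self):
        # levels 1..8 equally populated: entropy log2(8)=3, uniformity 1/8
        levels = np.repeat(np.arange(1, 9), 8).reshape(8, 8, 1)
        vol = PETVolume(data=levels.astype(float), spacing=(4, 4, 4))
        mask = np.ones((8, 8, 1), dtype=bool)
        f = _intensity(vol, mask, n_bins=8)
        assert f["ih_entropy_log2"] == pytest.approx(3.0)
        assert f["ih_uniformity"] == pytest.approx(1.0 / 8.0)

    def test_global_intensity_peak_on_hot_core(self):
        data = np.ones((20, 20, 20))
        data[8:12, 8:12, 8:12] = 10.0
        vol = PETVolume(data=data, spacing=(4, 4, 4))
        mask = data > 5
        f = _intensity(vol, mask)
        # 1 cm^3 sphere at 4 mm spacing covers 7 voxels; centred in the hot
        # 4^3 core at least the centre voxel's neighbourhood is mostly hot
        assert 5.0 < f["global_intensity_peak"] <= 10.0 + 1e-9


class TestDiscretize:
    def test_equal_width_rule(self):
        vol = PETVolume(data=np.array([[[1.0, 2.0, 3.0, 4.0]]]), spacing=(4, 4, 4))
        mask = LesionMask(data=np.ones((1, 1, 4), dtype=bool), spacing=(4, 4, 4))
        voi = discretize(vol, mask, n_bins=2)
        np.testing.assert_array_equal(voi.in_mask_levels, [1, 1, 2, 2])

    def test_max_level_bounded_by_ng(self):
        rng = np.random.default_rng(0)
        vol = PETVolume(data=rng.random((6, 6, 6)) * 50, spacing=(4, 4, 4))
        mask = LesionMask(data=np.ones((6, 6, 6), dtype=bool), spacing=(4, 4, 4))
        voi = discretize(vol, mask, n_bins=64)
        assert voi.in_mask_levels.max() <= 64
        assert voi.in_mask_levels.min() >= 1

    def test_histogram_matches_direct_binning_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.random((5, 5, 5)) * 10
        vol = PETVolume(data=data, spacing=(4, 4, 4))
        mask = LesionMask(data=np.ones((5, 5, 5), dtype=bool), spacing=(4, 4, 4))
        voi = discretize(vol, mask, n_bins=8)
        # oracle: half-open equal-width bins, top value closed
        lo, hi = data.min(), data.max()
        edges = np.linspace(lo, hi, 9)
        oracle = np.clip(np.digitize(data.ravel(), edges[1:-1], right=False) + 1, 1, 8)
        np.testing.assert_array_equal(
            np.bincount(voi.in_mask_levels, minlength=9),
            np.bincount(oracle, minlength=9),
        )

    def test_affine_rescaling_invariance_of_levels(self):
        # histogram features operate on levels, which are invariant when the
        # SUVs are affinely rescaled (bins rescale with the data)
        rng = np.random.default_rng(4)
        data = rng.random((5, 5, 5)) * 10
        mask = LesionMask(data=np.ones((5, 5, 5), dtype=bool), spacing=(4, 4, 4))
        v1 = discretize(PETVolume(data=data, spacing=(4, 4, 4)), mask, 16)
        v2 = discretize(PETVolume(data=3.0 * data + 7.0, spacing=(4, 4, 4)), mask, 16)
        np.testing.assert_array_equal(v1.levels, v2.levels)
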