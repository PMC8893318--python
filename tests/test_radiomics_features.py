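"""First-order, shape and texture-feature formulas: closed-form fixtures,
hand-traced matrices and degenerate-input rules."""

import numpy as np
import pytest

from aneufuse.radiomics.features import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from aneufuse.radiomics.firstorder import first_order_features
from aneufuse.radiomics.matrices import glcm_matrix, gldm_matrix, glrlm_matrix, glszm_matrix, ngtdm_matrix
from aneufuse.radiomics.preprocess import DiscretizedROI, discretize
from aneufuse.radiomics.shape import shape3d_features
from aneufuse.types import GeometryError, SegMask, VolumeImage


def _pair(values: np.ndarray):
    """Wrap a flat value list as a 1xNx1 volume with a full mask."""
    arr = np.asarray(values, dtype=float).reshape(1, -1, 1)
    vol = VolumeImage(data=arr, spacing=[0.5] * 3)
    mask = SegMask(data=np.ones_like(arr, dtype=np.uint8), spacing=[0.5] * 3)
    return vol, mask


def _roi(levels: np.ndarray) -> DiscretizedROI:
    levels = np.asarray(levels)
    return DiscretizedROI(
        levels=levels.astype(np.int32), n_levels=int(levels.max()),
        mask=levels > 0, spacing=np.ones(3),
    )


class TestDiscretize:
    def test_bin_edges(self):
        vol, mask = _pair([0.0, 49.9, 50.0, 100.0])
        roi = discretize(vol, mask, n_bins=4)
        inmask = roi.levels[roi.mask]
        assert list(inmask) == [1, 2, 3, 4]  # 49.9 -> bin 2, 50.0 -> bin 3

    def test_constant_roi_single_level(self):
        vol, mask = _pair([7.0, 7.0, 7.0])
        roi = discretize(vol, mask, n_bins=8)
        assert roi.n_levels == 1
        assert set(roi.levels[roi.mask]) == {1}

    def test_eight_distinct_values_eight_bins(self):
        vol, mask = _pair(np.arange(1.0, 9.0))
        roi = discretize(vol, mask, n_bins=8)
        assert list(roi.levels[roi.mask]) == list(range(1, 9))


class TestFirstOrder:
    def test_small_roi_closed_forms(self):
        vol, mask = _pair([2.0, 2.0, 4.0, 4.0])
        roi = discretize(vol, mask, n_bins=2)
        f = first_order_features(vol, mask, roi)
        assert f["mean"] == 3.0
        assert f["range"] == 2.0
        assert f["variance"] == 1.0
        assert f["root_mean_squared"] == pytest.approx(np.sqrt(10.0))
        assert f["energy"] == 40.0
        assert f["total_energy"] == pytest.approx(0.5**3 * 40.0)
        assert f["uniformity"] == 0.5  # two levels, half the voxels each
        assert f["entropy"] == 1.0

    def test_constant_roi_degenerate_rules(self):
        vol, mask = _pair([5.0] * 6)
        roi = discretize(vol, mask, n_bins=4)
        f = first_order_features(vol, mask, roi)
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0
        assert f["skewness"] == 0.0
        assert f["kurtosis"] == 0.0

    def test_percentiles_match_bruteforce_oracle(self):
        values = np.arange(1.0, 11.0)
        vol, mask = _pair(values)
        f = first_order_features(vol, mask, discretize(vol, mask, n_bins=2))
        # oracle: linear-interpolation percentile computed from first principles
        def pct(q):
            pos = q / 100 * (len(values) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            hi = min(lo + 1, len(values) - 1)
            return values[lo] * (1 - frac) + values[hi] * frac

        assert f["percentile10"] == pytest.approx(pct(10))
        assert f["percentile90"] == pytest.approx(pct(90))
        assert f["median"] == pytest.approx(pct(50))
        assert f["interquartile_range"] == pytest.approx(pct(75) - pct(25))

    def test_count_is_18(self):
        vol, mask = _pair(np.arange(12.0))
        f = first_order_features(vol, mask, discretize(vol, mask, n_bins=4))
        assert len(f) == 18


class TestShape3D:
    @staticmethod
    def _ball_mask(radius_vox=10, spacing=1.0):
        n = 2 * radius_vox + 5
        c = (n - 1) / 2
        xx, yy, zz = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        ball = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius_vox**2
        return SegMask(data=ball.astype(np.uint8), spacing=[spacing] * 3)

    def test_digital_ball_sphericity(self):
        f = shape3d_features(self._ball_mask())
        assert f["sphericity"] == pytest.approx(1.0, rel=0.05)
        assert f["elongation"] == pytest.approx(1.0, rel=0.05)
        assert f["maximum_3d_diameter"] == pytest.approx(20.0, rel=0.1)

    def test_rod_inertia_closed_form(self):
        """1x1x10 voxel rod: eigenvalues of a discrete uniform line of 10
        points; axis lengths follow 4*sqrt(lambda)."""
        m = np.zeros((5, 5, 14), dtype=np.uint8)
        m[2, 2, 2:12] = 1
        f = shape3d_features(SegMask(data=m, spacing=[1.0] * 3))
        pts = np.arange(10.0)
        lam = np.var(pts)  # population variance of voxel centres on the axis
        assert f["major_axis_length"] == pytest.approx(4 * np.sqrt(lam), rel=1e-9)
        assert f["elongation"] < 0.1
        assert f["flatness"] < 0.1
        assert f["minor_axis_length"] == 0.0

    def test_exactly_14_values(self):
        f = shape3d_features(self._ball_mask(radius_vox=4))
        assert len(f) == 14

    def test_single_voxel_rejected(self):
        m = np.zeros((3, 3, 3), dtype=np.uint8)
        m[1, 1, 1] = 1
        with pytest.raises(GeometryError):
            shape3d_features(SegMask(data=m, spacing=[1.0] * 3))


class TestGLCMFeatures:
    def test_constant_roi_degenerates(self):
        tm = glcm_matrix(_roi(np.ones((3, 3, 3), dtype=int)))
        f = glcm_features(tm)
        assert f["contrast"] == 0.0
        assert f["maximum_probability"] == 1.0
        assert f["correlation"] == 1.0
        assert f["imc1"] == 0.0
        assert f["mcc"] == 1.0
        assert len(f) == 24
        assert tuple(f) == GLCM_NAMES

    def test_two_level_hand_trace(self):
        """Single-direction GLCM of [[1,1],[2,2]] along y: pairs (1,1),(2,2);
        symmetrized P = diag(0.5, 0.5)."""
        levels = np.array([[1, 1], [2, 2]]).reshape(2, 2, 1)
        tm = glcm_matrix(_roi(levels), directions=[(0, 1, 0)])
        f = glcm_features(tm)
        assert f["contrast"] == 0.0
        assert f["joint_energy"] == 0.5
        assert f["joint_entropy"] == 1.0
        assert f["joint_average"] == 1.5
        assert f["correlation"] == pytest.approx(1.0)
        assert f["sum_average"] == pytest.approx(3.0)

    def test_checkerboard_contrast(self):
        """Alternating 1/2 along one axis: all x-direction pairs differ by 1."""
        levels = np.tile(np.array([1, 2, 1, 2]).reshape(4, 1, 1), (1, 1, 1))
        tm = glcm_matrix(_roi(levels), directions=[(1, 0, 0)])
        f = glcm_features(tm)
        assert f["contrast"] == 1.0
        assert f["idm"] == 0.5


class TestRunZoneFeatures:
    def test_glrlm_hand_trace_two_runs(self):
        """[1,1,1,2] single direction: p = {(1,3): 1/2, (2,1): 1/2}."""
        levels = np.array([1, 1, 1, 2]).reshape(1, 1, 4)
        tm = glrlm_matrix(_roi(levels), directions=[(0, 0, 1)])
        f = glrlm_features(tm)
        # GLN: level sums are (1,1) -> (1+1)/2; RLN: length sums (1,0,1)
        assert f["gray_level_non_uniformity"] == pytest.approx(1.0)
        assert f["run_length_non_uniformity"] == pytest.approx(1.0)
        assert f["short_run_emphasis"] == pytest.approx(0.5 * (1 / 9) + 0.5 * 1)
        assert f["long_run_emphasis"] == pytest.approx(0.5 * 9 + 0.5 * 1)
        assert f["run_percentage"] == pytest.approx(2 / 4)
        assert len(f) == 16 and tuple(f) == GLRLM_NAMES

    def test_glszm_constant_roi(self):
        tm = glszm_matrix(_roi(np.ones((3, 3, 3), dtype=int)))
        f = glszm_features(tm)
        assert f["zone_percentage"] == pytest.approx(1 / 27)
        assert f["large_area_emphasis"] == pytest.approx(27.0**2)
        assert f["gray_level_variance"] == 0.0
        assert len(f) == 16 and tuple(f) == GLSZM_NAMES


class TestNGTDMFeatures:
    def test_constant_roi_degenerate_rules(self):
        tm = ngtdm_matrix(_roi(np.ones((3, 3, 3), dtype=int)))
        f = ngtdm_features(tm)
        assert f["busyness"] == 0.0
        assert f["complexity"] == 0.0
        assert f["contrast"] == 0.0
        assert f["strength"] == 0.0
        assert f["coarseness"] == 1e6  # capped
        assert len(f) == 5 and tuple(f) == NGTDM_NAMES

    def test_two_level_hand_trace(self):
        """1x1x2 ROI [1,2]: each voxel's only neighbour is the other level, so
        s_1 = s_2 = 1 and p_1 = p_2 = 1/2."""
        tm = ngtdm_matrix(_roi(np.array([1, 2]).reshape(1, 1, 2)))
        np.testing.assert_allclose(tm.matrix, [[1, 0.5, 1], [1, 0.5, 1]])
        f = ngtdm_features(tm)
        assert f["coarseness"] == pytest.approx(1.0)  # 1 / (0.5*1 + 0.5*1)
        # contrast: (1/(2*1)) * sum p_i p_j (i-j)^2 = 0.25... times mean s = 1
        assert f["contrast"] == pytest.approx(0.5 * 0.25 * 2 * (2 / 2))


class TestGLDMFeatures:
    def test_constant_roi(self):
        tm = gldm_matrix(_roi(np.ones((3, 3, 3), dtype=int)))
        f = gldm_features(tm)
        assert len(f) == 14 and tuple(f) == GLDM_NAMES
        # corner voxels depend on 7 neighbours + self, etc.; all level 1
        assert f["low_gray_level_emphasis"] == 1.0
        assert f["high_gray_level_emphasis"] == 1.0
        assert f["gray_level_variance"] == 0.0

    def test_isolated_voxels_dependence_one(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        levels[0, 0, 0] = 1
        levels[2, 2, 2] = 1
        tm = gldm_matrix(_roi(levels))
        assert tm.matrix.shape == (1, 1)
        assert tm.matrix[0, 0] == 2  # two voxels, dependence size 1 each
        f = gldm_features(tm)
        assert f["small_dependence_emphasis"] == 1.0
        assert f["large_dependence_emphasis"] == 1.0
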