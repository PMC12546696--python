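import numpy as np
import pytest
from oracles import naive_cov_stack, naive_mean_std_cov

from octacov import cov_engine as ce
from octacov import phantom as ph
from octacov.volume_io import (
    AcquisitionSeries,
    EnFaceMap,
    LayerBoundaries,
    MapKind,
    Modality,
    ValidationError,
    VolumeGrid,
)


def series_from_stack(stack, spacing=(1.0, 1.0, 1.0)):
    vols = [VolumeGrid(v, spacing, Modality.OCTA) for v in stack]
    octs = [VolumeGrid(np.zeros_like(stack[0]), spacing, Modality.OCT) for _ in stack]
    return AcquisitionSeries(vols, octs)


class TestVolumetricCoV:
    def test_constant_series_has_zero_cov(self):
        stack = np.full((10, 3, 3, 3), 5.0)
        res = ce.cov_volumetric(series_from_stack(stack))
        assert (res.mean.data == 5.0).all()
        assert (res.std.data == 0.0).all()
        assert (res.cov.data == 0.0).all()

    def test_one_to_ten_sequence(self):
        # direct evaluation: mean 5.5, sample std sqrt(82.5/9), CoV ratio
        stack = np.arange(1.0, 11.0).reshape(10, 1, 1, 1)
        res = ce.cov_volumetric(series_from_stack(stack))
        mean, std, cov = naive_mean_std_cov(range(1, 11))
        assert res.mean.data[0, 0, 0] == pytest.approx(5.5)
        assert res.std.data[0, 0, 0] == pytest.approx(std)  # 3.02765...
        assert res.cov.data[0, 0, 0] == pytest.approx(cov)  # 0.55048...
        assert abs(res.std.data[0, 0, 0] - 3.0277) < 1e-4
        assert abs(res.cov.data[0, 0, 0] - 0.5505) < 1e-4

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        stack = rng.uniform(1.0, 2.0, (10, 8, 8, 4))
        res = ce.cov_volumetric(series_from_stack(stack))
        expected = naive_cov_stack(stack)
        rel = np.abs(res.cov.data - expected) / expected
        assert rel.max() < 1e-10

    def test_zero_mean_gives_zero_cov(self):
        stack = np.zeros((4, 2, 2, 2))
        stack[0, 0, 0, 0] = 0.0  # all-zero voxel: mean 0 -> CoV defined as 0
        res = ce.cov_volumetric(series_from_stack(stack))
        assert (res.cov.data == 0).all()


class TestNoiseEstimate:
    def _volume(self, data):
        return VolumeGrid(np.asarray(data, dtype=float), (1, 1, 1), Modality.OCTA)

    def test_constant_region(self):
        nz, nx, ny = 40, 2, 2
        vol = self._volume(np.full((nz, nx, ny), 7.0))
        ilm = np.full((nx, ny), 35)
        est = ce.estimate_noise(vol, ilm, delta=0.0)
        assert np.allclose(est.noise_mean, 7.0)
        assert np.allclose(est.noise_std, 0.0)
        assert np.allclose(est.threshold, 7.0)

    def test_two_two_four_four_with_offset(self):
        # R(y) = {2,2,4,4}: mean 3, sample std 2/sqrt(3), T = 3 + 1.1547 + 1
        nz = 40
        data = np.zeros((nz, 2, 1))
        ilm = np.full((2, 1), 31)
        data[1:22, 0, 0] = 2.0
        data[1:22, 1, 0] = 4.0
        vol = self._volume(data)
        est = ce.estimate_noise(vol, ilm, delta=1.0, region=(10, 11))
        # band is z in [20, 21] for both A-scans -> values {2, 2, 4, 4}
        assert est.noise_mean[0] == pytest.approx(3.0)
        assert est.noise_std[0] == pytest.approx(1.1547, abs=1e-4)
        assert est.threshold[0] == pytest.approx(5.1547, abs=1e-4)

    def test_band_location_ten_to_thirty_above_ilm(self):
        # ILM at z=100 -> band covers z in [70, 90]
        nz, nx, ny = 128, 1, 1
        data = np.zeros((nz, nx, ny))
        data[70:91] = 42.0  # fill exactly the expected band
        data[69] = 1e6  # sentinels just outside must not leak in
        data[91] = 1e6
        vol = self._volume(data)
        est = ce.estimate_noise(vol, np.full((nx, ny), 100), delta=0.0)
        assert est.noise_mean[0] == pytest.approx(42.0)
        assert est.noise_std[0] == pytest.approx(0.0)

    def test_threshold_identity(self):
        est = ce.NoiseEstimate(np.array([1.0]), np.array([2.0]), 3.0, (10, 30))
        assert est.threshold[0] == 6.0


class TestBinaryMask:
    def _setup(self, values, thr):
        vol = VolumeGrid(np.asarray(values, dtype=float)[..., None].T.reshape(1, -1, 1),
                         (1, 1, 1), Modality.OCTA)
        noise = ce.NoiseEstimate(np.array([thr]), np.array([0.0]), 0.0, (10, 30))
        return vol, noise

    def test_exactly_at_threshold_excluded(self):
        vol, noise = self._setup([5.0], 5.0)
        mask = ce.binary_mask(vol, noise)
        assert mask.data.sum() == 0

    def test_epsilon_above_included(self):
        vol, noise = self._setup([5.0 + 1e-9], 5.0)
        mask = ce.binary_mask(vol, noise)
        assert mask.data.sum() == 1

    def test_count_above_threshold(self):
        rng = np.random.default_rng(0)
        data = rng.permutation(np.arange(20.0)).reshape(4, 5, 1)
        vol = VolumeGrid(data, (1, 1, 1), Modality.OCTA)
        noise = ce.NoiseEstimate(np.array([12.5]), np.array([0.0]), 0.0, (10, 30))
        mask = ce.binary_mask(vol, noise)
        assert mask.data.sum() == 7  # values 13..19


class TestFilteredCoV:
    def _raw(self, shape=(4, 4, 4)):
        rng = np.random.default_rng(1)
        stack = rng.uniform(1, 2, (6, *shape))
        return ce.cov_volumetric(series_from_stack(stack))

    @pytest.mark.parametrize("mask_value", [0, 1])
    def test_uniform_masks(self, mask_value):
        raw = self._raw()
        mask = VolumeGrid(np.full(raw.cov.shape, mask_value, dtype=np.uint8),
                          raw.cov.spacing, Modality.MASK)
        res = ce.filtered_cov(raw, mask)
        if mask_value:
            assert np.array_equal(res.filtered.data, raw.cov.data)
        else:
            assert (res.filtered.data == 0).all()

    def test_checkerboard_support(self):
        raw = self._raw()
        idx = np.indices(raw.cov.shape).sum(axis=0) % 2
        mask = VolumeGrid(idx.astype(np.uint8), raw.cov.spacing, Modality.MASK)
        res = ce.filtered_cov(raw, mask)
        assert ((res.filtered.data > 0) == ((idx == 1) & (raw.cov.data > 0))).all()

    def test_shape_mismatch_rejected(self):
        raw = self._raw()
        mask = VolumeGrid(np.ones((2, 2, 2), dtype=np.uint8), (1, 1, 1), Modality.MASK)
        with pytest.raises(ValidationError):
            ce.filtered_cov(raw, mask)


class TestDeltaSelection:
    def test_separable_phantom_keeps_vessels(self, motion_free_phantom):
        _, series, truth = motion_free_phantom
        raw = ce.cov_volumetric(series)
        ref = EnFaceMap((truth.vessel_probability.data > 0).astype(np.uint8),
                        truth.vessel_probability.spacing, MapKind.MASK)
        grid = np.arange(0.0, 100.0, 5.0)
        delta = ce.select_delta(raw.mean, ref, truth.layers, delta_grid=grid)
        assert delta > 0  # background alone must be suppressed
        noise = ce.estimate_noise(raw.mean, truth.layers, delta=delta)
        mask = ce.binary_mask(raw.mean, noise)
        # en face vessel support intact at the selected delta ...
        upper, lower = ce.slab_bounds(truth.layers)
        zz = np.arange(raw.mean.nz)[:, None, None]
        proj = (mask.data.astype(bool)
                & (zz >= upper[None]) & (zz < lower[None])).any(axis=0)
        refb = ref.data > 0
        dice = 2 * (proj & refb).sum() / (proj.sum() + refb.sum())
        assert dice >= 0.95
        # ... and most vessel voxels survive the thresholding
        union = np.zeros(raw.cov.shape, dtype=bool)
        for m in truth.class_masks.values():
            union |= m
        assert mask.data[union].mean() > 0.8
        # background almost fully suppressed
        assert mask.data[~union].mean() < 0.01

    def test_single_value_grid_returned(self, motion_free_phantom):
        _, series, truth = motion_free_phantom
        raw = ce.cov_volumetric(series)
        ref = EnFaceMap((truth.vessel_probability.data > 0).astype(np.uint8),
                        truth.vessel_probability.spacing, MapKind.MASK)
        assert ce.select_delta(raw.mean, ref, truth.layers, delta_grid=[3.25]) == 3.25

    def test_mask_count_non_increasing_in_delta(self, motion_free_phantom):
        _, series, truth = motion_free_phantom
        raw = ce.cov_volumetric(series)
        base = ce.estimate_noise(raw.mean, truth.layers, delta=0.0)
        counts = []
        for d in [0.0, 5.0, 20.0, 80.0]:
            noise = ce.NoiseEstimate(base.noise_mean, base.noise_std, d, base.region)
            counts.append(int(ce.binary_mask(raw.mean, noise).data.sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBaselineProtocols:
    def test_protocol_a_identical_images_zero(self):
        maps = [EnFaceMap(np.full((4, 4), 3.0), (1, 1)) for _ in range(5)]
        out = ce.protocol_a_cov(maps)
        assert (out.data == 0).all()

    def test_protocol_a_matches_oracle(self):
        rng = np.random.default_rng(2)
        stack = rng.uniform(1, 2, (10, 6, 6))
        maps = [EnFaceMap(s, (1, 1)) for s in stack]
        out = ce.protocol_a_cov(maps)
        expected = naive_cov_stack(stack)
        assert np.abs(out.data - expected).max() < 1e-12
        _, _, cov = naive_mean_std_cov(range(1, 11))
        series = np.arange(1.0, 11.0).reshape(10, 1, 1)
        single = ce.protocol_a_cov([EnFaceMap(s, (1, 1)) for s in series])
        assert single.data[0, 0] == pytest.approx(cov)

    def test_protocol_a_biased_on_enhanced_projections(self, motion_free_phantom):
        # the contrast refinement makes en face CoV misrepresent the
        # true temporal CoV — the failure mode motivating the 3D method
        _, series, truth = motion_free_phantom
        stack = [ph.emulate_device_enface(v, truth.layers) for v in series.octa_volumes]
        cov_a = ce.protocol_a_cov(stack)
        cap = truth.class_masks["capillary_svp"].any(axis=0)
        true_cov = truth.true_class_cov["capillary_svp"]
        assert abs(np.median(cov_a.data[cap]) - true_cov) > 0.05

    def test_protocol_b_identical_repeats_zero(self, two_depth_series):
        series, layers, _ = two_depth_series
        same = AcquisitionSeries([series.octa_volumes[0]] * 4, series.oct_volumes[:4])
        out = ce.protocol_b_cov(same, layers)
        assert (out.data == 0).all()

    def test_protocol_b_single_slice_slab_equals_volumetric(self):
        rng = np.random.default_rng(3)
        stack = rng.uniform(1, 2, (8, 5, 6, 6))
        series = series_from_stack(stack)
        layers = LayerBoundaries(np.full((6, 6), 2), np.full((6, 6), 2),
                                 np.full((6, 6), 3))
        out = ce.protocol_b_cov(series, layers)  # slab = {z=2} only
        raw = ce.cov_volumetric(series)
        assert np.allclose(out.data, raw.cov.data[2], atol=1e-12)

    def test_depth_mixing_hides_variability(self, two_depth_series):
        # MIP alternates its source depth -> Protocol B sees a constant
        series, layers, vessel = two_depth_series
        out = ce.protocol_b_cov(series, layers)
        raw = ce.cov_volumetric(series)
        _, _, true_cov = naive_mean_std_cov([100, 102] * 5)
        assert np.allclose(out.data[vessel], 0.0, atol=1e-12)
        assert np.allclose(raw.cov.data[10][vessel], true_cov, atol=1e-12)


class TestDepthIndexVariability:
    def test_stable_maximum_zero_std(self, two_depth_series):
        series, layers, _ = two_depth_series
        same = AcquisitionSeries([series.octa_volumes[0]] * 4, series.oct_volumes[:4])
        out = ce.depth_index_variability(same, layers)
        assert (out.std == 0).all()

    def test_alternating_indices_std(self, two_depth_series):
        series, layers, vessel = two_depth_series
        out = ce.depth_index_variability(series, layers)
        _, std, _ = naive_mean_std_cov([10] * 5 + [20] * 5)
        assert np.allclose(out.std[vessel], std)  # 5.2705...
        assert abs(out.std[vessel][0] - 5.2705) < 1e-4

    def test_tie_breaks_to_smallest_z(self):
        nz, nx, ny = 10, 2, 2
        stack = np.zeros((3, nz, nx, ny))
        stack[:, 4] = 7.0
        stack[:, 6] = 7.0  # tied maximum deeper down
        series = series_from_stack(stack)
        layers = LayerBoundaries(np.full((nx, ny), 2), np.full((nx, ny), 3),
                                 np.full((nx, ny), 9))
        out = ce.depth_index_variability(series, layers)
        assert (out.indices == 4).all()


class TestProjectionsAndMasking:
    def _filtered(self, slab_values):
        # build a filtered CoV volume whose A-scan (0,0) slab is slab_values
        nz = len(slab_values) + 2
        data = np.zeros((nz, 1, 1))
        data[1:-1, 0, 0] = slab_values
        return VolumeGrid(data, (1, 1, 1), Modality.COV)

    @pytest.mark.parametrize(
        "slab,expected",
        [
            ([0.7, 0.7, 0.7], 0.7),
            ([0.0, 0.2, 0.8], 0.2),
            ([0.1, 0.3, 0.5, 0.9], 0.4),  # even count: mean of central pair
        ],
    )
    def test_median_projection_values(self, slab, expected):
        vol = self._filtered(slab)
        upper = np.array([[1]])
        lower = np.array([[1 + len(slab)]])
        out = ce.median_projection(vol, upper, lower)
        assert out.data[0, 0] == pytest.approx(expected)

    def test_median_projection_rejects_bad_slab(self):
        vol = self._filtered([0.1, 0.2])
        with pytest.raises(ValidationError):
            ce.median_projection(vol, np.array([[3]]), np.array([[3]]))

    def test_vessel_mask_boundary_kept(self):
        cov = EnFaceMap(np.full((2, 2), 0.4), (1, 1), MapKind.COV)
        prob = EnFaceMap(np.array([[0.5, 0.49], [1.0, 0.0]]), (1, 1),
                         MapKind.PROBABILITY)
        out = ce.apply_vessel_mask(cov, prob)
        assert out.data[0, 0] == 0.4  # exactly 0.5 counts as vessel
        assert out.data[0, 1] == 0.0
        assert out.data[1, 0] == 0.4
        assert out.data[1, 1] == 0.0

    def test_vessel_mask_truth_support(self):
        rng = np.random.default_rng(4)
        cov = EnFaceMap(rng.uniform(0.1, 1.0, (8, 8)), (1, 1), MapKind.COV)
        truth = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
        out = ce.apply_vessel_mask(cov, EnFaceMap(truth, (1, 1), MapKind.PROBABILITY))
        assert ((out.data > 0) == (truth > 0)).all()


class TestScaleInvariance:
    def test_global_intensity_scaling_leaves_cov_unchanged(self, two_depth_series):
        series, layers, _ = two_depth_series
        scaled = AcquisitionSeries(
            [VolumeGrid(v.data * 37.5, v.spacing, v.modality)
             for v in series.octa_volumes],
            series.oct_volumes,
        )
        a = ce.cov_volumetric(series).cov.data
        b = ce.cov_volumetric(scaled).cov.data
        assert np.allclose(a, b, atol=1e-12)
        pa = ce.protocol_b_cov(series, layers).data
        pb = ce.protocol_b_cov(scaled, layers).data
        assert np.allclose(pa, pb, atol=1e-12)

    def test_threshold_scales_with_intensity(self, motion_free_phantom):
        _, series, truth = motion_free_phantom
        raw = ce.cov_volumetric(series)
        est1 = ce.estimate_noise(raw.mean, truth.layers, delta=2.0)
        scaled = VolumeGrid(raw.mean.data * 3.0, raw.mean.spacing, Modality.OCTA)
        est3 = ce.estimate_noise(scaled, truth.layers, delta=6.0)
        assert np.allclose(est3.threshold, est1.threshold * 3.0)
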