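"""Staining-front segmentation, sphere approximation and decay fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cect.errors import ContractError, SegmentationError
from cect.kinetics import (
    StainThreshold,
    derive_stain_threshold,
    fit_penetration_decay,
    measure_volume,
    segment_stained,
    segment_tissue,
    segment_unstained_core,
    spherical_kinetics,
    volume_change_series,
)
from cect.volume import GrayVolume, Mask


def ball_mask(n, r, center=None):
    c = (n - 1) / 2 if center is None else center
    z, y, x = np.ogrid[0:n, 0:n, 0:n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= r**2


class TestSegmentTissue:
    def test_phantom_volume_within_2pct(self, stained_scene):
        v, man = stained_scene
        mask = segment_tissue(v, exclude_vois=list(man["reference_vois"].values()))
        measured = measure_volume(mask, v.voxel_size_um)
        assert abs(measured / man["v_entire_mm3"] - 1) < 0.02

    def test_two_blobs_keeps_larger(self):
        data = np.zeros((30, 30, 30), np.uint16)
        data[ball_mask(30, 8, 10)] = 40000
        data[25:28, 25:28, 25:28] = 40000
        v = GrayVolume(data, 6.0)
        m = segment_tissue(v, method="fixed", threshold=20000)
        assert m.voxel_count == int(ball_mask(30, 8, 10).sum())

    def test_all_background_errors(self):
        v = GrayVolume(np.zeros((8, 8, 8), np.uint16), 6.0)
        with pytest.raises(SegmentationError):
            segment_tissue(v, method="fixed", threshold=100)

    def test_holes_filled(self):
        data = np.zeros((24, 24, 24), np.uint16)
        shell = ball_mask(24, 9) & ~ball_mask(24, 4)
        data[shell] = 40000
        v = GrayVolume(data, 6.0)
        m = segment_tissue(v, method="fixed", threshold=20000)
        assert m.voxel_count == int(ball_mask(24, 9).sum())


class TestMeasureVolume:
    def test_count_times_voxel_volume(self):
        m = Mask(np.ones((10, 10, 10), bool))
        assert measure_volume(m, 10.0) == pytest.approx(0.001)
        assert measure_volume(Mask(np.zeros((5, 5, 5), bool)), 10.0) == 0.0

    def test_digitized_sphere_within_1pct(self):
        r = 20
        m = Mask(ball_mask(2 * r + 5, r))
        analytic = 4.0 / 3.0 * math.pi * r**3
        assert abs(m.voxel_count / analytic - 1) < 0.01


class TestStainThreshold:
    def test_constant_tissue(self):
        v = GrayVolume(np.full((8, 8, 8), 12345, np.uint16), 6.0)
        m = Mask(np.ones((8, 8, 8), bool))
        assert derive_stain_threshold(v, m).value == 12345

    def test_percentile_matches_sort_oracle(self, rng):
        data = rng.integers(0, 65536, (12, 12, 12)).astype(np.uint16)
        v = GrayVolume(data, 6.0)
        m = Mask(np.ones(v.shape, bool))
        thr = derive_stain_threshold(v, m, percentile=1.0)
        assert thr.value == pytest.approx(np.percentile(np.sort(data.ravel()), 1.0))

    def test_percentile_zero_is_minimum(self, rng):
        data = rng.integers(500, 60000, (8, 8, 8)).astype(np.uint16)
        v = GrayVolume(data, 6.0)
        thr = derive_stain_threshold(v, Mask(np.ones(v.shape, bool)), percentile=0.0)
        assert thr.value == data.min()

    def test_empty_tissue_rejected(self, ramp_volume):
        with pytest.raises(ContractError):
            derive_stain_threshold(ramp_volume, Mask(np.zeros(ramp_volume.shape, bool)))


class TestSegmentStained:
    def test_threshold_extremes(self, ramp_volume):
        tissue = Mask(np.ones(ramp_volume.shape, bool))
        all_st = segment_stained(ramp_volume, tissue, StainThreshold(0.0, 0))
        assert all_st.voxel_count == tissue.voxel_count
        none_st = segment_stained(ramp_volume, tissue, StainThreshold(70000.0, 0))
        assert none_st.voxel_count == 0

    def test_shell_phantom_core_volume(self, scene_spec):
        from cect.phantom import make_scene

        v, man = make_scene(scene_spec, 1.0)
        tissue = Mask(man["tissue_mask"])
        thr = StainThreshold(
            (man["compartment_grays"]["stained"] + man["compartment_grays"]["unstained"]) / 2,
            50.0,
        )
        core = segment_unstained_core(v, tissue, thr)
        v_u = measure_volume(core, v.voxel_size_um)
        assert abs(v_u / man["v_unstained_mm3"] - 1) < 0.03


class TestSphericalKinetics:
    def test_unit_sphere_fully_stained(self):
        sk = spherical_kinetics(4 * math.pi / 3, 0.0, 1.0)
        assert sk.r_entire_mm == pytest.approx(1.0, abs=1e-12)
        assert sk.penetration_depth_mm == pytest.approx(1.0, abs=1e-12)

    def test_nothing_stained(self):
        sk = spherical_kinetics(2.0, 2.0, 1.0)
        assert sk.penetration_depth_mm == pytest.approx(0.0, abs=1e-12)

    def test_two_to_one_radius(self):
        sk = spherical_kinetics(8 * 4 * math.pi / 3, 4 * math.pi / 3, 2.0)
        assert sk.r_entire_mm == pytest.approx(2.0, abs=1e-12)
        assert sk.r_unstained_mm == pytest.approx(1.0, abs=1e-12)
        assert sk.penetration_depth_mm == pytest.approx(1.0, abs=1e-12)

    def test_vu_above_ve_rejected(self):
        with pytest.raises(ContractError):
            spherical_kinetics(1.0, 2.0, 1.0)

    @settings(deadline=None, max_examples=100)
    @given(
        ve=st.floats(0.01, 100),
        frac=st.floats(0, 1),
    )
    def test_radius_round_trip_and_monotonicity(self, ve, frac):
        vu = ve * frac
        sk = spherical_kinetics(ve, vu, 1.0)
        # reconstruct volumes from radii
        assert 4 / 3 * math.pi * sk.r_entire_mm**3 == pytest.approx(ve, rel=1e-9)
        assert 4 / 3 * math.pi * sk.r_unstained_mm**3 == pytest.approx(vu, rel=1e-9)
        assert 0 <= sk.penetration_depth_mm <= sk.r_entire_mm + 1e-12
        # r_p decreases when V_u grows
        sk2 = spherical_kinetics(ve, min(ve, vu + 0.1 * ve), 1.0)
        assert sk2.penetration_depth_mm <= sk.penetration_depth_mm + 1e-12


class TestDecayFit:
    @staticmethod
    def curve(t, re, k):
        return re * (1 - np.exp(-k * np.asarray(t)))

    def test_noiseless_recovery(self):
        t = [1.0, 2.0, 4.0, 9.0]
        pts = list(zip(t, self.curve(t, 2.0, 0.5)))
        fit = fit_penetration_decay(pts)
        assert fit.converged
        assert fit.r_entire_mm == pytest.approx(2.0, abs=1e-6)
        assert fit.rate_per_day == pytest.approx(0.5, abs=1e-6)

    def test_fit_passes_through_origin(self):
        t = [1.0, 2.0, 4.0, 9.0]
        fit = fit_penetration_decay(list(zip(t, self.curve(t, 1.5, 0.8))))
        assert fit.predict(0.0) == 0.0

    def test_monte_carlo_median_error_below_5pct(self):
        rng = np.random.default_rng(2024)
        t = np.array([1.0, 2.0, 4.0, 9.0])
        truth = self.curve(t, 2.0, 0.5)
        errs = []
        for _ in range(200):
            noisy = truth + rng.normal(0, 0.05, t.shape)
            fit = fit_penetration_decay(list(zip(t, np.clip(noisy, 0, None))))
            errs.append(abs(fit.r_entire_mm - 2.0) / 2.0)
        assert np.median(errs) < 0.05

    def test_constant_depths_flagged(self):
        fit = fit_penetration_decay([(1.0, 1.2), (2.0, 1.2), (4.0, 1.2)])
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ContractError):
            fit_penetration_decay([(1.0, 0.5), (2.0, 0.8)])


class TestVolumeSeries:
    def test_constant_series_zero_change(self):
        vs = volume_change_series([(1, 5.0), (2, 5.0), (4, 5.0)])
        assert vs.relative_change_pct == (0.0, 0.0, 0.0)

    def test_doubling_is_plus_100(self):
        vs = volume_change_series([(1, 2.0), (9, 4.0)])
        assert vs.relative_change_pct[-1] == pytest.approx(100.0)

    def test_radius_factor_cubed(self):
        # a 1.07 radius scale is a 1.07^3 - 1 = +22.5 % volume change
        v0 = 3.0
        vs = volume_change_series([(1, v0), (9, v0 * 1.07**3)])
        assert vs.relative_change_pct[-1] == pytest.approx(22.5, abs=0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ContractError):
            volume_change_series([(1, 1.0), (2, 0.0)])
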