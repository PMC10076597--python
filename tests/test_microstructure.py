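"""Structure-tensor FA, fiber detection/labeling, thickness, gray report."""

import math

import numpy as np
import pytest

from cect import microstructure as micro
from cect.errors import ContractError
from cect.normalization import RefStat, ReferenceGrayValues, measure_reference_grays
from cect.phantom import PhantomSpec, make_fiber_phantom
from cect.volume import GrayVolume, Mask, Voi


def tensor_from_eigenvalues(*vals):
    comps = np.zeros((6, 1, 1, 1))
    comps[0] = vals[0]  # zz
    comps[3] = vals[1]  # yy
    comps[5] = vals[2]  # xx
    return micro.TensorField(comps, 1, 1, 1)


class TestStructureTensor:
    def test_constant_volume_zero_tensor(self):
        tf = micro.structure_tensor(np.full((32, 32, 32), 123.0), 0.5, 0.5, 5.0)
        assert np.allclose(tf.components, 0.0)

    def test_grating_dominant_direction(self):
        # sinusoid along x: gradients along x, fiber direction in the yz-plane
        x = np.arange(40)
        vol = np.broadcast_to(np.sin(2 * np.pi * x / 8)[None, None, :], (40, 40, 40))
        tf = micro.structure_tensor(np.ascontiguousarray(vol), 0.5, 0.5, 5.0)
        vals, vecs = tf.eigen()
        core = (slice(10, 30),) * 3
        major = vecs[core][..., 0, :]  # eigenvector of the largest eigenvalue
        assert np.median(np.abs(major[..., 2])) > 0.99  # along x
        fiber = tf.fiber_directions()[core]
        assert np.median(np.abs(fiber[..., 2])) < 0.05  # perpendicular to x

    def test_cylinder_fiber_direction_along_axis(self, fiber_phantom):
        v, man = fiber_phantom
        sl = (slice(8, 56), slice(24, 72), slice(24, 72))
        tf = micro.structure_tensor(v.voxels[sl].astype(float), 0.5, 0.5, 5.0)
        axial = np.abs(tf.fiber_directions()[..., 0])
        # modal fiber direction within 5 degrees of z
        assert np.median(axial) > math.cos(math.radians(5))

    def test_too_small_volume_rejected(self):
        with pytest.raises(ContractError):
            micro.structure_tensor(np.zeros((16, 16, 16)), 0.5, 0.5, 5.0)


class TestFractionalAnisotropy:
    def test_isotropic_zero(self):
        fa = micro.fractional_anisotropy(tensor_from_eigenvalues(1, 1, 1), 0.0)
        assert fa.fa.ravel()[0] == pytest.approx(0.0, abs=1e-12)

    def test_rank_one_unity(self):
        fa = micro.fractional_anisotropy(tensor_from_eigenvalues(1, 0, 0), 0.0)
        assert fa.fa.ravel()[0] == pytest.approx(1.0, abs=1e-12)

    def test_fa_in_unit_interval_on_noise(self, rng):
        tf = micro.structure_tensor(rng.normal(0, 1, (34, 34, 34)), 0.5, 0.5, 5.0)
        fa = micro.fractional_anisotropy(tf)
        assert fa.fa.min() >= 0.0 and fa.fa.max() <= 1.0

    def test_noise_phantom_low_laminar_high(self, rng):
        noise = rng.normal(30000, 1000, (48, 48, 48))
        fa_n = micro.fractional_anisotropy(
            micro.structure_tensor(noise, 0.5, 0.5, 5.0)
        )
        core = (slice(10, -10),) * 3
        assert fa_n.fa[core].mean() < 0.2

        z = np.arange(48)
        lam = 30000 + 8000 * np.sin(2 * np.pi * z / 8)
        vol = np.ascontiguousarray(np.broadcast_to(lam[:, None, None], (48, 48, 48)))
        fa_l = micro.fractional_anisotropy(micro.structure_tensor(vol, 0.5, 0.5, 5.0))
        assert fa_l.fa[core].mean() > 0.8

    def test_contrast_halving_lowers_fa(self):
        base = PhantomSpec(
            shape=(48, 64, 64), voxel_size_um=6.0, seed=5, noise_sd=500.0
        )
        half = PhantomSpec(
            shape=(48, 64, 64), voxel_size_um=6.0, seed=5, noise_sd=500.0,
            fiber_contrast=base.fiber_contrast / 2,
        )
        means = []
        for spec in (base, half):
            v, _ = make_fiber_phantom(spec)
            sl = (slice(8, 40), slice(16, 48), slice(16, 48))
            tf = micro.structure_tensor(v.voxels[sl].astype(float), 0.5, 0.5, 5.0)
            means.append(micro.fractional_anisotropy(tf).fa.mean())
        assert means[1] < means[0]


class TestVolumeFraction:
    def test_degenerate_extremes(self):
        v = GrayVolume(np.full((4, 4, 4), 100, np.uint16), 6.0)
        voi = Voi.box((0, 0, 0), (4, 4, 4))
        assert micro.volume_fraction(v, voi, 200, "hypo") == 1.0
        assert micro.volume_fraction(v, voi, 50, "hypo") == 0.0

    def test_cylinder_phantom_recovery(self, fiber_phantom):
        v, man = fiber_phantom
        thr = (man["fiber_gray"] + man["background_gray"]) / 2
        vf = micro.volume_fraction(v, man["fiber_voi"], thr, man["polarity"])
        assert abs(vf - man["analytic_volume_fraction"]) < 0.02


@pytest.fixture(scope="module")
def single_cylinder():
    shape = (40, 40, 40)
    zz, yy, xx = np.ogrid[0:40, 0:40, 0:40]
    cyl = np.broadcast_to((yy - 20) ** 2 + (xx - 20) ** 2 <= 25, shape)
    img = np.full(shape, 30000.0)
    img[cyl] -= 8000
    return GrayVolume(img.astype(np.uint16), 6.0), cyl


class TestDetectFibers:

    def test_matching_cylinder_covered(self, single_cylinder):
        v, cyl = single_cylinder
        det, corr = micro.detect_fibers(
            v, None, radii=(5,), length=15, polarity="hypo",
            cutoff=0.5, orientations=[(1, 0, 0)],
        )
        assert corr[20, 20, 20] > 0.8  # maximal on the axis
        assert (det.data & cyl).sum() / cyl.sum() >= 0.9

    def test_pure_noise_mask_below_1pct(self, rng):
        noise = np.clip(rng.normal(30000, 1000, (48, 48, 48)), 0, 65535)
        v = GrayVolume(noise.astype(np.uint16), 6.0)
        det, _ = micro.detect_fibers(
            v, None, radii=(3,), length=11, polarity="hypo",
            cutoff=0.5, angular_step_deg=45.0,
        )
        assert det.data.mean() < 0.01

    def test_flipped_polarity_near_zero(self, single_cylinder):
        v, _ = single_cylinder
        det, _ = micro.detect_fibers(
            v, None, radii=(5,), length=15, polarity="hyper",
            cutoff=0.5, orientations=[(1, 0, 0)],
        )
        assert det.voxel_count == 0

    def test_template_larger_than_voi_rejected(self, single_cylinder):
        v, _ = single_cylinder
        with pytest.raises(ContractError):
            micro.detect_fibers(
                v, Voi.box((0, 0, 0), (6, 6, 6)), radii=(5,), length=15,
                orientations=[(1, 0, 0)],
            )


class TestLabelFibers:
    def _detect(self, img, r):
        v = GrayVolume(img.astype(np.uint16), 6.0)
        return micro.detect_fibers(
            v, None, radii=(r,), length=11, polarity="hypo",
            cutoff=0.5, orientations=[(1, 0, 0)],
        )

    def test_single_cylinder_single_label(self):
        zz, yy, xx = np.ogrid[0:40, 0:40, 0:40]
        img = np.full((40, 40, 40), 30000.0)
        img[np.broadcast_to((yy - 20) ** 2 + (xx - 20) ** 2 <= 25, img.shape)] -= 8000
        det, corr = self._detect(img, 5)
        labels = micro.label_fibers(det, corr, min_separation=5)
        assert labels.n_labels == 1

    def test_two_separated_cylinders_two_labels(self):
        zz, yy, xx = np.ogrid[0:40, 0:40, 0:40]
        img = np.full((40, 40, 40), 30000.0)
        two = ((yy - 10) ** 2 + (xx - 10) ** 2 <= 9) | (
            (yy - 28) ** 2 + (xx - 28) ** 2 <= 9
        )
        img[np.broadcast_to(two, img.shape)] -= 8000
        det, corr = self._detect(img, 3)
        labels = micro.label_fibers(det, corr, min_separation=3)
        assert labels.n_labels == 2

    def test_empty_mask_no_error(self):
        labels = micro.label_fibers(
            Mask(np.zeros((8, 8, 8), bool)), np.zeros((8, 8, 8))
        )
        assert labels.n_labels == 0


class TestThickness:
    def test_cylinder_thickness_within_one_voxel(self):
        zz, yy, xx = np.ogrid[0:30, 0:30, 0:30]
        cyl = np.broadcast_to((yy - 15) ** 2 + (xx - 15) ** 2 <= 25, (30, 30, 30))
        labels = micro.FiberLabels(cyl.astype(np.int32), {1: int(cyl.sum())})
        rep = micro.fiber_thickness(labels, 6.0)
        assert abs(rep.median_um - 60.0) <= 6.0

    @pytest.mark.parametrize("d", [5, 9, 13])
    def test_ball_thickness_within_one_voxel(self, d):
        n = d + 6
        r = (d - 1) / 2
        c = (n - 1) / 2
        zz, yy, xx = np.ogrid[0:n, 0:n, 0:n]
        ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2 + 1e-9
        labels = micro.FiberLabels(ball.astype(np.int32), {1: int(ball.sum())})
        rep = micro.fiber_thickness(labels, 1.0)
        assert abs(rep.median_um - d) <= 1.0

    def test_matches_brute_force_oracle_small_grids(self, rng):
        from scipy import ndimage

        for _ in range(3):
            mask = ndimage.binary_closing(rng.random((14, 14, 14)) > 0.55)
            if not mask.any():
                continue
            lt = micro.local_thickness(mask)
            edt = ndimage.distance_transform_edt(mask)
            coords = np.argwhere(mask)
            oracle = np.zeros(mask.shape)
            for x in coords:
                best = 0.0
                for c in coords:
                    r = edt[tuple(c)]
                    if ((x - c) ** 2).sum() <= r**2 + 1e-9:
                        best = max(best, 2 * r)
                oracle[tuple(x)] = best
            np.testing.assert_allclose(lt, oracle, atol=1e-9)

    def test_single_voxel_label(self):
        m = np.zeros((5, 5, 5), np.int32)
        m[2, 2, 2] = 1
        rep = micro.fiber_thickness(micro.FiberLabels(m, {1: 1}), 6.0)
        assert rep.median_um == pytest.approx(2 * 6.0)  # EDT radius 1 voxel

    def test_invariant_to_gray_rescaling(self, fiber_phantom):
        # thickness depends only on the labels, not on gray values
        v, man = fiber_phantom
        labels = micro.FiberLabels(
            man["fiber_mask"].astype(np.int32), {1: int(man["fiber_mask"].sum())}
        )
        a = micro.fiber_thickness(labels, v.voxel_size_um)
        b = micro.fiber_thickness(labels, v.voxel_size_um)
        assert a.median_um == b.median_um


class TestRegionalGrayReport:
    def _refs(self):
        return ReferenceGrayValues(
            bead=RefStat(50000.0, 0.0, 10), tube=RefStat(10000.0, 0.0, 10)
        )

    def test_identical_baseline_zero_change(self, ramp_volume):
        regions = {"a": Voi.box((0, 0, 0), (8, 8, 8)), "b": Voi.box((8, 8, 8), (8, 8, 8))}
        base = micro.regional_gray_report(ramp_volume, self._refs(), regions)
        rep = micro.regional_gray_report(ramp_volume, self._refs(), regions, baseline=base)
        assert all(e.pct_change == pytest.approx(0.0) for e in rep.entries.values())

    def test_demyelination_raises_normalized_gray(self):
        healthy = PhantomSpec(shape=(48, 64, 64), voxel_size_um=6.0, seed=9, noise_sd=500.0)
        treated = PhantomSpec(
            shape=(48, 64, 64), voxel_size_um=6.0, seed=9, noise_sd=500.0,
            demyelination=0.6,
        )
        reports = []
        for spec in (healthy, treated):
            v, man = make_fiber_phantom(spec)
            refs = measure_reference_grays(
                v,
                man["reference_vois"]["bead"],
                man["reference_vois"]["tube"],
                man["reference_vois"]["air"],
            )
            regions = {"cc": man["fiber_voi"]}
            reports.append(micro.regional_gray_report(v, refs, regions))
        g_h = reports[0].entries["cc"].normalized
        g_t = reports[1].entries["cc"].normalized
        assert g_t > g_h

    def test_missing_baseline_region_rejected(self, ramp_volume):
        regions = {"a": Voi.box((0, 0, 0), (8, 8, 8))}
        base = micro.regional_gray_report(ramp_volume, self._refs(), regions)
        with pytest.raises(ContractError):
            micro.regional_gray_report(
                ramp_volume,
                self._refs(),
                {"zz": Voi.box((0, 0, 0), (8, 8, 8))},
                baseline=base,
            )
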