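import numpy as np
import pytest

from vsrdv.hemodynamics import (background_phase_correct, bland_altman,
                                make_roi_mask, pcmra, plane_quantify,
                                repeatability_coefficient)
from vsrdv.phantom import PlaneSpec
from vsrdv.recon import VelocityVolume


def _volume(vel, voxel_size=1.0, venc=110.0):
    mag = np.ones(vel.shape[1:])
    return VelocityVolume(velocity=np.asarray(vel, dtype=np.float64),
                          magnitude=mag, venc=venc, role="DV",
                          voxel_size_mm=voxel_size)


def _linear_field(shape, coeffs):
    nx, ny, nz = shape
    gx, gy, gz = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
                             np.linspace(-1, 1, nz), indexing="ij")
    a0, a1, a2, a3 = coeffs
    return a0 + a1 * gx + a2 * gy + a3 * gz


class TestBackgroundCorrection:
    SHAPE = (12, 10, 8)

    def _vol_with_offset(self, coeffs, nt=3):
        field = _linear_field(self.SHAPE, coeffs)
        vel = np.zeros((3, *self.SHAPE, nt))
        vel[0] = field[..., None]
        return _volume(vel)

    def test_recovers_planted_coefficients(self):
        vol = self._vol_with_offset((2.0, 0.4, -0.3, 0.7))
        static = np.ones(self.SHAPE, bool)
        out = background_phase_correct(vol, static)
        assert np.abs(out.velocity).max() < 1e-6

    def test_partial_static_coverage(self):
        vol = self._vol_with_offset((1.0, -0.5, 0.2, 0.1))
        static = np.zeros(self.SHAPE, bool)
        static[::2, 1::2, :] = True
        out = background_phase_correct(vol, static)
        assert np.abs(out.velocity).max() < 1e-6

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        vel = rng.normal(0, 3, (3, *self.SHAPE, 2))
        vol = _volume(vel)
        static = np.zeros(self.SHAPE, bool)
        static[2:8, 2:8, 2:6] = True
        once = background_phase_correct(vol, static)
        twice = background_phase_correct(once, static)
        assert np.allclose(once.velocity, twice.velocity, atol=1e-5)

    def test_zero_static_velocity_leaves_volume_unchanged(self):
        vel = np.zeros((3, *self.SHAPE, 2))
        vel[1, 5, 5, 3, :] = 40.0  # a "vessel" voxel outside the static mask
        static = np.ones(self.SHAPE, bool)
        static[5, 5, 3] = False
        out = background_phase_correct(_volume(vel), static)
        assert np.allclose(out.velocity, vel, atol=1e-9)

    def test_too_few_static_voxels_raises(self):
        vol = self._vol_with_offset((1, 0, 0, 0))
        static = np.zeros(self.SHAPE, bool)
        static[0, 0, 0] = True
        with pytest.raises(ValueError, match="static"):
            background_phase_correct(vol, static)

    def test_coplanar_static_raises(self):
        vol = self._vol_with_offset((1, 0, 0, 0))
        static = np.zeros(self.SHAPE, bool)
        static[:, :, 3] = True  # single plane: z coefficient unidentifiable
        with pytest.raises(ValueError, match="coplanar"):
            background_phase_correct(vol, static)


class TestPcmra:
    def test_static_tissue_is_zero(self):
        vel = np.zeros((3, 4, 4, 4, 3))
        out = pcmra(np.ones((4, 4, 4, 3)), _volume(vel))
        assert np.all(out == 0)

    def test_constant_speed(self):
        vel = np.zeros((3, 4, 4, 4, 3))
        vel[0] = 10.0
        out = pcmra(np.ones((4, 4, 4, 3)), _volume(vel))
        assert np.allclose(out, 10.0)

    def test_homogeneous_in_magnitude(self):
        rng = np.random.default_rng(0)
        vel = rng.normal(0, 5, (3, 4, 4, 4, 3))
        mag = rng.uniform(0.5, 1.0, (4, 4, 4, 3))
        assert np.allclose(pcmra(2 * mag, _volume(vel)),
                           2 * pcmra(mag, _volume(vel)))


class TestRoiMask:
    def _tube_map(self, radius=5.0):
        gx, gy = np.meshgrid(np.arange(24) - 12, np.arange(24) - 12,
                             indexing="ij")
        disk = (np.sqrt(gx**2 + gy**2) <= radius).astype(float)
        return np.repeat(disk[:, :, None], 16, axis=2)

    def test_erosion_shrinks_tube_radius(self):
        mask = make_roi_mask(self._tube_map(5.0), 0.5, erosion_voxels=2)
        radii = np.sqrt(((np.argwhere(mask[:, :, 8]) - 12) ** 2).sum(axis=1))
        assert 2.0 <= radii.max() <= 4.0  # radius-5 tube -> radius ~3

    def test_zero_erosion_is_pure_threshold(self):
        m = self._tube_map()
        assert np.array_equal(make_roi_mask(m, 0.5, 0), m >= 0.5)

    def test_flat_map_keeps_everything(self):
        flat = np.ones((6, 6, 6))
        assert make_roi_mask(flat, 0.99, 0).all()

    def test_min_component_removes_speckle(self):
        m = self._tube_map()
        m[0, 0, 0] = 1.0  # isolated bright voxel
        mask = make_roi_mask(m, 0.5, 0, min_component=10)
        assert not mask[0, 0, 0]

    def test_empty_after_erosion_raises(self):
        small = np.zeros((8, 8, 8))
        small[4, 4, 4] = 1.0
        with pytest.raises(ValueError, match="empty"):
            make_roi_mask(small, 0.5, erosion_voxels=2)


def _poiseuille_volume(n=48, voxel=0.5, radius=3.0, vmax=100.0, nt=2):
    """Straight tube along z through the grid center, exact parabolic flow."""
    c = (n / 2 - 0.5) * voxel
    x = np.arange(n) * voxel
    gx, gy = np.meshgrid(x - c, x - c, indexing="ij")
    r = np.sqrt(gx**2 + gy**2)
    prof = np.clip(1 - (r / radius) ** 2, 0, None) * vmax
    nz = 16
    vel = np.zeros((3, n, n, nz, nt))
    vel[2] = prof[:, :, None, None]
    # partial-volume occupancy: sub-voxel-accurate lumen boundary
    occ = np.clip((radius - r) / voxel + 0.5, 0.0, 1.0)
    lumen = np.repeat(occ[:, :, None], nz, axis=2)
    return _volume(vel, voxel_size=voxel), lumen, c


class TestPlaneQuantify:
    def test_poiseuille_mean_and_peak(self):
        vol, lumen, c = _poiseuille_volume(n=96, voxel=0.25)
        plane = PlaneSpec((c, c, 2.0), (0.0, 0.0, 1.0), 9.0, "tube")
        s = plane_quantify(vol, lumen, plane, pixel_mm=0.125)
        assert s.mean_ta == pytest.approx(50.0, rel=0.02)
        assert s.peak_ta == pytest.approx(100.0, rel=0.02)
        assert s.area_mm2 == pytest.approx(np.pi * 9.0, abs=1.5)

    def test_reversed_normal_negates(self):
        vol, lumen, c = _poiseuille_volume()
        up = plane_quantify(vol, lumen,
                            PlaneSpec((c, c, 4.0), (0, 0, 1.0), 9.0, "t"))
        dn = plane_quantify(vol, lumen,
                            PlaneSpec((c, c, 4.0), (0, 0, -1.0), 9.0, "t"))
        assert dn.mean_ta == pytest.approx(-up.mean_ta)
        assert dn.peak_ta == pytest.approx(-up.peak_ta)
        assert np.allclose(dn.mean_velocity, -up.mean_velocity)
        assert np.allclose(dn.peak_velocity, -up.peak_velocity)

    def test_convergence_with_resolution(self):
        errs = []
        for n, voxel in ((48, 0.5), (96, 0.25)):
            vol, lumen, c = _poiseuille_volume(n=n, voxel=voxel)
            plane = PlaneSpec((c, c, 8 * voxel), (0.0, 0.0, 1.0), 9.0, "tube")
            s = plane_quantify(vol, lumen, plane, pixel_mm=voxel / 2)
            errs.append(abs(s.mean_ta - 50.0))
        assert errs[1] < errs[0]

    def test_empty_intersection_raises(self):
        vol, lumen, c = _poiseuille_volume()
        far = PlaneSpec((1.0, 1.0, 4.0), (0.0, 0.0, 1.0), 1.0, "t")
        with pytest.raises(ValueError, match="lumen"):
            plane_quantify(vol, lumen, far)


class TestBlandAltman:
    def test_identity_pair(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = bland_altman(x, x)
        assert res.bias == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_hand_computed_example(self):
        ref = np.array([10.0, 10.0, 10.0, 10.0])
        test = ref + np.array([1.0, -1.0, 2.0, 0.0])
        res = bland_altman(ref, test)
        sd = np.sqrt(5.0 / 3.0)
        assert res.bias == pytest.approx(0.5, abs=1e-9)
        assert res.loa_lower == pytest.approx(0.5 - 1.96 * sd, abs=1e-9)
        assert res.loa_upper == pytest.approx(0.5 + 1.96 * sd, abs=1e-9)
        assert res.bias_pct_ref == pytest.approx(5.0, abs=1e-9)

    def test_constant_offset(self):
        x = np.array([3.0, 5.0, 9.0])
        res = bland_altman(x, x + 2.0)
        assert res.bias == pytest.approx(2.0)
        assert res.loa_upper - res.loa_lower == pytest.approx(0.0, abs=1e-9)

    def test_rejects_short_input(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestRepeatability:
    def test_identical_sessions(self):
        x = [4.0, 5.0, 6.0]
        assert repeatability_coefficient(x, x).rpc == 0.0

    def test_hand_computed_example(self):
        s1 = np.array([10.0, 10.0, 10.0, 10.0])
        s2 = s1 + np.array([1.0, -1.0, 1.0, -1.0])
        res = repeatability_coefficient(s1, s2)
        assert res.rpc == pytest.approx(1.96 * np.sqrt(4.0 / 3.0), abs=1e-9)
        assert res.rpc_pct_session1 == pytest.approx(
            100 * 1.96 * np.sqrt(4 / 3) / 10.0, abs=1e-9)

    def test_scales_linearly(self):
        rng = np.random.default_rng(2)
        s1 = rng.uniform(5, 10, 6)
        s2 = s1 + rng.normal(0, 1, 6)
        r1 = repeatability_coefficient(s1, s2).rpc
        r3 = repeatability_coefficient(3 * s1, 3 * s2).rpc
        assert r3 == pytest.approx(3 * r1)
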