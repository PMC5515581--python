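"""Ground-truth generators: geometry, symmetry, corruption model, determinism."""

import numpy as np
import pytest

import spherulescope as s
from spherulescope import phantom as ph
from spherulescope.align import rotate_volume
from spherulescope.symmetry import (
    angular_intensity_profile,
    crown_band_defaults,
    detect_symmetry_order,
    rotational_power_spectrum,
)

from conftest import correlation


class TestCrownGeometry:
    def test_rotational_autocorrelation_peaks_every_30_degrees(self, crown_map):
        """C12 teeth give rotational autocorrelation maxima at multiples of 30 deg."""
        zz, yy, xx = np.meshgrid(*[np.arange(48)] * 3, indexing="ij")
        c = 23.5
        inside = np.sqrt((yy - c) ** 2 + (xx - c) ** 2) < 22
        ref = crown_map.data[inside]

        def ac(theta):
            rot = rotate_volume(crown_map, [0, 0, theta], cval=0.0)
            return correlation(rot.data[inside], ref)

        for k in range(1, 4):
            assert ac(30.0 * k) > ac(30.0 * k - 12.0) + 0.02
            assert ac(30.0 * k) > ac(30.0 * k + 12.0) + 0.02

    def test_c12_rotation_invariance_within_support(self, crown_map):
        rot = rotate_volume(crown_map, [0, 0, 30], cval=0.0)
        zz, yy, xx = np.meshgrid(*[np.arange(48)] * 3, indexing="ij")
        c = 23.5
        inside = np.sqrt((yy - c) ** 2 + (xx - c) ** 2) < 22
        rms = np.sqrt(np.mean((rot.data - crown_map.data)[inside] ** 2))
        assert rms / crown_map.data[inside].std() < 0.08  # voxelization tolerance at 1 nm

    def test_single_tooth_gives_single_lobe(self):
        spec = s.CrownSpec(teeth_count=1)
        vol = s.make_crown_density(spec)
        rb, hb = crown_band_defaults(spec)
        prof = angular_intensity_profile(vol, rb, hb)
        spectrum = rotational_power_spectrum([prof])
        # dominant component is 1 (a single angular lobe)
        assert int(np.argmax(spectrum.mean_power[1:]) + 1) == 1

    def test_channel_core_empty_at_turret_midheight(self, crown_map):
        """The 11 nm channel is open: no density on-axis at mid-height."""
        c = 23  # box center voxel; mid-height of the turret
        core = crown_map.data[c, 22:26, 22:26]  # within ~2 nm of the axis
        assert core.max() < 1e-3 * crown_map.data.max()

    def test_box_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            s.make_crown_density(box_edge_vox=32)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            s.CrownSpec(channel_diameter_nm=20.0)  # channel wider than turret
        with pytest.raises(ValueError):
            s.CrownSpec(teeth_count=0)

    def test_generator_is_deterministic(self, crown_map):
        again = s.make_crown_density()
        assert np.array_equal(crown_map.data, again.data)


class TestMissingWedge:
    def test_mask_zeroes_wedge_region(self):
        vol = s.DensityVolume(np.random.default_rng(0).normal(size=(32, 32, 32)).astype(np.float32), 1.0)
        out = s.apply_missing_wedge(vol)
        f = np.fft.fftn(out.data)
        mask = s.missing_wedge_mask(out.data.shape)
        assert np.abs(f[~mask]).max() < 1e-6 * np.abs(f).max()

    def test_idempotent(self, crown_map):
        once = s.apply_missing_wedge(crown_map)
        twice = s.apply_missing_wedge(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-4)

    def test_full_tilt_range_is_identity(self, crown_map):
        tilt = s.TiltGeometry(-90.0, 90.0)
        out = s.apply_missing_wedge(crown_map, tilt)
        np.testing.assert_allclose(out.data, crown_map.data, atol=1e-5)

    def test_tilt_validation(self):
        with pytest.raises(ValueError):
            s.TiltGeometry(60, -60)
        with pytest.raises(ValueError):
            s.TiltGeometry(increment_deg=0)


class TestNoise:
    def test_snr_calibration(self, crown_map):
        wedged = s.apply_missing_wedge(crown_map)
        noise = ph.NoiseModel(snr=0.5, seed=3)
        noisy = ph.add_noise(wedged, noise)
        added = noisy.data - wedged.data
        support = np.abs(wedged.data) > 0.05 * np.abs(wedged.data).max()
        expected_sd = np.sqrt(np.var(wedged.data[support]) / 0.5)
        assert added.std() == pytest.approx(expected_sd, rel=0.02)

    def test_seeded_reproducibility(self, crown_map):
        a = ph.add_noise(crown_map, ph.NoiseModel(snr=1.0, seed=9))
        b = ph.add_noise(crown_map, ph.NoiseModel(snr=1.0, seed=9))
        assert np.array_equal(a.data, b.data)

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            ph.NoiseModel(snr=0.0)


class TestSpherulePhantom:
    def test_filament_confined_and_spaced(self, spherule_phantom):
        vol, truth = spherule_phantom
        center = truth.center_vox * vol.voxel_size_nm
        r = np.linalg.norm(truth.filament_path_nm - center, axis=1)
        # stays at least half a membrane + one filament radius inside
        assert r.max() <= truth.radius_nm - ph.MEMBRANE_THICKNESS_NM / 2 - ph.FILAMENT_RADIUS_NM + 1e-6
        from spherulescope.morphometry import interfilament_spacing

        spacing = interfilament_spacing(truth.filament_path_nm)
        assert 5.8 <= spacing <= 7.0  # target 6.4 nm +/- 10%

    def test_capacity_grows_with_radius(self):
        _, small = s.make_spherule_phantom(s.SpheruleSpec(radius_nm=15.0), seed=4)
        _, large = s.make_spherule_phantom(s.SpheruleSpec(radius_nm=25.0), seed=4)
        assert len(large.filament_path_nm) > len(small.filament_path_nm)

    def test_same_seed_identical(self):
        a, _ = s.make_spherule_phantom(seed=6, box_edge_vox=64)
        b, _ = s.make_spherule_phantom(seed=6, box_edge_vox=64)
        assert np.array_equal(a.data, b.data)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            s.make_spherule_phantom(seed=None)

    def test_spacing_unreachable_for_tiny_radius(self):
        with pytest.raises(ValueError, match="unreachable|stalled"):
            s.make_spherule_phantom(s.SpheruleSpec(radius_nm=8.0), seed=0)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            s.SpheruleSpec(radius_nm=5.0, neck_diameter_nm=11.0)


class TestTomogram:
    def test_identity_limit(self):
        """Full tilt range and no noise: the tomogram is the phantom sum."""
        vol, truth = s.make_spherule_phantom(s.SpheruleSpec(radius_nm=18.0), seed=2)
        center = np.array([d / 2 for d in vol.data.shape])
        tomo, pset = s.make_tomogram(
            [(vol, truth, center, 0.0)],
            tilt=s.TiltGeometry(-90.0, 90.0),
            noise=None,
            shape=vol.data.shape,
        )
        assert correlation(tomo.data, vol.data) > 0.99
        assert len(pset) == 1

    def test_wedge_region_suppressed(self):
        vol, truth = s.make_spherule_phantom(s.SpheruleSpec(radius_nm=15.0), seed=3)
        center = np.array([d / 2 for d in vol.data.shape])
        tomo, _ = s.make_tomogram([(vol, truth, center, 0.0)], noise=None, shape=vol.data.shape)
        f = np.fft.fftn(tomo.data)
        mask = s.missing_wedge_mask(tomo.data.shape)
        assert np.abs(f[~mask]).max() < 1e-5 * np.abs(f).max()

    def test_overlap_rejected(self):
        vol, truth = s.make_spherule_phantom(s.SpheruleSpec(radius_nm=15.0), seed=3)
        center = np.array([d / 2 for d in vol.data.shape])
        with pytest.raises(ValueError, match="overlap"):
            s.make_tomogram(
                [(vol, truth, center, 0.0), (vol, truth, center + 2.0, 90.0)],
                noise=None,
                shape=vol.data.shape,
            )

    def test_particle_ground_truth_positions(self):
        vol, truth = s.make_spherule_phantom(s.SpheruleSpec(radius_nm=15.0), seed=3)
        pos = np.array([30.0, 40.0, 50.0])
        tomo, pset = s.make_tomogram([(vol, truth, pos, 33.0)], noise=None, shape=(64, 80, 100))
        crown_off = truth.crown_center_vox - (np.array(vol.data.shape) - 1) / 2.0
        np.testing.assert_allclose(pset[0].position_vox, pos + crown_off, atol=1e-9)
        # an axial spin normalizes into the first+third euler angles jointly
        e = pset[0].true_euler_zyz_deg
        assert (e[0] + e[2]) % 360.0 == pytest.approx(33.0)
        assert e[1] == pytest.approx(0.0)


class TestVolumeMixtureSampler:
    def test_zero_sd_collapses_to_mean(self):
        draws = s.sample_volume_mixture([50_000.0], [0.0], [1.0], 20, seed=0)
        np.testing.assert_allclose(draws, 50_000.0)

    def test_law_of_large_numbers(self):
        means, sds, w = [12_000.0, 108_000.0], [2_400.0, 21_600.0], [0.5, 0.5]
        n = 10_000
        draws = s.sample_volume_mixture(means, sds, w, n, seed=1)
        mix_mean = 60_000.0
        mix_var = 0.5 * (sds[0] ** 2 + sds[1] ** 2) + 0.5 * (12_000.0**2 + 108_000.0**2) - mix_mean**2
        se = np.sqrt(mix_var / n)
        assert abs(draws.mean() - mix_mean) < 3 * se

    def test_reproducible_and_positive(self):
        a = s.sample_volume_mixture([1000.0], [5000.0], [1.0], 200, seed=2)
        b = s.sample_volume_mixture([1000.0], [5000.0], [1.0], 200, seed=2)
        assert np.array_equal(a, b)
        assert np.all(a > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="weights"):
            s.sample_volume_mixture([1.0, 2.0], [0.1, 0.1], [0.6, 0.6], 5, seed=0)
        with pytest.raises(ValueError, match="n must be"):
            s.sample_volume_mixture([1.0], [0.1], [1.0], 0, seed=0)
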