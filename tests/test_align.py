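"""Subtomogram extraction, rotation kernel, scoring and iterative refinement."""

import numpy as np
import pytest

import spherulescope as s
import spherulescope.volumes as V
from spherulescope.align import (
    AlignmentConfig,
    PlanarMembrane,
    _perturbation_rotations,
    align_iterate,
    angular_difference_deg,
    cone_directions,
    extract_subtomogram,
    initial_orientations_from_normals,
    rotate_volume,
    score_pose,
    search_best_pose,
)
from spherulescope.volumes import Particle, ParticleSet

from conftest import SMALL_CROWN, correlation


class TestExtract:
    def test_center_voxel_preserved(self, blob_volume):
        p = Particle([15.5, 15.5, 15.5], [0, 0, 0])
        sub = extract_subtomogram(blob_volume, p, 16)
        c_in = blob_volume.data[16, 16, 16]
        assert sub.data[8, 8, 8] == pytest.approx(c_in)

    def test_corner_with_padding_fills_mean(self, blob_volume):
        p = Particle([1.0, 1.0, 1.0], [0, 0, 0])
        sub = extract_subtomogram(blob_volume, p, 16, pad=True)
        assert sub.data[0, 0, 0] == pytest.approx(float(blob_volume.data.mean()))

    def test_out_of_bounds_without_padding_rejected(self, blob_volume):
        p = Particle([1.0, 1.0, 1.0], [0, 0, 0])
        with pytest.raises(ValueError, match="pad"):
            extract_subtomogram(blob_volume, p, 16)

    def test_crown_boxes_carry_signal_above_background(self):
        """Boxed crowns from a synthetic stack stand out from the background."""
        subs, _ = s.make_crown_particle_stack(n_particles=5, snr=1.0, seed=0)
        for sub in subs:
            center_mean = sub.data[16:32, 16:32, 16:32].mean()
            assert center_mean > sub.data.mean() + 0.02


class TestInitialOrientations:
    def test_flat_membrane_gives_identity(self):
        pset = ParticleSet([Particle([10, 10, 10], [90, 90, 90])])
        out = initial_orientations_from_normals(pset, PlanarMembrane([10, 0, 0], [0, 0, 1]))
        np.testing.assert_allclose(out[0].euler_zyz_deg[:2], [0, 0], atol=1e-9)

    def test_membrane_tilted_30deg_about_y(self):
        normal = [np.sin(np.deg2rad(30.0)), 0.0, np.cos(np.deg2rad(30.0))]
        pset = ParticleSet([Particle([10, 10, 10], [0, 0, 0])])
        out = initial_orientations_from_normals(pset, PlanarMembrane([10, 0, 0], normal))
        assert out[0].euler_zyz_deg[1] == pytest.approx(30.0, abs=1.0)
        # the rotation carries +z onto the normal
        z_rot = V.euler_to_matrix(out[0].euler_zyz_deg) @ [0, 0, 1]
        np.testing.assert_allclose(z_rot, normal, atol=1e-9)

    def test_far_particle_flagged_not_reoriented(self):
        pset = ParticleSet([Particle([200, 10, 10], [5, 5, 5])])
        out = initial_orientations_from_normals(pset, PlanarMembrane([10, 0, 0], [0, 0, 1]))
        np.testing.assert_allclose(out[0].euler_zyz_deg, [5, 5, 5], atol=1e-9)
        assert "[0]" in out.provenance[-1]

    def test_synthetic_stack_normals_within_2deg(self):
        """Membrane-normal initialization starts within ~2 deg of truth."""
        _, pset = s.make_crown_particle_stack(n_particles=20, snr=None, seed=5, tilt_jitter_deg=2.0)
        errors = []
        for p in pset:
            z_true = V.euler_to_matrix(p.true_euler_zyz_deg) @ [0, 0, 1]
            z_init = V.euler_to_matrix(p.euler_zyz_deg) @ [0, 0, 1]
            errors.append(np.degrees(np.arccos(np.clip(np.dot(z_true, z_init), -1, 1))))
        assert np.median(errors) <= 2.0


class TestRotation:
    def test_identity(self, blob_volume):
        out = rotate_volume(blob_volume, [0, 0, 0])
        np.testing.assert_allclose(out.data, blob_volume.data, atol=1e-5)

    def test_90deg_rotation_moves_axis_aligned_bar(self):
        data = np.zeros((17, 17, 17), np.float32)
        data[8, 8, 4:13] = 1.0  # bar along x
        vol = s.DensityVolume(data, 1.0)
        out = rotate_volume(vol, [90, 0, 0], cval=0.0)  # 90 deg about z
        np.testing.assert_allclose(out.data[8, 4:13, 8], 1.0, atol=1e-5)  # now along y
        assert out.data[8, 8, 4:13].sum() == pytest.approx(1.0, abs=0.1)  # only center voxel remains

    def test_forward_then_inverse_keeps_correlation(self, blob_volume):
        euler = [25.0, 40.0, 10.0]
        fwd = rotate_volume(blob_volume, euler, cval=0.0)
        R_inv = V.euler_to_matrix(euler).T
        back = rotate_volume(fwd, V.matrix_to_euler(R_inv), cval=0.0)
        assert correlation(back.data, blob_volume.data) >= 0.98


class TestScoring:
    def test_self_score_is_one(self, blob_volume):
        assert score_pose(blob_volume, blob_volume, [0, 0, 0]) == pytest.approx(1.0, abs=1e-6)

    def test_negation_scores_minus_one(self, blob_volume):
        neg = s.DensityVolume(-blob_volume.data, 1.0)
        assert score_pose(blob_volume, neg, [0, 0, 0]) == pytest.approx(-1.0, abs=1e-6)

    def test_affine_intensity_invariance(self, blob_volume):
        scaled = s.DensityVolume(3.0 * blob_volume.data + 7.0, 1.0)
        a = score_pose(blob_volume, blob_volume, [10, 5, 0])
        b = score_pose(scaled, blob_volume, [10, 5, 0])
        assert a == pytest.approx(b, abs=1e-5)

    def test_zero_variance_rejected(self, blob_volume):
        flat = s.DensityVolume(np.ones((32, 32, 32), np.float32), 1.0)
        with pytest.raises(ValueError, match="zero-variance"):
            score_pose(flat, blob_volume, [0, 0, 0])

    def test_posed_copy_scores_one(self, blob_volume):
        euler = [40.0, 15.0, 120.0]
        posed = rotate_volume(blob_volume, euler, cval=0.0)
        assert score_pose(posed, blob_volume, euler) == pytest.approx(1.0, abs=1e-4)


class TestSearchOracle:
    def test_hierarchical_search_matches_exhaustive_scoring(self, blob_volume):
        """The fast batched search equals a brute-force score_pose sweep."""
        true_euler = [35.0, 12.0, 0.0]
        sub = rotate_volume(blob_volume, true_euler, cval=0.0)
        sub0 = sub.data - sub.data.mean()
        tmpl = blob_volume.data - blob_volume.data.mean()
        perts = _perturbation_rotations(20.0, 10.0, 0.0, 359.9, 10.0)
        w = np.ones((32, 32, 17), np.float32)
        w[0, 0, 0] = 0.0
        score, pi, shift = search_best_pose(sub0, tmpl, perts, w, 0.0)
        brute_best = (-2.0, None)
        for j, R in enumerate(perts):
            v = score_pose(
                s.DensityVolume(sub0, 1.0), s.DensityVolume(tmpl, 1.0), V.matrix_to_euler(R)
            )
            if v > brute_best[0] + 1e-12:
                brute_best = (v, j)
        assert pi == brute_best[1]
        assert score == pytest.approx(brute_best[0], abs=1e-4)
        np.testing.assert_allclose(shift, 0.0, atol=1e-9)

    def test_cone_directions_stay_in_cone(self):
        dirs = cone_directions(25.0, 5.0)
        assert np.all(dirs[:, 2] >= np.cos(np.deg2rad(25.0)) - 1e-9)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(dirs[0], [0, 0, 1], atol=1e-12)  # exact axis first


class TestAlignIterate:
    def _exact_copies(self, vol, eulers):
        subs, parts = [], []
        for i, e in enumerate(eulers):
            subs.append(rotate_volume(vol, e, cval=0.0))
            parts.append(
                Particle([15.5] * 3, [0, 0, 0], half_set="A" if i % 2 == 0 else "B",
                         true_euler_zyz_deg=e)
            )
        return subs, ParticleSet(parts)

    def test_exact_copies_recovered_within_one_step(self, blob_volume):
        eulers = [[0, 0, 0], [20, 10, 0], [345, 14, 0], [130, 6, 0]]
        subs, pset = self._exact_copies(blob_volume, eulers)
        cfg = AlignmentConfig(
            box_edge_vox=32,
            cone_halfangle_schedule_deg=(20.0, 10.0),
            angular_step_schedule_deg=(10.0, 5.0),
            max_iterations=2,
            lowpass_nm=None,
            wedge_compensation=False,
            shift_limit_vox=2.0,
        )
        refined, _ = align_iterate(subs, pset, template=blob_volume, config=cfg)
        # recovered within one final angular step (plus grid-quantization slack)
        for p in refined:
            assert angular_difference_deg(p.euler_zyz_deg, p.true_euler_zyz_deg) <= 5.0 * 1.2

    def test_noiseless_identical_particles_reach_fixed_point(self, blob_volume):
        """Identical unrotated particles: the average reproduces the template."""
        from spherulescope.align import _apodization_window

        subs, pset = self._exact_copies(blob_volume, [[0, 0, 0]] * 4)
        cfg = AlignmentConfig(
            box_edge_vox=32,
            cone_halfangle_schedule_deg=(10.0,),
            angular_step_schedule_deg=(5.0,),
            max_iterations=1,
            lowpass_nm=None,
            wedge_compensation=False,
            shift_limit_vox=1.0,
        )
        refined, avg = align_iterate(subs, pset, template=blob_volume, config=cfg)
        expected = (blob_volume.data - blob_volume.data.mean()) * _apodization_window(32)
        assert correlation(avg.map.data, expected) >= 0.999
        assert all(p.score >= 0.99 for p in refined)

    def test_shift_never_exceeds_limit(self, blob_volume):
        rng = np.random.default_rng(2)
        subs, parts = [], []
        for i in range(4):
            shift = rng.integers(-2, 3, size=3).astype(float)
            rolled = np.roll(blob_volume.data, shift.astype(int), axis=(0, 1, 2))
            subs.append(s.DensityVolume(rolled, 1.0))
            parts.append(Particle([15.5] * 3, [0, 0, 0], half_set="AB"[i % 2]))
        cfg = AlignmentConfig(
            box_edge_vox=32,
            cone_halfangle_schedule_deg=(5.0,),
            angular_step_schedule_deg=(5.0,),
            max_iterations=1,
            lowpass_nm=None,
            wedge_compensation=False,
            shift_limit_vox=3.0,
        )
        refined, _ = align_iterate(subs, ParticleSet(parts), template=blob_volume, config=cfg)
        for p, q in zip(refined, parts):
            assert np.linalg.norm(p.position_vox - q.position_vox) <= 3.0 + 1e-6

    def test_empty_and_mismatched_inputs_rejected(self, blob_volume):
        with pytest.raises(ValueError):
            align_iterate([], ParticleSet([]), config=AlignmentConfig(box_edge_vox=32))
        small = s.DensityVolume(np.zeros((16, 16, 16), np.float32), 1.0)
        with pytest.raises(ValueError, match="template"):
            align_iterate(
                [blob_volume],
                ParticleSet([Particle([15.5] * 3, [0, 0, 0], half_set="A")]),
                template=small,
                config=AlignmentConfig(box_edge_vox=32, gold_standard=False),
            )

    def test_config_validation(self):
        with pytest.raises(ValueError, match="non-increasing"):
            AlignmentConfig(cone_halfangle_schedule_deg=(10.0, 20.0),
                            angular_step_schedule_deg=(5.0, 5.0))
        with pytest.raises(ValueError, match="equal length"):
            AlignmentConfig(cone_halfangle_schedule_deg=(10.0,),
                            angular_step_schedule_deg=(5.0, 2.0))


class TestNoImposedSymmetry:
    def test_average_quality_nondecreasing_on_phantoms(self):
        """Refinement does not degrade the average on noisy crown data."""
        subs, pset = s.make_crown_particle_stack(
            SMALL_CROWN, n_particles=12, snr=1.0, box_edge_vox=32, seed=7
        )
        cfg = AlignmentConfig(
            box_edge_vox=32,
            cone_halfangle_schedule_deg=(20.0, 10.0),
            angular_step_schedule_deg=(15.0, 7.5),
            max_iterations=2,
        )
        _, avg = align_iterate(subs, pset, config=cfg)
        scores = [rec["mean_score"] for rec in avg.iteration_log]
        assert scores[-1] >= scores[0] - 0.02  # within noise tolerance
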