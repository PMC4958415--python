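import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ctrsa import (
    DetectionParams,
    MarkerSet,
    PhantomConfig,
    RigidTransform,
    detect_beads,
    label_markers,
    make_phantom_markers,
    refine_centroid,
    render_ct,
)
from ctrsa.errors import DetectionError, LabellingError, RefinementError, ValidationError
from ctrsa.volume import VoxelVolume
from conftest import single_bead_config


def _render_noiseless(config=None):
    config = config or single_bead_config(noise_sd=0.0)
    pelvis, cup = make_phantom_markers(config)
    volume = render_ct(pelvis, cup, RigidTransform.identity(), config)
    truth = np.vstack([pelvis.coords, cup.coords])
    return volume, truth, config


def _match_errors(found, truth):
    dists = np.linalg.norm(found[:, None, :] - truth[None, :, :], axis=2)
    return dists.min(axis=1)


class TestDetectBeads:
    def test_noiseless_phantom_all_beads_within_half_voxel(self):
        volume, truth, config = _render_noiseless()
        found = detect_beads(volume)
        assert len(found) == len(truth)
        assert _match_errors(found, truth).max() < 0.5 * max(config.spacing)

    def test_candidate_count_stable_under_default_noise(self):
        """No spurious or lost components at the default threshold, across seeds."""
        for seed in range(8):
            config = single_bead_config(seed=seed)
            volume, truth, _ = _render_noiseless(config)
            assert len(detect_beads(volume)) == len(truth)

    def test_background_only_volume_raises_with_diagnostics(self, rng):
        volume = VoxelVolume(
            100.0 + rng.normal(0, 20, size=(30, 30, 30)).astype(np.float32),
            (0.6, 0.6, 0.3),
        )
        with pytest.raises(DetectionError, match="threshold"):
            detect_beads(volume)

    def test_param_validation(self):
        with pytest.raises(ValidationError):
            DetectionParams(min_voxels=10, max_voxels=5)


class TestRefineCentroid:
    def test_symmetric_bead_on_voxel_center(self):
        """A bead centred exactly on a voxel centre refines to that centre."""
        config = single_bead_config(noise_sd=0.0)
        origin = np.array([-13.2, -13.2, -6.6])
        center = np.zeros(3)  # centre of voxel (22, 22, 22)
        bead = MarkerSet("cup", ["c1", "c2", "c3"],
                         np.array([center, [10, 0, 0], [-10, 0, 0]]))
        pelvis = MarkerSet("pelvis", ["p1", "p2", "p3"],
                           np.array([[0, 10, 0], [0, -10, 0], [10, 10, 0]]))
        volume = render_ct(pelvis, bead, RigidTransform.identity(), config,
                           origin=origin, shape=(45, 45, 45))
        refined = refine_centroid(volume, center + 0.1)
        np.testing.assert_allclose(refined, center, atol=1e-6)

    def test_subvoxel_offsets_recovered(self):
        """Beads at arbitrary subvoxel positions refine to < 0.05 mm (noiseless)."""
        config = single_bead_config(noise_sd=0.0)
        offsets = [
            np.array([0.3, 0.3, 0.15]),  # voxel corner
            np.array([0.17, -0.05, 0.08]),
            np.array([-0.21, 0.29, -0.11]),
        ]
        for off in offsets:
            center = off
            others = np.array([[14, 0, 0], [0, 14, 0]])
            cup = MarkerSet("cup", ["c1", "c2", "c3"], np.vstack([center, others]))
            pelvis = MarkerSet("pelvis", ["p1", "p2", "p3"],
                               np.array([[0, -14, 0], [-14, 0, 0], [-10, -10, 0]]))
            volume = render_ct(pelvis, cup, RigidTransform.identity(), config)
            refined = refine_centroid(volume, center + 0.2)
            assert np.linalg.norm(refined - center) < 0.05

    def test_monte_carlo_mean_error_under_noise(self):
        """Across noisy replicates the mean centroid error stays below 0.1 mm."""
        errors = []
        for seed in range(60):
            config = single_bead_config(seed=seed, n_pelvis_markers=3, n_cup_markers=3)
            rng = np.random.default_rng(seed)
            center = rng.uniform(-0.3, 0.3, 3)
            cup = MarkerSet("cup", ["c1", "c2", "c3"],
                            np.vstack([center, [[13, 0, 0], [0, 13, 0]]]))
            pelvis = MarkerSet("pelvis", ["p1", "p2", "p3"],
                               np.array([[0, -13, 0], [-13, 0, 0], [-9, -9, 0]]))
            volume = render_ct(pelvis, cup, RigidTransform.identity(), config,
                               noise_stream=seed)
            refined = refine_centroid(volume, center)
            errors.append(np.linalg.norm(refined - center))
        assert np.mean(errors) < 0.1

    def test_empty_window_raises(self, rng):
        volume = VoxelVolume(
            np.full((30, 30, 30), 100.0, dtype=np.float32), (0.6, 0.6, 0.3)
        )
        with pytest.raises(RefinementError):
            refine_centroid(volume, np.array([5.0, 5.0, 5.0]))


class TestLabelMarkers:
    def _template(self, rng, n=9):
        coords = rng.uniform(-30, 30, size=(n, 3))
        return MarkerSet("pelvis", [f"p{k:02d}" for k in range(n)], coords)

    def test_identity_labelling(self, rng):
        template = self._template(rng)
        result = label_markers(template.coords, template)
        assert result.markers.ids == template.ids
        assert result.missing == ()
        np.testing.assert_allclose(result.markers.coords, template.coords)

    def test_displaced_template_fully_recovered(self, rng):
        """15 mm + 5 degrees of rigid displacement does not confuse labelling."""
        template = self._template(rng)
        motion = RigidTransform(
            Rotation.from_euler("XYZ", [5, -3, 4], degrees=True).as_matrix(),
            np.array([15.0, -8.0, 5.0]),
        )
        candidates = motion.apply(template.coords)
        perm = rng.permutation(len(candidates))
        result = label_markers(candidates[perm], template)
        assert result.missing == ()
        for marker_id, coord in zip(result.markers.ids, result.markers.coords):
            truth = motion.apply(template.coords[template.ids.index(marker_id)])
            assert np.linalg.norm(coord - truth) < 1e-6

    def test_large_pose_with_outliers_from_other_body(self, rng):
        """Labelling tolerates the other rigid body's beads as outliers."""
        config = PhantomConfig(seed=11)
        pelvis, cup = make_phantom_markers(config)
        pose = RigidTransform(
            Rotation.from_euler("XYZ", [9, -7, 6], degrees=True).as_matrix(),
            np.array([-18.0, 12.0, 15.0]),
        )
        candidates = np.vstack([pose.apply(cup.coords), pose.apply(pelvis.coords)])
        result = label_markers(candidates, pelvis)
        assert result.missing == ()
        assert len(result.unmatched) == len(cup)
        np.testing.assert_allclose(
            result.transform.rotation, pose.rotation, atol=1e-6
        )

    def test_missing_bead_reported(self, rng):
        template = self._template(rng)
        candidates = template.coords[1:]  # first bead occluded
        result = label_markers(candidates, template)
        assert result.missing == (template.ids[0],)
        assert len(result.markers) == len(template) - 1

    def test_order_invariance(self, rng):
        template = self._template(rng)
        candidates = template.coords + rng.normal(0, 0.02, (len(template), 3))
        a = label_markers(candidates, template)
        b = label_markers(candidates[::-1], template)
        assert a.markers.ids == b.markers.ids
        np.testing.assert_allclose(
            a.markers.coords, b.markers.coords, atol=1e-12
        )

    def test_ambiguous_assignment_raises(self):
        template = MarkerSet(
            "pelvis", ["a", "b", "c", "d"],
            np.array([[0, 0, 0], [20, 0, 0], [0, 20, 0], [0.4, 0.0, 0.0]], float),
        )
        # candidates: one bead serving two nearby template ids
        candidates = np.array([[0.2, 0, 0], [20, 0, 0], [0, 20, 0]], float)
        with pytest.raises(LabellingError, match="match candidate"):
            label_markers(candidates, template, prealigned=True, match_radius=1.0)

    def test_too_few_candidates(self):
        template = MarkerSet("pelvis", ["a", "b", "c"], np.eye(3) * 10)
        with pytest.raises(LabellingError):
            label_markers(np.zeros((2, 3)), template)
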