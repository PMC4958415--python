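import numpy as np
import pytest
from scipy.spatial.distance import pdist

from ctrsa import (
    JigSetting,
    PhantomConfig,
    RigidTransform,
    apply_jig,
    build_study,
    make_phantom_markers,
    render_ct,
)
from ctrsa.errors import ConfigurationError, GeometryError
from conftest import single_bead_config


class TestMarkers:
    def test_cemented_marker_counts(self):
        pelvis, cup = make_phantom_markers(PhantomConfig(cup_type="cemented"))
        assert (len(pelvis), len(cup)) == (9, 9)

    def test_uncemented_marker_counts(self):
        pelvis, cup = make_phantom_markers(PhantomConfig(cup_type="uncemented"))
        assert (len(pelvis), len(cup)) == (9, 12)

    def test_seed_determinism(self):
        a = make_phantom_markers(PhantomConfig(seed=42))
        b = make_phantom_markers(PhantomConfig(seed=42))
        np.testing.assert_array_equal(a[0].coords, b[0].coords)
        np.testing.assert_array_equal(a[1].coords, b[1].coords)

    def test_pelvis_scatter_and_separation(self, default_config):
        pelvis, cup = make_phantom_markers(default_config)
        center = np.asarray(default_config.pelvis_center)
        half = np.asarray(default_config.pelvis_spread) / 2
        assert np.all(np.abs(pelvis.coords - center) <= half + 1e-9)
        assert pdist(pelvis.coords).min() >= default_config.min_marker_separation
        radii = np.linalg.norm(cup.coords - cup.centroid, axis=1)
        np.testing.assert_allclose(radii, default_config.cup_radius, atol=1e-9)

    def test_too_few_markers_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(n_pelvis_markers=2)


class TestJig:
    def test_pure_translation(self, default_config):
        _, cup = make_phantom_markers(default_config)
        moved = apply_jig(cup, JigSetting(dx=1.0))
        np.testing.assert_allclose(moved.coords - cup.coords, [[1.0, 0, 0]] * len(cup))

    def test_identity_setting(self, default_config):
        _, cup = make_phantom_markers(default_config)
        np.testing.assert_array_equal(apply_jig(cup, JigSetting()).coords, cup.coords)

    def test_rigidity_preserves_pairwise_distances(self, default_config):
        _, cup = make_phantom_markers(default_config)
        moved = apply_jig(cup, JigSetting(0.5, -2.0, 1.0, 3.0))
        np.testing.assert_allclose(pdist(moved.coords), pdist(cup.coords), atol=1e-12)

    def test_rotation_composition(self, default_config):
        """Two 90-degree jig rotations equal a single 180-degree rotation."""
        _, cup = make_phantom_markers(default_config)
        twice = apply_jig(apply_jig(cup, JigSetting(rx=90.0)), JigSetting(rx=90.0))
        once = apply_jig(cup, JigSetting(rx=180.0))
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-9)

    def test_increment_grid_check(self):
        assert JigSetting(1.0, 2.0, 0.0, 3.0).on_increment_grid()
        assert not JigSetting(0.5, 0, 0, 0).on_increment_grid()


class TestStudyManifest:
    def test_structure_twelve_examinations(self, manifest):
        assert manifest.n_positions == 6
        keys = [(m, p, s) for (m, p, s) in manifest.poses if m == "CT"]
        assert len(keys) == 12  # 6 positions x 2 series per modality

    def test_series_share_cup_pose_but_not_phantom_pose(self, manifest):
        for p in (1, 4):
            assert manifest.cup_at(p) is not None
            pose1 = manifest.pose(p, 1, "CT")
            pose2 = manifest.pose(p, 2, "CT")
            assert not np.allclose(pose1.rotation, pose2.rotation)
            # cup relative to pelvis is identical within the position
            pel1, cup1 = manifest.exam_markers(p, 1)
            pel2, cup2 = manifest.exam_markers(p, 2)
            rel1 = cup1.coords - pel1.centroid
            rel2 = cup2.coords - pel2.centroid
            np.testing.assert_allclose(
                np.linalg.norm(rel1, axis=1), np.linalg.norm(rel2, axis=1), atol=1e-9
            )

    def test_within_position_truth_is_zero(self, manifest):
        gt = manifest.true_migration(3, 3)
        np.testing.assert_allclose(gt.translations, 0, atol=1e-12)
        np.testing.assert_allclose(gt.rotations, 0, atol=1e-12)

    def test_ground_truth_equals_composed_jig_settings(self, manifest):
        for (p, q), gt in manifest.ground_truth.items():
            sp, sq = manifest.positions[p - 1], manifest.positions[q - 1]
            np.testing.assert_allclose(
                gt.translations, [sq.dx - sp.dx, sq.dy - sp.dy, sq.dz - sp.dz], atol=1e-9
            )
            np.testing.assert_allclose(gt.rotations, [sq.rx - sp.rx, 0, 0], atol=1e-9)

    def test_manifest_determinism_and_serialization(self, default_config, manifest):
        again = build_study(default_config)
        np.testing.assert_array_equal(
            again.pose(2, 1, "CT").rotation, manifest.pose(2, 1, "CT").rotation
        )
        back = type(manifest).from_dict(manifest.to_dict())
        np.testing.assert_allclose(back.pelvis.coords, manifest.pelvis.coords)
        np.testing.assert_allclose(
            back.pose(5, 2, "RSA").translation, manifest.pose(5, 2, "RSA").translation
        )


class TestRenderCT:
    def test_bead_center_voxel_value(self):
        """Noiseless, unblurred: the voxel holding a bead centre scores at least
        bead_intensity times its overlap fraction."""
        config = single_bead_config(noise_sd=0.0, blur_sigma=0.0)
        pelvis, cup = make_phantom_markers(config)
        volume = render_ct(pelvis, cup, RigidTransform.identity(), config)
        voxel_volume = np.prod(config.spacing)
        sphere_volume = 4 / 3 * np.pi * (config.bead_diameter / 2) ** 3
        for center in np.vstack([pelvis.coords, cup.coords]):
            idx = np.round(volume.world_to_voxel(center)).astype(int)
            value = volume.data[tuple(idx)]
            overlap = min(sphere_volume / voxel_volume, 1.0)
            assert value >= config.background_intensity
            assert value <= config.bead_intensity + 1e-3

    def test_integrated_signal_matches_sphere_volume(self):
        """Conservation: sum(volume - background) ~= intensity * V_sphere / V_voxel."""
        config = single_bead_config(
            noise_sd=0.0, background_intensity=0.0, n_pelvis_markers=3, n_cup_markers=3
        )
        pelvis, cup = make_phantom_markers(config)
        volume = render_ct(pelvis, cup, RigidTransform.identity(), config)
        total = float(volume.data.sum())
        sphere_voxels = 4 / 3 * np.pi * (config.bead_diameter / 2) ** 3 / np.prod(config.spacing)
        expected = 6 * config.bead_intensity * sphere_voxels
        assert total == pytest.approx(expected, rel=0.02)

    def test_render_determinism(self, default_config):
        pelvis, cup = make_phantom_markers(default_config)
        a = render_ct(pelvis, cup, RigidTransform.identity(), default_config)
        b = render_ct(pelvis, cup, RigidTransform.identity(), default_config)
        np.testing.assert_array_equal(a.data, b.data)

    def test_translation_equivariance(self):
        """Shifting the phantom by one voxel shifts the noiseless image by one voxel."""
        config = single_bead_config(noise_sd=0.0, spacing=(0.5, 0.5, 0.25))
        pelvis, cup = make_phantom_markers(config)
        origin = np.array([-40.0, -40.0, -64.0])
        shape = (170, 170, 520)
        base = render_ct(pelvis, cup, RigidTransform.identity(), config, origin, shape)
        shift = RigidTransform(np.eye(3), np.array(config.spacing))
        moved = render_ct(pelvis, cup, shift, config, origin, shape)
        np.testing.assert_allclose(
            moved.data[1:, 1:, 1:], base.data[:-1, :-1, :-1], atol=1e-9
        )

    def test_marker_outside_fov_raises(self, default_config):
        pelvis, cup = make_phantom_markers(default_config)
        with pytest.raises(GeometryError, match="p0"):
            render_ct(
                pelvis,
                cup,
                RigidTransform.identity(),
                default_config,
                origin=np.array([0.0, 0.0, 0.0]),
                shape=(40, 40, 40),
            )
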