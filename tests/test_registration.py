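import numpy as np
import pytest
import trimesh

from earmorph import (
    PointCloud,
    RigidTransform,
    TemplateMesh,
    bootstrap_correspondence,
    mesh_from_points,
    nonrigid_icp,
    rigid_icp,
)
from earmorph.errors import InvalidConfigError, InvalidInputError
from earmorph.registration import (
    procrustes_align,
    rigid_align_to_mesh,
    vertex_normals,
)
from earmorph.synthetic import _sample_surface


def rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestTemplateMesh:
    def test_topology_id_stable_under_vertex_change(self, template):
        moved = template.with_vertices(template.vertices + 1.0)
        assert moved.topology_id == template.topology_id

    def test_disconnected_mesh_rejected(self):
        verts = np.vstack([np.eye(3), np.eye(3) + 10.0])
        faces = np.array([[0, 1, 2], [3, 4, 5]])
        with pytest.raises(InvalidInputError):
            TemplateMesh(verts, faces)

    def test_face_index_bounds_checked(self):
        with pytest.raises(InvalidInputError):
            TemplateMesh(np.eye(3), np.array([[0, 1, 3]]))


class TestRigidIcp:
    def test_identity_input_zero_rmse(self, template):
        T, rmse = rigid_icp(template.vertices, template.vertices)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)

    def test_recovers_15_degree_transform(self, template):
        R, t = rot_z(15.0), np.array([4.0, -3.0, 2.0])
        target = template.vertices @ R.T + t
        T, rmse = rigid_icp(template.vertices, target)
        assert rmse < 1e-6
        np.testing.assert_allclose(T.rotation, R, atol=1e-4)
        np.testing.assert_allclose(T.translation, t, atol=1e-4)

    def test_robust_to_gross_outlier_points(self, template, rng):
        R, t = rot_z(10.0), np.array([1.0, 2.0, -1.0])
        target = template.vertices @ R.T + t
        n_out = int(0.05 * len(target))
        junk = rng.uniform(-200, 200, size=(n_out, 3))
        target_with_outliers = np.vstack([target, junk])
        T, _ = rigid_icp(template.vertices, target_with_outliers)
        assert np.abs(T.rotation - R).max() < 1e-3

    def test_final_rmse_not_worse_than_centroid_start(self, template, rng):
        jitter = template.vertices + rng.normal(0, 0.5, template.vertices.shape)
        from scipy.spatial import cKDTree

        tree = cKDTree(template.vertices)
        d0, _ = tree.query(jitter - jitter.mean(0) + template.vertices.mean(0))
        T, rmse = rigid_icp(jitter, template.vertices)
        assert rmse <= np.sqrt(np.mean(d0**2)) + 1e-9

    def test_max_iter_validated(self, template):
        with pytest.raises(InvalidConfigError):
            rigid_icp(template.vertices, template.vertices, max_iter=0)


class TestNonrigidIcp:
    def test_fixed_point_when_target_is_template_surface(self, template):
        out = nonrigid_icp(template, template.vertices)
        disp = np.linalg.norm(out.to_points() - template.vertices, axis=1)
        assert disp.max() < 1e-3 * template.bounding_box_diagonal()

    def test_sphere_inflation_reaches_target_radius(self):
        src = trimesh.creation.icosphere(subdivisions=2)
        tmpl = TemplateMesh(np.asarray(src.vertices), np.asarray(src.faces))
        target = np.asarray(trimesh.creation.icosphere(subdivisions=4).vertices) * 1.2
        out = nonrigid_icp(tmpl, target)
        radii = np.linalg.norm(out.to_points(), axis=1)
        assert np.abs(radii - 1.2).max() < 1e-2

    def test_topology_preserved(self, template, rng):
        target = template.vertices + rng.normal(0, 0.5, template.vertices.shape)
        out = nonrigid_icp(template, target)
        assert out.topology_id == template.topology_id
        assert out.n_vertices == template.n_vertices

    def test_vectorization_round_trip(self, template):
        out = nonrigid_icp(template, template.vertices)
        from earmorph import CorrespondedShape

        again = CorrespondedShape.from_points(out.to_points(), out.topology_id)
        np.testing.assert_array_equal(again.vector, out.vector)

    def test_non_decreasing_schedule_rejected(self, template):
        with pytest.raises(InvalidConfigError):
            nonrigid_icp(template, template.vertices, stiffness_schedule=[1.0, 2.0])
        with pytest.raises(InvalidConfigError):
            nonrigid_icp(template, template.vertices, stiffness_schedule=[])

    def test_mean_distance_to_clean_target_small(self, generator_model, template, rng):
        from earmorph import synthesize

        alpha = rng.normal(size=generator_model.d) * np.sqrt(generator_model.eigenvalues)
        surf = synthesize(generator_model, alpha).to_points()
        target = _sample_surface(surf, generator_model.faces, 2500, rng)
        out = nonrigid_icp(template, target)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(target).query(out.to_points())
        assert d.mean() < 0.02 * template.bounding_box_diagonal()


class TestMeshFromPoints:
    def test_builds_single_component_patch(self, template, rng):
        pts = _sample_surface(template.vertices, template.faces, 1500, rng)
        mesh = mesh_from_points(pts, target_size=200, seed=0)
        assert mesh.n_vertices == 200
        assert mesh.faces.shape[1] == 3  # construction validates connectivity


class TestProcrustesAlign:
    def test_removes_rigid_variance(self, template, rng):
        from earmorph import CorrespondedShape

        base = template.vertices
        shapes = []
        for _ in range(5):
            R = rot_z(float(rng.uniform(-20, 20)))
            t = rng.uniform(-5, 5, 3)
            shapes.append(CorrespondedShape.from_points(base @ R.T + t, template.topology_id))
        aligned = procrustes_align(shapes)
        ref = aligned[0].to_points()
        for s in aligned[1:]:
            assert np.abs(s.to_points() - ref).max() < 1e-6


class TestRigidAlignToMesh:
    def test_aligns_posed_sampling(self, template, rng):
        pts = _sample_surface(template.vertices, template.faces, 1500, rng)
        R, t = rot_z(25.0), np.array([10.0, -8.0, 5.0])
        T, aligned = rigid_align_to_mesh(pts @ R.T + t, template)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(aligned).query(template.vertices)
        assert np.sqrt(np.mean(d**2)) < 1.0  # sub-sample-spacing alignment


class TestBootstrapCorrespondence:
    def test_identical_scans_converge_to_that_shape(self, template, rng):
        pts = _sample_surface(template.vertices, template.faces, 900, rng)
        scans = [PointCloud(pts, label=f"s{i}") for i in range(3)]
        result = bootstrap_correspondence(scans, rounds=1, seed=0, template_size=150)
        vecs = np.array([s.vector for s in result.shapes])
        assert np.abs(vecs - vecs[0]).max() < 1e-6

    def test_fixed_seed_reproducible(self, template, rng):
        scans = [
            PointCloud(_sample_surface(template.vertices, template.faces, 700, rng), label=f"s{i}")
            for i in range(3)
        ]
        a = bootstrap_correspondence(scans, rounds=1, seed=7, template_size=120)
        b = bootstrap_correspondence(scans, rounds=1, seed=7, template_size=120)
        np.testing.assert_array_equal(a.template.vertices, b.template.vertices)
        for sa, sb in zip(a.shapes, b.shapes):
            np.testing.assert_array_equal(sa.vector, sb.vector)

    def test_recovers_population_mean(self, generator_model, rng):
        # scans from known shapes: the bootstrapped mean should approximate
        # the generating mean surface within a small fraction of its size
        from earmorph import PopulationConfig, sample_population, synthesize
        from scipy.spatial import cKDTree

        cfg = PopulationConfig(
            seed=9, n_subjects=6, samples_per_subject=2, points_per_scan=900,
            latent_dim=8, between_subject_sd=tuple(np.geomspace(4.0, 1.0, 8)),
            within_subject_noise_sd=0.0, pose_rotation_range=10.0,
            pose_translation_range=5.0,
        )
        ss = sample_population(cfg)
        result = bootstrap_correspondence(ss.all_scans, rounds=2, seed=9, template_size=180)
        diag = 65.0
        base_mesh = TemplateMesh(
            synthesize(ss.generator_model, np.zeros(ss.generator_model.d)).to_points(),
            ss.generator_model.faces,
        )
        # the bootstrapped template lives in the frame of the seed scan; align
        # rigidly before comparing against the generating surface
        _, aligned = rigid_align_to_mesh(result.template.vertices, base_mesh)
        dense = _sample_surface(base_mesh.vertices, base_mesh.faces, 20000, rng)
        d, _ = cKDTree(dense).query(aligned)
        assert d.mean() < 0.02 * diag

    def test_too_few_scans_rejected(self, template, rng):
        pts = _sample_surface(template.vertices, template.faces, 500, rng)
        with pytest.raises(InvalidInputError):
            bootstrap_correspondence([PointCloud(pts)], rounds=1)


class TestVertexNormals:
    def test_unit_length_and_outward_for_sphere(self):
        s = trimesh.creation.icosphere(subdivisions=2)
        n = vertex_normals(np.asarray(s.vertices), np.asarray(s.faces))
        np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-12)
        # outward: normal aligned with position on a centered sphere
        cos = np.sum(n * (s.vertices / np.linalg.norm(s.vertices, axis=1, keepdims=True)), axis=1)
        assert cos.min() > 0.9
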