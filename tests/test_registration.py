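"""Point-based (Kabsch) and surface (ICP) registration behavior."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from splintnav.geometry import (
    BL_IMAGE,
    Frame,
    FrameChainError,
    LandmarkSet,
    PATIENT,
    Transform,
    compose,
    invert,
)
from splintnav.registration import (
    ConfigurationError,
    SurfaceModel,
    closest_points_on_surface,
    fre,
    register_point_based,
    register_point_based_numeric,
    register_surface,
)
from splintnav.simulator import make_phantom

from conftest import random_rigid

IM = Frame("IM")


def lmset(coords, frame=PATIENT, labels=None):
    coords = np.atleast_2d(coords)
    return LandmarkSet(labels or [f"f{i}" for i in range(len(coords))], coords, frame)


@pytest.fixture()
def cloud(rng):
    return rng.normal(0, 40, (5, 3))


class TestPointBased:
    def test_identity_when_sets_equal(self, cloud):
        res = register_point_based(lmset(cloud), lmset(cloud))
        assert res.fre_mm < 1e-12
        assert np.abs(res.transform.matrix - np.eye(4)).max() < 1e-12
        assert res.iterations == 1

    def test_recovers_constructed_transform(self, rng, cloud):
        t = Transform.from_rotation_translation(
            Rotation.from_euler("z", 90, degrees=True).as_matrix(), (5, 0, 0),
            PATIENT, IM,
        )
        fixed = lmset(t.transform_points(cloud), frame=IM)
        res = register_point_based(lmset(cloud), fixed)
        assert np.abs(res.transform.matrix - t.matrix).max() < 1e-9
        assert res.fre_mm < 1e-9
        assert res.transform.to_frame == IM

    def test_two_points_rejected(self):
        with pytest.raises(ConfigurationError, match=">= 3"):
            register_point_based(lmset([(0, 0, 0), (1, 0, 0)]),
                                 lmset([(0, 0, 0), (1, 0, 0)]))

    def test_collinear_rejected(self):
        line = np.outer(np.arange(4.0), (1.0, 2.0, 0.5))
        with pytest.raises(ConfigurationError, match="collinear"):
            register_point_based(lmset(line), lmset(line))

    def test_label_mismatch_is_pairing_error(self, cloud):
        with pytest.raises(KeyError):
            register_point_based(
                lmset(cloud), lmset(cloud, labels=[f"g{i}" for i in range(5)])
            )

    def test_mirrored_input_yields_proper_rotation(self, cloud):
        mirrored = cloud * np.array([-1.0, 1.0, 1.0])
        res = register_point_based(lmset(cloud), lmset(mirrored))
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-12)

    def test_equivariance_under_common_rotation(self, rng, cloud):
        # noisy correspondence so the solution is non-trivial
        fixed = random_rigid(rng, PATIENT, PATIENT).transform_points(cloud)
        fixed = fixed + rng.normal(0, 1.0, cloud.shape)
        base = register_point_based(lmset(cloud), lmset(fixed))
        q = random_rigid(rng, PATIENT, PATIENT, trans_scale=0.0)
        # rotating both point sets by Q conjugates the solution: Q T Q^-1
        rot_both = register_point_based(
            lmset(q.transform_points(cloud)), lmset(q.transform_points(fixed))
        )
        conj = compose(compose(invert(q), base.transform), q)
        assert np.abs(rot_both.transform.matrix - conj.matrix).max() < 1e-8
        assert rot_both.fre_mm == pytest.approx(base.fre_mm, abs=1e-10)

    def test_agrees_with_numeric_minimizer(self, rng):
        for trial in range(5):
            n = int(rng.integers(3, 9))
            moving = rng.normal(0, 30, (n, 3))
            fixed = random_rigid(rng, PATIENT, IM).transform_points(moving)
            fixed = fixed + rng.normal(0, 0.5, fixed.shape)
            a = register_point_based(lmset(moving), lmset(fixed, frame=IM))
            b = register_point_based_numeric(
                lmset(moving), lmset(fixed, frame=IM), n_restarts=4, seed=trial
            )
            assert abs(a.fre_mm - b.fre_mm) < 1e-6
            assert np.linalg.det(a.transform.rotation) == pytest.approx(1.0, abs=1e-9)


class TestFre:
    def test_zero_for_perfect_fit(self, cloud):
        res = register_point_based(lmset(cloud), lmset(cloud))
        assert fre(res, lmset(cloud), lmset(cloud)) < 1e-12

    def test_matches_direct_formula(self, rng, cloud):
        fixed = cloud + rng.normal(0, 1.0, cloud.shape)
        res = register_point_based(lmset(cloud), lmset(fixed))
        resid = res.transform.transform_points(cloud) - fixed
        expected = np.sqrt(np.mean(np.sum(resid**2, axis=1)))
        assert fre(res, lmset(cloud), lmset(fixed)) == pytest.approx(expected)
        assert res.fre_mm == pytest.approx(expected)

    def test_invariant_to_label_order(self, rng, cloud):
        fixed = cloud + rng.normal(0, 1.0, cloud.shape)
        res = register_point_based(lmset(cloud), lmset(fixed))
        perm = [3, 1, 4, 0, 2]
        shuffled = LandmarkSet(
            [f"f{i}" for i in perm], cloud[perm], PATIENT
        )
        assert fre(res, shuffled, lmset(fixed)) == pytest.approx(res.fre_mm)


@pytest.fixture(scope="module")
def skull_surface():
    ph = make_phantom(3)
    return SurfaceModel(
        ph.true_ct_pose.transform_points(ph.skin_surface.vertices),
        ph.skin_surface.faces,
        BL_IMAGE,
    )


def sample_probes(surface, n, rng, frame=PATIENT, transform=None):
    tri = surface.vertices[surface.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    idx = rng.choice(len(tri), size=n, p=areas / areas.sum())
    u, v = np.sqrt(rng.random(n)), rng.random(n)
    pts = (tri[idx, 0] * (1 - u)[:, None] + tri[idx, 1] * (u * (1 - v))[:, None]
           + tri[idx, 2] * (u * v)[:, None])
    if transform is not None:
        pts = transform.transform_points(pts)
    return LandmarkSet([f"probe_{i}" for i in range(n)], pts, frame)


class TestClosestPoint:
    def test_on_surface_points_have_zero_distance(self, skull_surface, rng):
        probes = sample_probes(skull_surface, 25, rng, frame=BL_IMAGE)
        _, dist, _ = closest_points_on_surface(probes.coordinates, skull_surface)
        assert dist.max() < 1e-9

    def test_single_triangle_regions(self):
        surf = SurfaceModel([(0, 0, 0), (1, 0, 0), (0, 1, 0)], [(0, 1, 2)], PATIENT)
        queries = np.array([
            (0.25, 0.25, 1.0),   # above interior
            (-1.0, -1.0, 0.0),   # vertex region A
            (0.5, -2.0, 0.0),    # edge AB region
            (2.0, 2.0, 0.0),     # edge BC region
        ])
        closest, dist, _ = closest_points_on_surface(queries, surf)
        np.testing.assert_allclose(closest[0], (0.25, 0.25, 0.0), atol=1e-12)
        np.testing.assert_allclose(closest[1], (0, 0, 0), atol=1e-12)
        np.testing.assert_allclose(closest[2], (0.5, 0, 0), atol=1e-12)
        np.testing.assert_allclose(closest[3], (0.5, 0.5, 0.0), atol=1e-12)
        np.testing.assert_allclose(
            dist, np.linalg.norm(queries - closest, axis=1)
        )


class TestSurfaceIcp:
    def test_fixed_point_at_true_pose(self, skull_surface, rng):
        ph = make_phantom(3)
        true = ph.true_ct_pose
        probes = sample_probes(skull_surface, 30, rng, PATIENT, invert(true))
        res = register_surface(probes, skull_surface, true)
        assert res.converged
        assert res.fre_mm < 1e-6
        assert np.abs(res.transform.matrix - true.matrix).max() < 1e-9

    def test_recovers_small_motion(self, skull_surface, rng):
        ph = make_phantom(3)
        true = ph.true_ct_pose
        probes = sample_probes(skull_surface, 40, rng, PATIENT, invert(true))
        perturb = Transform.from_rotation_translation(
            Rotation.from_euler("xyz", [2.0, -1.5, 1.0], degrees=True).as_matrix(),
            (1.5, -1.0, 2.0), BL_IMAGE, BL_IMAGE,
        )
        res = register_surface(probes, skull_surface, compose(true, perturb),
                               max_iterations=3000)
        assert res.converged
        delta = compose(res.transform, invert(true))
        angle_deg = np.rad2deg(
            np.linalg.norm(Rotation.from_matrix(delta.rotation).as_rotvec())
        )
        assert angle_deg < 0.1
        assert np.linalg.norm(delta.translation_vector) < 0.1

    def test_rms_monotone_non_increasing(self, skull_surface, rng):
        ph = make_phantom(3)
        probes = sample_probes(skull_surface, 40, rng, PATIENT, invert(ph.true_ct_pose))
        noisy = LandmarkSet(
            list(probes.labels), probes.coordinates + rng.normal(0, 0.5, (40, 3)),
            PATIENT,
        )
        perturb = Transform.from_rotation_translation(
            Rotation.from_euler("z", 3.0, degrees=True).as_matrix(), (2, 1, -1),
            BL_IMAGE, BL_IMAGE,
        )
        res = register_surface(noisy, skull_surface, compose(ph.true_ct_pose, perturb))
        diffs = np.diff(res.rms_history)
        assert np.all(diffs <= 1e-9)

    def test_face_order_invariance(self, skull_surface, rng):
        probes = sample_probes(skull_surface, 30, rng, frame=PATIENT,
                               transform=invert(make_phantom(3).true_ct_pose))
        perm = np.random.default_rng(0).permutation(len(skull_surface.faces))
        shuffled = SurfaceModel(
            skull_surface.vertices, skull_surface.faces[perm], BL_IMAGE
        )
        init = make_phantom(3).true_ct_pose
        a = register_surface(probes, skull_surface, init)
        b = register_surface(probes, shuffled, init)
        assert np.abs(a.transform.matrix - b.transform.matrix).max() < 1e-9

    def test_too_few_probes_rejected(self, skull_surface, rng):
        probes = sample_probes(skull_surface, 5, rng, frame=BL_IMAGE)
        with pytest.raises(ConfigurationError, match=">= 10"):
            register_surface(probes, skull_surface, Transform.identity(BL_IMAGE))

    def test_frame_mismatch_rejected(self, skull_surface, rng):
        probes = sample_probes(skull_surface, 12, rng, frame=PATIENT)
        with pytest.raises(FrameChainError):
            register_surface(probes, skull_surface, Transform.identity(BL_IMAGE))
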