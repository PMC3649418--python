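"""Surface-variation curvature, ICP, merging, reconstruction, margins."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

from orthomodel import surface_model as sm
from orthomodel.core import PointCloud, RigidTransform
from orthomodel.errors import (ConvergenceError, InputError,
                               ReconstructionError, SegmentationError)


# ---------------------------------------------------------------------------
# surface variation
# ---------------------------------------------------------------------------

def test_coplanar_neighbourhood_gives_zero():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(-1, 1, (50, 2)), np.zeros(50)])
    field = sm.surface_variation(PointCloud(pts), radius=5.0)
    assert field.defined.all()
    np.testing.assert_allclose(field.delta_n, 0.0, atol=1e-15)
    # v0 is the plane normal
    assert np.allclose(np.abs(field.normals[:, 2]), 1.0, atol=1e-9)


def test_isotropic_neighbourhood_gives_one_third():
    octa = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    field = sm.surface_variation(PointCloud(octa), radius=3.0)
    np.testing.assert_allclose(field.delta_n, 1.0 / 3.0, atol=1e-12)


def test_matches_brute_force_eigen_oracle():
    """delta_n equals lambda0/(lambda0+lambda1+lambda2) computed by an
    independent per-point loop over the same spherical neighbourhoods."""
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(50, 3))
    radius = 1.5
    field = sm.surface_variation(PointCloud(pts), radius=radius)
    for i in range(len(pts)):
        nbrs = [q for q in pts if np.linalg.norm(q - pts[i]) <= radius]
        Q = np.array(nbrs)
        if len(Q) < 3:
            assert not field.defined[i]
            continue
        diffs = Q - Q.mean(axis=0)
        C = np.zeros((3, 3))
        for dq in diffs:
            C += np.outer(dq, dq)
        lam = np.sort(np.linalg.eigvalsh(C))
        expected = lam[0] / lam.sum()
        assert abs(field.delta_n[i] - expected) < 1e-12


def test_delta_range_and_rigid_invariance():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(200, 3)) * [3, 2, 0.3]
    field = sm.surface_variation(PointCloud(pts), radius=1.0)
    d = field.delta_n[field.defined]
    assert np.all(d >= 0.0) and np.all(d <= 1.0 / 3.0 + 1e-12)
    T = RigidTransform.from_axis_angle((1, 2, 3), 33.0, (4, 5, 6))
    field2 = sm.surface_variation(PointCloud(T.apply(pts)), radius=1.0)
    np.testing.assert_allclose(field2.delta_n[field.defined],
                               field.delta_n[field.defined], atol=1e-9)


def test_isolated_points_flagged_undefined():
    pts = np.array([[0.0, 0, 0], [100.0, 0, 0], [200.0, 0, 0]])
    field = sm.surface_variation(PointCloud(pts), radius=1.0)
    assert not field.defined.any()
    assert np.isnan(field.delta_n).all()


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------

def test_icp_identity_on_equal_clouds():
    pts = np.random.default_rng(0).uniform(-10, 10, (200, 3))
    T, rms = sm.icp_register(PointCloud(pts), PointCloud(pts))
    assert rms < 1e-12
    np.testing.assert_allclose(T.matrix(), np.eye(4), atol=1e-9)


def test_icp_recovers_small_transform_from_identity():
    rng = np.random.default_rng(1)
    pts = rng.uniform(-10, 10, (500, 3))
    T_true = RigidTransform.from_axis_angle((0.3, 0.5, 1.0), 10.0, (2, 1, 0))
    T, rms = sm.icp_register(PointCloud(pts), PointCloud(T_true.apply(pts)),
                             reject_dist=25.0)
    assert abs(T.rotation_angle_deg - T_true.rotation_angle_deg) < 1e-3
    assert np.abs(T.translation - T_true.translation).max() < 1e-3
    assert rms < 1e-6


@pytest.mark.parametrize("seed", range(5))
def test_icp_refines_landmark_alignment_to_exact(seed):
    """Transforms up to 20 deg / 10 mm: a noisy 4-landmark Procrustes
    initialization refined by ICP recovers the truth to 1e-3, mirroring
    the manual-points-then-refinement workflow."""
    rng = np.random.default_rng(1)
    u = rng.normal(size=(800, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pts = u * [10, 6, 4]
    pts[:200] += [3, 0, 2]     # bump breaks the shell's near-symmetry
    r2 = np.random.default_rng(seed)
    angle = r2.uniform(5, 20)
    T_true = RigidTransform.from_axis_angle(r2.normal(size=3), angle,
                                            r2.uniform(-10, 10, 3))
    tgt = T_true.apply(pts)
    lm = [0, 200, 400, 600]
    T0 = sm.kabsch(pts[lm], tgt[lm] + r2.normal(0, 0.3, (4, 3)))
    T, rms = sm.icp_register(PointCloud(pts), PointCloud(tgt), init=T0,
                             reject_dist=5.0, max_iter=100)
    assert abs(T.rotation_angle_deg - T_true.rotation_angle_deg) < 1e-3
    assert np.abs(T.translation - T_true.translation).max() < 1e-3
    assert rms < 1e-6


def test_icp_rms_monotone_non_increasing():
    rng = np.random.default_rng(5)
    pts = rng.uniform(-10, 10, (300, 3))
    T_true = RigidTransform.from_axis_angle((0, 0, 1), 15.0, (3, 0, 0))
    target = PointCloud(T_true.apply(pts))
    source = PointCloud(pts)
    # track RMS across increasing iteration budgets: must not increase
    rms_values = [sm.icp_register(source, target, max_iter=k,
                                  reject_dist=25.0)[1]
                  for k in (1, 2, 5, 10, 30)]
    assert all(b <= a + 1e-12 for a, b in zip(rms_values, rms_values[1:]))


def test_icp_disjoint_clouds_error():
    a = PointCloud(np.random.default_rng(0).uniform(0, 1, (50, 3)))
    b = PointCloud(a.positions + 100.0)
    with pytest.raises(ConvergenceError):
        sm.icp_register(a, b, reject_dist=1.0)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def test_merge_deduplicates_exact_copy():
    pts = np.random.default_rng(2).uniform(-5, 5, (300, 3))
    merged = sm.merge_scans(PointCloud(pts), PointCloud(pts.copy()),
                            merge_tolerance=0.1)
    assert len(merged) == len(pts)
    np.testing.assert_allclose(np.sort(merged.positions, axis=0),
                               np.sort(pts, axis=0), atol=1e-12)


def test_merge_zero_tolerance_concatenates():
    a = PointCloud(np.zeros((10, 3)))
    b = PointCloud(np.ones((20, 3)))
    assert len(sm.merge_scans(a, b, merge_tolerance=0.0)) == 30


def test_merge_empty_inputs_pass_through():
    a = PointCloud(np.zeros((0, 3)))
    b = PointCloud(np.ones((5, 3)))
    assert len(sm.merge_scans(a, b, merge_tolerance=0.1)) == 5


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def test_reconstruct_sphere_within_pitch():
    rng = np.random.default_rng(2)
    u = rng.normal(size=(8000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    cloud = PointCloud(10.0 * u, normals=u)
    mesh = sm.reconstruct_mesh(cloud, voxel_pitch=0.2)
    r = np.linalg.norm(mesh.vertices, axis=1)
    assert np.abs(r - 10.0).max() < 0.2
    d = cKDTree(cloud.positions).query(mesh.vertices)[0]
    assert d.mean() <= 0.2


def test_reconstruct_phantom_crown(single_tooth_crown, single_tooth_jaw):
    tooth = single_tooth_jaw.teeth[0]
    rng = np.random.default_rng(0)
    mesh = single_tooth_crown
    # sample the crown surface and reconstruct it
    areas = mesh.area_faces
    faces = rng.choice(len(areas), 20000, p=areas / areas.sum())
    tri = mesh.triangles[faces]
    r1 = np.sqrt(rng.random(20000))[:, None]
    r2 = rng.random(20000)[:, None]
    pts = (1 - r1) * tri[:, 0] + r1 * (1 - r2) * tri[:, 1] + r1 * r2 * tri[:, 2]
    cloud = PointCloud(pts, normals=mesh.face_normals[faces])
    recon = sm.reconstruct_mesh(cloud, voxel_pitch=0.3)
    d = cKDTree(pts).query(recon.vertices)[0]
    assert d.mean() <= 0.3


def test_reconstruct_rejects_degenerate_inputs():
    with pytest.raises(ReconstructionError):
        sm.reconstruct_mesh(PointCloud(np.random.rand(10, 3)))
    plane = np.column_stack([np.random.rand(200, 2), np.zeros(200)])
    with pytest.raises(ReconstructionError):
        sm.reconstruct_mesh(PointCloud(plane), voxel_pitch=0.1)


# ---------------------------------------------------------------------------
# margin splines
# ---------------------------------------------------------------------------

def test_margin_spline_on_circle():
    th = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    R = 5.0
    seeds = np.column_stack([R * np.cos(th), R * np.sin(th), np.zeros(12)])
    ml = sm.fit_margin_spline(seeds, "11")
    samp = ml.sample(1000)
    assert np.abs(np.hypot(samp[:, 0], samp[:, 1]) - R).max() < 1e-3 * R


def test_margin_spline_interpolates_seeds():
    rng = np.random.default_rng(1)
    th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    seeds = np.column_stack([np.cos(th) * 4, np.sin(th) * 3,
                             rng.normal(0, 0.2, 8)])
    ml = sm.fit_margin_spline(seeds, "21")
    at_knots = ml.evaluate(ml.knots[:-1])
    np.testing.assert_allclose(at_knots, seeds, atol=1e-9)
    # closure: start equals end
    np.testing.assert_allclose(ml.evaluate([0.0]), ml.evaluate([ml.knots[-1]]),
                               atol=1e-9)


def test_margin_spline_input_errors():
    with pytest.raises(InputError):
        sm.fit_margin_spline(np.random.rand(3, 3), "11")
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(InputError):
        sm.fit_margin_spline(line, "11")
    bowtie = np.array([[0, 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0.0]])
    with pytest.raises(InputError):
        sm.fit_margin_spline(bowtie, "11")


# ---------------------------------------------------------------------------
# crown segmentation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def segmented(arch_jaw, mouth_mesh):
    curv = sm.surface_variation(PointCloud(mouth_mesh.vertices), radius=2.0)
    margins = [sm.fit_margin_spline(
        t.margin_ring(arch_jaw.gingiva_top + 0.1, 8), t.tooth_id)
        for t in arch_jaw.teeth]
    return sm.segment_crowns(mouth_mesh, curv, margins), curv


def test_crown_segmentation_agreement(arch_jaw, mouth_mesh, segmented):
    seg, _ = segmented
    truth = mouth_mesh.vertex_attributes["tooth_index"]
    agree = np.sum((seg.assignment == "") & (truth == -1))
    for i, t in enumerate(arch_jaw.teeth):
        agree += np.sum((seg.assignment == t.tooth_id) & (truth == i))
    assert agree / len(truth) >= 0.95


def test_crown_boundary_sits_on_curvature_ridge(mouth_mesh, segmented):
    seg, curv = segmented
    delta = np.nan_to_num(curv.delta_n, nan=0.0)
    crown_any = seg.assignment != ""
    boundary = set()
    for a, b in mouth_mesh.edges_unique:
        if crown_any[a] != crown_any[b]:
            boundary.add(int(a) if crown_any[a] else int(b))
    assert delta[sorted(boundary)].mean() > delta[seg.assignment == ""].mean()


def test_crown_regions_are_connected(arch_jaw, segmented):
    seg, _ = segmented
    for t in arch_jaw.teeth:
        sub = seg.crown_submesh(t.tooth_id)
        assert len(sub.split(only_watertight=False)) == 1


def test_partition_property(segmented, mouth_mesh):
    seg, _ = segmented
    labels = set(np.unique(seg.assignment.astype(str)))
    assert labels <= {"", "11", "12", "13"}
    assert len(seg.assignment) == len(mouth_mesh.vertices)


def test_margin_off_mesh_raises(mouth_mesh, segmented, arch_jaw):
    _, curv = segmented
    th = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    far = np.column_stack([np.cos(th), np.sin(th), np.full(8, 500.0)])
    bad = sm.fit_margin_spline(far, "18")
    with pytest.raises(SegmentationError):
        sm.segment_crowns(mouth_mesh, curv, [bad])
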