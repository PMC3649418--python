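"""DICOM IO, iso-surfaces, threshold optimization, DRLSE and propagation."""
import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage import measure

from orthomodel import cbct_seg as cs
from orthomodel import phantom as ph
from orthomodel.core import VoxelVolume
from orthomodel.errors import (AlignmentError, FormatError, InputError,
                               ManualInitRequired, ParameterError,
                               PropagationError, ReconstructionError,
                               SweepError)


def _identity_landmarks(mesh, k=4):
    pts = mesh.vertices[np.linspace(0, len(mesh.vertices) - 1, k).astype(int)]
    return np.stack([pts, pts], axis=1)


# ---------------------------------------------------------------------------
# DICOM loading
# ---------------------------------------------------------------------------

def test_dicom_series_sorted_by_position(tmp_path, single_tooth_jaw):
    import random
    import shutil
    vol, _ = ph.voxelize_phantom(single_tooth_jaw, (0.4, 0.4, 0.4),
                                 ph.IntensityModel(noise_sd=0.0))
    src = tmp_path / "ordered"
    ph.write_dicom_series(vol, src)
    # shuffle file names: the reader must sort by slice position, not name
    shuffled = tmp_path / "shuffled"
    shuffled.mkdir()
    files = sorted(src.glob("*.dcm"))
    names = [f.name for f in files]
    random.Random(1).shuffle(names)
    for f, n in zip(files, names):
        shutil.copy(f, shuffled / n)
    a = cs.load_dicom_series(src)
    b = cs.load_dicom_series(shuffled)
    np.testing.assert_array_equal(a.intensities, b.intensities)


def test_dicom_mixed_orientation_rejected(tmp_path, single_tooth_jaw):
    import pydicom
    vol, _ = ph.voxelize_phantom(single_tooth_jaw, (0.4, 0.4, 0.4),
                                 ph.IntensityModel(noise_sd=0.0))
    d = tmp_path / "dicom"
    ph.write_dicom_series(vol, d)
    victim = sorted(d.glob("*.dcm"))[3]
    ds = pydicom.dcmread(victim)
    ds.ImageOrientationPatient = [0, 1, 0, 1, 0, 0]
    ds.save_as(victim, enforce_file_format=True)
    with pytest.raises(FormatError):
        cs.load_dicom_series(d)


# ---------------------------------------------------------------------------
# iso-surfaces
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def sphere_volume():
    """Analytic sphere, HU 1500 inside / 0 outside, radius 8 mm."""
    n = 48
    sp = 0.4
    ax = (np.arange(n) - n / 2) * sp
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    data = np.where(X ** 2 + Y ** 2 + Z ** 2 <= 8.0 ** 2, 1500.0, 0.0)
    return VoxelVolume(data, (sp, sp, sp), (ax[0], ax[0], ax[0]))


def test_iso_surface_sphere_radius(sphere_volume):
    mesh = cs.extract_iso_surface(sphere_volume, 750.0)
    r = np.linalg.norm(mesh.vertices, axis=1)
    assert np.abs(r - 8.0).max() <= 0.2 + 1e-6  # half a voxel


def test_iso_surface_out_of_range_is_empty(sphere_volume):
    mesh = cs.extract_iso_surface(sphere_volume, 10_000.0)
    assert mesh.metadata["empty"] and len(mesh.faces) == 0


def test_nested_spheres_two_components():
    n = 64
    sp = 0.4
    ax = (np.arange(n) - n / 2) * sp
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = X ** 2 + Y ** 2 + Z ** 2
    data = np.where(r2 <= 4.0 ** 2, 1500.0, np.where(r2 <= 9.0 ** 2, 0.0, 1500.0))
    vol = VoxelVolume(data, (sp, sp, sp), (ax[0], ax[0], ax[0]))
    mesh = cs.extract_iso_surface(vol, 750.0)
    assert len(mesh.split(only_watertight=False)) == 2


# ---------------------------------------------------------------------------
# alignment and threshold optimization
# ---------------------------------------------------------------------------

def test_self_alignment_discrepancy_below_half_voxel(
        single_tooth_crown, single_tooth_volume):
    vol, _ = single_tooth_volume
    lm = _identity_landmarks(single_tooth_crown)
    T, mean, sd = cs.align_crowns_to_volume(single_tooth_crown, vol, 250.0, lm)
    assert mean < 0.2
    assert T.rotation_angle_deg < 1.0


def test_icp_refinement_beats_landmark_only(
        single_tooth_crown, single_tooth_volume):
    vol, _ = single_tooth_volume
    rng = np.random.default_rng(0)
    pts = single_tooth_crown.vertices[
        np.linspace(0, len(single_tooth_crown.vertices) - 1, 4).astype(int)]
    noisy = np.stack([pts, pts + rng.normal(0, 0.4, pts.shape)], axis=1)
    iso = cs.extract_iso_surface(vol, 250.0)
    from orthomodel.surface_model import kabsch, point_to_surface_distance
    T0 = kabsch(noisy[:, 0], noisy[:, 1])
    before = point_to_surface_distance(
        iso, T0.apply(single_tooth_crown.vertices))
    T, mean, _ = cs.align_crowns_to_volume(single_tooth_crown, vol, 250.0,
                                           noisy)
    assert mean < np.mean(before[before <= 1.0])


def test_two_landmarks_rejected(single_tooth_crown, single_tooth_volume):
    vol, _ = single_tooth_volume
    lm = _identity_landmarks(single_tooth_crown)[:2]
    with pytest.raises(InputError):
        cs.align_crowns_to_volume(single_tooth_crown, vol, 250.0, lm)


def test_threshold_sweep_interior_minimum(single_tooth_crown,
                                          single_tooth_volume):
    vol, _ = single_tooth_volume
    lm = _identity_landmarks(single_tooth_crown)
    grid = [-750.0, -500.0, -250.0, 0.0, 250.0, 500.0, 750.0, 1000.0]
    sweep = cs.optimize_threshold(single_tooth_crown, vol, grid, lm)
    i = sweep.optimal_index
    assert 0 < i < len(grid) - 1                     # interior minimum
    finite = ~np.isnan(sweep.mean_discrepancy)
    assert (sweep.mean_discrepancy[i]
            <= np.nanmin(sweep.mean_discrepancy[finite]))
    # the optimum sits at the phantom's half-intensity boundary threshold
    assert abs(sweep.tau_opt - 250.0) <= 250.0       # within one grid step


def test_sweep_on_single_tissue_volume_errors(single_tooth_crown):
    vol = VoxelVolume(np.full((20, 20, 20), 500.0), (1, 1, 1), (0, 0, 0))
    lm = _identity_landmarks(single_tooth_crown)
    with pytest.raises(SweepError):
        cs.optimize_threshold(single_tooth_crown, vol, [100.0, 200.0], lm)


# ---------------------------------------------------------------------------
# edge indicator
# ---------------------------------------------------------------------------

def test_edge_indicator_constant_image_is_one():
    g = cs.edge_indicator(np.full((64, 64), 7.0), sigma=1.5)
    np.testing.assert_allclose(g, 1.0)


def test_edge_indicator_minimum_on_step_edge():
    img = np.zeros((32, 64))
    img[:, 32:] = 10.0
    g = cs.edge_indicator(img, sigma=1.5)
    cols = np.argmin(g, axis=1)
    assert np.all(np.abs(cols - 31.5) <= 1.0)


def test_edge_indicator_bounds():
    rng = np.random.default_rng(0)
    g = cs.edge_indicator(rng.normal(size=(40, 40)) * 100, sigma=1.0)
    assert g.min() > 0.0 and g.max() <= 1.0


# ---------------------------------------------------------------------------
# DRLSE core
# ---------------------------------------------------------------------------

def _oracle_step(phi, g, params):
    """Independent scalar-loop finite-difference implementation of one
    evolution step (same discretization conventions, assembled from
    scratch)."""
    mu, lam, alpha = params.mu, params.lambda_, params.alpha
    dt, eps = params.timestep, params.epsilon
    f = phi.copy()
    # replicate-inward border
    f[0, :] = f[2, :]
    f[-1, :] = f[-3, :]
    f[:, 0] = f[:, 2]
    f[:, -1] = f[:, -3]
    H, W = f.shape

    def grad(a):
        gx = np.empty_like(a)
        gy = np.empty_like(a)
        for i in range(H):
            for j in range(W):
                if 0 < i < H - 1:
                    gx[i, j] = (a[i + 1, j] - a[i - 1, j]) / 2.0
                elif i == 0:
                    gx[i, j] = a[1, j] - a[0, j]
                else:
                    gx[i, j] = a[-1, j] - a[-2, j]
                if 0 < j < W - 1:
                    gy[i, j] = (a[i, j + 1] - a[i, j - 1]) / 2.0
                elif j == 0:
                    gy[i, j] = a[i, 1] - a[i, 0]
                else:
                    gy[i, j] = a[i, -1] - a[i, -2]
        return gx, gy

    px, py = grad(f)
    mag = np.sqrt(px ** 2 + py ** 2)
    s = np.maximum(mag, 1e-12)
    dp = np.where(s <= 1.0, np.sinc(2.0 * s), (s - 1.0) / s)
    dist = grad(dp * px)[0] + grad(dp * py)[1]
    nx = px / (mag + 1e-10)
    ny = py / (mag + 1e-10)
    dirac = np.where(np.abs(f) <= eps,
                     (1.0 / (2 * eps)) * (1 + np.cos(np.pi * f / eps)), 0.0)
    edge = dirac * (grad(g * nx)[0] + grad(g * ny)[1])
    return f + dt * (mu * dist + lam * edge + alpha * g * dirac)


def test_one_step_matches_finite_difference_oracle():
    rng = np.random.default_rng(0)
    phi = rng.normal(size=(5, 5)) * 2
    g = rng.uniform(0.1, 1.0, (5, 5))
    params = cs.DrlseParams()
    mine = cs.drlse_step(phi, g, params)
    oracle = _oracle_step(phi, g, params)
    np.testing.assert_allclose(mine, oracle, atol=1e-10)


def _disk_setup(disk_image):
    g = cs.edge_indicator(disk_image, sigma=1.5)
    return g


def test_drlse_shrinks_onto_disk(disk_image):
    g = _disk_setup(disk_image)
    init = np.zeros_like(disk_image, dtype=bool)
    init[8:56, 8:56] = True  # square outside the disk
    phi0 = cs.binary_step_lsf(init, (1, 1), (0, 0))
    out = cs.drlse_evolve(phi0, g, cs.DrlseParams(alpha=0.5), iterations=800)
    contours = measure.find_contours(out.phi, 0.0)
    assert contours
    r = np.hypot(*(np.vstack(contours) - 32).T)
    assert np.abs(r - 15.0).max() <= 1.0  # within 1 px of the disk boundary


def test_drlse_expands_onto_disk(disk_image):
    """Negative alpha expands a contour initialized inside the target."""
    g = _disk_setup(disk_image)
    yy, xx = np.mgrid[0:64, 0:64]
    init = (xx - 32) ** 2 + (yy - 32) ** 2 <= 7 ** 2
    phi0 = cs.binary_step_lsf(init, (1, 1), (0, 0))
    out = cs.drlse_evolve(phi0, g, cs.DrlseParams(alpha=-1.5), iterations=800)
    contours = measure.find_contours(out.phi, 0.0)
    assert contours
    r = np.hypot(*(np.vstack(contours) - 32).T)
    assert np.abs(r - 15.0).max() <= 1.0


def test_drlse_curve_shortening_without_edges():
    """alpha = 0 on a blank image: pure curvature flow, contour length
    non-increasing."""
    g = np.ones((64, 64))
    yy, xx = np.mgrid[0:64, 0:64]
    init = (np.abs(xx - 32) < 18) & (np.abs(yy - 32) < 10)
    phi = cs.binary_step_lsf(init, (1, 1), (0, 0)).phi
    params = cs.DrlseParams(alpha=0.0)

    def contour_length(p):
        cs_ = measure.find_contours(p, 0.0)
        return sum(np.linalg.norm(np.diff(c, axis=0), axis=1).sum()
                   for c in cs_)

    lengths = []
    for _ in range(10):
        for _ in range(20):
            phi = cs.drlse_step(phi, g, params)
        lengths.append(contour_length(phi))
    assert all(b <= a + 1e-6 for a, b in zip(lengths, lengths[1:]))


def test_distance_regularization_maintains_signed_distance():
    """The double-well regularization term keeps |grad phi| near 1 in the
    narrow band: a signed-distance initialization stays a signed distance
    under pure regularization, and a steepened one is drawn back."""
    yy, xx = np.mgrid[0:64, 0:64]
    init = (xx - 32) ** 2 + (yy - 32) ** 2 <= 15 ** 2
    g = np.ones((64, 64))
    params = cs.DrlseParams(lambda_=1e-9, alpha=0.0)

    def band_frac(phi):
        gx, gy = np.gradient(phi)
        mag = np.hypot(gx, gy)
        band = np.abs(phi) <= 1.5
        return np.mean((mag[band] >= 0.8) & (mag[band] <= 1.2))

    phi = cs.signed_distance_lsf(init, (1, 1), (0, 0)).phi
    for _ in range(500):
        phi = cs.drlse_step(phi, g, params)
    assert band_frac(phi) >= 0.9
    steep = cs.signed_distance_lsf(init, (1, 1), (0, 0)).phi * 1.6
    gx, gy = np.gradient(steep)
    assert np.median(np.hypot(gx, gy)) > 1.4   # clearly off the target
    for _ in range(500):
        steep = cs.drlse_step(steep, g, params)
    assert band_frac(steep) >= 0.4  # drawn back toward the well target


def test_cfl_violation_rejected(disk_image):
    g = _disk_setup(disk_image)
    phi0 = cs.binary_step_lsf(np.zeros_like(disk_image, bool), (1, 1), (0, 0))
    with pytest.raises(ParameterError):
        cs.drlse_evolve(phi0, g, cs.DrlseParams(mu=0.3, timestep=1.0))


# ---------------------------------------------------------------------------
# crown-guided initialization and propagation
# ---------------------------------------------------------------------------

def test_init_from_crown_first_slice_and_dilation(
        single_tooth_jaw, single_tooth_volume, single_tooth_crown):
    vol, _ = single_tooth_volume
    k0, r0, c_init, phi = cs.init_from_crown(single_tooth_crown, vol)
    # entry is at the occlusal end: near the top of the crown (z close to
    # crown_height), a little below the exact tip because of the area floor
    z0 = vol.slice_world_position(k0)
    h = single_tooth_jaw.teeth[0].spec.crown_height
    assert h - 1.5 <= z0 <= h
    # C_init strictly contains R0
    dilated = phi.inside_mask
    assert np.all(dilated[r0])
    assert dilated.sum() > r0.sum()


def test_init_from_crown_outside_volume_needs_manual(
        single_tooth_volume, single_tooth_crown):
    vol, _ = single_tooth_volume
    moved = single_tooth_crown.copy()
    moved.apply_translation([500.0, 0.0, 0.0])
    with pytest.raises(ManualInitRequired):
        cs.init_from_crown(moved, vol)


def test_single_root_volume_and_contour_recovery(
        single_tooth_jaw, single_tooth_volume, single_tooth_crown):
    vol, _ = single_tooth_volume
    tooth = single_tooth_jaw.teeth[0]
    stack = cs.segment_tooth(vol, crown_mesh_aligned=single_tooth_crown,
                             tooth_id="11")
    true_vol = tooth.volume_mm3(0.15)
    assert abs(stack.volume_mm3() - true_vol) / true_vol <= 0.05
    xs = vol.origin[0] + np.arange(vol.shape[0]) * vol.spacing[0]
    ys = vol.origin[1] + np.arange(vol.shape[1]) * vol.spacing[1]
    dists = []
    for k in stack.slice_indices:
        truth = tooth.cross_section_mask(vol.slice_world_position(k), xs, ys)
        tc = measure.find_contours(truth.astype(float), 0.5)
        if not tc or not stack.contours[k]:
            continue
        seg_px = np.vstack([(c - vol.origin[:2]) / vol.spacing[:2]
                            for c in stack.contours[k]])
        dists.append(cKDTree(np.vstack(tc)).query(seg_px)[0].mean())
    assert np.mean(dists) <= 1.0  # within one voxel on average


def test_two_root_furcation_split():
    spec = ph.ToothPhantomSpec("16", crown_radii=(5.0, 4.2), root_count=2,
                               root_taper=0.5)
    jaw = ph.make_jaw_phantom([spec])
    tooth = jaw.teeth[0]
    vol, _ = ph.voxelize_phantom(jaw, (0.4, 0.4, 0.4),
                                 ph.IntensityModel(noise_sd=30, seed=1))
    stack = cs.segment_tooth(vol, crown_mesh_aligned=tooth.crown_mesh(0.2),
                             tooth_id="16")
    ax = vol.slice_axis
    furcation_z = -tooth._furcation_depth
    k_furc = int(round((furcation_z - vol.origin[ax]) / vol.spacing[ax]))
    # single loop in the trunk just above the furcation
    above = [k for k in stack.slice_indices
             if k_furc + 2 <= k <= k_furc + 6]
    assert above and all(stack.loop_count(k) == 1 for k in above)
    # two loops appear below the furcation
    below = [k for k in stack.slice_indices if k < k_furc]
    assert any(stack.loop_count(k) >= 2 for k in below)


def test_manual_init_path_matches_crown_path(
        single_tooth_jaw, single_tooth_volume, single_tooth_crown):
    """The impacted-tooth path (manual polygon + start slice) reaches the
    same accuracy as the crown-guided path."""
    vol, _ = single_tooth_volume
    tooth = single_tooth_jaw.teeth[0]
    k0, r0, contours, _ = cs.init_from_crown(single_tooth_crown, vol)
    stack = cs.segment_tooth(vol, manual_init_contour=contours[0],
                             start_slice=k0, direction=-1, tooth_id="11")
    true_vol = tooth.volume_mm3(0.15)
    assert abs(stack.volume_mm3() - true_vol) / true_vol <= 0.05


def test_propagation_divergence_detected():
    """A small bright disk followed by a much larger one: an expanding
    contour blows the area up more than 3x between adjacent slices and the
    propagation aborts with the offending index."""
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (xx - 32) ** 2 + (yy - 32) ** 2
    data = np.zeros((n, n, 4))
    data[:, :, 0] = np.where(r2 <= 3 ** 2, 1000.0, 0.0).T
    for k in (1, 2, 3):
        data[:, :, k] = np.where(r2 <= 24 ** 2, 1000.0, 0.0).T
    vol = VoxelVolume(data, (1, 1, 1), (0, 0, 0))
    th = np.linspace(0, 2 * np.pi, 24)
    poly = 32.0 + 4.0 * np.column_stack([np.cos(th), np.sin(th)])
    params = cs.DrlseParams(alpha=-1.0, iterations=200,
                            first_slice_iterations=100)
    with pytest.raises(PropagationError) as exc:
        cs.segment_tooth(vol, manual_init_contour=poly, start_slice=0,
                         direction=1, params=params, tooth_id="13")
    assert exc.value.slice_index >= 1


def test_contours_to_mesh_cylinder():
    stack = cs.SliceContourStack(tooth_id="11", slice_axis=2,
                                 spacing=np.array([0.5, 0.5, 0.5]),
                                 origin=np.zeros(3))
    yy, xx = np.mgrid[0:40, 0:40]
    mask = (xx - 20) ** 2 + (yy - 20) ** 2 <= 12 ** 2
    lsf = cs.binary_step_lsf(mask, (0.5, 0.5), (0.0, 0.0))
    for k in range(10):
        stack.add(k, lsf.contours_mm(), mask)
    mesh = cs.contours_to_mesh(stack)
    # radius within half a voxel, height = 10 slices
    mid = (mesh.vertices[:, 2] > 1.0) & (mesh.vertices[:, 2] < 3.5)
    r = np.hypot(mesh.vertices[mid, 0] - 10.0, mesh.vertices[mid, 1] - 10.0)
    assert np.abs(r - 6.0).max() < 0.5
    assert mesh.is_watertight


def test_contours_to_mesh_requires_two_slices():
    stack = cs.SliceContourStack(tooth_id="11", slice_axis=2,
                                 spacing=np.array([0.5, 0.5, 0.5]),
                                 origin=np.zeros(3))
    with pytest.raises(ReconstructionError):
        cs.contours_to_mesh(stack)
    stack.add(0, [], np.zeros((4, 4), bool))
    with pytest.raises(ReconstructionError):
        cs.contours_to_mesh(stack)


# ---------------------------------------------------------------------------
# bone segmentation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def bone_case(single_tooth_jaw, single_tooth_crown):
    jaw = single_tooth_jaw
    # a margin wide enough that the alveolar slab ends inside the volume
    vol, labels = ph.voxelize_phantom(jaw, (0.4, 0.4, 0.4),
                                      ph.IntensityModel(noise_sd=30, seed=3),
                                      margin=8.0)
    tooth_stack = cs.segment_tooth(vol, crown_mesh_aligned=single_tooth_crown,
                                   tooth_id="11")
    ax = vol.slice_axis
    z_start = jaw.bone_top - 2.0 * vol.spacing[ax]
    k_start = int(round((z_start - vol.origin[ax]) / vol.spacing[ax]))
    from scipy import ndimage
    bone_mask = np.take(labels == ph.LABEL_BONE, k_start, axis=ax)
    init = ndimage.binary_dilation(bone_mask, iterations=3)
    contour = max(measure.find_contours(init.astype(float), 0.5), key=len)
    a, b = vol.in_plane_axes()
    contour_mm = vol.origin[[a, b]] + contour * vol.spacing[[a, b]]
    socket, warnings = cs.segment_bone(vol, contour_mm, k_start,
                                       tooth_stacks=[tooth_stack],
                                       direction=-1)
    return vol, labels, tooth_stack, socket, warnings


def test_socketed_bone_disjoint_from_tooth(bone_case):
    _, _, tooth_stack, socket, _ = bone_case
    for k in socket.slice_indices:
        tm = tooth_stack.masks.get(k)
        if tm is not None:
            assert not np.any(socket.masks[k] & tm)


def test_socket_area_additivity(bone_case):
    vol, labels, tooth_stack, socket, _ = bone_case
    # the socketed region plus the (disjoint) tooth region partitions the
    # bone envelope on each shared slice: areas add exactly
    checked = 0
    for k in socket.slice_indices:
        tm = tooth_stack.masks.get(k)
        if tm is None:
            continue
        union = (socket.masks[k] | tm).sum()
        assert union == socket.masks[k].sum() + tm.sum()
        checked += 1
    assert checked > 0


def test_bone_envelope_recovery(bone_case):
    vol, labels, tooth_stack, socket, _ = bone_case
    ax = vol.slice_axis
    errs = []
    for k in socket.slice_indices:
        truth = np.take(labels == ph.LABEL_BONE, k, axis=ax)
        # compare the outer envelope: socket + tooth regions vs bone + PDL
        seg = socket.masks[k].copy()
        tm = tooth_stack.masks.get(k)
        if tm is not None:
            seg |= tm
        inner = np.take(labels == ph.LABEL_SOFT_TISSUE, k, axis=ax)
        env_truth = truth | inner | np.take(labels == ph.LABEL_TOOTH, k, axis=ax)
        tc = measure.find_contours(env_truth.astype(float), 0.5)
        sc = measure.find_contours(seg.astype(float), 0.5)
        if not tc or not sc:
            continue
        errs.append(cKDTree(np.vstack(tc)).query(np.vstack(sc))[0].mean())
    assert np.mean(errs) <= 2.5  # px
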