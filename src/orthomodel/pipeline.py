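"""End-to-end pipeline driver and input validation.

Stage order mirrors the clinical workflow: optical scan simulation and
merging -> crown/gingiva segmentation -> crown-to-CBCT alignment with
threshold optimization -> per-tooth DRLSE segmentation -> crown/root
fusion and bone socketing -> multi-body model.  Every run emits a
machine-readable report of per-stage metrics and archives its resolved
configuration next to the outputs.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage import measure
import trimesh

from . import cbct_seg, fusion, phantom, surface_model
from .config import PipelineConfig
from .core import PointCloud, RigidTransform
from .errors import OrthoModelError

__all__ = ["run_pipeline", "validate_inputs", "StageFailure"]


class StageFailure(OrthoModelError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


def _concat_views(views: list[PointCloud]) -> PointCloud:
    out = views[0]
    for v in views[1:]:
        out = out.concatenated(v)
    return out


def run_pipeline(config: PipelineConfig, output_dir=None
                 ) -> tuple[fusion.MultiBodyModel | None, dict]:
    """Run the configured stages on a synthetic phantom and return the
    multi-body model plus the metrics report."""
    out_dir = Path(output_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.write_resolved(out_dir)
    report: dict = {"stages": {}, "config_seed": config.seed}

    def _fail(stage: str, exc: Exception):
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        raise StageFailure(stage, exc)

    # --- phantom ----------------------------------------------------------
    stage = "phantom"
    try:
        specs = phantom.default_arch_specs(config.n_teeth)
        jaw = phantom.make_jaw_phantom(
            specs, phantom.ArchParameters(radius=config.arch_radius,
                                          interproximal_gap=config.interproximal_gap))
        intensity = phantom.IntensityModel(
            noise_sd=config.noise_sd, streak_amplitude=config.streak_amplitude,
            seed=config.seed)
        volume, truth_labels = phantom.voxelize_phantom(
            jaw, config.spacing, intensity)
        report["stages"][stage] = {
            "status": "ok", "n_teeth": len(jaw.teeth),
            "volume_shape": list(volume.shape),
            "spacing_mm": volume.spacing.tolist()}
    except OrthoModelError as e:
        _fail(stage, e)

    model = None
    seg = None
    aligned_crowns: dict[str, trimesh.Trimesh] = {}
    params = cbct_seg.DrlseParams(
        mu=config.drlse_mu, lambda_=config.drlse_lambda,
        alpha=config.drlse_alpha, sigma=config.drlse_sigma,
        timestep=config.drlse_timestep, iterations=config.drlse_iterations,
        first_slice_iterations=config.drlse_first_slice_iterations)

    # --- optical scanning + merge ----------------------------------------
    if config.do_scan:
        stage = "scan_merge"
        try:
            imp_views, _ = phantom.simulate_surface_scan(
                jaw, "impression", config.view_count, config.scan_noise_sd,
                seed=config.seed + 1, point_spacing=config.point_spacing,
                mesh_pitch=config.mesh_pitch)
            cast_views, _ = phantom.simulate_surface_scan(
                jaw, "cast", config.view_count, config.scan_noise_sd,
                seed=config.seed + 2, point_spacing=config.point_spacing,
                mesh_pitch=config.mesh_pitch)
            impression = _concat_views(imp_views)
            cast = _concat_views(cast_views)
            T_reg, rms = surface_model.icp_register(
                impression, cast, max_iter=config.icp_max_iter,
                tol=config.icp_tol, reject_dist=config.icp_reject_dist)
            merged = surface_model.merge_scans(
                impression, cast, T_reg, config.merge_tolerance)
            report["stages"][stage] = {
                "status": "ok", "icp_rms_mm": rms,
                "n_impression": len(impression), "n_cast": len(cast),
                "n_merged": len(merged)}
        except OrthoModelError as e:
            _fail(stage, e)
    else:
        merged = None

    # --- crown segmentation ----------------------------------------------
    if config.do_crown_segmentation:
        stage = "crown_segmentation"
        try:
            if merged is not None:
                mouth_mesh = surface_model.reconstruct_mesh(
                    merged, voxel_pitch=config.reconstruction_pitch)
            else:
                mouth_mesh = jaw.mouth_mesh(pitch=config.mesh_pitch)
            curvature = surface_model.surface_variation(
                PointCloud(mouth_mesh.vertices), radius=config.curvature_radius)
            margins = [
                surface_model.fit_margin_spline(
                    t.margin_ring(jaw.gingiva_top + 0.4, config.margin_seeds),
                    t.tooth_id)
                for t in jaw.teeth]
            seg = surface_model.segment_crowns(mouth_mesh, curvature, margins)
            counts = {tid: int(np.sum(seg.assignment == tid))
                      for tid in seg.tooth_ids}
            report["stages"][stage] = {"status": "ok",
                                       "crown_vertex_counts": counts}
        except OrthoModelError as e:
            _fail(stage, e)

    # --- CBCT alignment, threshold sweep, per-tooth DRLSE -----------------
    tooth_stacks: list[cbct_seg.SliceContourStack] = []
    root_meshes: dict[str, trimesh.Trimesh] = {}
    if config.do_cbct and seg is not None:
        stage = "cbct_alignment"
        try:
            crowns = {tid: seg.crown_submesh(tid) for tid in seg.tooth_ids}
            all_crowns = trimesh.util.concatenate(list(crowns.values()))
            # landmark stand-ins: scans and volume share the frame already,
            # so the operator's >= 3 common points are identity pairs
            lm_pts = all_crowns.vertices[
                np.linspace(0, len(all_crowns.vertices) - 1, 4).astype(int)]
            landmarks = np.stack([lm_pts, lm_pts], axis=1)
            sweep = cbct_seg.optimize_threshold(
                all_crowns, volume, config.tau_grid, landmarks,
                delta_eps=config.delta_eps)
            T_align = sweep.transforms[sweep.optimal_index]
            report["stages"][stage] = {
                "status": "ok", "tau_opt_hu": sweep.tau_opt,
                "mean_discrepancy_mm":
                    float(sweep.mean_discrepancy[sweep.optimal_index]),
                "sd_discrepancy_mm":
                    float(sweep.sd_discrepancy[sweep.optimal_index])}
        except OrthoModelError as e:
            _fail(stage, e)

        stage = "tooth_segmentation"
        try:
            volumes_mm3 = {}
            for tid, crown in crowns.items():
                aligned = crown.copy()
                aligned.apply_transform(T_align.matrix())
                aligned_crowns[tid] = aligned
                stack = cbct_seg.segment_tooth(
                    volume, crown_mesh_aligned=aligned, params=params,
                    tooth_id=tid)
                tooth_stacks.append(stack)
                root_meshes[tid] = cbct_seg.contours_to_mesh(stack)
                volumes_mm3[tid] = stack.volume_mm3()
            report["stages"][stage] = {"status": "ok",
                                       "tooth_volumes_mm3": volumes_mm3}
        except OrthoModelError as e:
            _fail(stage, e)

    # --- bone -------------------------------------------------------------
    bone_mesh = None
    if config.do_bone and config.do_cbct:
        stage = "bone_segmentation"
        try:
            bone_mesh, bone_warnings = _segment_bone_stage(
                jaw, volume, truth_labels, params, tooth_stacks)
            report["stages"][stage] = {"status": "ok",
                                       "warnings": bone_warnings}
        except OrthoModelError as e:
            _fail(stage, e)

    # --- fusion and assembly ----------------------------------------------
    stage = "fusion"
    try:
        teeth_models = []
        if config.do_fusion and root_meshes:
            for tid, root in root_meshes.items():
                teeth_models.append(fusion.fuse_crown_root(
                    aligned_crowns[tid], root, seam_band=config.seam_band,
                    tooth_id=tid))
        gingiva_mesh = None
        if seg is not None:
            gmask = seg.assignment == ""
            faces_keep = gmask[seg.mesh.faces].all(axis=1)
            if faces_keep.any():
                gingiva_mesh = seg.mesh.submesh(
                    [np.nonzero(faces_keep)[0]], append=True)
        model = fusion.build_orthodontic_model(
            teeth_models, gingiva=gingiva_mesh, bone_mesh=bone_mesh)
        fusion.export_model(model, out_dir / "model")
        report["stages"][stage] = {
            "status": "ok", "n_teeth": len(teeth_models),
            "collisions": [list(c) for c in model.collisions]}
    except OrthoModelError as e:
        _fail(stage, e)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return model, report


def _segment_bone_stage(jaw, volume, truth_labels, params, tooth_stacks):
    """Bone envelope via DRLSE from an operator-style contour drawn around
    the true bone outline on a starting slice near the bone top."""
    ax = volume.slice_axis
    z_start = jaw.bone_top - 2.0 * volume.spacing[ax]
    k_start = int(round((z_start - volume.origin[ax]) / volume.spacing[ax]))
    k_start = int(np.clip(k_start, 0, volume.n_slices - 1))
    bone_mask = np.take(truth_labels == phantom.LABEL_BONE, k_start, axis=ax)
    if not bone_mask.any():
        raise cbct_seg.ManualInitRequired("no bone on the starting slice")
    from scipy import ndimage as ndi
    init_mask = ndi.binary_dilation(bone_mask, iterations=3)
    contour = max(measure.find_contours(init_mask.astype(float), 0.5), key=len)
    a, b = volume.in_plane_axes()
    contour_mm = volume.origin[[a, b]] + contour * volume.spacing[[a, b]]
    socket, warnings = cbct_seg.segment_bone(
        volume, contour_mm, k_start, params=params,
        tooth_stacks=tooth_stacks, direction=-1)
    mesh = cbct_seg.contours_to_mesh(socket)
    return mesh, warnings


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths) -> dict:
    """Sanity-check input files without mutating them.

    Meshes: loadable, watertightness flag, bounding box in a plausible mm
    range (a >1000 mm box suggests meters).  DICOM directories: required
    geometry tags present.  Returns a report dict; never raises for bad
    content.
    """
    report: dict = {}
    for p in map(Path, paths):
        entries = []
        if p.is_dir():
            entries.extend(_check_dicom_dir(p))
        elif p.suffix.lower() in (".stl", ".ply"):
            entries.extend(_check_mesh(p))
        elif p.suffix.lower() in (".xyz", ".txt"):
            entries.extend(_check_cloud(p))
        else:
            entries.append({"level": "warning",
                            "message": f"unrecognized input type '{p.suffix}'"})
        report[str(p)] = entries
    return report


def _check_mesh(path: Path) -> list[dict]:
    entries = []
    try:
        mesh = trimesh.load(path, force="mesh")
    except Exception as e:
        return [{"level": "error", "message": f"unreadable mesh: {e}"}]
    extent = mesh.extents.max() if len(mesh.vertices) else 0.0
    if extent > 1000.0:
        entries.append({"level": "warning",
                        "message": f"bounding box {extent:.0f} suggests the "
                                   "mesh is not in mm (meters?)"})
    elif extent < 0.5:
        entries.append({"level": "warning",
                        "message": "bounding box under 0.5 mm; wrong units?"})
    entries.append({"level": "ok",
                    "message": f"{len(mesh.vertices)} vertices, "
                               f"watertight={bool(mesh.is_watertight)}"})
    return entries


def _check_cloud(path: Path) -> list[dict]:
    try:
        cloud = PointCloud.load_xyz(path)
    except Exception as e:
        return [{"level": "error", "message": f"unreadable point cloud: {e}"}]
    return [{"level": "ok", "message": f"{len(cloud)} points"}]


def _check_dicom_dir(path: Path) -> list[dict]:
    import pydicom
    entries = []
    files = sorted(path.glob("*.dcm")) or [f for f in sorted(path.iterdir())
                                           if f.is_file()]
    if not files:
        return [{"level": "error", "message": "no DICOM files found"}]
    required = ("PixelSpacing", "ImagePositionPatient",
                "ImageOrientationPatient", "SliceThickness")
    for f in files[:3]:
        try:
            ds = pydicom.dcmread(str(f), stop_before_pixels=True)
        except Exception as e:
            entries.append({"level": "error",
                            "message": f"{f.name}: unreadable ({e})"})
            continue
        missing = [t for t in required if t not in ds]
        if missing:
            entries.append({"level": "error",
                            "message": f"{f.name}: missing tags {missing}"})
    if not entries:
        entries.append({"level": "ok",
                        "message": f"{len(files)} slices, tags complete"})
    return entries
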