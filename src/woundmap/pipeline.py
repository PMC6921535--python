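"""End-to-end orchestration: photographs -> reconstruction -> unwrap -> area.

The measurement runs in three phases mirroring clinical use: (1) multi-view
sparse reconstruction of the wound region, (2) meshing and least-squares
conformal unwrapping onto a textured 2D chart, (3) planimetry on the chart
with the two-tape scale calibration. Phase 3 needs operator input (the tape
endpoints and the traced wound outline), so the pipeline supports two-phase
operation: ``reconstruct_and_unwrap`` produces the chart, and
``measure_from_unwrapped`` consumes the operator's ROI and calibration.

All randomness fans out deterministically from a single pipeline seed;
reruns with identical inputs produce byte-identical measurement reports.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi

from . import measure as _measure
from . import sfm as _sfm
from . import synthetic as _synthetic
from .features import RasterImage, load_image
from .meshing import TriangleMesh, mesh_point_cloud, save_mesh
from .unwrap import UVMap, lscm, pick_pins, rasterize_unwrapped

__all__ = ["PipelineConfig", "PipelineError", "UnwrapResult",
           "reconstruct_and_unwrap", "measure_from_unwrapped", "run_pipeline",
           "measure_synthetic_scene"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and a remediation hint."""


@dataclass
class PipelineConfig:
    """All stage parameters of an end-to-end run."""

    sfm: _sfm.SfmConfig = field(default_factory=_sfm.SfmConfig)
    mesh_grid_resolution: int | None = None   # None: density-adaptive
    mesh_smooth_cells: float = 1.0
    mesh_trim_boundary: bool = True
    unwrap_resolution: int = 1024
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sfm_d = d.pop("sfm", {})
        return cls(sfm=_sfm.SfmConfig(**sfm_d), **d)


@dataclass
class UnwrapResult:
    """Phase 1+2 output: the textured unwrapped chart and all geometry."""

    unwrapped: RasterImage
    alpha: np.ndarray
    meta: dict
    mesh: TriangleMesh
    uvmap: UVMap
    poses: dict
    cloud: _sfm.SparseCloud
    log: dict


def _bilinear(img: RasterImage, px: np.ndarray, fill: float = 0.6) -> np.ndarray:
    vals = _ndi.map_coordinates(img.pixels, [px[:, 1], px[:, 0]], order=1,
                                mode="constant", cval=fill)
    return vals


def _texture_sampler(images: dict[str, RasterImage], poses: dict,
                     mesh: TriangleMesh, fill: float = 0.6):
    """Project 3D chart positions into the most fronto-parallel registered
    photograph that sees them; fall back through the preference order."""
    tm_normal = np.zeros(3)
    a = mesh.V[mesh.T[:, 1]] - mesh.V[mesh.T[:, 0]]
    b = mesh.V[mesh.T[:, 2]] - mesh.V[mesh.T[:, 0]]
    tm_normal = np.cross(a, b).sum(0)
    nrm = np.linalg.norm(tm_normal)
    if nrm > 0:
        tm_normal /= nrm
    # preference: camera viewing direction anti-parallel to the mean normal
    pref = sorted(poses, key=lambda i: (poses[i].R[2] @ tm_normal))

    def sampler(points3d: np.ndarray) -> np.ndarray:
        out = np.full(len(points3d), np.nan)
        for iid in pref:
            todo = np.isnan(out)
            if not todo.any():
                break
            pose = poses[iid]
            px, z = pose.project(points3d[todo])
            im = images[iid]
            ok = (z > 0) & (px[:, 0] >= 1) & (px[:, 0] <= im.width - 2) \
                & (px[:, 1] >= 1) & (px[:, 1] <= im.height - 2)
            if not ok.any():
                continue
            idx = np.nonzero(todo)[0][ok]
            out[idx] = _bilinear(im, px[ok], fill)
        return np.where(np.isnan(out), fill, out)

    return sampler


def reconstruct_and_unwrap(images: list[RasterImage],
                           config: PipelineConfig | None = None,
                           seed: int | None = None) -> UnwrapResult:
    """Phases 1 and 2: sparse reconstruction, meshing, LSCM, rasterization."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    try:
        poses, cloud, tracks, log = _sfm.reconstruct(images, config.sfm, seed=seed)
    except ValueError as exc:
        raise PipelineError(f"[reconstruction] {exc}; capture more overlapping "
                            "views (>= 20 recommended, <= 30 deg apart)") from exc
    cam_mean = np.mean([p.center for p in poses.values()], axis=0)
    try:
        mesh = mesh_point_cloud(cloud.points, config.mesh_grid_resolution,
                                camera_center=cam_mean,
                                smooth_cells=config.mesh_smooth_cells,
                                trim_boundary=config.mesh_trim_boundary)
    except ValueError as exc:
        raise PipelineError(f"[meshing] {exc}") from exc
    try:
        uvmap = lscm(mesh, pick_pins(mesh))
    except ValueError as exc:
        raise PipelineError(f"[unwrap] {exc}") from exc
    by_id = {im.id: im for im in images}
    sampler = _texture_sampler(by_id, poses, mesh)
    unwrapped, alpha, meta = rasterize_unwrapped(
        mesh, uvmap, resolution=config.unwrap_resolution,
        texture_sampler=sampler)
    log["stages"]["unwrap"] = {"energy": uvmap.energy,
                               "uv_area": uvmap.area(mesh),
                               "mesh_area": mesh.area()}
    return UnwrapResult(unwrapped, alpha, meta, mesh, uvmap, poses, cloud, log)


def measure_from_unwrapped(calib: _measure.ScaleCalibration,
                           roi: _measure.PolygonROI) -> _measure.WoundMeasurement:
    """Phase 3: planimetry of the traced outline under the tape calibration."""
    S_img = _measure.polygon_area_px(roi)
    return _measure.wound_area(calib, S_img)


def run_pipeline(image_paths: list, calib_path, roi_path,
                 config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Full three-phase run from files on disk.

    ``calib_path``/``roi_path`` follow the JSON schemas of
    :mod:`woundmap.measure` with pixel coordinates on the unwrapped image
    (two-phase workflows obtain that image first via
    ``reconstruct_and_unwrap``). Returns the measurement report; with
    ``out_dir`` all intermediates are written alongside it.
    """
    config = config or PipelineConfig()
    # fail fast on missing operator inputs before any heavy computation
    for p, what in ((calib_path, "calibration"), (roi_path, "ROI")):
        if not os.path.exists(p):
            raise PipelineError(f"[inputs] {what} file not found: {p}")
    calib = _measure.load_calibration_json(calib_path)
    roi = _measure.load_roi_json(roi_path)
    images = [load_image(p, id=os.path.basename(str(p))) for p in image_paths]
    res = reconstruct_and_unwrap(images, config)
    meas = measure_from_unwrapped(calib, roi)
    report = {
        "S_img_px2": meas.S_img,
        "S_wound_cm2": meas.S_wound,
        "S_wound_cm2_exact": meas.S_wound_exact,
        "calibration": dataclasses.asdict(meas.calibration),
        "config": config.to_dict(),
        "log": res.log,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        _write_outputs(out_dir, res, report)
    return report


def _write_outputs(out_dir, res: UnwrapResult, report: dict) -> None:
    from PIL import Image as _PILImage

    save_mesh(res.mesh, os.path.join(out_dir, "mesh.obj"), uv=res.uvmap.uv)
    res.mesh.as_trimesh().export(os.path.join(out_dir, "cloud_mesh.ply"))
    poses = {i: {"R": p.R.ravel().tolist(), "t": p.t.tolist(),
                 "focal": p.focal, "cx": p.cx, "cy": p.cy}
             for i, p in res.poses.items()}
    with open(os.path.join(out_dir, "poses.json"), "w") as fh:
        json.dump(poses, fh, sort_keys=True, indent=1)
    arr = np.dstack([res.unwrapped.pixels] * 3 + [res.alpha.astype(float)])
    _PILImage.fromarray((arr * 255).astype(np.uint8), "RGBA").save(
        os.path.join(out_dir, "unwrapped.png"))
    with open(os.path.join(out_dir, "unwrapped_meta.json"), "w") as fh:
        json.dump(res.meta, fh, sort_keys=True, indent=1)
    with open(os.path.join(out_dir, "measurement.json"), "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)


def measure_synthetic_scene(scene: _synthetic.SyntheticScene,
                            config: PipelineConfig | None = None,
                            seed: int = 0, resolution: int | None = None) -> dict:
    """Closed-loop benchmark on one synthetic scene.

    Renders the camera ring, runs the full pipeline, emulates the operator
    (tape-end marking and wound tracing on the unwrapped chart via intensity
    segmentation), and compares the measured area against the scene's exact
    quadrature area. Returns a report with the measured and true areas and
    the relative error in percent.
    """
    config = config or PipelineConfig()
    if config.sfm.focal is None:
        # the renderer's focal length is known scene metadata (EXIF stand-in)
        cam0 = scene.cameras[0]
        fct = 1.0 if resolution is None else resolution / cam0.width
        config = PipelineConfig(**{**config.to_dict(),
                                   "sfm": dataclasses.replace(
                                       config.sfm, focal=cam0.f * fct)})
    images = _synthetic.render_images(scene, resolution=resolution)
    res = reconstruct_and_unwrap(images, config, seed=seed)
    try:
        tapes_px = _synthetic.locate_tapes(res.unwrapped)
    except ValueError as exc:
        raise PipelineError(f"[calibration] {exc}") from exc
    # tape assignment: both marks carry their known printed length
    lens = {t.axis: t.length_cm for t in scene.tapes}
    calib = _measure.calibrate((tapes_px[0][0], tapes_px[0][1], lens["x"]),
                               (tapes_px[1][0], tapes_px[1][1], lens["y"]))
    poly = _synthetic.trace_dark_region(res.unwrapped, alpha=res.alpha)
    roi = _measure.PolygonROI(poly)
    meas = measure_from_unwrapped(calib, roi)
    true = scene.wound_area_cm2
    return {
        "true_area_cm2": true,
        "measured_area_cm2": meas.S_wound,
        "measured_area_cm2_exact": meas.S_wound_exact,
        "relative_error_pct": 100.0 * (meas.S_wound_exact - true) / true,
        "abs_relative_error_pct": 100.0 * abs(meas.S_wound_exact - true) / true,
        "n_images": len(images),
        "n_points": len(res.cloud),
        "log": res.log,
    }
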