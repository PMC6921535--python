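"""Ground-truthed synthetic wound scenes.

Every stage of the measurement pipeline is testable without clinical
photographs: a parametric body-like surface (plane, cylinder patch, or
spherical cap) carries a speckle texture, a darkened wound patch of exactly
known surface area, and two high-contrast tape marks of known physical
length; a ring of >= 2 pinhole cameras observes the patch. Scenes are pure
functions of (parameters, seed).

Scene geometry lives in a surface parameter chart (s, t) in centimetres,
chosen so that the chart is arc-length along both axes for the developable
surfaces (plane, cylinder); areas and tape lengths on the spherical cap are
obtained by quadrature with the exact metric. The wound's quadrature area
plays the role of film-coverage counting ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon

from .features import RasterImage

__all__ = [
    "Camera", "Tape", "SyntheticScene", "make_scene", "true_area",
    "project_tracks", "render_images", "look_at",
    "locate_tapes", "trace_dark_region",
]


# ---------------------------------------------------------------- cameras

def look_at(center: np.ndarray, target: np.ndarray, up=(0.0, 0.0, 1.0)) -> np.ndarray:
    """World-to-camera rotation for a camera at ``center`` looking at
    ``target`` (camera z forward, x right, y down)."""
    zc = np.asarray(target, float) - np.asarray(center, float)
    zc = zc / np.linalg.norm(zc)
    up = np.asarray(up, float)
    xc = np.cross(up, zc)
    if np.linalg.norm(xc) < 1e-8:
        xc = np.cross([1.0, 0.0, 0.0], zc)
    xc /= np.linalg.norm(xc)
    yc = np.cross(zc, xc)
    return np.stack([xc, yc, zc])


@dataclass
class Camera:
    """Pinhole camera: ``x_cam = R (X - C)``, pixel ``(f x/z + cx, f y/z + cy)``."""

    R: np.ndarray
    center: np.ndarray
    f: float
    cx: float
    cy: float
    width: int
    height: int
    id: str = ""

    @property
    def t(self) -> np.ndarray:
        return -self.R @ self.center

    def K(self) -> np.ndarray:
        return np.array([[self.f, 0, self.cx], [0, self.f, self.cy], [0, 0, 1.0]])

    def project(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project world points; returns pixel coordinates and depths."""
        Xc = (np.atleast_2d(X) - self.center) @ self.R.T
        z = Xc[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            px = np.column_stack([self.f * Xc[:, 0] / z + self.cx,
                                  self.f * Xc[:, 1] / z + self.cy])
        return px, z

    def scaled(self, width: int) -> "Camera":
        """Same field of view at a different image resolution."""
        fct = width / self.width
        return Camera(self.R, self.center, self.f * fct, self.cx * fct,
                      self.cy * fct, int(width), int(round(self.height * fct)),
                      self.id)


# ---------------------------------------------------------------- surfaces

class _Surface:
    kind = "abstract"

    def point(self, s, t):  # pragma: no cover - interface
        raise NotImplementedError

    def normal(self, s, t):
        raise NotImplementedError

    def area_density(self, s, t):
        """dA / (ds dt) of the chart."""
        raise NotImplementedError

    def ray_hits(self, origin, dirs):
        """Ray-cast; returns (s, t, depth, valid) arrays."""
        raise NotImplementedError


@dataclass
class Plane(_Surface):
    kind = "plane"

    def point(self, s, t):
        s, t = np.broadcast_arrays(np.asarray(s, float), np.asarray(t, float))
        return np.stack([s, t, np.zeros_like(s)], axis=-1)

    def normal(self, s, t):
        s = np.asarray(s, float)
        n = np.zeros(s.shape + (3,))
        n[..., 2] = 1.0
        return n

    def area_density(self, s, t):
        return np.ones_like(np.asarray(s, float))

    def ray_hits(self, origin, dirs):
        dz = dirs[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            depth = -origin[2] / dz
        valid = np.isfinite(depth) & (depth > 0)
        s = origin[0] + depth * dirs[..., 0]
        t = origin[1] + depth * dirs[..., 1]
        return s, t, depth, valid


@dataclass
class CylinderPatch(_Surface):
    """Outer surface of a cylinder of radius ``radius`` (axis along t/y),
    tangent to z=0 at the chart origin; s is arc length."""

    radius: float
    kind = "cylinder"

    def point(self, s, t):
        s, t = np.broadcast_arrays(np.asarray(s, float), np.asarray(t, float))
        a = s / self.radius
        return np.stack([self.radius * np.sin(a), t,
                         self.radius * (np.cos(a) - 1.0)], axis=-1)

    def normal(self, s, t):
        s, t = np.broadcast_arrays(np.asarray(s, float), np.asarray(t, float))
        a = s / self.radius
        return np.stack([np.sin(a), np.zeros_like(a), np.cos(a)], axis=-1)

    def area_density(self, s, t):
        return np.ones_like(np.asarray(s, float))

    def ray_hits(self, origin, dirs):
        # x^2 + (z + r)^2 = r^2 along ray O + u d
        r = self.radius
        ox, oz = origin[0], origin[2] + r
        dx, dz = dirs[..., 0], dirs[..., 2]
        a = dx ** 2 + dz ** 2
        b = 2 * (ox * dx + oz * dz)
        c = ox ** 2 + oz ** 2 - r ** 2
        disc = b ** 2 - 4 * a * c
        ok = (disc >= 0) & (a > 0)
        sq = np.sqrt(np.maximum(disc, 0.0))
        u1 = (-b - sq) / np.where(a > 0, 2 * a, 1.0)
        u2 = (-b + sq) / np.where(a > 0, 2 * a, 1.0)
        # nearest positive root first; outer surface faces the camera
        depth = np.where(u1 > 1e-9, u1, u2)
        valid = ok & (depth > 1e-9)
        x = origin[0] + depth * dirs[..., 0]
        y = origin[1] + depth * dirs[..., 1]
        z = origin[2] + depth * dirs[..., 2]
        s = r * np.arctan2(x, z + r)
        return s, y, depth, valid


@dataclass
class SphericalCap(_Surface):
    """Spherical cap of radius ``radius`` tangent to z=0 at the origin,
    charted in geodesic polar coordinates flattened to Cartesian (s, t)."""

    radius: float
    kind = "sphere"

    def point(self, s, t):
        s, t = np.broadcast_arrays(np.asarray(s, float), np.asarray(t, float))
        R = self.radius
        rho = np.hypot(s, t)
        phi = rho / R
        with np.errstate(invalid="ignore", divide="ignore"):
            cb = np.where(rho > 0, s / np.maximum(rho, 1e-300), 1.0)
            sb = np.where(rho > 0, t / np.maximum(rho, 1e-300), 0.0)
        return np.stack([R * np.sin(phi) * cb, R * np.sin(phi) * sb,
                         R * (np.cos(phi) - 1.0)], axis=-1)

    def normal(self, s, t):
        P = self.point(s, t)
        n = P - np.array([0.0, 0.0, -self.radius])
        return n / self.radius

    def area_density(self, s, t):
        s, t = np.broadcast_arrays(np.asarray(s, float), np.asarray(t, float))
        rho = np.hypot(s, t)
        R = self.radius
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(rho > 1e-12, R * np.sin(rho / R) / np.maximum(rho, 1e-300), 1.0)
        return d

    def ray_hits(self, origin, dirs):
        R = self.radius
        C = np.array([0.0, 0.0, -R])
        oc = origin - C
        a = np.einsum("...i,...i->...", dirs, dirs)
        b = 2 * np.einsum("...i,i->...", dirs, oc)
        c = oc @ oc - R ** 2
        disc = b ** 2 - 4 * a * c
        ok = (disc >= 0) & (a > 0)
        sq = np.sqrt(np.maximum(disc, 0.0))
        a2 = np.where(a > 0, 2 * a, 1.0)
        u1 = (-b - sq) / a2
        depth = np.where(u1 > 1e-9, u1, (-b + sq) / a2)
        valid = ok & (depth > 1e-9)
        P = origin + depth[..., None] * dirs
        rel = P - C
        cphi = np.clip(rel[..., 2] / R, -1.0, 1.0)
        phi = np.arccos(cphi)
        rho = R * phi
        beta = np.arctan2(rel[..., 1], rel[..., 0])
        return rho * np.cos(beta), rho * np.sin(beta), depth, valid


def _make_surface(kind: str, radius: float | None, half_extent: float) -> _Surface:
    if kind == "plane":
        return Plane()
    if kind == "cylinder":
        r = radius if radius is not None else max(3.5, 1.1 * half_extent)
        if half_extent / r > np.deg2rad(60):
            raise ValueError("cylinder patch arc exceeds 120 degrees")
        return CylinderPatch(r)
    if kind == "sphere":
        R = radius if radius is not None else max(8.0, 2.2 * half_extent)
        if np.sqrt(2) * half_extent / R > np.deg2rad(60):
            raise ValueError("spherical cap too large for its radius")
        return SphericalCap(R)
    raise ValueError(f"unknown surface kind {kind!r}")


# ---------------------------------------------------------------- scene

@dataclass
class Tape:
    """A straight adhesive-tape mark on the surface chart."""

    p0: np.ndarray            # chart endpoint (s, t)
    p1: np.ndarray
    width: float              # cm, across the centreline in the chart
    length_cm: float          # true physical length of the centreline
    axis: str                 # "x" or "y"


@dataclass
class SyntheticScene:
    surface: _Surface
    half_extent: float                       # chart half-extent (cm)
    wound: np.ndarray                        # closed chart polygon (n, 2)
    wound_area_cm2: float                    # exact surface area
    tapes: list[Tape]
    cameras: list[Camera]
    texture: np.ndarray                      # speckle grid over the chart
    seed: int
    meta: dict = field(default_factory=dict)

    def texture_at(self, s, t):
        """Bilinear sample of the speckle grid at chart coordinates."""
        n = self.texture.shape[0]
        he = self.half_extent
        gx = (np.asarray(s, float) + he) / (2 * he) * (n - 1)
        gy = (np.asarray(t, float) + he) / (2 * he) * (n - 1)
        gx = np.clip(gx, 0, n - 1 - 1e-9)
        gy = np.clip(gy, 0, n - 1 - 1e-9)
        x0 = gx.astype(int)
        y0 = gy.astype(int)
        fx, fy = gx - x0, gy - y0
        T = self.texture
        return ((1 - fx) * (1 - fy) * T[y0, x0] + fx * (1 - fy) * T[y0, x0 + 1]
                + (1 - fx) * fy * T[y0 + 1, x0] + fx * fy * T[y0 + 1, x0 + 1])

    def manifest(self) -> dict:
        """Ground-truth manifest (JSON-serializable)."""
        return {
            "surface": {"kind": self.surface.kind,
                        "radius": getattr(self.surface, "radius", None)},
            "half_extent_cm": self.half_extent,
            "true_area_cm2": self.wound_area_cm2,
            "tapes": [{"p0": t.p0.tolist(), "p1": t.p1.tolist(),
                       "width_cm": t.width, "length_cm": t.length_cm,
                       "axis": t.axis} for t in self.tapes],
            "cameras": [{"id": c.id, "R": c.R.ravel().tolist(),
                         "center": c.center.tolist(), "f": c.f,
                         "cx": c.cx, "cy": c.cy,
                         "width": c.width, "height": c.height}
                        for c in self.cameras],
            "seed": self.seed,
            **self.meta,
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, sort_keys=True, indent=1)

    def ground_truth_mesh(self, n: int = 200):
        """Fine surface mesh of the chart (for inspection/export)."""
        import trimesh
        s, t = np.meshgrid(np.linspace(-self.half_extent, self.half_extent, n),
                           np.linspace(-self.half_extent, self.half_extent, n))
        V = self.surface.point(s.ravel(), t.ravel())
        faces = []
        for j in range(n - 1):
            for i in range(n - 1):
                a = j * n + i
                faces.append((a, a + 1, a + n + 1))
                faces.append((a, a + n + 1, a + n))
        return trimesh.Trimesh(vertices=V, faces=np.array(faces), process=False)

    def save_ground_truth_mesh(self, path, n: int = 200) -> None:
        self.ground_truth_mesh(n).export(str(path))


def _star_polygon(rng: np.random.Generator, n_vertices: int = 96) -> np.ndarray:
    """Seeded smooth star-shaped boundary with unit nominal radius."""
    gamma = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones(n_vertices)
    for kmode in range(2, 6):
        amp = 0.28 / kmode * rng.uniform(0.3, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(kmode * gamma + phase)
    r = np.maximum(r, 0.35)
    return np.column_stack([r * np.cos(gamma), r * np.sin(gamma)])


def _chart_polygon_area(surface: _Surface, poly: np.ndarray, n_grid: int = 512) -> float:
    """Surface area enclosed by a chart polygon, by metric-weighted grid
    quadrature (midpoint rule over the polygon's bounding box)."""
    if surface.kind in ("plane", "cylinder"):
        # arc-length chart: surface area equals chart (shoelace) area
        x, y = poly[:, 0], poly[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
    sp = _ShapelyPolygon(poly)
    minx, miny, maxx, maxy = sp.bounds
    xs = np.linspace(minx, maxx, n_grid + 1)
    ys = np.linspace(miny, maxy, n_grid + 1)
    cx = (xs[:-1] + xs[1:]) / 2
    cy = (ys[:-1] + ys[1:]) / 2
    gx, gy = np.meshgrid(cx, cy)
    inside = shapely.contains_xy(sp, gx.ravel(), gy.ravel()).reshape(gx.shape)
    dens = surface.area_density(gx, gy)
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return float((dens * inside).sum() * cell)


def _polyline_length(surface: _Surface, p0, p1, n: int = 400) -> float:
    u = np.linspace(0, 1, n + 1)[:, None]
    pts = surface.point(*(p0 + u * (np.asarray(p1) - p0)).T)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def true_area(scene: SyntheticScene, n_grid: int = 512) -> float:
    """Exact wound surface area (cm^2) by metric quadrature; the synthetic
    stand-in for film-coverage square counting."""
    return _chart_polygon_area(scene.surface, scene.wound, n_grid)


def make_scene(surface_kind: str = "cylinder", wound_area_target: float = 2.0,
               n_cameras: int = 20, seed: int = 0, radius: float | None = None,
               wound_shape: str = "star", tape_length: float = 5.0,
               tape_width: float = 0.6, image_size: tuple[int, int] = (1280, 960),
               focal: float = 1200.0, ring_tilt_deg: float = 35.0,
               texture_res: int = 384) -> SyntheticScene:
    """Build a deterministic synthetic wound scene.

    The wound boundary (seeded star polygon, or a rectangle for
    ``wound_shape='rect'``) is scaled so its exact surface area equals
    ``wound_area_target`` cm^2 within 0.1%. Cameras sit on a full ring at
    ``ring_tilt_deg`` from the surface normal, radius 3x the chart
    half-extent, all looking at the patch centre; with the default 20 cameras
    the adjacent angular spacing is 18 degrees (<= 30 required).
    """
    if n_cameras < 2:
        raise ValueError("need at least 2 cameras")
    rng = np.random.default_rng(seed)
    if wound_shape == "star":
        base = _star_polygon(rng)
    elif wound_shape == "rect":
        aspect = rng.uniform(0.6, 1.6)
        hw, hh = np.sqrt(aspect), 1.0 / np.sqrt(aspect)
        base = np.array([[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]], float)
    else:
        raise ValueError("wound_shape must be 'star' or 'rect'")

    # chart extent sized to hold the wound, a clearance gap, and the two
    # tapes laid out as an L below/left of the wound (never touching: the
    # operator must see two distinct marks)
    nominal_r = np.sqrt(wound_area_target / np.pi) * 1.4
    off_nom = nominal_r + 0.7 + tape_width / 2
    s0_nom = -off_nom + tape_width / 2 + 0.35
    half_extent = float(max(nominal_r + 2.0,
                            off_nom + tape_width / 2 + 1.0,
                            s0_nom + tape_length + 1.0))
    surface = _make_surface(surface_kind, radius, half_extent)

    # scale the boundary to the exact target area
    s0 = np.sqrt(wound_area_target / _chart_polygon_area(surface, base))
    if surface.kind == "sphere":
        from scipy.optimize import brentq
        fun = lambda fac: _chart_polygon_area(surface, base * fac) - wound_area_target
        s0 = brentq(fun, 0.5 * s0, 2.0 * s0, xtol=1e-6)
    wound = base * s0
    area = _chart_polygon_area(surface, wound)
    if abs(area - wound_area_target) > 1e-3 * wound_area_target:
        raise ValueError("wound area scaling failed to converge")
    wr = np.abs(wound).max()
    if wr + 1.3 + tape_width > half_extent:
        raise ValueError("wound larger than the surface patch")

    gap = 0.7
    off = wr + gap + tape_width / 2
    s0 = -off + tape_width / 2 + 0.35
    tapes = []
    for axis, (p0, p1) in (("x", ([s0, -off], [s0 + tape_length, -off])),
                           ("y", ([-off, s0], [-off, s0 + tape_length]))):
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        L = _polyline_length(surface, p0, p1)
        tapes.append(Tape(p0, p1, tape_width, L, axis))

    # band-limited speckle texture (skin-texture stand-in for the detector):
    # three blob scales, contrast-normalised so the detector sees structure
    # at every pyramid level
    noise = rng.standard_normal((texture_res, texture_res))
    tex = sum(w * ndimage.gaussian_filter(noise, s, mode="wrap")
              / ndimage.gaussian_filter(noise, s, mode="wrap").std()
              for w, s in ((0.45, 1.2), (0.35, 2.5), (0.20, 6.0)))
    tex = np.clip(0.5 + 0.30 * tex / tex.std(), 0.0, 1.0)

    w, h = image_size
    tilt = np.deg2rad(ring_tilt_deg)
    ring_r = 3.0 * half_extent
    cams = []
    target = np.zeros(3)
    for i in range(n_cameras):
        az = 2 * np.pi * i / n_cameras
        C = ring_r * np.array([np.sin(tilt) * np.cos(az),
                               np.sin(tilt) * np.sin(az), np.cos(tilt)])
        cams.append(Camera(look_at(C, target), C, focal, w / 2.0, h / 2.0,
                           w, h, id=f"view{i:03d}"))

    return SyntheticScene(surface, half_extent, wound, area, tapes, cams,
                          tex, seed,
                          meta={"wound_shape": wound_shape,
                                "ring_tilt_deg": ring_tilt_deg,
                                "ring_radius_cm": ring_r})


# ----------------------------------------------------------- observations

def project_tracks(scene: SyntheticScene, pixel_noise_sd: float = 0.0,
                   outlier_rate: float = 0.0, seed: int = 0,
                   n_points: int = 400) -> dict:
    """Noisy pinhole observations of seeded surface sample points.

    Returns ``{"points3d": (n,3), "observations": {image_id: (track_id, x, y)
    rows}, "outliers": {image_id: bool array}}``; a track id indexes
    ``points3d``. Points behind a camera, outside the frame, or on surface
    seen from the back are excluded from that image.
    """
    if pixel_noise_sd < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    he = 0.95 * scene.half_extent
    st = rng.uniform(-he, he, size=(n_points, 2))
    P = scene.surface.point(st[:, 0], st[:, 1])
    N = scene.surface.normal(st[:, 0], st[:, 1])
    obs, outl = {}, {}
    for cam in scene.cameras:
        px, z = cam.project(P)
        facing = np.einsum("ij,ij->i", N, cam.center - P) > 0
        vis = (z > 0) & facing & (px[:, 0] >= 0) & (px[:, 0] < cam.width) \
            & (px[:, 1] >= 0) & (px[:, 1] < cam.height)
        ids = np.nonzero(vis)[0]
        pts = px[vis] + rng.normal(0.0, pixel_noise_sd, size=(vis.sum(), 2)) \
            if pixel_noise_sd > 0 else px[vis]
        is_out = rng.random(len(ids)) < outlier_rate
        if is_out.any():
            pts = pts.copy()
            pts[is_out] = rng.uniform([0, 0], [cam.width, cam.height],
                                      size=(is_out.sum(), 2))
        obs[cam.id] = np.column_stack([ids, pts])
        outl[cam.id] = is_out
    return {"points3d": P, "observations": obs, "outliers": outl}


# ---------------------------------------------------------------- render

#: rendering intensity model
_BG = 0.25          # featureless backdrop
_SKIN_LO, _SKIN_HI = 0.35, 0.85
_WOUND_GAIN, _WOUND_BASE = 0.20, 0.05
_TAPE = 1.0


def _shade(scene: SyntheticScene, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    base = _SKIN_LO + (_SKIN_HI - _SKIN_LO) * scene.texture_at(s, t)
    val = base.copy()
    inside = shapely.contains_xy(_ShapelyPolygon(scene.wound), s.ravel(), t.ravel())
    inside = inside.reshape(s.shape)
    val[inside] = _WOUND_BASE + _WOUND_GAIN * base[inside]
    for tape in scene.tapes:
        d = tape.p1 - tape.p0
        L = np.linalg.norm(d)
        u = ((s - tape.p0[0]) * d[0] + (t - tape.p0[1]) * d[1]) / L
        v = ((s - tape.p0[0]) * -d[1] + (t - tape.p0[1]) * d[0]) / L
        on = (u >= 0) & (u <= L) & (np.abs(v) <= tape.width / 2)
        val[on] = _TAPE
    return val


def render_view(scene: SyntheticScene, cam: Camera) -> RasterImage:
    """Analytic ray-cast render of one camera view."""
    u, v = np.meshgrid(np.arange(cam.width) + 0.0, np.arange(cam.height) + 0.0)
    d_cam = np.stack([(u - cam.cx) / cam.f, (v - cam.cy) / cam.f,
                      np.ones_like(u)], axis=-1)
    d_world = d_cam @ cam.R          # rows of R are camera axes
    s, t, depth, valid = scene.surface.ray_hits(cam.center, d_world)
    he = scene.half_extent
    on_patch = valid & (np.abs(s) <= he) & (np.abs(t) <= he)
    # reject back-facing hits (inner side of a curved patch)
    N = scene.surface.normal(np.where(on_patch, s, 0.0), np.where(on_patch, t, 0.0))
    P = scene.surface.point(np.where(on_patch, s, 0.0), np.where(on_patch, t, 0.0))
    facing = np.einsum("...i,...i->...", N, cam.center - P) > 0
    on_patch &= facing
    img = np.full(u.shape, _BG)
    if on_patch.any():
        img[on_patch] = _shade(scene, s[on_patch], t[on_patch])
    return RasterImage(np.clip(img, 0, 1), id=cam.id)


def render_images(scene: SyntheticScene, resolution: int | None = None,
                  seed: int = 0) -> list[RasterImage]:
    """Render all camera views (deterministic; ``seed`` kept for interface
    symmetry — the scene itself carries all stochastic state).

    ``resolution`` overrides the horizontal image size while preserving the
    field of view.
    """
    if resolution is not None and resolution < 256:
        raise ValueError("resolution must be >= 256")
    cams = scene.cameras if resolution is None \
        else [c.scaled(resolution) for c in scene.cameras]
    return [render_view(scene, c) for c in cams]


# ------------------------------------------- emulated operator interactions

def locate_tapes(img: RasterImage, level: float = 0.925,
                 min_pixels: int = 50) -> list[tuple[np.ndarray, np.ndarray]]:
    """Find the two tape marks on an unwrapped (or rendered) image.

    Stands in for the operator clicking the tape ends: pixels above
    ``level`` are grouped into connected components; for each of the two
    largest, the end points are the extreme projections of its sub-pixel
    boundary contour onto the component's principal axis. Returns endpoint
    pairs ``((x0, y0), (x1, y1))`` ordered x-dominant tape first.
    """
    from skimage import measure as _skm

    mask = img.pixels >= level
    lab, n = ndimage.label(mask)
    if n < 2:
        raise ValueError("could not find two tape marks")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1][:2] + 1
    out = []
    for li in order:
        if sizes[li - 1] < min_pixels:
            raise ValueError("tape component too small")
        comp = lab == li
        # unbiased edge localisation: re-contour at the mid-level between the
        # tape interior and its immediate surround, where a blurred step
        # crosses at the true edge position
        ring = ndimage.binary_dilation(comp, iterations=4) & ~comp
        inside = float(np.median(img.pixels[comp]))
        outside = float(np.median(img.pixels[ring])) if ring.any() else 0.0
        mid = 0.5 * (inside + outside)
        region = ndimage.binary_dilation(comp, iterations=4)
        masked = np.where(region, img.pixels, outside)
        cont = _skm.find_contours(masked, mid)
        if not cont:
            cont = _skm.find_contours(comp.astype(float), 0.5)
        pts = np.concatenate(cont)[:, ::-1]          # (x, y)
        c = pts.mean(0)
        _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
        axis = vt[0]
        proj = (pts - c) @ axis
        out.append((pts[np.argmin(proj)], pts[np.argmax(proj)]))
    # x-dominant tape first
    def _xness(seg):
        d = seg[1] - seg[0]
        return -abs(d[0]) / (np.linalg.norm(d) + 1e-12)
    out.sort(key=_xness)
    return out


def trace_dark_region(img: RasterImage, level: float = 0.30,
                      min_pixels: int = 50, simplify_px: float = 0.5,
                      alpha: np.ndarray | None = None) -> np.ndarray:
    """Trace the wound outline on an image as a closed polygon.

    Stands in for the operator tracing the dark wound region: the largest
    connected component below ``level`` is outlined with a sub-pixel
    marching-squares contour, simplified to ``simplify_px`` tolerance.
    Returns an (n, 2) array of (x, y) vertices.
    """
    from skimage import measure as _skm

    dark = img.pixels <= level
    if alpha is not None:
        interior = ndimage.binary_erosion(alpha > 0, iterations=6)
        dark &= interior
    lab, n = ndimage.label(dark)
    if n == 0:
        raise ValueError("no dark region found")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    # A wound is a compact blob; rendering seams along the chart boundary are
    # elongated bands. Score candidates by area x circularity (4 pi A / P^2)
    # and keep the best.
    best_li, best_score = None, 0.0
    for li in np.nonzero(sizes >= min_pixels)[0] + 1:
        comp = ndimage.binary_fill_holes(lab == li)
        area = float(comp.sum())
        perim = float(np.count_nonzero(comp ^ ndimage.binary_erosion(comp)))
        circ = 4 * np.pi * area / max(perim, 1.0) ** 2
        score = area * min(circ, 1.0) ** 2
        if circ >= 0.2 and score > best_score:
            best_li, best_score = int(li), score
    if best_li is None:
        raise ValueError("no compact dark region found to trace")
    comp = ndimage.binary_fill_holes(lab == best_li)
    # unbiased edge localisation: contour at the mid-level between the wound
    # interior and the surrounding skin rather than the detection threshold
    ring = ndimage.binary_dilation(comp, iterations=6) &         ~ndimage.binary_dilation(comp, iterations=2)
    inside = float(np.median(img.pixels[comp]))
    outside = float(np.median(img.pixels[ring])) if ring.any() else 1.0
    mid = 0.5 * (inside + outside)
    region = ndimage.binary_dilation(comp, iterations=4)
    masked = np.where(region, img.pixels, outside)
    conts = _skm.find_contours(masked, mid)
    if not conts:
        conts = _skm.find_contours(np.where(region, img.pixels, 1.0), level)
    cont = max(conts, key=len)
    poly = cont[:, ::-1]                              # (x, y)
    if simplify_px > 0:
        ls = _ShapelyPolygon(poly).simplify(simplify_px)
        poly = np.asarray(ls.exterior.coords)[:-1]
    return poly
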