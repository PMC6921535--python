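"""Least-squares conformal flattening of the wound-region mesh.

A conformal (angle-preserving) parameterization maps the 3D mesh into a 2D
(u, v) plane. Per triangle, the map from an isometric local 2D frame to
(u, v) is affine; its deviation from the Cauchy-Riemann equations,

    dU/dx + i dU/dy = 0,   U = u + i v,

squared and weighted by triangle area, is the conformal energy. Minimising
it subject to two (or more) pinned vertices — the gauge, since similarities
are conformal — yields the least-squares conformal map. For developable
surfaces (cylinder patches) the flattening is isometric up to numerical
error, so the uv-plane preserves areas; this is what makes downstream
planimetry on the unwrapped image meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import spsolve

from .features import RasterImage
from .meshing import TriangleMesh

__all__ = ["LocalBasis", "UVMap", "local_basis", "conformal_energy",
           "lscm", "pick_pins", "rasterize_unwrapped"]


@dataclass
class LocalBasis:
    """Isometric 2D coordinates of one triangle's vertices: vertex 1 at the
    origin, vertex 2 on +x, vertex 3 with positive y."""

    coords: np.ndarray        # (3, 2)


def local_basis(mesh: TriangleMesh, ti: int) -> LocalBasis:
    """Flatten triangle ``ti`` isometrically into its own plane."""
    p = mesh.V[mesh.T[ti]]
    e1 = p[1] - p[0]
    e2 = p[2] - p[0]
    l1 = np.linalg.norm(e1)
    nrm = np.cross(e1, e2)
    a2 = np.linalg.norm(nrm)
    if l1 == 0 or a2 == 0:
        raise ValueError(f"triangle {ti} is degenerate")
    x = e1 / l1
    y = np.cross(nrm / a2, x)
    return LocalBasis(np.array([[0.0, 0.0], [l1, 0.0], [e2 @ x, e2 @ y]]))


@dataclass
class UVMap:
    """Per-vertex planar coordinates with the pin gauge and achieved energy."""

    uv: np.ndarray
    pinned: list[int] = field(default_factory=list)
    energy: float = 0.0

    def signed_areas(self, mesh: TriangleMesh) -> np.ndarray:
        a = self.uv[mesh.T[:, 1]] - self.uv[mesh.T[:, 0]]
        b = self.uv[mesh.T[:, 2]] - self.uv[mesh.T[:, 0]]
        return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

    def area(self, mesh: TriangleMesh) -> float:
        return float(np.abs(self.signed_areas(mesh)).sum())

    def has_flips(self, mesh: TriangleMesh) -> bool:
        s = self.signed_areas(mesh)
        return bool((s.max() > 0) and (s.min() < 0))


def _gradient_coeffs(basis: LocalBasis) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficient 3-vectors a, b with  f_x = a . f,  f_y = b . f  for a
    function f affine over the triangle, plus the triangle area."""
    (x1, y1), (x2, y2), (x3, y3) = basis.coords
    area2 = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
    if area2 <= 0:
        raise ValueError("degenerate local basis")
    a = np.array([y2 - y3, y3 - y1, y1 - y2]) / area2
    b = np.array([x3 - x2, x1 - x3, x2 - x1]) / area2
    return a, b, area2 / 2.0


def conformal_energy(mesh: TriangleMesh, uvmap: UVMap | np.ndarray) -> float:
    """Area-weighted squared Cauchy-Riemann residual, summed over triangles."""
    uv = uvmap.uv if isinstance(uvmap, UVMap) else np.asarray(uvmap, float)
    E = 0.0
    for ti in range(len(mesh.T)):
        a, b, A = _gradient_coeffs(local_basis(mesh, ti))
        u = uv[mesh.T[ti], 0]
        v = uv[mesh.T[ti], 1]
        ux, uy = a @ u, b @ u
        vx, vy = a @ v, b @ v
        E += ((ux - vy) ** 2 + (uy + vx) ** 2) * A
    return float(E)


def pick_pins(mesh: TriangleMesh) -> list[tuple[int, float, float]]:
    """Default gauge: the two boundary vertices at (approximately) maximal
    geodesic distance, pinned at (0, 0) and (d, 0) with d their geodesic
    distance — this keeps the uv chart near physical scale, though exact
    scale always comes from the tape calibration downstream."""
    edges = mesh.edges()
    w = np.linalg.norm(mesh.V[edges[:, 0]] - mesh.V[edges[:, 1]], axis=1)
    n = len(mesh.V)
    g = sparse.coo_matrix((np.r_[w, w], (np.r_[edges[:, 0], edges[:, 1]],
                                         np.r_[edges[:, 1], edges[:, 0]])),
                          shape=(n, n)).tocsr()
    boundary = mesh.boundary_vertices()
    if len(boundary) < 2:
        boundary = np.arange(n)
    # two sweeps of the farthest-point heuristic
    d0 = dijkstra(g, indices=boundary[0])
    v1 = boundary[np.argmax(d0[boundary])]
    d1 = dijkstra(g, indices=v1)
    v2 = boundary[np.argmax(d1[boundary])]
    d = float(d1[v2])
    if not np.isfinite(d) or d <= 0:
        raise ValueError("mesh is disconnected or degenerate")
    return [(int(v1), 0.0, 0.0), (int(v2), d, 0.0)]


def lscm(mesh: TriangleMesh, pins: list[tuple[int, float, float]] | None = None,
         strict_flips: bool = False) -> UVMap:
    """Minimise the conformal energy subject to pinned vertices.

    The energy is assembled as a sparse real linear least-squares system
    (two unknowns per free vertex, two equations per triangle, rows weighted
    by sqrt of triangle area) and solved through the normal equations —
    deterministic and exact to solver precision. Requires >= 2 pins at
    distinct positions and an edge-connected mesh.
    """
    if pins is None:
        pins = pick_pins(mesh)
    if len(pins) < 2:
        raise ValueError("gauge underdetermined: need at least 2 pinned vertices")
    pin_idx = [p[0] for p in pins]
    pin_uv = {p[0]: (p[1], p[2]) for p in pins}
    if len({tuple(pin_uv[i]) for i in pin_idx}) < 2:
        raise ValueError("pinned vertices must have distinct target positions")
    if not mesh.is_edge_connected():
        comps = mesh.as_trimesh().split(only_watertight=False)
        raise ValueError(f"mesh has {len(comps)} connected components; "
                         "lscm needs a single chart")

    n = len(mesh.V)
    free = np.array([i for i in range(n) if i not in pin_uv])
    col_of = np.full(n, -1)
    col_of[free] = np.arange(len(free))

    rows, cols, vals = [], [], []
    nf = len(free)
    m = len(mesh.T)
    rhs = np.zeros(2 * m)
    for ti in range(m):
        a, b, A = _gradient_coeffs(local_basis(mesh, ti))
        wgt = np.sqrt(A)
        verts = mesh.T[ti]
        # residual rows: (a.u - b.v) and (b.u + a.v), weighted by sqrt(A)
        for r, (cu, cv) in ((2 * ti, (a, -b)), (2 * ti + 1, (b, a))):
            for k, vtx in enumerate(verts):
                if col_of[vtx] >= 0:
                    rows.append(r); cols.append(col_of[vtx]); vals.append(wgt * cu[k])
                    rows.append(r); cols.append(nf + col_of[vtx]); vals.append(wgt * cv[k])
                else:
                    pu, pv = pin_uv[vtx]
                    rhs[r] -= wgt * (cu[k] * pu + cv[k] * pv)
    M = sparse.coo_matrix((vals, (rows, cols)), shape=(2 * m, 2 * nf)).tocsr()
    if nf:
        AtA = (M.T @ M).tocsc()
        Atb = M.T @ rhs
        sol = spsolve(AtA, Atb)
        sol = np.atleast_1d(sol)
    else:
        sol = np.zeros(0)
    uv = np.zeros((n, 2))
    uv[free, 0] = sol[:nf]
    uv[free, 1] = sol[nf:]
    for i, (pu, pv) in pin_uv.items():
        uv[i] = (pu, pv)
    out = UVMap(uv, pinned=pin_idx)
    out.energy = conformal_energy(mesh, out)
    if out.has_flips(mesh):
        msg = "uv map contains flipped triangles"
        if strict_flips:
            raise ValueError(msg)
        import warnings
        warnings.warn(msg)
    return out


def rasterize_unwrapped(mesh: TriangleMesh, uvmap: UVMap, resolution: int = 1024,
                        colors: np.ndarray | None = None,
                        texture_sampler=None,
                        ) -> tuple[RasterImage, np.ndarray, dict]:
    """Rasterize the flattened mesh into an image.

    The uv bounding box is mapped by an affine transform (returned in the
    metadata as ``uv_to_pixel``, a 2x3 matrix) onto an image whose longer
    side is ``resolution`` pixels. Pixels are filled per triangle with
    barycentric interpolation of per-vertex ``colors`` (defaults to the mesh
    colors, else mid-grey); when a ``texture_sampler(points3d) -> intensity``
    is given it is evaluated at the interpolated 3D surface position of every
    covered pixel — this is how the photographs are projected onto the
    unwrapped chart. Returns (image, alpha mask, metadata).
    """
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    uv = uvmap.uv
    lo = uv.min(0)
    hi = uv.max(0)
    span = hi - lo
    if span.max() <= 0:
        raise ValueError("degenerate uv bounding box")
    scale = (resolution - 1) / span.max()
    W = max(int(np.ceil(span[0] * scale)) + 1, 2)
    H = max(int(np.ceil(span[1] * scale)) + 1, 2)
    uv_to_pixel = np.array([[scale, 0.0, -lo[0] * scale],
                            [0.0, scale, -lo[1] * scale]])
    px = uv @ uv_to_pixel[:, :2].T + uv_to_pixel[:, 2]

    if colors is None:
        colors = mesh.colors if mesh.colors is not None \
            else np.full((len(mesh.V), 3), 0.5)
    colors = np.asarray(colors, float)
    if colors.ndim == 1:
        colors = colors[:, None]

    img = np.zeros((H, W, colors.shape[1]))
    alpha = np.zeros((H, W), bool)
    pos3d = np.zeros((H, W, 3))
    for ti in range(len(mesh.T)):
        tv = mesh.T[ti]
        p = px[tv]
        x0, y0 = np.floor(p.min(0)).astype(int)
        x1, y1 = np.ceil(p.max(0)).astype(int)
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, W - 1), min(y1, H - 1)
        if x1 < x0 or y1 < y0:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        d = (p[1, 0] - p[0, 0]) * (p[2, 1] - p[0, 1]) \
            - (p[2, 0] - p[0, 0]) * (p[1, 1] - p[0, 1])
        if abs(d) < 1e-12:
            continue
        w1 = ((gx - p[0, 0]) * (p[2, 1] - p[0, 1])
              - (p[2, 0] - p[0, 0]) * (gy - p[0, 1])) / d
        w2 = ((p[1, 0] - p[0, 0]) * (gy - p[0, 1])
              - (gx - p[0, 0]) * (p[1, 1] - p[0, 1])) / d
        w0 = 1.0 - w1 - w2
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        ys, xs = gy[inside], gx[inside]
        wb = np.stack([w0[inside], w1[inside], w2[inside]], axis=1)
        img[ys, xs] = wb @ colors[tv]
        pos3d[ys, xs] = wb @ mesh.V[tv]
        alpha[ys, xs] = True

    if texture_sampler is not None and alpha.any():
        vals = np.asarray(texture_sampler(pos3d[alpha]), float)
        if vals.ndim == 1:
            vals = vals[:, None]          # grayscale: broadcast over channels
        img[alpha] = vals

    gray = img.mean(2) if img.shape[2] > 1 else img[..., 0]
    meta = {"uv_to_pixel": uv_to_pixel.tolist(),
            "pixel_per_uv": scale,
            "width": W, "height": H}
    return RasterImage(np.clip(gray, 0, 1)), alpha, meta
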