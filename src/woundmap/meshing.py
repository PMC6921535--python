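"""Point-cloud meshing for locally height-field-like skin patches.

A photographed wound patch is, at desk scale, a height field over the
dominant plane of its reconstructed point cloud. The mesher exploits this:
it fits the dominant plane by PCA, bins points on a regular in-plane grid,
takes a robust per-cell height, fills small interior holes, and triangulates
the occupied cells into a consistently oriented mesh. An injection point
(``load_mesh``) accepts externally produced meshes (e.g. a Poisson surface
reconstruction) with the same downstream contract.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage

__all__ = ["TriangleMesh", "mesh_point_cloud", "load_mesh", "save_mesh"]


@dataclass
class TriangleMesh:
    """Indexed triangle mesh ``K = (V, T)`` with optional per-vertex color."""

    V: np.ndarray                       # (n, 3) vertex positions
    T: np.ndarray                       # (m, 3) vertex indices
    colors: np.ndarray | None = None    # (n, 3) in [0, 1]

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, float).reshape(-1, 3)
        self.T = np.asarray(self.T, int).reshape(-1, 3)
        if self.T.size and (self.T.min() < 0 or self.T.max() >= len(self.V)):
            raise ValueError("triangle indices out of range")

    def triangle_areas(self) -> np.ndarray:
        a = self.V[self.T[:, 1]] - self.V[self.T[:, 0]]
        b = self.V[self.T[:, 2]] - self.V[self.T[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def edges(self) -> np.ndarray:
        e = np.concatenate([self.T[:, [0, 1]], self.T[:, [1, 2]], self.T[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def boundary_vertices(self) -> np.ndarray:
        e = np.concatenate([self.T[:, [0, 1]], self.T[:, [1, 2]], self.T[:, [2, 0]]])
        e_sorted = np.sort(e, axis=1)
        uniq, counts = np.unique(e_sorted, axis=0, return_counts=True)
        return np.unique(uniq[counts == 1])

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.V, faces=self.T, process=False)

    def is_edge_connected(self) -> bool:
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components
        e = self.edges()
        n = len(self.V)
        g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        ncomp, labels = connected_components(g, directed=False)
        used = np.zeros(n, bool)
        used[self.T.ravel()] = True
        return len(np.unique(labels[used])) == 1 and used.all()

    def compacted(self) -> "TriangleMesh":
        """Drop unreferenced vertices, remapping triangle indices."""
        used = np.unique(self.T.ravel())
        remap = np.full(len(self.V), -1)
        remap[used] = np.arange(len(used))
        cols = self.colors[used] if self.colors is not None else None
        return TriangleMesh(self.V[used], remap[self.T], cols)


def mesh_point_cloud(points: np.ndarray, grid_resolution: int | None = 64,
                     camera_center: np.ndarray | None = None,
                     smooth_cells: float = 1.0, trim_boundary: bool = False,
                     min_points: int = 20) -> TriangleMesh:
    """Triangulate a height-field-like point cloud.

    The dominant plane is the span of the two leading PCA axes of the
    centred cloud. Points are binned on a ``grid_resolution`` square grid
    over the in-plane bounding box (``None`` selects the resolution from the
    point density, about 3 points per cell, capped at 64 — a sparse
    feature-based cloud cannot support a finer grid without fragmenting); each occupied cell takes the median
    height of its points (robust to stray outliers), lightly smoothed over
    the grid (``smooth_cells`` Gaussian cells) to suppress sparse-cloud
    noise that would otherwise wrinkle — and so inflate — the surface.
    Interior holes — typical wherever the photographs are featureless, i.e.
    inside the wound and under the tapes — are filled by a global quadratic
    height fit plus linear interpolation of its residuals, which reproduces
    the patch curvature across the hole to second order. Triangle
    orientation is made consistent, with normals toward ``camera_center``
    when given (else toward the PCA plane's +z).

    Raises when the cloud is too small or not height-field-like (per-cell
    height spreads comparable to the patch extent indicate a folded
    surface; use an external mesher and ``load_mesh`` instead).
    """
    P = np.asarray(points, float).reshape(-1, 3)
    if len(P) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(P)}")
    c = P.mean(0)
    Q = P - c
    # PCA of the cloud: rows of vt are the principal axes
    _, sv, vt = np.linalg.svd(Q, full_matrices=False)
    ex, ey, ez = vt
    uv = Q @ np.column_stack([ex, ey])
    h = Q @ ez

    if grid_resolution is None:
        grid_resolution = int(np.clip(np.sqrt(len(P) / 3.0), 16, 64))
    n = int(grid_resolution)
    lo = uv.min(0)
    hi = uv.max(0)
    span = np.maximum(hi - lo, 1e-12)
    ij = np.minimum((uv - lo) / span * n, n - 1e-9).astype(int)
    flat = ij[:, 1] * n + ij[:, 0]

    # median height and occupancy per cell
    order = np.argsort(flat, kind="stable")
    flat_s, h_s = flat[order], h[order]
    uniq, starts = np.unique(flat_s, return_index=True)
    H = np.full(n * n, np.nan)
    spread = []
    ends = np.append(starts[1:], len(flat_s))
    for u, a, b in zip(uniq, starts, ends):
        vals = h_s[a:b]
        H[u] = np.median(vals)
        if b - a > 1:
            spread.append(vals.max() - vals.min())
    H = H.reshape(n, n)
    extent = float(span.max())
    if spread and np.median(spread) > 0.25 * extent:
        raise ValueError("cloud is not height-field-like; "
                         "mesh externally and inject via load_mesh")

    occ = ~np.isnan(H)
    # Interior holes (cells enclosed by occupied ones) arise wherever the
    # photographs are featureless — notably inside the wound itself and under
    # the tapes. Fill them with a global quadratic height fit (capturing the
    # patch curvature to second order) plus linear interpolation of its
    # residuals from the occupied cells.
    filled = ndimage.binary_fill_holes(occ)
    holes = filled & ~occ
    if holes.any():
        gy, gx = np.mgrid[0:n, 0:n] / max(n - 1, 1)
        def qbasis(xx, yy):
            return np.column_stack([np.ones_like(xx), xx, yy, xx * yy,
                                    xx ** 2, yy ** 2])
        A = qbasis(gx[occ], gy[occ])
        coef, *_ = np.linalg.lstsq(A, H[occ], rcond=None)
        resid = H[occ] - A @ coef
        from scipy.interpolate import griddata
        r_fill = griddata(np.column_stack([gx[occ], gy[occ]]), resid,
                          np.column_stack([gx[holes], gy[holes]]),
                          method="linear", fill_value=0.0)
        H[holes] = qbasis(gx[holes], gy[holes]) @ coef + r_fill
        occ = filled

    # Optionally trim the outermost ring of cells: edge cells of a sparse
    # photogrammetric cloud are constrained by few points and extrapolate
    # poorly, producing rim artefacts on the textured chart. Off by default
    # so that the mesh footprint covers the full cloud.
    if trim_boundary and occ.sum() > 200:
        occ = ndimage.binary_erosion(occ)
        H = np.where(occ, H, np.nan)

    if smooth_cells > 0:
        W = occ.astype(float)
        Hs = ndimage.gaussian_filter(np.where(occ, H, 0.0), smooth_cells)
        Ws = ndimage.gaussian_filter(W, smooth_cells)
        with np.errstate(invalid="ignore"):
            H = np.where(occ, Hs / np.maximum(Ws, 1e-12), np.nan)

    # vertices at occupied cell centres
    vid = np.full((n, n), -1, dtype=int)
    iy, ix = np.nonzero(occ)
    vid[iy, ix] = np.arange(len(ix))
    cu = lo[0] + (ix + 0.5) / n * span[0]
    cv = lo[1] + (iy + 0.5) / n * span[1]
    V = c + np.outer(cu, ex) + np.outer(cv, ey) + np.outer(H[iy, ix], ez)

    tris = []
    for yy in range(n - 1):
        for xx in range(n - 1):
            a, b2 = vid[yy, xx], vid[yy, xx + 1]
            d, e = vid[yy + 1, xx], vid[yy + 1, xx + 1]
            if min(a, b2, d, e) >= 0:
                tris.append((a, b2, e))
                tris.append((a, e, d))
            elif a >= 0 and b2 >= 0 and d >= 0:
                tris.append((a, b2, d))
            elif a >= 0 and b2 >= 0 and e >= 0:
                tris.append((a, b2, e))
            elif a >= 0 and d >= 0 and e >= 0:
                tris.append((a, e, d))
            elif b2 >= 0 and d >= 0 and e >= 0:
                tris.append((b2, e, d))
    if not tris:
        raise ValueError("occupied cells do not form any triangle")
    mesh = TriangleMesh(V, np.array(tris)).compacted()

    # keep only the largest edge-connected component
    tm = mesh.as_trimesh()
    comps = tm.split(only_watertight=False)
    if len(comps) > 1:
        big = max(comps, key=lambda m: len(m.faces))
        mesh = TriangleMesh(np.asarray(big.vertices), np.asarray(big.faces)).compacted()

    # orient: consistent winding, normals toward the camera side
    ref = np.asarray(camera_center, float) if camera_center is not None else c + ez
    tm = mesh.as_trimesh()
    trimesh.repair.fix_winding(tm)
    normals = tm.face_normals
    centers = tm.triangles_center
    toward = np.einsum("ij,ij->i", normals, ref - centers)
    if np.median(toward) < 0:
        tm.invert()
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def load_mesh(path, strict: bool = False) -> TriangleMesh:
    """Read a PLY/OBJ mesh. Degenerate (zero-area) faces are dropped with a
    warning, or rejected in strict mode; quads are triangulated by trimesh."""
    tm = trimesh.load_mesh(path, process=False)
    mesh = TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))
    areas = mesh.triangle_areas()
    bad = areas <= 0
    if bad.any():
        if strict:
            raise ValueError(f"{int(bad.sum())} degenerate faces in {path}")
        import warnings
        warnings.warn(f"dropping {int(bad.sum())} degenerate faces from {path}")
        mesh = TriangleMesh(mesh.V, mesh.T[~bad])
    return mesh


def save_mesh(mesh: TriangleMesh, path, uv: np.ndarray | None = None) -> None:
    """Write PLY or OBJ; with ``uv`` given, OBJ output carries ``vt`` records
    and ``f v/vt`` faces."""
    path = str(path)
    if uv is not None and path.lower().endswith(".obj"):
        lines = []
        for v in mesh.V:
            lines.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
        for q in uv:
            lines.append(f"vt {q[0]:.9g} {q[1]:.9g}")
        for t in mesh.T:
            lines.append("f " + " ".join(f"{i + 1}/{i + 1}" for i in t))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return
    mesh.as_trimesh().export(path)
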