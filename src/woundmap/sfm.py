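"""Incremental structure from motion over a set of overlapping photographs.

Recovers camera poses and a sparse 3D point cloud from pairwise feature
matches: union-find track building, essential-matrix initialisation of a
seed pair, DLT triangulation, RANSAC PnP registration of further views, and
sparse bundle adjustment. The reconstruction is metric only up to an
arbitrary global similarity — the gauge fixes the first camera at the
identity and the seed baseline at 1; physical scale enters the pipeline
solely through the downstream tape calibration.

Pose convention: ``x_cam = R X + t`` (world to camera), pixel
``(f x/z + cx, f y/z + cy)``; the camera centre is ``-R^T t``.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix
from scipy.spatial.transform import Rotation

from .features import (FundamentalMatrix, Keypoint, MatchSet, RasterImage,
                       detect_and_describe, match_descriptors, ransac_fundamental)

__all__ = [
    "CameraPose", "Track", "SparseCloud", "SfmConfig", "stage_seed",
    "build_tracks", "fundamental_from_poses", "initialize_pair",
    "triangulate", "ransac_pnp", "register_next", "bundle_adjust",
    "reconstruct",
]


def stage_seed(pipeline_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out (CRC32 of "seed:stage")."""
    return zlib.crc32(f"{pipeline_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class CameraPose:
    """World-to-camera rigid transform plus pinhole intrinsics."""

    R: np.ndarray
    t: np.ndarray
    focal: float
    cx: float
    cy: float
    id: str = ""

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float).reshape(3, 3)
        self.t = np.asarray(self.t, float).reshape(3)
        err = np.abs(self.R @ self.R.T - np.eye(3)).max()
        if err > 1e-6 or np.linalg.det(self.R) < 0:
            raise ValueError("R must be a proper rotation")

    @property
    def center(self) -> np.ndarray:
        return -self.R.T @ self.t

    def K(self) -> np.ndarray:
        return np.array([[self.focal, 0, self.cx],
                         [0, self.focal, self.cy], [0, 0, 1.0]])

    def project(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Xc = np.atleast_2d(X) @ self.R.T + self.t
        z = Xc[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            px = np.column_stack([self.focal * Xc[:, 0] / z + self.cx,
                                  self.focal * Xc[:, 1] / z + self.cy])
        return px, z


@dataclass
class Track:
    """One physical surface point observed in >= 2 images."""

    observations: list[tuple[str, int, float, float]]  # (image, kp index, x, y)
    point3d: np.ndarray | None = None

    def images(self) -> list[str]:
        return [o[0] for o in self.observations]


@dataclass
class SparseCloud:
    points: np.ndarray                       # (n, 3)
    errors: np.ndarray                       # per-point mean reprojection (px)
    track_ids: np.ndarray                    # index into the track list

    def __len__(self) -> int:
        return len(self.points)


class _DSU:
    def __init__(self):
        self.parent: dict = {}

    def find(self, a):
        p = self.parent.setdefault(a, a)
        if p != a:
            p = self.parent[a] = self.find(p)
        return p

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_tracks(matchsets: list[MatchSet],
                 keypoints: dict[str, list[Keypoint]]) -> list[Track]:
    """Connected components of the pairwise (inlier) match graph.

    A component containing two different keypoints of the same image is
    internally inconsistent and discarded.
    """
    dsu = _DSU()
    for ms in matchsets:
        for i, j, _ in ms.inlier_pairs():
            dsu.union((ms.image_a, i), (ms.image_b, j))
    comps: dict = {}
    for node in list(dsu.parent):
        comps.setdefault(dsu.find(node), []).append(node)
    tracks = []
    for members in comps.values():
        if len(members) < 2:
            continue
        imgs = [m[0] for m in members]
        if len(set(imgs)) != len(imgs):
            continue  # same image twice: inconsistent
        obs = []
        for img, idx in sorted(members):
            kp = keypoints[img][idx]
            obs.append((img, idx, kp.x, kp.y))
        tracks.append(Track(obs))
    tracks.sort(key=lambda tr: tuple(o[:2] for o in tr.observations))
    return tracks


def fundamental_from_poses(pa: CameraPose, pb: CameraPose) -> FundamentalMatrix:
    """Ground-truth F of a camera pair (convention ``p_b^T F p_a = 0``)."""
    R = pb.R @ pa.R.T
    t = pb.t - R @ pa.t
    tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
    F = np.linalg.inv(pb.K()).T @ tx @ R @ np.linalg.inv(pa.K())
    F = F / np.linalg.norm(F)
    idx = np.unravel_index(np.argmax(np.abs(F)), F.shape)
    return FundamentalMatrix(F if F[idx] > 0 else -F)


def _triangulate_linear(P1, P2, x1, x2):
    A = np.array([x1[0] * P1[2] - P1[0], x1[1] * P1[2] - P1[1],
                  x2[0] * P2[2] - P2[0], x2[1] * P2[2] - P2[1]])
    _, _, vt = np.linalg.svd(A)
    X = vt[-1]
    return X[:3] / X[3]


def triangulate(pose_a: CameraPose, pose_b: CameraPose,
                obs_a, obs_b) -> tuple[np.ndarray, tuple[float, float], bool]:
    """Linear (DLT) two-view triangulation.

    Returns the 3D point, its two reprojection residuals (px), and a
    low-confidence flag raised when the viewing rays subtend < 0.5 degrees.
    """
    if np.allclose(pose_a.center, pose_b.center):
        raise ValueError("camera centres coincide; cannot triangulate")
    P1 = pose_a.K() @ np.hstack([pose_a.R, pose_a.t[:, None]])
    P2 = pose_b.K() @ np.hstack([pose_b.R, pose_b.t[:, None]])
    X = _triangulate_linear(P1, P2, np.asarray(obs_a, float), np.asarray(obs_b, float))
    res = []
    for pose, obs in ((pose_a, obs_a), (pose_b, obs_b)):
        px, _ = pose.project(X)
        res.append(float(np.linalg.norm(px[0] - obs)))
    r1 = X - pose_a.center
    r2 = X - pose_b.center
    cosang = r1 @ r2 / (np.linalg.norm(r1) * np.linalg.norm(r2))
    low_conf = np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 0.5
    return X, (res[0], res[1]), bool(low_conf)


def _refine_relative_pose(R: np.ndarray, t: np.ndarray, na: np.ndarray,
                          nb: np.ndarray, max_nfev: int = 100):
    """Refine (R, t-direction) by minimising the Sampson error of the
    essential matrix over normalised inlier correspondences.

    The closed-form decomposition of an estimated F is exquisitely sensitive
    to noise for short baselines; this 5-dof refinement restores the epipole
    using every inlier."""
    r0 = Rotation.from_matrix(R).as_rotvec()
    th0 = np.arccos(np.clip(t[2] / np.linalg.norm(t), -1, 1))
    ph0 = np.arctan2(t[1], t[0])
    pa = np.column_stack([na, np.ones(len(na))])
    pb = np.column_stack([nb, np.ones(len(nb))])

    def unpack(p):
        Rm = Rotation.from_rotvec(p[:3]).as_matrix()
        st, ct = np.sin(p[3]), np.cos(p[3])
        tv = np.array([st * np.cos(p[4]), st * np.sin(p[4]), ct])
        return Rm, tv

    def resid(p):
        Rm, tv = unpack(p)
        tx = np.array([[0, -tv[2], tv[1]], [tv[2], 0, -tv[0]],
                       [-tv[1], tv[0], 0]])
        E = tx @ Rm
        Ea = pa @ E.T
        Etb = pb @ E
        num = np.einsum("ij,ij->i", pb, Ea)
        den = np.sqrt(Ea[:, 0] ** 2 + Ea[:, 1] ** 2
                      + Etb[:, 0] ** 2 + Etb[:, 1] ** 2)
        return num / np.maximum(den, 1e-300)

    sol = least_squares(resid, np.array([*r0, th0, ph0]), method="lm",
                        max_nfev=max_nfev)
    return unpack(sol.x)


def initialize_pair(F: FundamentalMatrix, ka: CameraPose | None,
                    xa: np.ndarray, xb: np.ndarray, Ka: np.ndarray,
                    Kb: np.ndarray, ids=("a", "b"),
                    ) -> tuple[CameraPose, CameraPose, np.ndarray]:
    """Seed a reconstruction from a fundamental matrix and inlier matches.

    The essential matrix ``E = Kb^T F Ka`` is decomposed into the four
    rotation/translation candidates; the candidate that places the most
    triangulated points in front of both cameras wins. The first camera is
    the identity pose and the baseline is normalised to 1.
    """
    del ka  # the first camera is pinned at the identity by convention
    xa = np.atleast_2d(np.asarray(xa, float))
    xb = np.atleast_2d(np.asarray(xb, float))
    E = Kb.T @ F.F @ Ka
    U, _, Vt = np.linalg.svd(E)
    if np.linalg.det(U) < 0:
        U = -U
    if np.linalg.det(Vt) < 0:
        Vt = -Vt
    W = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    cands = []
    for R in (U @ W @ Vt, U @ W.T @ Vt):
        for tsign in (1.0, -1.0):
            cands.append((R, tsign * U[:, 2]))
    fa = (Ka[0, 0] + Ka[1, 1]) / 2
    fb = (Kb[0, 0] + Kb[1, 1]) / 2
    pose_a = CameraPose(np.eye(3), np.zeros(3), fa, Ka[0, 2], Ka[1, 2], ids[0])
    best = None
    counts = []
    for R, t in cands:
        pose_b = CameraPose(R, t, fb, Kb[0, 2], Kb[1, 2], ids[1])
        P1 = pose_a.K() @ np.hstack([pose_a.R, pose_a.t[:, None]])
        P2 = pose_b.K() @ np.hstack([pose_b.R, pose_b.t[:, None]])
        pts = np.array([_triangulate_linear(P1, P2, p, q) for p, q in zip(xa, xb)])
        z1 = pts @ pose_a.R[2] + pose_a.t[2]
        z2 = pts @ pose_b.R[2] + pose_b.t[2]
        good = int(((z1 > 0) & (z2 > 0)).sum())
        counts.append(good)
        if best is None or good > best[0]:
            best = (good, pose_b, pts)
    counts.sort(reverse=True)
    if best[0] < 0.5 * len(xa) or (len(counts) > 1 and counts[0] == counts[1]):
        raise ValueError("degenerate initial pair (cheirality test failed)")
    if np.linalg.norm(best[1].t) < 1e-12:
        raise ValueError("degenerate initial pair (no baseline)")
    # refine the winning candidate on all inliers (short-baseline pairs make
    # the closed-form epipole unreliable), then re-triangulate
    na = (np.column_stack([xa, np.ones(len(xa))]) @ np.linalg.inv(Ka).T)[:, :2]
    nb = (np.column_stack([xb, np.ones(len(xb))]) @ np.linalg.inv(Kb).T)[:, :2]
    Rr, tr = _refine_relative_pose(best[1].R, best[1].t, na, nb)
    pose_b = CameraPose(Rr, tr / np.linalg.norm(tr), fb, Kb[0, 2], Kb[1, 2], ids[1])
    P1 = pose_a.K() @ np.hstack([pose_a.R, pose_a.t[:, None]])
    P2 = pose_b.K() @ np.hstack([pose_b.R, pose_b.t[:, None]])
    pts = np.array([_triangulate_linear(P1, P2, p, q) for p, q in zip(xa, xb)])
    z1 = pts @ pose_a.R[2] + pose_a.t[2]
    z2 = pts @ pose_b.R[2] + pose_b.t[2]
    if int(((z1 > 0) & (z2 > 0)).sum()) < 0.5 * len(xa):
        raise ValueError("degenerate initial pair (cheirality after refinement)")
    return pose_a, pose_b, pts


def _pose_from_plane(X: np.ndarray, x: np.ndarray, K: np.ndarray) -> tuple | None:
    """Resection for (near-)coplanar points via plane-to-image homography.

    Wound patches reconstruct to shallow, almost planar clouds, for which
    the 12-parameter DLT resection is ill-conditioned; the homography
    decomposition ``H ~ K [r1 r2 t]`` stays well-posed there.
    """
    c = X.mean(0)
    _, _, vt = np.linalg.svd(X - c, full_matrices=False)
    uv = (X - c) @ vt[:2].T            # plane coordinates
    n = len(X)
    A = np.zeros((2 * n, 9))
    for i, ((u, v), xi) in enumerate(zip(uv, x)):
        A[2 * i] = [u, v, 1, 0, 0, 0, -xi[0] * u, -xi[0] * v, -xi[0]]
        A[2 * i + 1] = [0, 0, 0, u, v, 1, -xi[1] * u, -xi[1] * v, -xi[1]]
    try:
        _, _, vh = np.linalg.svd(A)
    except np.linalg.LinAlgError:
        return None
    H = vh[-1].reshape(3, 3)
    M = np.linalg.inv(K) @ H
    n1, n2 = np.linalg.norm(M[:, 0]), np.linalg.norm(M[:, 1])
    if n1 < 1e-12 or n2 < 1e-12:
        return None
    lam = 2.0 / (n1 + n2)
    best = None
    for sign in (1.0, -1.0):
        r1, r2 = sign * lam * M[:, 0], sign * lam * M[:, 1]
        Rp = np.column_stack([r1, r2, np.cross(r1, r2)])
        U, _, Vt = np.linalg.svd(Rp)
        Rp = U @ np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))]) @ Vt
        tp = sign * lam * M[:, 2]
        # compose plane frame -> world: X = c + basis^T uv
        R = Rp @ np.vstack([vt[:2], np.cross(vt[0], vt[1])])
        t = tp - R @ c
        depths = X @ R[2] + t[2]
        front = int((depths > 0).sum())
        if best is None or front > best[0]:
            best = (front, R, t)
    if best is None or best[0] < 0.75 * n:
        return None
    return best[1], best[2]


def _pose_from_dlt(X: np.ndarray, x: np.ndarray, K: np.ndarray) -> tuple | None:
    """Linear camera resection: P from >= 6 2D-3D pairs, decomposed against
    the known intrinsics into the nearest rigid pose."""
    flat = np.linalg.svd(X - X.mean(0), full_matrices=False)[1]
    if flat[0] > 0 and flat[2] / flat[0] < 0.05:
        return _pose_from_plane(X, x, K)
    n = len(X)
    A = np.zeros((2 * n, 12))
    for i, (Xi, xi) in enumerate(zip(X, x)):
        Xh = np.append(Xi, 1.0)
        A[2 * i, 0:4] = Xh
        A[2 * i, 8:12] = -xi[0] * Xh
        A[2 * i + 1, 4:8] = Xh
        A[2 * i + 1, 8:12] = -xi[1] * Xh
    try:
        _, _, vt = np.linalg.svd(A)
    except np.linalg.LinAlgError:
        return None
    P = vt[-1].reshape(3, 4)
    M = np.linalg.inv(K) @ P
    U, s, Vt = np.linalg.svd(M[:, :3])
    if s[-1] / s[0] < 1e-8:
        return None
    R = U @ Vt
    scale = s.mean()
    if np.linalg.det(R) < 0:
        R, scale = -R, -scale
    t = M[:, 3] / scale
    # orient so points lie in front
    if np.median(X @ R[2] + t[2]) < 0:
        R, t = -R, -t
        if np.linalg.det(R) < 0:  # flipping all three axes is improper
            return None
    return R, t


def _refine_pose(R, t, X, x, K, max_nfev=50):
    r0 = Rotation.from_matrix(R).as_rotvec()

    def resid(p):
        Rm = Rotation.from_rotvec(p[:3]).as_matrix()
        Xc = X @ Rm.T + p[3:]
        px = Xc[:, :2] / Xc[:, 2:3] * K[0, 0] + np.array([K[0, 2], K[1, 2]])
        return (px - x).ravel()

    sol = least_squares(resid, np.concatenate([r0, t]), method="lm",
                        max_nfev=max_nfev)
    return Rotation.from_rotvec(sol.x[:3]).as_matrix(), sol.x[3:]


def ransac_pnp(points3d: np.ndarray, points2d: np.ndarray, K: np.ndarray,
               threshold_px: float = 4.0, iterations: int = 500,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RANSAC pose estimation from 2D-3D correspondences.

    Returns (R, t, inlier_mask); the pose is refined on the inliers by
    nonlinear minimisation of the squared reprojection error.
    """
    X = np.asarray(points3d, float)
    x = np.asarray(points2d, float)
    n = len(X)
    if n < 6:
        raise ValueError("need at least 6 correspondences for PnP")
    rng = np.random.default_rng(seed)
    best_mask, best_count = None, -1
    for _ in range(iterations):
        idx = rng.choice(n, size=6, replace=False)
        res = _pose_from_dlt(X[idx], x[idx], K)
        if res is None:
            continue
        R, t = res
        Xc = X @ R.T + t
        ok = Xc[:, 2] > 1e-9
        px = np.full_like(x, np.inf)
        px[ok] = Xc[ok, :2] / Xc[ok, 2:3] * K[0, 0] + np.array([K[0, 2], K[1, 2]])
        d = np.linalg.norm(px - x, axis=1)
        mask = ok & (d <= threshold_px)
        if mask.sum() > best_count:
            best_count, best_mask = int(mask.sum()), mask
            if best_count == n:
                break
    if best_mask is None or best_count < 6:
        raise ValueError("PnP failed: no consensus pose")
    res = _pose_from_dlt(X[best_mask], x[best_mask], K)
    if res is None:
        raise ValueError("PnP failed on the consensus set")
    R, t = _refine_pose(*res, X[best_mask], x[best_mask], K)
    Xc = X @ R.T + t
    d = np.linalg.norm(Xc[:, :2] / Xc[:, 2:3] * K[0, 0]
                       + np.array([K[0, 2], K[1, 2]]) - x, axis=1)
    mask = (Xc[:, 2] > 0) & (d <= threshold_px)
    return R, t, mask


def register_next(points3d: np.ndarray, points2d: np.ndarray, K: np.ndarray,
                  image_id: str = "", seed: int = 0,
                  threshold_px: float = 4.0) -> tuple[CameraPose, np.ndarray]:
    """Register one new image against the current cloud (RANSAC PnP)."""
    R, t, mask = ransac_pnp(points3d, points2d, K, threshold_px=threshold_px,
                            seed=seed)
    pose = CameraPose(R, t, (K[0, 0] + K[1, 1]) / 2, K[0, 2], K[1, 2], image_id)
    return pose, mask


# ------------------------------------------------------------------ bundle

def bundle_adjust(poses: list[CameraPose], points: np.ndarray,
                  observations: list[tuple[int, int, float, float]],
                  refine_focal: bool = False, max_nfev: int = 60,
                  verbose: int = 0) -> tuple[list[CameraPose], np.ndarray, dict]:
    """Joint nonlinear refinement of poses and structure.

    ``observations`` rows are ``(camera index, point index, x, y)``. The
    first camera is pinned (gauge); the overall scale is re-pinned after
    optimisation by restoring the initial distance between the first two
    camera centres. Total squared reprojection error is non-increasing (the
    trust-region solver only accepts descent steps).
    """
    n_cam, n_pts = len(poses), len(points)
    obs = np.asarray(observations, float)
    cam_i = obs[:, 0].astype(int)
    pt_i = obs[:, 1].astype(int)
    meas = obs[:, 2:4]
    cx, cy = poses[0].cx, poses[0].cy
    f0 = poses[0].focal

    def pack():
        p = []
        for pose in poses[1:]:
            p.append(Rotation.from_matrix(pose.R).as_rotvec())
            p.append(pose.t)
        p.append(points.ravel())
        if refine_focal:
            p.append([f0])
        return np.concatenate([np.ravel(v) for v in p])

    def unpack(vec):
        Rs = [poses[0].R]
        ts = [poses[0].t]
        off = 0
        for _ in range(n_cam - 1):
            Rs.append(Rotation.from_rotvec(vec[off:off + 3]).as_matrix())
            ts.append(vec[off + 3:off + 6])
            off += 6
        pts = vec[off:off + 3 * n_pts].reshape(-1, 3)
        off += 3 * n_pts
        f = vec[off] if refine_focal else f0
        return Rs, ts, pts, f

    def resid(vec):
        Rs, ts, pts, f = unpack(vec)
        Rstack = np.stack(Rs)
        tstack = np.stack(ts)
        Xc = np.einsum("oij,oj->oi", Rstack[cam_i], pts[pt_i]) + tstack[cam_i]
        z = np.maximum(Xc[:, 2], 1e-9)
        px = Xc[:, :2] / z[:, None] * f + np.array([cx, cy])
        return (px - meas).ravel()

    # sparsity pattern: each residual touches one camera block and one point
    n_params = 6 * (n_cam - 1) + 3 * n_pts + (1 if refine_focal else 0)
    spar = lil_matrix((2 * len(obs), n_params), dtype=np.uint8)
    for row, (ci, pi) in enumerate(zip(cam_i, pt_i)):
        if ci > 0:
            spar[2 * row:2 * row + 2, 6 * (ci - 1):6 * ci] = 1
        base = 6 * (n_cam - 1) + 3 * pi
        spar[2 * row:2 * row + 2, base:base + 3] = 1
        if refine_focal:
            spar[2 * row:2 * row + 2, -1] = 1

    x0 = pack()
    e0 = resid(x0)
    sol = least_squares(resid, x0, jac_sparsity=spar.tocsr(), method="trf",
                        x_scale="jac", max_nfev=max_nfev, verbose=verbose)
    Rs, ts, pts, f = unpack(sol.x)
    base0 = np.linalg.norm(poses[0].center - poses[1].center)
    new_poses = []
    for k in range(n_cam):
        new_poses.append(CameraPose(Rs[k], ts[k], f if refine_focal else poses[k].focal,
                                    poses[k].cx, poses[k].cy, poses[k].id))
    # re-pin the scale gauge to the initial seed baseline
    base1 = np.linalg.norm(new_poses[0].center - new_poses[1].center)
    if base1 > 0 and base0 > 0:
        sfac = base0 / base1
        pts = pts * sfac
        for pose in new_poses:
            pose.t = pose.t * sfac
    info = {"initial_rms": float(np.sqrt((e0 ** 2).mean())),
            "final_rms": float(np.sqrt((sol.fun ** 2).mean())),
            "nfev": int(sol.nfev), "focal": float(f)}
    return new_poses, pts, info


# -------------------------------------------------------------- pipeline

@dataclass
class SfmConfig:
    """Knobs of the reconstruction front end and back end."""

    focal: float | None = None        # px; None -> 1.2 * max(width, height)
    sigma0: float = 1.6
    levels: int = 3
    contrast_threshold: float = 0.03
    edge_ratio: float = 10.0
    max_keypoints: int = 2000
    match_ratio: float = 0.8
    match_window: int = 2             # cyclic neighbour span for pairing
    ransac_threshold_px: float = 1.5
    ransac_iterations: int = 2000
    min_pair_inliers: int = 30
    pnp_threshold_px: float = 4.0
    cull_reprojection_px: float = 4.0
    min_triangulation_deg: float = 0.5
    ba_every: int = 4
    ba_max_nfev: int = 40
    refine_focal: bool = False
    min_images_warning: int = 20


def _intrinsics_for(img: RasterImage, cfg: SfmConfig) -> np.ndarray:
    f = cfg.focal if cfg.focal is not None else 1.2 * max(img.width, img.height)
    return np.array([[f, 0, img.width / 2.0], [0, f, img.height / 2.0], [0, 0, 1.0]])


def reconstruct(images: list[RasterImage], cfg: SfmConfig | None = None,
                seed: int = 0) -> tuple[dict[str, CameraPose], SparseCloud,
                                        list[Track], dict]:
    """Full incremental reconstruction from photographs.

    Returns registered poses keyed by image id, the sparse cloud, the track
    list (tracks carry their 3D point when reconstructed), and a per-stage
    log. Fewer than ``cfg.min_images_warning`` images is allowed but logged
    as a warning (measurement accuracy degrades with very few views).
    """
    cfg = cfg or SfmConfig()
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    log: dict = {"warnings": [], "stages": {}}
    if len(images) < cfg.min_images_warning:
        log["warnings"].append(
            f"only {len(images)} images; >= {cfg.min_images_warning} recommended")

    # ---- features
    kps: dict[str, list[Keypoint]] = {}
    desc: dict[str, np.ndarray] = {}
    ids = [im.id or f"img{k:03d}" for k, im in enumerate(images)]
    for im, iid in zip(images, ids):
        k, d = detect_and_describe(im, sigma0=cfg.sigma0, levels=cfg.levels,
                                   contrast_threshold=cfg.contrast_threshold,
                                   edge_ratio=cfg.edge_ratio,
                                   max_keypoints=cfg.max_keypoints)
        kps[iid], desc[iid] = k, d
    log["stages"]["features"] = {i: len(kps[i]) for i in ids}

    # ---- pairwise matching over a cyclic neighbour window
    n = len(ids)
    pairs = set()
    for i in range(n):
        for w in range(1, cfg.match_window + 1):
            j = (i + w) % n
            if i != j:
                pairs.add((min(i, j), max(i, j)) if n > 2 else (0, 1))
    matchsets = []
    pair_log = {}
    for i, j in sorted(pairs):
        a, b = ids[i], ids[j]
        ms = match_descriptors(desc[a], desc[b], ratio=cfg.match_ratio,
                               image_a=a, image_b=b)
        if len(ms.pairs) < 8:
            continue
        try:
            F, filtered = ransac_fundamental(
                ms, kps[a], kps[b], threshold_px=cfg.ransac_threshold_px,
                iterations=cfg.ransac_iterations,
                seed=stage_seed(seed, f"ransac:{a}:{b}"))
        except ValueError:
            continue
        n_in = int(filtered.inlier_mask.sum())
        pair_log[f"{a}|{b}"] = n_in
        if n_in >= cfg.min_pair_inliers:
            matchsets.append(filtered)
    log["stages"]["pairs"] = pair_log
    if not matchsets:
        raise ValueError("no image pair with enough verified matches")

    tracks = build_tracks(matchsets, kps)
    log["stages"]["tracks"] = len(tracks)

    # ---- initial pair: the matchset with the most inliers that triangulates
    Ks = {iid: _intrinsics_for(im, cfg) for im, iid in zip(images, ids)}
    order = sorted(matchsets, key=lambda m: -int(m.inlier_mask.sum()))
    poses: dict[str, CameraPose] = {}
    init_err = None
    for ms in order:
        xa = np.array([[kps[ms.image_a][i].x, kps[ms.image_a][i].y]
                       for i, _, _ in ms.inlier_pairs()])
        xb = np.array([[kps[ms.image_b][j].x, kps[ms.image_b][j].y]
                       for _, j, _ in ms.inlier_pairs()])
        try:
            F, _ = ransac_fundamental(ms, kps[ms.image_a], kps[ms.image_b],
                                      threshold_px=cfg.ransac_threshold_px,
                                      iterations=cfg.ransac_iterations,
                                      seed=stage_seed(seed, "init"))
            pa, pb, _ = initialize_pair(F, None, xa, xb, Ks[ms.image_a],
                                        Ks[ms.image_b],
                                        ids=(ms.image_a, ms.image_b))
        except ValueError as exc:
            init_err = exc
            continue
        poses[ms.image_a] = pa
        poses[ms.image_b] = pb
        break
    if not poses:
        raise ValueError(f"no valid initial pair: {init_err}")

    # ---- incremental registration and triangulation
    def triangulate_ready():
        for ti, tr in enumerate(tracks):
            if tr.point3d is not None:
                continue
            reg = [(img, x, y) for img, _, x, y in tr.observations if img in poses]
            if len(reg) < 2:
                continue
            (ia, xa_, ya_), (ib, xb_, yb_) = reg[0], reg[-1]
            try:
                X, res, low = triangulate(poses[ia], poses[ib],
                                          (xa_, ya_), (xb_, yb_))
            except ValueError:
                continue
            if low or max(res) > cfg.cull_reprojection_px:
                continue
            # require positive depth everywhere observed
            ok = True
            for img, _, x, y in tr.observations:
                if img in poses:
                    _, z = poses[img].project(X)
                    if z[0] <= 0:
                        ok = False
                        break
            if ok:
                tr.point3d = X

    def run_ba(max_nfev):
        reg_ids = [i for i in ids if i in poses]
        idx_of = {i: k for k, i in enumerate(reg_ids)}
        live = [(ti, tr) for ti, tr in enumerate(tracks) if tr.point3d is not None]
        if len(live) < 8:
            return
        pts = np.array([tr.point3d for _, tr in live])
        obs = []
        for pk, (_, tr) in enumerate(live):
            for img, _, x, y in tr.observations:
                if img in poses:
                    obs.append((idx_of[img], pk, x, y))
        plist = [poses[i] for i in reg_ids]
        new_poses, new_pts, info = bundle_adjust(plist, pts, obs,
                                                 refine_focal=cfg.refine_focal,
                                                 max_nfev=max_nfev)
        for i, pose in zip(reg_ids, new_poses):
            poses[i] = pose
        for (_, tr), X in zip(live, new_pts):
            tr.point3d = X
        log["stages"].setdefault("ba", []).append(info)

    triangulate_ready()
    pending = [i for i in ids if i not in poses]
    since_ba = 0
    while pending:
        # next image: most 2D-3D correspondences; ties by id order
        counts = {}
        for iid in pending:
            c = sum(1 for tr in tracks
                    if tr.point3d is not None and iid in tr.images())
            counts[iid] = c
        nxt = max(sorted(pending), key=lambda i: counts[i])
        if counts[nxt] < 6:
            log["warnings"].append(f"image {nxt} skipped: "
                                   f"{counts[nxt]} correspondences (< 6)")
            pending.remove(nxt)
            continue
        X3, x2 = [], []
        for tr in tracks:
            if tr.point3d is None:
                continue
            for img, _, x, y in tr.observations:
                if img == nxt:
                    X3.append(tr.point3d)
                    x2.append((x, y))
        try:
            pose, _ = register_next(np.array(X3), np.array(x2), Ks[nxt],
                                    image_id=nxt,
                                    seed=stage_seed(seed, f"pnp:{nxt}"))
        except ValueError:
            log["warnings"].append(f"image {nxt} skipped: PnP failed")
            pending.remove(nxt)
            continue
        poses[nxt] = pose
        pending.remove(nxt)
        triangulate_ready()
        since_ba += 1
        if since_ba >= cfg.ba_every:
            run_ba(cfg.ba_max_nfev)
            since_ba = 0
    run_ba(2 * cfg.ba_max_nfev)

    # ---- final culling and cloud assembly
    pts, errs, tids = [], [], []
    for ti, tr in enumerate(tracks):
        if tr.point3d is None:
            continue
        res = []
        for img, _, x, y in tr.observations:
            if img in poses:
                px, z = poses[img].project(tr.point3d)
                if z[0] <= 0:
                    res = None
                    break
                res.append(np.linalg.norm(px[0] - (x, y)))
        if not res:
            tr.point3d = None
            continue
        mean_err = float(np.mean(res))
        if mean_err > cfg.cull_reprojection_px:
            tr.point3d = None
            continue
        pts.append(tr.point3d)
        errs.append(mean_err)
        tids.append(ti)
    cloud = SparseCloud(np.array(pts).reshape(-1, 3), np.array(errs),
                        np.array(tids, dtype=int))
    log["stages"]["cloud"] = len(cloud)
    log["stages"]["registered"] = len(poses)
    if len(cloud) < 20:
        raise ValueError("reconstruction produced too few points")
    return poses, cloud, tracks, log
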