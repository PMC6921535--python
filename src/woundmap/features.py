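"""Scale/rotation-invariant features, matching, and epipolar filtering.

The multi-view reconstruction front end: a Gaussian scale-space pyramid with
difference-of-Gaussians (DoG) keypoint detection, gradient-orientation
assignment, 128-dimensional gradient-histogram descriptors, nearest-neighbour
matching with a ratio test, and fundamental-matrix RANSAC to keep only
matches consistent with a two-view epipolar geometry.

Coordinate convention used throughout the package: 0-based pixel centres,
origin at the top-left corner, x to the right (columns), y down (rows).
Orientations are ``atan2(B, A)`` of the pixel-difference gradient, mapped to
[0, 2pi); atan2 (rather than a bare arctan of B/A) resolves the quadrant.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "RasterImage", "ScaleSpace", "Keypoint", "Descriptor", "MatchSet",
    "FundamentalMatrix", "load_image", "build_scale_space", "dog",
    "detect_keypoints", "gradient_mag_ori", "assign_orientation",
    "compute_descriptor", "detect_and_describe", "match_descriptors",
    "sampson_distance", "ransac_fundamental",
    "keypoints_to_json", "keypoints_from_json",
]

# luminance weights for RGB -> gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class RasterImage:
    """A grayscale photograph with intensities in [0, 1]."""

    pixels: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("RasterImage expects a 2D grayscale array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


def load_image(path, id: str | None = None) -> RasterImage:
    """Read a PNG/JPEG image and convert to grayscale luminance."""
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    arr = arr / 255.0
    return RasterImage(np.clip(arr, 0.0, 1.0), id=id or str(path))


@dataclass
class ScaleSpace:
    """Gaussian pyramid: ``octaves[o]`` is a stack of smoothed images.

    Level ``(o, s)`` carries absolute scale ``sigma0 * k**s * 2**o``. Each
    octave holds ``levels + 3`` Gaussian images so that DoG extrema can be
    localised at the ``levels`` interior scales.
    """

    octaves: list[np.ndarray]
    sigmas: list[np.ndarray]          # absolute scale per level, per octave
    sigma0: float
    k: float
    levels: int                       # interior DoG scales searched per octave

    def dog_levels(self, octave: int) -> np.ndarray:
        L = self.octaves[octave]
        return L[1:] - L[:-1]

    @property
    def n_octaves(self) -> int:
        return len(self.octaves)


def _blur(img: np.ndarray, sigma: float) -> np.ndarray:
    # truncate=4 keeps < 1e-4 of the kernel mass outside the support
    return ndimage.gaussian_filter(img, sigma, mode="nearest", truncate=4.0)


def build_scale_space(img: RasterImage, sigma0: float = 1.6, k: float | None = None,
                      levels: int = 3, octaves: int | None = None) -> ScaleSpace:
    """Build the Gaussian scale-space pyramid of an image.

    The input is treated as an unsmoothed signal; level ``(o, s)`` equals the
    image convolved with a Gaussian of scale ``sigma0 * k**s * 2**o``
    (computed incrementally, using the semigroup property of Gaussians).
    ``k`` defaults to ``2**(1/levels)``. Octaves are generated until the
    smaller image dimension would drop below 16 pixels (or ``octaves`` if
    given).
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if levels < 3:
        raise ValueError("levels must be >= 3")
    if k is None:
        k = 2.0 ** (1.0 / levels)
    if k <= 1:
        raise ValueError("k must exceed 1")
    base = img.pixels
    if min(base.shape) < 16:
        raise ValueError("image too small for feature detection (min dim 16)")
    n_per_octave = levels + 3
    max_oct = 1
    d = min(base.shape)
    while d // 2 >= 16:
        max_oct += 1
        d //= 2
    n_oct = max_oct if octaves is None else min(octaves, max_oct)

    octs, sigs = [], []
    prev_sigma = 0.0
    current = base
    for o in range(n_oct):
        stack = np.empty((n_per_octave,) + current.shape)
        abs_sigmas = np.array([sigma0 * k ** s * 2.0 ** o for s in range(n_per_octave)])
        for s, target in enumerate(abs_sigmas):
            inc = np.sqrt(max(target ** 2 - prev_sigma ** 2, 0.0))
            # incremental sigma is in octave pixel units
            current = _blur(current, inc / 2.0 ** o) if inc > 0 else current.copy()
            stack[s] = current
            prev_sigma = target
        octs.append(stack)
        sigs.append(abs_sigmas)
        # next octave: the level at twice sigma0, subsampled by 2
        current = stack[levels][::2, ::2]
        prev_sigma = abs_sigmas[levels]
    return ScaleSpace(octs, sigs, sigma0, k, levels)


def dog(space: ScaleSpace) -> list[np.ndarray]:
    """Difference-of-Gaussians stacks, one per octave."""
    return [space.dog_levels(o) for o in range(space.n_octaves)]


@dataclass
class Keypoint:
    """Sub-pixel oriented scale-space feature (image coordinates)."""

    x: float
    y: float
    sigma: float
    theta: float = 0.0
    response: float = 0.0
    octave: int = 0
    level: float = 1.0       # fractional interior DoG level within the octave

    def octave_xy(self) -> tuple[float, float]:
        f = 2.0 ** self.octave
        return self.x / f, self.y / f


def gradient_mag_ori(L: np.ndarray, x: int, y: int) -> tuple[float, float]:
    """Pixel-difference gradient magnitude and direction at interior (x, y).

    ``A = L(x+1, y) - L(x-1, y)``, ``B = L(x, y+1) - L(x, y-1)``,
    magnitude ``sqrt(A^2 + B^2)``, direction ``atan2(B, A)`` in [0, 2pi).
    """
    h, w = L.shape
    if not (1 <= x <= w - 2 and 1 <= y <= h - 2):
        raise ValueError("gradient undefined on the image border")
    A = L[y, x + 1] - L[y, x - 1]
    B = L[y + 1, x] - L[y - 1, x]
    m = float(np.hypot(A, B))
    theta = float(np.arctan2(B, A)) % (2 * np.pi)
    return m, theta


def detect_keypoints(space: ScaleSpace, contrast_threshold: float = 0.03,
                     edge_ratio: float = 10.0, max_keypoints: int | None = None,
                     ) -> list[Keypoint]:
    """Detect 26-neighbourhood DoG extrema, refined to sub-pixel position.

    A candidate is an extremum of the DoG stack over its 3x3x3 neighbourhood,
    refined by a quadratic fit in (x, y, scale); keypoints with interpolated
    contrast below ``contrast_threshold`` or with an edge-like Hessian
    (principal-curvature ratio above ``edge_ratio``) are discarded.
    """
    kps: list[Keypoint] = []
    for o in range(space.n_octaves):
        D = space.dog_levels(o)
        if D.shape[0] < 3:
            continue
        interior = D[1:-1]
        fp = np.ones((3, 3, 3), bool)
        is_max = (D == ndimage.maximum_filter(D, footprint=fp, mode="nearest"))[1:-1]
        is_min = (D == ndimage.minimum_filter(D, footprint=fp, mode="nearest"))[1:-1]
        cand = (is_max | is_min) & (np.abs(interior) > 0.5 * contrast_threshold)
        cand[:, :8, :] = cand[:, -8:, :] = cand[:, :, :8] = cand[:, :, -8:] = False
        for s0, y0, x0 in zip(*np.nonzero(cand)):
            kp = _refine_extremum(D, int(s0) + 1, int(y0), int(x0),
                                  contrast_threshold, edge_ratio)
            if kp is None:
                continue
            s, y, x, val = kp
            f = 2.0 ** o
            kps.append(Keypoint(x=x * f, y=y * f,
                                sigma=space.sigma0 * space.k ** s * f,
                                response=val, octave=o, level=s))
    # deduplicate: tied extrema in adjacent cells refine to the same
    # sub-pixel point (strongest response wins)
    kps.sort(key=lambda q: -abs(q.response))
    kept: list[Keypoint] = []
    grid: dict[tuple, list[Keypoint]] = {}
    for kp in kps:
        xo, yo = kp.octave_xy()
        cell = (kp.octave, int(xo), int(yo))
        dup = False
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for other in grid.get((kp.octave, cell[1] + dx, cell[2] + dy), ()):
                    ox, oy = other.octave_xy()
                    if (abs(ox - xo) < 0.7 and abs(oy - yo) < 0.7
                            and abs(other.level - kp.level) < 0.7):
                        dup = True
                        break
                if dup:
                    break
            if dup:
                break
        if not dup:
            kept.append(kp)
            grid.setdefault(cell, []).append(kp)
    if max_keypoints is not None:
        kept = kept[:max_keypoints]
    return kept


def _refine_extremum(D, s, y, x, contrast_threshold, edge_ratio, max_iter=5):
    ns, h, w = D.shape
    for _ in range(max_iter):
        if not (1 <= s <= ns - 2 and 1 <= y <= h - 2 and 1 <= x <= w - 2):
            return None
        g = 0.5 * np.array([D[s, y, x + 1] - D[s, y, x - 1],
                            D[s, y + 1, x] - D[s, y - 1, x],
                            D[s + 1, y, x] - D[s - 1, y, x]])
        c = D[s, y, x]
        H = np.empty((3, 3))
        H[0, 0] = D[s, y, x + 1] + D[s, y, x - 1] - 2 * c
        H[1, 1] = D[s, y + 1, x] + D[s, y - 1, x] - 2 * c
        H[2, 2] = D[s + 1, y, x] + D[s - 1, y, x] - 2 * c
        H[0, 1] = H[1, 0] = 0.25 * (D[s, y + 1, x + 1] - D[s, y + 1, x - 1]
                                    - D[s, y - 1, x + 1] + D[s, y - 1, x - 1])
        H[0, 2] = H[2, 0] = 0.25 * (D[s + 1, y, x + 1] - D[s + 1, y, x - 1]
                                    - D[s - 1, y, x + 1] + D[s - 1, y, x - 1])
        H[1, 2] = H[2, 1] = 0.25 * (D[s + 1, y + 1, x] - D[s + 1, y - 1, x]
                                    - D[s - 1, y + 1, x] + D[s - 1, y - 1, x])
        try:
            off = -np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(off) < 0.5):
            val = c + 0.5 * g @ off
            if abs(val) < contrast_threshold:
                return None
            # edge response: ratio of principal curvatures of the spatial Hessian
            tr = H[0, 0] + H[1, 1]
            det = H[0, 0] * H[1, 1] - H[0, 1] ** 2
            r = edge_ratio
            if det <= 0 or tr * tr * r >= det * (r + 1) ** 2:
                return None
            return s + off[2], y + off[1], x + off[0], float(val)
        x += int(round(np.clip(off[0], -1, 1)))
        y += int(round(np.clip(off[1], -1, 1)))
        s += int(round(np.clip(off[2], -1, 1)))
    return None


def _level_image(space: ScaleSpace, kp: Keypoint) -> tuple[np.ndarray, float]:
    """Gaussian level closest in scale to the keypoint, and the keypoint scale
    expressed in that octave's pixel units."""
    o = kp.octave
    s = int(np.clip(round(kp.level), 0, space.octaves[o].shape[0] - 1))
    return space.octaves[o][s], kp.sigma / 2.0 ** o


def assign_orientation(kp: Keypoint, space: ScaleSpace,
                       n_bins: int = 36, peak_ratio: float = 0.8) -> list[Keypoint]:
    """Assign one keypoint per dominant gradient orientation.

    A 36-bin orientation histogram of gradient directions, weighted by
    gradient magnitude and a Gaussian of width 1.5 sigma, is accumulated over
    a circular window of radius 3 * 1.5 * sigma around the keypoint. Every
    smoothed-histogram peak reaching ``peak_ratio`` of the maximum yields an
    oriented copy of the keypoint (parabolic sub-bin interpolation).
    """
    L, sig = _level_image(space, kp)
    xo, yo = kp.octave_xy()
    radius = int(np.ceil(3.0 * 1.5 * sig))
    xi, yi = int(round(xo)), int(round(yo))
    h, w = L.shape
    if not (radius + 1 <= xi < w - radius - 1 and radius + 1 <= yi < h - radius - 1):
        return []  # window exceeds the image; keypoint dropped
    patch = L[yi - radius - 1:yi + radius + 2, xi - radius - 1:xi + radius + 2]
    A = patch[1:-1, 2:] - patch[1:-1, :-2]
    B = patch[2:, 1:-1] - patch[:-2, 1:-1]
    mag = np.hypot(A, B)
    ang = np.arctan2(B, A) % (2 * np.pi)
    ys, xs = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    r2 = xs ** 2 + ys ** 2
    wgt = np.exp(-r2 / (2.0 * (1.5 * sig) ** 2))
    wgt[r2 > radius ** 2] = 0.0
    hist = np.zeros(n_bins)
    bins = ((ang / (2 * np.pi)) * n_bins).astype(int) % n_bins
    np.add.at(hist, bins.ravel(), (mag * wgt).ravel())
    # circular smoothing, twice, with a 1-4-6-4-1 kernel
    for _ in range(2):
        hist = (np.roll(hist, 2) + 4 * np.roll(hist, 1) + 6 * hist
                + 4 * np.roll(hist, -1) + np.roll(hist, -2)) / 16.0
    if hist.max() <= 0:
        return []
    out = []
    thr = peak_ratio * hist.max()
    for b in range(n_bins):
        left, right = hist[(b - 1) % n_bins], hist[(b + 1) % n_bins]
        if hist[b] >= thr and hist[b] > left and hist[b] > right:
            denom = left - 2 * hist[b] + right
            off = 0.5 * (left - right) / denom if denom != 0 else 0.0
            theta = ((b + off + 0.5) / n_bins * 2 * np.pi) % (2 * np.pi)
            out.append(replace(kp, theta=theta))
    return out


@dataclass
class Descriptor:
    """128-vector of spatially binned gradient-orientation histograms."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (128,):
            raise ValueError("descriptor must have 128 components")


def compute_descriptor(kp: Keypoint, space: ScaleSpace, grid: int = 4,
                       ori_bins: int = 8, clamp: float = 0.2) -> Descriptor | None:
    """Gradient-histogram descriptor in the keypoint's oriented frame.

    A ``grid x grid`` spatial arrangement of ``ori_bins``-bin orientation
    histograms sampled over a Gaussian-weighted window rotated by the
    keypoint orientation, trilinearly interpolated, L2-normalised, clamped at
    ``clamp`` and renormalised. Returns None when the window leaves the image.
    """
    L, sig = _level_image(space, kp)
    xo, yo = kp.octave_xy()
    hist_width = 3.0 * sig
    radius = int(round(hist_width * (grid + 1) * np.sqrt(2) / 2.0))
    xi, yi = int(round(xo)), int(round(yo))
    h, w = L.shape
    if not (radius + 1 <= xi < w - radius - 1 and radius + 1 <= yi < h - radius - 1):
        return None
    patch = L[yi - radius - 1:yi + radius + 2, xi - radius - 1:xi + radius + 2]
    A = patch[1:-1, 2:] - patch[1:-1, :-2]
    B = patch[2:, 1:-1] - patch[:-2, 1:-1]
    mag = np.hypot(A, B).ravel()
    ang = (np.arctan2(B, A).ravel() - kp.theta) % (2 * np.pi)
    ys, xs = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    ct, st = np.cos(kp.theta), np.sin(kp.theta)
    # rotate into the keypoint frame, in units of sub-histogram width
    xr = (ct * xs.ravel() + st * ys.ravel()) / hist_width
    yr = (-st * xs.ravel() + ct * ys.ravel()) / hist_width
    rbin = yr + grid / 2.0 - 0.5
    cbin = xr + grid / 2.0 - 0.5
    obin = ang / (2 * np.pi) * ori_bins
    wgt = np.exp(-(xr ** 2 + yr ** 2) / (0.5 * grid ** 2))
    keep = (rbin > -1) & (rbin < grid) & (cbin > -1) & (cbin < grid)
    rbin, cbin, obin, val = rbin[keep], cbin[keep], obin[keep], (mag * wgt)[keep]
    hist = np.zeros((grid + 2, grid + 2, ori_bins))
    r0 = np.floor(rbin).astype(int)
    c0 = np.floor(cbin).astype(int)
    o0 = np.floor(obin).astype(int)
    dr, dc, do = rbin - r0, cbin - c0, obin - o0
    for ir in (0, 1):
        for ic in (0, 1):
            for io in (0, 1):
                wv = (val * (dr if ir else 1 - dr) * (dc if ic else 1 - dc)
                      * (do if io else 1 - do))
                np.add.at(hist, (r0 + ir + 1, c0 + ic + 1, (o0 + io) % ori_bins), wv)
    vec = hist[1:-1, 1:-1, :].ravel()
    n = np.linalg.norm(vec)
    if n == 0:
        return None
    vec = np.minimum(vec / n, clamp)
    n = np.linalg.norm(vec)
    return Descriptor(vec / n) if n > 0 else None


def detect_and_describe(img: RasterImage, sigma0: float = 1.6, levels: int = 3,
                        contrast_threshold: float = 0.03, edge_ratio: float = 10.0,
                        max_keypoints: int | None = 2000,
                        ) -> tuple[list[Keypoint], np.ndarray]:
    """Full feature extraction: detect, orient, describe.

    Returns the oriented keypoints and an (n, 128) descriptor matrix.
    """
    space = build_scale_space(img, sigma0=sigma0, levels=levels)
    raw = detect_keypoints(space, contrast_threshold, edge_ratio,
                           max_keypoints=max_keypoints)
    kps, desc = [], []
    for kp in raw:
        for okp in assign_orientation(kp, space):
            d = compute_descriptor(okp, space)
            if d is not None:
                kps.append(okp)
                desc.append(d.vector)
    D = np.array(desc) if desc else np.zeros((0, 128))
    return kps, D


@dataclass
class MatchSet:
    """Putative (and, after RANSAC, filtered) correspondences."""

    image_a: str
    image_b: str
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    inlier_mask: np.ndarray | None = None

    def inlier_pairs(self) -> list[tuple[int, int, float]]:
        if self.inlier_mask is None:
            return list(self.pairs)
        return [p for p, keep in zip(self.pairs, self.inlier_mask) if keep]


def _pairwise_sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # BLAS-backed squared Euclidean distances
    sq = (a ** 2).sum(1)[:, None] + (b ** 2).sum(1)[None, :] - 2.0 * a @ b.T
    return np.maximum(sq, 0.0)


def match_descriptors(da: np.ndarray, db: np.ndarray, ratio: float = 0.8,
                      image_a: str = "a", image_b: str = "b",
                      mutual: bool = True) -> MatchSet:
    """Nearest-neighbour matching with a ratio test.

    Pair (i, j) is kept iff j is i's nearest neighbour, the nearest/second
    distance ratio is at most ``ratio``, and (by default) i is also j's
    nearest neighbour; a target matched by several sources keeps only the
    smallest-distance pair.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    da = np.asarray(da, float)
    db = np.asarray(db, float)
    ms = MatchSet(image_a, image_b)
    if len(da) == 0 or len(db) == 0:
        return ms
    d2 = _pairwise_sqdist(da, db)
    nn = np.argmin(d2, axis=1)
    best = np.sqrt(d2[np.arange(len(da)), nn])
    if db.shape[0] >= 2:
        part = np.partition(d2, 1, axis=1)
        second = np.sqrt(part[:, 1])
    else:
        second = np.full(len(da), np.inf)
    ok = best <= ratio * second
    if mutual:
        rev = np.argmin(d2, axis=0)
        ok &= rev[nn] == np.arange(len(da))
    taken: dict[int, tuple[int, float]] = {}
    for i in np.nonzero(ok)[0]:
        j, dist = int(nn[i]), float(best[i])
        if j not in taken or dist < taken[j][1]:
            taken[j] = (int(i), dist)
    ms.pairs = sorted((i, j, dist) for j, (i, dist) in taken.items())
    return ms


@dataclass
class FundamentalMatrix:
    """Rank-2, Frobenius-normalised fundamental matrix.

    Convention: for homogeneous pixel coordinates ``p = [x, y, 1]`` in the
    first image and ``p' = [x', y', 1]`` in the second, inliers satisfy
    ``p'^T F p = 0``.
    """

    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float).reshape(3, 3)

    def epipolar_residual(self, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        pa = np.column_stack([xa, np.ones(len(xa))])
        pb = np.column_stack([xb, np.ones(len(xb))])
        return np.einsum("ij,jk,ik->i", pb, self.F, pa)


def _normalize_points(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = x.mean(0)
    d = np.sqrt(((x - c) ** 2).sum(1)).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
    xh = np.column_stack([x, np.ones(len(x))]) @ T.T
    return xh, T


def _eight_point(xa: np.ndarray, xb: np.ndarray,
                 strict_rank: bool = True) -> np.ndarray | None:
    """Normalised (Hartley) 8-point estimate from >= 8 correspondences.

    ``strict_rank`` rejects rank-deficient design matrices (collinear or
    otherwise degenerate minimal samples); the final all-inlier re-estimate
    disables it, since near-planar scenes legitimately leave a family of
    compatible F and the least-squares member is still a valid epipolar
    filter.
    """
    pa, Ta = _normalize_points(xa)
    pb, Tb = _normalize_points(xb)
    A = np.column_stack([
        pb[:, 0] * pa[:, 0], pb[:, 0] * pa[:, 1], pb[:, 0],
        pb[:, 1] * pa[:, 0], pb[:, 1] * pa[:, 1], pb[:, 1],
        pa[:, 0], pa[:, 1], np.ones(len(pa))])
    try:
        _, sv, vt = np.linalg.svd(A)
    except np.linalg.LinAlgError:
        return None
    if strict_rank and len(sv) >= 9 and sv[0] > 0 and sv[7] / sv[0] < 1e-12:
        return None  # degenerate (e.g. collinear) sample
    F = vt[-1].reshape(3, 3)
    F = Tb.T @ F @ Ta
    # enforce rank 2 and fix scale/sign
    U, s, Vt = np.linalg.svd(F)
    F = U @ np.diag([s[0], s[1], 0.0]) @ Vt
    n = np.linalg.norm(F)
    if n == 0:
        return None
    F = F / n
    idx = np.unravel_index(np.argmax(np.abs(F)), F.shape)
    return F if F[idx] > 0 else -F


def sampson_distance(F: np.ndarray, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """First-order geometric (Sampson) distance of correspondences to the
    epipolar constraint, in pixels."""
    pa = np.column_stack([xa, np.ones(len(xa))])
    pb = np.column_stack([xb, np.ones(len(xb))])
    Fa = pa @ F.T        # epipolar lines in image b
    Ftb = pb @ F         # epipolar lines in image a
    num = np.einsum("ij,ij->i", pb, Fa)
    den = Fa[:, 0] ** 2 + Fa[:, 1] ** 2 + Ftb[:, 0] ** 2 + Ftb[:, 1] ** 2
    den = np.maximum(den, 1e-300)
    return np.abs(num) / np.sqrt(den)


def ransac_fundamental(ms: MatchSet, ka: list[Keypoint], kb: list[Keypoint],
                       threshold_px: float = 1.5, iterations: int = 2000,
                       seed: int = 0, confidence: float = 0.999,
                       ) -> tuple[FundamentalMatrix, MatchSet]:
    """Robust fundamental-matrix estimation over a match set.

    Random minimal 8-point samples are drawn with a seeded generator
    (bit-reproducible); inliers are matches with Sampson distance at most
    ``threshold_px``; the final F is re-estimated from all inliers of the
    best model with rank 2 enforced and unit Frobenius norm.
    """
    if len(ms.pairs) < 8:
        raise ValueError("need at least 8 matches to estimate F")
    xa = np.array([[ka[i].x, ka[i].y] for i, _, _ in ms.pairs])
    xb = np.array([[kb[j].x, kb[j].y] for _, j, _ in ms.pairs])
    n = len(ms.pairs)
    rng = np.random.default_rng(seed)
    best_mask = None
    best_F = None
    best_count = -1
    best_err = np.inf
    needed = iterations
    it = 0
    while it < min(needed, iterations):
        it += 1
        idx = rng.choice(n, size=8, replace=False)
        F = _eight_point(xa[idx], xb[idx])
        if F is None:
            continue
        d = sampson_distance(F, xa, xb)
        mask = d <= threshold_px
        count = int(mask.sum())
        err = float(d[mask].sum())
        if count > best_count or (count == best_count and err < best_err):
            best_count, best_err, best_mask, best_F = count, err, mask, F
            w = max(count / n, 1e-9)
            fail = min(max(1.0 - w ** 8, 1e-12), 1.0 - 1e-12)
            needed = int(min(iterations,
                             np.ceil(np.log(1 - confidence) / np.log(fail))))
    if best_mask is None or best_count < 8:
        raise ValueError("RANSAC failed to find a valid fundamental matrix")
    # re-estimate on all inliers; for (near-)planar scenes the least-squares
    # solution may leave the realizable family, so keep the minimal-sample
    # model whenever re-estimation loses consensus
    F = _eight_point(xa[best_mask], xb[best_mask], strict_rank=False)
    if F is not None:
        d = sampson_distance(F, xa, xb)
        mask = d <= threshold_px
        if int(mask.sum()) < best_count:
            F, mask = best_F, best_mask
    else:
        F, mask = best_F, best_mask
    out = MatchSet(ms.image_a, ms.image_b, list(ms.pairs), mask)
    return FundamentalMatrix(F), out


def keypoints_to_json(image_id: str, kps: list[Keypoint]) -> str:
    return json.dumps({
        "image_id": image_id,
        "keypoints": [{"x": kp.x, "y": kp.y, "sigma": kp.sigma, "theta": kp.theta}
                      for kp in kps],
    }, sort_keys=True)


def keypoints_from_json(text: str) -> tuple[str, list[Keypoint]]:
    obj = json.loads(text)
    kps = [Keypoint(d["x"], d["y"], d["sigma"], d.get("theta", 0.0))
           for d in obj["keypoints"]]
    return obj["image_id"], kps
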