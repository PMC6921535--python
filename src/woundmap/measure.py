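"""Tape-calibrated planimetry on the unwrapped image.

Two adhesive tape marks of known physical length, laid out roughly along
the X and Y directions next to the wound, appear on the unwrapped image
with pixel lengths L_x and L_y. With actual lengths l_x and l_y, a traced
wound polygon of pixel area S_img converts to physical area as

    S_wound = (l_x / L_x) * (l_y / L_y) * S_img       [cm^2]

The two-axis product corrects axis-dependent scaling of the unwrap rather
than assuming a single isotropic scale. Measured areas are reported to
0.01 cm^2 (1 mm^2), half-up; the unrounded value is retained.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["ScaleCalibration", "PolygonROI", "WoundMeasurement",
           "polygon_area_px", "calibrate", "wound_area",
           "load_roi_json", "load_calibration_json"]


@dataclass(frozen=True)
class ScaleCalibration:
    """Actual tape lengths (cm) and their pixel lengths on the unwrapped image."""

    l_x: float
    L_x: float
    l_y: float
    L_y: float

    def __post_init__(self) -> None:
        if min(self.l_x, self.L_x, self.l_y, self.L_y) <= 0:
            raise ValueError("calibration lengths must be positive")

    @property
    def area_factor(self) -> float:
        """cm^2 per px^2."""
        return (self.l_x / self.L_x) * (self.l_y / self.L_y)


@dataclass
class PolygonROI:
    """Closed traced wound outline in pixel coordinates (implicitly closed)."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")


@dataclass(frozen=True)
class WoundMeasurement:
    S_img: float             # px^2
    S_wound: float           # cm^2, rounded to 0.01
    S_wound_exact: float     # cm^2, unrounded
    calibration: ScaleCalibration


def _segments_cross(p, q, r, s) -> bool:
    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
    o1, o2 = orient(p, q, r), orient(p, q, s)
    o3, o4 = orient(r, s, p), orient(r, s, q)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def _check_simple(v: np.ndarray) -> None:
    n = len(v)
    for i in range(n):
        a, b = v[i], v[(i + 1) % n]
        for j in range(i + 1, n):
            if abs(i - j) <= 1 or (i == 0 and j == n - 1):
                continue
            c, d = v[j], v[(j + 1) % n]
            if _segments_cross(a, b, c, d):
                raise ValueError(f"polygon self-intersects: edge {i}-{i + 1} "
                                 f"crosses edge {j}-{j + 1}")


def polygon_area_px(roi: PolygonROI, check_simple: bool | None = None) -> float:
    """Shoelace area (px^2) of the closed polygon; orientation-independent.

    Self-intersection is rejected with the offending edge pair named; the
    O(n^2) check is skipped by default above 2000 vertices (dense traced
    contours are effectively simple by construction).
    """
    v = roi.vertices
    if check_simple is None:
        check_simple = len(v) <= 2000
    if check_simple:
        _check_simple(v)
    x, y = v[:, 0], v[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def calibrate(mark_x: tuple[np.ndarray, np.ndarray, float],
              mark_y: tuple[np.ndarray, np.ndarray, float]) -> ScaleCalibration:
    """Build the scale calibration from two labelled tape segments.

    Each mark is ``(pixel_endpoint_0, pixel_endpoint_1, actual_length_cm)``;
    the pixel length is the Euclidean distance between the endpoints.
    """
    out = []
    for p0, p1, l in (mark_x, mark_y):
        L = float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p0, float)))
        if L <= 0:
            raise ValueError("zero-length tape segment")
        if l <= 0:
            raise ValueError("tape physical length must be positive")
        out.append((l, L))
    (l_x, L_x), (l_y, L_y) = out
    return ScaleCalibration(l_x, L_x, l_y, L_y)


def wound_area(calib: ScaleCalibration, S_img: float) -> WoundMeasurement:
    """Apply the two-tape scale conversion to a pixel area."""
    if S_img < 0:
        raise ValueError("pixel area must be non-negative")
    exact = calib.area_factor * S_img
    rounded = float(Decimal(repr(exact)).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))
    return WoundMeasurement(float(S_img), rounded, exact, calib)


def load_roi_json(path) -> PolygonROI:
    """ROI file: ``{"vertices": [[x, y], ...]}``."""
    with open(path) as fh:
        obj = json.load(fh)
    return PolygonROI(np.asarray(obj["vertices"], float))


def load_calibration_json(path) -> ScaleCalibration:
    """Calibration file:
    ``{"x": {"px": [[x0,y0],[x1,y1]], "cm": 5.0}, "y": {...}}``."""
    with open(path) as fh:
        obj = json.load(fh)
    marks = []
    for axis in ("x", "y"):
        seg = obj[axis]
        marks.append((np.asarray(seg["px"][0], float),
                      np.asarray(seg["px"][1], float), float(seg["cm"])))
    return calibrate(*marks)
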