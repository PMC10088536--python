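"""Depot geometry in needle-centered coordinates.

A 2-D Cartesian frame is imposed with its origin at the needle tip, X-axis
along the needle insertion direction and Y-axis perpendicular to it.  In
this frame the module computes, per post-onset frame: the area centroid
path, the minimum and maximum Feret (caliper) diameters of the segmented
depot, and — for the final frame — the volume of the solid of revolution of
the depot about the needle axis.  Dividing that rotation volume by the
injected volume gives the retention fraction; the remainder is the volume
estimated to have escaped the imaged plane.

Rotation volume uses Pappus's theorem applied separately to the two
half-planes (y > 0 and y < 0): each half contributes 2*pi*|y_centroid|*area,
and the contributions are summed.  This remains well defined for depots
deflected off the needle axis, and reduces to the classical solid of
revolution for axis-adjacent shapes (a half-disk of radius r on the axis
yields the full sphere volume 4/3 pi r^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

from .io import InjectionAnnotation
from .segmentation import DepotMaskSeries

__all__ = [
    "NeedleFrame",
    "ShapeTrace",
    "RetentionEstimate",
    "needle_frame_from_annotation",
    "to_needle_frame",
    "centroid_path",
    "feret_diameters",
    "rotation_volume",
    "retention",
    "shape_trace",
]


@dataclass(frozen=True)
class NeedleFrame:
    """Needle-centered coordinate frame.

    origin: needle-tip pixel (row, col).
    x_axis / y_axis: orthonormal (row, col) unit vectors; x along the
        insertion direction, y rotated 90 degrees counterclockwise from x in
        image coordinates (right-handed with the row axis pointing down).
    px_per_cm: pixel calibration.
    """

    origin: tuple[float, float]
    x_axis: tuple[float, float]
    y_axis: tuple[float, float]
    px_per_cm: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x_axis)
        y = np.asarray(self.y_axis)
        if not (math.isclose(float(x @ x), 1.0, abs_tol=1e-9) and math.isclose(float(y @ y), 1.0, abs_tol=1e-9)):
            raise ValueError("axes must be unit vectors")
        if not math.isclose(float(x @ y), 0.0, abs_tol=1e-9):
            raise ValueError("axes must be orthogonal")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


def needle_frame_from_annotation(annotation: InjectionAnnotation) -> NeedleFrame:
    """Build the needle frame from an annotation's tip and axis angle.

    The angle is in degrees from the image +column axis toward the +row
    (downward) axis.  The y-axis is x rotated 90 degrees counterclockwise in
    image coordinates: (dr, dc) -> (dc, -dr).
    """
    if annotation.needle_tip is None or annotation.needle_angle_deg is None:
        raise ValueError("annotation must carry a needle tip and angle")
    th = math.radians(annotation.needle_angle_deg)
    x_axis = (math.sin(th), math.cos(th))  # (d_row, d_col)
    y_axis = (x_axis[1], -x_axis[0])
    return NeedleFrame(
        origin=tuple(annotation.needle_tip),
        x_axis=x_axis,
        y_axis=y_axis,
        px_per_cm=annotation.px_per_cm,
    )


def to_needle_frame(mask: np.ndarray, frame: NeedleFrame) -> np.ndarray:
    """Map the pixel centers of a binary mask to (x, y) needle coordinates in cm.

    Returns an (N, 2) array; empty masks yield an empty array.
    """
    rr, cc = np.nonzero(np.asarray(mask, dtype=bool))
    dr = rr - frame.origin[0]
    dc = cc - frame.origin[1]
    x = (dr * frame.x_axis[0] + dc * frame.x_axis[1]) / frame.px_per_cm
    y = (dr * frame.y_axis[0] + dc * frame.y_axis[1]) / frame.px_per_cm
    return np.column_stack([x, y])


@dataclass
class ShapeTrace:
    """Per-frame depot geometry; NaN marks frames with an empty mask."""

    times: np.ndarray
    centroid_x_cm: np.ndarray
    centroid_y_cm: np.ndarray
    feret_min_cm: np.ndarray
    feret_max_cm: np.ndarray
    area_cm2: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd
        from pathlib import Path

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "time_s": self.times,
                "centroid_x_cm": self.centroid_x_cm,
                "centroid_y_cm": self.centroid_y_cm,
                "feret_min_cm": self.feret_min_cm,
                "feret_max_cm": self.feret_max_cm,
                "area_cm2": self.area_cm2,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class RetentionEstimate:
    """Retained-drug estimate from the final-frame rotation volume."""

    rotation_volume_ml: float
    injected_volume_ml: float
    retention_pct: float
    escaped_volume_ml: float


def centroid_path(series: DepotMaskSeries, frame: NeedleFrame) -> ShapeTrace:
    """Area-centroid path (needle coordinates); Feret columns included."""
    return shape_trace(series, frame)


def shape_trace(series: DepotMaskSeries, frame: NeedleFrame) -> ShapeTrace:
    """Centroid, Feret diameters and area for every mask in the series."""
    n = series.masks.shape[0]
    cx = np.full(n, np.nan)
    cy = np.full(n, np.nan)
    fmin = np.full(n, np.nan)
    fmax = np.full(n, np.nan)
    area = np.zeros(n)
    px_area = (1.0 / frame.px_per_cm) ** 2
    for i, mask in enumerate(series.masks):
        pts = to_needle_frame(mask, frame)
        if pts.shape[0] == 0:
            continue
        cx[i], cy[i] = pts.mean(axis=0)
        area[i] = pts.shape[0] * px_area
        fmin[i], fmax[i] = _feret_from_points(pts)
    return ShapeTrace(
        times=series.times.copy(),
        centroid_x_cm=cx,
        centroid_y_cm=cy,
        feret_min_cm=fmin,
        feret_max_cm=fmax,
        area_cm2=area,
    )


def feret_diameters(mask: np.ndarray, frame: NeedleFrame) -> tuple[float, float]:
    """Minimum and maximum Feret (caliper) diameters of a mask, in cm.

    The maximum is the convex-hull diameter; the minimum is the smallest
    width over all support directions, attained for a direction normal to a
    hull edge.  Computed on pixel centers (no half-pixel boundary
    correction).
    """
    pts = to_needle_frame(mask, frame)
    if pts.shape[0] == 0:
        raise ValueError("mask is empty")
    return _feret_from_points(pts)


def _feret_from_points(pts: np.ndarray) -> tuple[float, float]:
    if pts.shape[0] == 1:
        return 0.0, 0.0
    unique = np.unique(pts, axis=0)
    if unique.shape[0] == 1:
        return 0.0, 0.0
    try:
        hull_pts = unique[ConvexHull(unique).vertices]
    except Exception:  # collinear points: QhullError
        proj = unique - unique.mean(axis=0)
        d = np.linalg.norm(proj, axis=1)
        span = float(np.max(np.linalg.norm(unique[:, None] - unique[None, :], axis=-1)))
        return 0.0, span
    # max Feret: hull diameter
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    fmax = float(np.sqrt((diffs**2).sum(-1)).max())
    # min Feret: min over hull edges of the extent along the edge normal
    edges = np.roll(hull_pts, -1, axis=0) - hull_pts
    lengths = np.linalg.norm(edges, axis=1)
    good = lengths > 0
    normals = np.column_stack([-edges[good, 1], edges[good, 0]]) / lengths[good, None]
    proj = hull_pts @ normals.T  # (n_pts, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    fmin = float(widths.min())
    return fmin, fmax


def rotation_volume(mask: np.ndarray, frame: NeedleFrame) -> float:
    """Volume of the solid of revolution of the mask about the needle axis, mL.

    Two-sided Pappus: the y > 0 and y < 0 parts each contribute
    2*pi*|y_centroid|*area; contributions are summed.  Pixels straddling the
    axis are assigned by the sign of their center.  With y in cm the result
    is in cm^3 = mL.
    """
    pts = to_needle_frame(mask, frame)
    if pts.shape[0] == 0:
        raise ValueError("mask is empty")
    px_area = (1.0 / frame.px_per_cm) ** 2
    # sum over pixels of 2*pi*|y|*dA equals the two-sided Pappus sum
    return float(2.0 * math.pi * np.abs(pts[:, 1]).sum() * px_area)


def retention(
    series: DepotMaskSeries,
    frame: NeedleFrame,
    injected_volume_ml: float,
    smooth_window_s: float = 1.0,
) -> tuple[RetentionEstimate, np.ndarray]:
    """Retention estimate from the final mask plus a per-frame trace.

    Returns the point estimate (final post-onset mask) and a per-frame
    retention-percent trace smoothed with a centered moving average
    (NaN where masks are empty).
    """
    if injected_volume_ml <= 0:
        raise ValueError("injected_volume_ml must be positive")
    final = series.masks[-1]
    if not final.any():
        raise ValueError("final mask is empty: no depot detected")
    vol = rotation_volume(final, frame)
    est = RetentionEstimate(
        rotation_volume_ml=vol,
        injected_volume_ml=injected_volume_ml,
        retention_pct=100.0 * vol / injected_volume_ml,
        escaped_volume_ml=injected_volume_ml - vol,
    )
    pct = np.full(series.masks.shape[0], np.nan)
    for i, m in enumerate(series.masks):
        if m.any():
            pct[i] = 100.0 * rotation_volume(m, frame) / injected_volume_ml
    # centered moving average ignoring NaNs
    if series.times.size >= 2:
        fr = 1.0 / float(series.times[1] - series.times[0])
        n = max(int(round(smooth_window_s * fr)), 1)
        valid = np.isfinite(pct)
        filled = np.where(valid, pct, 0.0)
        kernel = np.ones(n)
        num = np.convolve(filled, kernel, mode="same")
        den = np.convolve(valid.astype(float), kernel, mode="same")
        smoothed = np.divide(num, den, out=np.full_like(num, np.nan), where=den > 0)
    else:
        smoothed = pct
    return est, smoothed
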