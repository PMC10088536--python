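"""Needle-frame geometry: centroids, Feret diameters, rotation volume."""

import math

import numpy as np
import pytest

from ebusdepot.io import InjectionAnnotation
from ebusdepot.segmentation import DepotMaskSeries
from ebusdepot.shape import (
    NeedleFrame,
    feret_diameters,
    needle_frame_from_annotation,
    retention,
    rotation_volume,
    shape_trace,
    to_needle_frame,
)


def frame_at(tip=(100.0, 100.0), angle=90.0, px_per_cm=100.0):
    ann = InjectionAnnotation(
        needle_tip=tip,
        needle_angle_deg=angle,
        t0=0.0,
        injected_volume_ml=8.0,
        px_per_cm=px_per_cm,
    )
    return needle_frame_from_annotation(ann)


def disk_mask(shape, center, radius_px):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


class TestNeedleFrame:
    def test_tip_maps_to_origin(self):
        frame = frame_at()
        mask = np.zeros((200, 200), bool)
        mask[100, 100] = True
        pts = to_needle_frame(mask, frame)
        np.testing.assert_allclose(pts, [[0.0, 0.0]], atol=1e-12)

    def test_100px_along_axis_is_1cm(self):
        frame = frame_at(angle=90.0, px_per_cm=100.0)
        mask = np.zeros((250, 250), bool)
        mask[200, 100] = True  # 100 px down = along the needle
        pts = to_needle_frame(mask, frame)
        np.testing.assert_allclose(pts, [[1.0, 0.0]], atol=1e-9)

    def test_rotation_equivariance(self):
        # rotating the image and needle angle by 90 deg together leaves
        # needle-frame coordinates unchanged
        rng = np.random.default_rng(0)
        mask = rng.random((101, 101)) > 0.9
        f0 = frame_at(tip=(50.0, 50.0), angle=90.0, px_per_cm=50.0)
        pts0 = to_needle_frame(mask, f0)
        rotated = np.rot90(mask, k=1)
        f1 = frame_at(tip=(50.0, 50.0), angle=0.0, px_per_cm=50.0)
        pts1 = to_needle_frame(rotated, f1)
        assert pts0.shape == pts1.shape
        s0 = set(map(tuple, np.round(pts0, 6)))
        s1 = set(map(tuple, np.round(pts1, 6)))
        assert s0 == s1

    def test_orthonormality_enforced(self):
        with pytest.raises(ValueError, match="unit"):
            NeedleFrame(origin=(0, 0), x_axis=(2.0, 0.0), y_axis=(0.0, 1.0), px_per_cm=10.0)


class TestCentroid:
    def test_disk_at_tip_centered(self):
        frame = frame_at()
        mask = disk_mask((200, 200), (100, 100), 20)
        series = DepotMaskSeries(masks=mask[None], times=np.array([0.0]))
        trace = shape_trace(series, frame)
        assert trace.centroid_x_cm[0] == pytest.approx(0.0, abs=1e-6)
        assert trace.centroid_y_cm[0] == pytest.approx(0.0, abs=1e-6)

    def test_disk_along_axis(self):
        frame = frame_at(angle=90.0, px_per_cm=100.0)
        mask = disk_mask((300, 300), (150, 100), 20)  # 50 px = 0.5 cm down
        series = DepotMaskSeries(masks=mask[None], times=np.array([0.0]))
        trace = shape_trace(series, frame)
        assert trace.centroid_x_cm[0] == pytest.approx(0.5, abs=1e-3)
        assert trace.centroid_y_cm[0] == pytest.approx(0.0, abs=1e-3)

    def test_empty_mask_yields_missing(self):
        frame = frame_at()
        series = DepotMaskSeries(masks=np.zeros((2, 50, 50), bool), times=np.array([0.0, 0.1]))
        trace = shape_trace(series, frame)
        assert np.isnan(trace.centroid_x_cm).all()
        assert np.isnan(trace.feret_max_cm).all()

    def test_symmetric_simulated_growth_stays_on_axis(self, noiseless_sim):
        from ebusdepot.simulate import annotation_for

        config, _, truth = noiseless_sim
        frame = needle_frame_from_annotation(annotation_for(config))
        series = DepotMaskSeries(masks=truth.depot_mask_series, times=truth.times)
        trace = shape_trace(series, frame)
        finite = np.isfinite(trace.centroid_y_cm)
        assert np.all(np.abs(trace.centroid_y_cm[finite]) <= 0.05)


class TestFeret:
    def test_square_diameters(self):
        frame = frame_at(px_per_cm=100.0)
        mask = np.zeros((300, 300), bool)
        mask[100:200, 100:200] = True  # 1 cm x 1 cm
        fmin, fmax = feret_diameters(mask, frame)
        tol = 2.0 / 100.0
        assert fmin == pytest.approx(1.0, abs=tol)
        assert fmax == pytest.approx(math.sqrt(2), abs=tol)

    def test_disk_isotropic(self):
        frame = frame_at(px_per_cm=100.0)
        mask = disk_mask((300, 300), (150, 150), 50)  # diameter 1 cm
        fmin, fmax = feret_diameters(mask, frame)
        tol = 2.0 / 100.0
        assert fmin == pytest.approx(1.0, abs=tol)
        assert fmax == pytest.approx(1.0, abs=tol)
        assert fmin <= fmax

    def test_matches_brute_force_direction_sweep(self):
        rng = np.random.default_rng(12)
        frame = frame_at(tip=(50.0, 50.0), angle=37.0, px_per_cm=40.0)
        angles = np.linspace(0, math.pi, 720, endpoint=False)
        dirs = np.column_stack([np.cos(angles), np.sin(angles)])
        for _ in range(100):
            mask = _random_blob(rng, (100, 100))
            pts = to_needle_frame(mask, frame)
            proj = pts @ dirs.T
            widths = proj.max(axis=0) - proj.min(axis=0)
            fmin, fmax = feret_diameters(mask, frame)
            assert fmax == pytest.approx(widths.max(), rel=0.01)
            assert fmin == pytest.approx(widths.min(), rel=0.01, abs=1e-6)
            assert fmin <= fmax + 1e-12

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            feret_diameters(np.zeros((10, 10), bool), frame_at())


class TestRotationVolume:
    def test_half_disk_gives_sphere(self):
        # half-disk of radius r with its flat edge on the needle axis sweeps
        # a full sphere: V = 4/3 pi r^3
        px = 100.0
        frame = frame_at(tip=(200.0, 200.0), angle=90.0, px_per_cm=px)
        r_px = 100  # r = 1 cm
        rr, cc = np.mgrid[0:400, 0:400]
        mask = ((rr - 200) ** 2 + (cc - 200) ** 2 <= r_px**2) & (cc > 200)
        vol = rotation_volume(mask, frame)
        assert vol == pytest.approx(4.0 / 3.0 * math.pi, rel=0.02)

    def test_rectangle_pappus_closed_form(self):
        # 1 cm x 0.2 cm rectangle with its long edge on the axis, in y > 0:
        # V = 2 pi * 0.1 * 0.2
        px = 100.0
        # tip offset by half a pixel so the rotation axis lies on the pixel
        # edge: columns 0..19 then represent the strip y in (0, 0.2) cm
        frame = frame_at(tip=(0.0, -0.5), angle=90.0, px_per_cm=px)
        mask = np.zeros((150, 50), bool)
        mask[0:100, 0:20] = True
        vol = rotation_volume(mask, frame)
        assert vol == pytest.approx(2 * math.pi * 0.1 * 0.2, rel=0.02)

    def test_reflection_invariance(self):
        rng = np.random.default_rng(3)
        frame = frame_at(tip=(50.0, 50.0), angle=90.0, px_per_cm=40.0)
        mask = _random_blob(rng, (101, 101))
        reflected = mask[:, ::-1]  # mirror across the needle (column) axis
        assert rotation_volume(mask, frame) == pytest.approx(
            rotation_volume(reflected, frame), rel=1e-9
        )

    def test_cubic_scaling(self):
        frame_1 = frame_at(tip=(100.0, 100.0), angle=90.0, px_per_cm=100.0)
        small = disk_mask((200, 200), (100, 130), 20)
        big = disk_mask((400, 400), (100, 160), 40)  # doubled radius and offset
        frame_2 = frame_at(tip=(100.0, 100.0), angle=90.0, px_per_cm=100.0)
        v_small = rotation_volume(small, frame_1)
        v_big = rotation_volume(big, frame_2)
        assert v_big == pytest.approx(8.0 * v_small, rel=0.03)

    def test_matches_washer_integration_oracle(self):
        rng = np.random.default_rng(21)
        frame = frame_at(tip=(60.0, 60.0), angle=90.0, px_per_cm=40.0)
        for _ in range(20):
            mask = _random_blob(rng, (120, 120))
            vol = rotation_volume(mask, frame)
            oracle = _washer_volume(mask, tip=(60, 60), px_per_cm=40.0)
            assert vol == pytest.approx(oracle, rel=0.02)


class TestRetention:
    def test_retention_arithmetic(self):
        # a depot whose rotation volume is 1.6 mL of an 8 mL injection: 20%
        px = 200.0
        frame = frame_at(tip=(0.0, 0.0), angle=90.0, px_per_cm=px)
        # rectangle x in [0,1], y in [ylo, ylo+w]: V = 2 pi (ylo + w/2) * w
        w = 0.2
        ylo = 1.6 / (2 * math.pi * w) - w / 2
        mask = np.zeros((int(1.2 * px), int(2.5 * px)), bool)
        c0 = int(round(ylo * px))
        mask[0 : int(px), c0 : c0 + int(w * px)] = True
        series = DepotMaskSeries(masks=mask[None], times=np.array([0.0]))
        est, trace = retention(series, frame, injected_volume_ml=8.0)
        assert est.retention_pct == pytest.approx(20.0, rel=0.02)
        assert est.escaped_volume_ml == pytest.approx(8.0 - est.rotation_volume_ml)

    def test_empty_final_mask_fails(self):
        series = DepotMaskSeries(masks=np.zeros((3, 20, 20), bool), times=np.arange(3.0))
        with pytest.raises(ValueError, match="no depot"):
            retention(series, frame_at(), 8.0)

    def test_nested_masks_monotone_volume(self):
        frame = frame_at(tip=(50.0, 50.0), angle=90.0, px_per_cm=40.0)
        inner = disk_mask((100, 100), (50, 70), 8)
        outer = disk_mask((100, 100), (50, 70), 14)
        assert rotation_volume(inner, frame) <= rotation_volume(outer, frame)


def _random_blob(rng, shape):
    """Union of 1-3 random ellipses; non-empty by construction."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, bool)
    for _ in range(rng.integers(1, 4)):
        r0 = rng.uniform(0.3 * h, 0.7 * h)
        c0 = rng.uniform(0.3 * w, 0.7 * w)
        ra = rng.uniform(4, 0.2 * h)
        rb = rng.uniform(4, 0.2 * w)
        th = rng.uniform(0, math.pi)
        dr = rr - r0
        dc = cc - c0
        u = dr * math.cos(th) + dc * math.sin(th)
        v = -dr * math.sin(th) + dc * math.cos(th)
        mask |= (u / ra) ** 2 + (v / rb) ** 2 <= 1
    return mask


def _washer_volume(mask, tip, px_per_cm):
    """Column-run washer integration about the needle (vertical) axis.

    For each image row (station x along the needle) and each half-plane,
    maximal runs of occupied pixels [a, b] (pixel edges, cm) contribute
    pi (b^2 - a^2) dx.  Independent discretization from the per-pixel
    centroid (Pappus) rule used by the implementation.
    """
    h_cm = 1.0 / px_per_cm
    total = 0.0
    tip_c = tip[1]
    for row in range(mask.shape[0]):
        cols = np.nonzero(mask[row])[0]
        if cols.size == 0:
            continue
        y = (cols - tip_c) / px_per_cm  # lateral pixel-center coordinate
        for half in (y[y > 0], -y[y < 0]):
            if half.size == 0:
                continue
            vals = np.sort(half)
            run_start = vals[0]
            prev = vals[0]
            for v in vals[1:]:
                if v - prev > 1.5 * h_cm:  # gap: close the run
                    total += math.pi * ((prev + h_cm / 2) ** 2 - (run_start - h_cm / 2) ** 2) * h_cm
                    run_start = v
                prev = v
            total += math.pi * ((prev + h_cm / 2) ** 2 - (run_start - h_cm / 2) ** 2) * h_cm
    return total
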