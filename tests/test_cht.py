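"""Circular Hough transform against brute-force voting oracles."""

import numpy as np
import pytest

from ma_screen.cht import (
    ChtConfig,
    cht_detect,
    detect_circles,
    edge_pixels,
    hough_accumulate,
)
from ma_screen.io_cli import PipelineConfig
from ma_screen.synth import SceneSpec, LesionSpec, render_fundus
from ma_screen.types import BinaryMap, ValidationError


def oracle_ring(radius):
    """Independent scalar enumeration of the voting ring."""
    pts = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if round((dx * dx + dy * dy) ** 0.5) == radius:
                pts.append((dx, dy))
    return pts


def oracle_accumulate(edges, radii, shape):
    """Exhaustive triple-loop voting: edge pixel x radius x ring offset."""
    h, w = shape
    acc = np.zeros((len(radii), h, w), dtype=np.int64)
    rings = [oracle_ring(r) for r in radii]
    for x, y in edges:
        for ri, r in enumerate(radii):
            for dx, dy in rings[ri]:
                cx, cy = x + dx, y + dy
                if 0 <= cx < w and 0 <= cy < h:
                    acc[ri, cy, cx] += 1
    return acc


def oracle_boundary(arr):
    """Per-pixel 4-neighbour scan."""
    h, w = arr.shape
    out = set()
    for y in range(h):
        for x in range(w):
            if not arr[y, x]:
                continue
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nx, ny = x + dx, y + dy
                if not (0 <= nx < w and 0 <= ny < h) or not arr[ny, nx]:
                    out.add((x, y))
                    break
    return out


def plant_disks(rng, n, shape=(64, 64), r_range=(5, 12)):
    h, w = shape
    arr = np.zeros(shape, bool)
    circles = []
    for _ in range(300):
        if len(circles) == n:
            break
        r = int(rng.integers(r_range[0], r_range[1] + 1))
        cx = int(rng.integers(r + 2, w - r - 2))
        cy = int(rng.integers(r + 2, h - r - 2))
        if any((cx - x) ** 2 + (cy - y) ** 2 < (r + rr + 4) ** 2 for x, y, rr in circles):
            continue
        yy, xx = np.ogrid[0:h, 0:w]
        arr |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        circles.append((cx, cy, r))
    return arr, circles


SMALL_CFG = ChtConfig(r_min=5, r_max=12, vote_threshold=0.35, min_center_distance=5)


class TestEdgePixels:
    def test_filled_square_has_16_perimeter_pixels(self):
        arr = np.zeros((9, 9), bool)
        arr[2:7, 2:7] = True
        edges = edge_pixels(BinaryMap(arr))
        assert len(edges) == 16
        assert set(map(tuple, edges)) == oracle_boundary(arr)

    def test_empty_map_gives_empty_set(self):
        assert edge_pixels(BinaryMap(np.zeros((8, 8), bool))).size == 0

    def test_random_blob_matches_neighbour_scan_oracle(self):
        rng = np.random.default_rng(4)
        arr = rng.random((20, 20)) < 0.4
        edges = edge_pixels(BinaryMap(arr))
        assert set(map(tuple, edges)) == oracle_boundary(arr)


class TestAccumulate:
    def test_single_edge_pixel_total_votes(self):
        cfg = ChtConfig(r_min=5, r_max=8, vote_threshold=0.5)
        # pixel centred in a map large enough that no vote leaves the frame
        acc = hough_accumulate(np.array([[30, 30]]), cfg, (61, 61))
        expected = sum(len(oracle_ring(r)) for r in cfg.radii)
        assert acc.sum() == expected

    def test_perfect_circle_argmax_at_true_center_and_radius(self):
        yy, xx = np.ogrid[0:64, 0:64]
        ring = np.rint(np.hypot(xx - 20, yy - 20)).astype(int) == 8
        edges = edge_pixels(BinaryMap(ring))
        acc = hough_accumulate(edges, SMALL_CFG, (64, 64))
        ri, cy, cx = np.unravel_index(np.argmax(acc), acc.shape)
        assert (SMALL_CFG.radii[ri], cy, cx) == (8, 20, 20)

    def test_empty_edges_give_zero_accumulator(self):
        acc = hough_accumulate(np.empty((0, 2), int), SMALL_CFG, (32, 32))
        assert not acc.any()

    def test_matches_triple_loop_oracle_vote_for_vote(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            arr, _ = plant_disks(rng, int(rng.integers(1, 4)))
            edges = edge_pixels(BinaryMap(arr))
            acc = hough_accumulate(edges, SMALL_CFG, arr.shape)
            oracle = oracle_accumulate(edges, SMALL_CFG.radii, arr.shape)
            assert np.array_equal(acc, oracle)


class TestDetectCircles:
    def test_one_perfect_circle_one_detection(self):
        yy, xx = np.ogrid[0:64, 0:64]
        arr = (xx - 30) ** 2 + (yy - 30) ** 2 <= 64
        edges = edge_pixels(BinaryMap(arr))
        acc = hough_accumulate(edges, SMALL_CFG, (64, 64))
        dets = detect_circles(acc, SMALL_CFG)
        assert len(dets) >= 1
        best = dets[0]
        assert abs(best.center_x - 30) <= 1 and abs(best.center_y - 30) <= 1
        assert abs(best.radius - 8) <= 1

    def test_two_separated_circles_recovered(self):
        rng = np.random.default_rng(11)
        arr = np.zeros((64, 64), bool)
        yy, xx = np.ogrid[0:64, 0:64]
        arr |= (xx - 16) ** 2 + (yy - 16) ** 2 <= 36
        arr |= (xx - 45) ** 2 + (yy - 45) ** 2 <= 100
        edges = edge_pixels(BinaryMap(arr))
        acc = hough_accumulate(edges, SMALL_CFG, (64, 64))
        dets = detect_circles(acc, SMALL_CFG)
        for cx, cy, r in ((16, 16, 6), (45, 45, 10)):
            assert any(
                abs(d.center_x - cx) <= 1 and abs(d.center_y - cy) <= 1
                and abs(d.radius - r) <= 1
                for d in dets
            )

    def test_unattainable_threshold_gives_empty_list(self):
        rng = np.random.default_rng(12)
        arr = rng.random((64, 64)) < 0.2
        cfg = ChtConfig(r_min=5, r_max=12, vote_threshold=1.0)
        acc = hough_accumulate(edge_pixels(BinaryMap(arr)), cfg, (64, 64))
        assert detect_circles(acc, cfg) == []

    def test_raising_threshold_never_increases_detections(self):
        rng = np.random.default_rng(13)
        arr, _ = plant_disks(rng, 3)
        edges = edge_pixels(BinaryMap(arr))
        counts = []
        for thr in (0.2, 0.4, 0.6, 0.8):
            cfg = ChtConfig(r_min=5, r_max=12, vote_threshold=thr, min_center_distance=5)
            acc = hough_accumulate(edges, cfg, arr.shape)
            counts.append(len(detect_circles(acc, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_ordered_output(self):
        rng = np.random.default_rng(14)
        arr, _ = plant_disks(rng, 2)
        edges = edge_pixels(BinaryMap(arr))
        acc = hough_accumulate(edges, SMALL_CFG, arr.shape)
        assert detect_circles(acc, SMALL_CFG) == detect_circles(acc, SMALL_CFG)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            ChtConfig(r_min=0)
        with pytest.raises(ValidationError):
            ChtConfig(vote_threshold=0.0)


class TestEndToEnd:
    def test_blank_fov_gives_no_detections(self):
        img, _ = render_fundus(SceneSpec(seed=21, vessel_tree=None, optic_disc=None))
        assert cht_detect(img) == []

    def test_radius_bounds_respected_on_detections(self, recovery_scene):
        _, img, _ = recovery_scene
        cfg = ChtConfig()
        for d in cht_detect(img, cht_cfg=cfg):
            assert cfg.r_min <= d.radius <= cfg.r_max

    def test_tiny_ma_below_r_min_is_not_detected(self):
        # radius-3 lesion sits below the 5 px lower bound of the circular
        # detector's radius range and must never be reported
        spec = SceneSpec(
            seed=22, mas=[LesionSpec((300.0, 300.0), 3.0, 80.0)],
        )
        img, _ = render_fundus(spec)
        from ma_screen.io_cli import detect_circles_in_image

        for dets in (cht_detect(img), detect_circles_in_image(img, PipelineConfig())):
            assert not any(
                np.hypot(d.center_x - 300, d.center_y - 300) <= 6 for d in dets
            )
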