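import math

import numpy as np
import pytest

from collafiber import features as ft
from collafiber.fiber_network import Fiber, CrossLink, FiberNetwork
from collafiber.segmentation import BinaryMask

from conftest import semicircle_vertices


def _mask(px, pixel_size_um=1.0):
    return BinaryMask(pixels=px, refined=True, min_segment_px=5,
                      pixel_size_um=pixel_size_um)


def _net(fibers, cross_links, shape, pixel_size_um):
    return FiberNetwork(fibers=fibers, cross_links=cross_links,
                        roi_area_px2=shape[0] * shape[1],
                        pixel_size_um=pixel_size_um)


def straight_fiber(fid, r, c0, c1, radius=2.0):
    verts = [(float(r), float(c)) for c in range(int(c0), int(c1) + 1)]
    return Fiber(fiber_id=fid, vertices=verts, mean_radius_px=radius)


class TestOrientationCoherence:
    def test_aligned_limit(self):
        assert ft.orientation_coherence([0.3] * 7) == pytest.approx(1.0)

    def test_orthogonal_pair_cancels(self):
        assert ft.orientation_coherence([0.0, math.pi / 2]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_uniform_angles_near_zero(self):
        rng = np.random.default_rng(42)
        angles = rng.uniform(0, math.pi, 10_000)
        assert ft.orientation_coherence(angles) < 0.05

    def test_empty_undefined(self):
        assert math.isnan(ft.orientation_coherence([]))


class TestCrosslinkSpace:
    def test_single_fiber_mean_gap(self):
        out = ft.crosslink_space([[20.0, 60.0, 120.0]], pixel_size_um=0.5)
        assert out == pytest.approx(25.0)

    def test_all_fibers_single_link_undefined(self):
        assert math.isnan(ft.crosslink_space([[5.0], [9.0], []], 1.0))

    def test_two_fibers_pooled_gaps(self):
        out = ft.crosslink_space([[0.0, 10.0], [5.0, 25.0]], pixel_size_um=1.0)
        assert out == pytest.approx(15.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ft.crosslink_space([[10.0, 4.0]], 1.0)


class TestComputeFeatureVector:
    def test_single_fiber_worked_example(self):
        """100-px straight fiber, 4 px wide, 200x200 ROI at 0.5 µm/px."""
        px = np.zeros((200, 200), dtype=bool)
        px[98:102, 50:150] = True  # 400 foreground px
        mask = _mask(px, pixel_size_um=0.5)
        fiber = straight_fiber(0, 100, 50, 150, radius=2.0)
        # vertices span 100 px end-to-end
        assert fiber.endpoint_distance_px == pytest.approx(100.0)
        net = _net([fiber], [], (200, 200), 0.5)
        fv = ft.compute_feature_vector(mask, net)
        assert fv.fiber_area == pytest.approx(0.01)
        assert fv.fiber_density == pytest.approx(100.0)  # 1 / (0.1 mm)^2
        assert fv.fiber_length_um == pytest.approx(50.0)
        assert fv.fiber_width_um == pytest.approx(2.0)
        assert fv.orientation == pytest.approx(1.0)
        assert fv.straightness == pytest.approx(1.0)
        assert fv.crosslink_density == 0.0
        assert math.isnan(fv.crosslink_space_um)

    def test_orthogonal_pair_zero_coherence(self):
        px = np.ones((200, 200), dtype=bool)
        mask = _mask(px, pixel_size_um=1.0)
        f1 = straight_fiber(0, 100, 20, 180)
        f2 = Fiber(1, [(float(r), 100.0) for r in range(20, 181)], 2.0)
        fv = ft.compute_feature_vector(mask, _net([f1, f2], [], (200, 200), 1.0))
        assert fv.orientation == pytest.approx(0.0, abs=1e-9)

    def test_semicircle_straightness(self):
        verts = semicircle_vertices(radius=60.0)
        fiber = Fiber(0, verts, 2.0)
        assert fiber.straightness == pytest.approx(2 / math.pi, abs=0.02)

    def test_empty_network_missing_feature_policy(self):
        px = np.zeros((64, 64), dtype=bool)
        fv = ft.compute_feature_vector(_mask(px), _net([], [], (64, 64), 1.0))
        assert fv.fiber_area == 0.0
        assert fv.fiber_density == 0.0
        for v in (fv.fiber_length_um, fv.fiber_width_um, fv.orientation,
                  fv.straightness, fv.crosslink_space_um, fv.crosslink_density):
            assert math.isnan(v)

    def test_crosslink_space_from_network_geometry(self):
        f1 = straight_fiber(0, 50, 0, 100)
        cls = [
            CrossLink((50.0, 20.0), frozenset({0, 1})),
            CrossLink((50.0, 70.0), frozenset({0, 2})),
        ]
        f2 = Fiber(1, [(40.0, 20.0), (50.0, 20.0), (60.0, 20.0)], 2.0)
        f3 = Fiber(2, [(40.0, 70.0), (50.0, 70.0), (60.0, 70.0)], 2.0)
        px = np.ones((110, 110), dtype=bool)
        fv = ft.compute_feature_vector(
            _mask(px, 1.0), _net([f1, f2, f3], cls, (110, 110), 1.0)
        )
        # only fiber 0 carries two cross-links, 50 px apart along its arc
        assert fv.crosslink_space_um == pytest.approx(50.0, abs=0.5)
        total_len = sum(f.length_px for f in [f1, f2, f3])
        assert fv.crosslink_density == pytest.approx(100 * 2 / total_len, rel=0.01)


class TestScaleAndRotationInvariance:
    def _setup(self, px_um):
        px = np.zeros((200, 200), dtype=bool)
        px[98:102, 50:150] = True
        px[40:140, 30:34] = True
        mask = _mask(px, pixel_size_um=px_um)
        f1 = straight_fiber(0, 100, 50, 150, radius=2.0)
        f2 = Fiber(1, [(float(r), 32.0) for r in range(40, 141)], 2.0)
        cls = [CrossLink((100.0, 150.0), frozenset({0, 1}))]
        return mask, _net([f1, f2], cls, (200, 200), px_um)

    def test_scale_equivariance(self):
        a = ft.compute_feature_vector(*self._setup(0.5))
        b = ft.compute_feature_vector(*self._setup(1.0))
        assert b.fiber_length_um == pytest.approx(2 * a.fiber_length_um)
        assert b.fiber_width_um == pytest.approx(2 * a.fiber_width_um)
        assert b.fiber_density == pytest.approx(a.fiber_density / 4)
        assert b.crosslink_density == pytest.approx(a.crosslink_density / 2)
        assert b.fiber_area == pytest.approx(a.fiber_area)
        assert b.orientation == pytest.approx(a.orientation)
        assert b.straightness == pytest.approx(a.straightness)

    def test_rotation_invariance_90deg(self):
        mask, net = self._setup(1.0)
        rot_mask = _mask(np.rot90(mask.pixels).copy(), pixel_size_um=1.0)
        h = mask.pixels.shape[1]

        def rot(v):
            return (h - 1 - v[1], v[0])

        rot_fibers = [
            Fiber(f.fiber_id, [rot(v) for v in f.vertices], f.mean_radius_px)
            for f in net.fibers
        ]
        rot_cls = [
            CrossLink(rot(c.position), c.incident_fiber_ids)
            for c in net.cross_links
        ]
        a = ft.compute_feature_vector(mask, net)
        b = ft.compute_feature_vector(
            rot_mask, _net(rot_fibers, rot_cls, rot_mask.pixels.shape, 1.0)
        )
        for x, y in zip(a.as_tuple(), b.as_tuple()):
            if math.isnan(x):
                assert math.isnan(y)
            else:
                assert y == pytest.approx(x, rel=1e-6)

    def test_straightness_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(10, 80)
            verts = np.cumsum(rng.normal(0, 1, (n, 2)), axis=0) + 100
            f = Fiber(0, [tuple(v) for v in verts], 1.0)
            assert f.straightness <= 1.0
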