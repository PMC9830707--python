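import math

import numpy as np
import pytest

from collafiber.segmentation import BinaryMask, refine_mask
from collafiber import fiber_network as fn


def make_mask(pixels: np.ndarray, pixel_size_um: float = 1.0, refined: bool = False):
    m = BinaryMask(pixels=pixels, refined=False, min_segment_px=5,
                   pixel_size_um=pixel_size_um)
    return refine_mask(m) if refined else m


@pytest.fixture
def bar_mask():
    """Horizontal solid bar, 100 x 5 px, in a 40 x 120 field."""
    px = np.zeros((40, 120), dtype=bool)
    px[18:23, 10:110] = True
    return make_mask(px, refined=True)


@pytest.fixture
def plus_mask():
    """Two perpendicular 5-px-wide bars, each 101 px, crossing centrally."""
    px = np.zeros((121, 121), dtype=bool)
    px[58:63, 10:111] = True
    px[10:111, 58:63] = True
    return make_mask(px, refined=True)


@pytest.fixture
def t_mask():
    """A 'T': stem meets the middle of a top bar at 90 degrees."""
    px = np.zeros((121, 121), dtype=bool)
    px[10:15, 10:111] = True  # top bar
    px[10:111, 58:63] = True  # stem
    return make_mask(px, refined=True)


def trace_network(mask, **kw):
    graph = fn.skeletonize_mask(mask)
    net = fn.extract_fibers(graph, **kw)
    net = fn.detect_cross_links(net)
    net = fn.estimate_widths(net, graph)
    return graph, net


def semicircle_vertices(radius: float = 60.0, center=(80.0, 80.0)):
    """Dense polyline along a semicircle (arc = pi * r, chord = 2r)."""
    n = int(math.pi * radius) + 1
    t = np.linspace(0.0, math.pi, n)
    return [
        (center[0] + radius * math.sin(a), center[1] + radius * math.cos(a))
        for a in t
    ]
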