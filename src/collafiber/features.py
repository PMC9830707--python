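"""The eight collagen morphometrics computed from a mask + network pair.

Feature definitions (units in parentheses):

- **fiber area** (a.u.): foreground fraction of the ROI, in [0, 1].
- **fiber density** (per mm^2): fiber count / ROI area in mm^2.
- **length** (µm): mean fiber arc length.
- **width** (µm): mean fiber width, 2 x mean centerline EDT radius.
- **orientation** (a.u.): alignment coherence — the mean resultant length
  of the doubled fiber chord angles, ``|sum_f exp(2i theta_f)| / N``; 1 for
  perfectly aligned fibers, ~0 for an isotropic network.  Angles are axial
  (identified mod pi), hence the doubling.
- **straightness** (a.u.): mean over fibers of end-to-end chord length
  divided by arc length; 1 iff every fiber is a straight chord.
- **cross-link space** (µm): mean along-fiber arc distance between
  consecutive cross-links on the same fiber; undefined (NaN) when no fiber
  carries at least two cross-links.
- **cross-link density** (a.u.): cross-links per 100 µm of total fiber
  length — scale-free per unit fiber, robust to ROI size.

Undefined values propagate as NaN and are excluded pairwise from group
statistics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from collafiber.segmentation import BinaryMask
from collafiber.fiber_network import FiberNetwork

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "compute_feature_vector",
    "crosslink_space",
    "orientation_coherence",
]

FEATURE_NAMES = (
    "area",
    "density",
    "length",
    "width",
    "orientation",
    "straightness",
    "crosslink_space",
    "crosslink_density",
)


@dataclass(frozen=True)
class FeatureVector:
    """The eight collagen morphometrics; undefined entries are NaN."""

    fiber_area: float
    fiber_density: float
    fiber_length_um: float
    fiber_width_um: float
    orientation: float
    straightness: float
    crosslink_space_um: float
    crosslink_density: float

    def as_tuple(self) -> tuple[float, ...]:
        """Values in canonical column order (see :data:`FEATURE_NAMES`)."""
        return (
            self.fiber_area,
            self.fiber_density,
            self.fiber_length_um,
            self.fiber_width_um,
            self.orientation,
            self.straightness,
            self.crosslink_space_um,
            self.crosslink_density,
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.as_tuple()))


def orientation_coherence(angles_rad) -> float:
    """Mean resultant length of doubled axial angles: ``|sum exp(2i t)|/N``.

    1 when all fibers share one axis, near 0 for isotropic orientations
    (expected resultant ~ N^-1/2 under uniformity).  NaN for an empty list.
    """
    angles = np.asarray(angles_rad, dtype=float)
    if angles.size == 0:
        return float("nan")
    z = np.exp(2j * angles)
    return float(abs(z.mean()))


def crosslink_space(
    fiber_arclengths_of_crosslinks: list[list[float]],
    pixel_size_um: float,
) -> float:
    """Mean consecutive along-fiber spacing of cross-links, in µm.

    ``fiber_arclengths_of_crosslinks`` holds, per fiber, the sorted arc
    positions (px) of that fiber's cross-links.  Undefined (NaN) when no
    fiber has two or more cross-links.
    """
    gaps: list[float] = []
    for arcs in fiber_arclengths_of_crosslinks:
        if len(arcs) >= 2:
            a = np.asarray(arcs, dtype=float)
            if np.any(np.diff(a) < 0):
                raise ValueError("arc positions must be sorted ascending")
            gaps.extend(np.diff(a))
    if not gaps:
        return float("nan")
    return float(np.mean(gaps) * pixel_size_um)


def _crosslink_arcs_per_fiber(net: FiberNetwork) -> list[list[float]]:
    """Arc position (px) of each cross-link along each incident fiber."""
    per_fiber: dict[int, list[float]] = {f.fiber_id: [] for f in net.fibers}
    fibers = {f.fiber_id: f for f in net.fibers}
    # cumulative arc length at each vertex, per fiber
    cum: dict[int, dict[tuple[float, float], float]] = {}
    for f in net.fibers:
        v = np.asarray(f.vertices, dtype=float)
        d = np.concatenate([[0.0], np.sqrt(((v[1:] - v[:-1]) ** 2).sum(axis=1))])
        arc = np.cumsum(d)
        # a position occurring twice on one fiber keeps its first arc value
        table: dict[tuple[float, float], float] = {}
        for vert, a in zip(f.vertices, arc):
            table.setdefault(vert, float(a))
        cum[f.fiber_id] = table
    for cl in net.cross_links:
        for fid in cl.incident_fiber_ids:
            a = cum[fid].get(cl.position)
            if a is not None:
                per_fiber[fid].append(a)
    return [sorted(v) for v in per_fiber.values()]


def compute_feature_vector(mask: BinaryMask, net: FiberNetwork) -> FeatureVector:
    """Compute the eight morphometrics from a refined mask and its network.

    The network must have widths estimated and cross-links detected.  An
    empty network yields area (still computable from the mask), density 0,
    and NaN for every fiber-wise mean.
    """
    if not mask.refined:
        raise ValueError("features require a refined mask")
    if mask.pixels.shape[0] * mask.pixels.shape[1] != net.roi_area_px2:
        raise ValueError("mask and network disagree on ROI size")
    px_um = net.pixel_size_um
    area = float(mask.pixels.mean())
    roi_mm2 = net.roi_area_px2 * (px_um / 1000.0) ** 2
    n_fib = len(net.fibers)
    density = n_fib / roi_mm2

    if n_fib == 0:
        nan = float("nan")
        return FeatureVector(area, 0.0, nan, nan, nan, nan, nan, nan)

    lengths_px = np.asarray([f.length_px for f in net.fibers])
    length_um = float(lengths_px.mean() * px_um)
    width_um = float(
        np.mean([2.0 * f.mean_radius_px for f in net.fibers]) * px_um
    )
    coher = orientation_coherence([f.orientation_rad for f in net.fibers])
    straight = float(np.mean([f.straightness for f in net.fibers]))
    cl_space = crosslink_space(_crosslink_arcs_per_fiber(net), px_um)
    total_len_um = float(lengths_px.sum() * px_um)
    cl_density = (
        100.0 * len(net.cross_links) / total_len_um if total_len_um > 0 else float("nan")
    )
    return FeatureVector(
        fiber_area=area,
        fiber_density=density,
        fiber_length_um=length_um,
        fiber_width_um=width_um,
        orientation=coher,
        straightness=straight,
        crosslink_space_um=cl_space,
        crosslink_density=cl_density,
    )
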