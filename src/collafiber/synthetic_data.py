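"""SHG-like phantom generator with vector ground truth.

Phantoms emulate stitched SHG fields: bright curvilinear fibers of varying
density, width, orientation concentration and crossing frequency over a dim
autofluorescent background, with Poisson photon noise and Gaussian read
noise.  Fiber centerlines are random walks with von Mises-distributed axial
orientations (angles identified mod pi, sampled via doubled angles) and
Gaussian per-step turning noise; rendering uses a Gaussian cross-profile
per fiber, composited by maximum so crossing brightness does not explode.

Two shipped contrast presets mimic the study conditions: a normal-muscularis
("nm") preset with dense, aligned, frequently crossing fibers, and a tumor
stroma ("gist") preset with sparse, short, disordered fibers.  A "null"
preset sits between the two and, used for both groups of a cohort, yields
exchangeable groups for type-I-error checks.

Everything is deterministic under the phantom's seed; cohorts derive
independent per-sample seeds from a master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import LineString, Point
from shapely.strtree import STRtree
from skimage.draw import line as draw_line

from collafiber.image_io import Channel, IntensityImage
from collafiber.features import FeatureVector, orientation_coherence, crosslink_space

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "sample_network",
    "render_phantom",
    "make_cohort",
    "nm_preset",
    "gist_preset",
    "null_preset",
]

_BORDER_MARGIN_PX = 8  # fiber seeds stay this far from the field edge


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom field.

    ``orientation_kappa`` is the von Mises concentration on doubled axial
    angles; ``curvature_sd_rad`` the SD of per-1-px-step turning noise;
    ``fiber_amplitude`` the centerline peak in photon units (so SNR =
    fiber_amplitude / noise_sd); ``psf_sigma_px`` an optical blur applied
    before noise.
    """

    height_px: int = 512
    width_px: int = 512
    pixel_size_um: float = 0.5
    n_fibers: int = 25
    length_range_px: tuple[float, float] = (100.0, 250.0)
    width_px_mean: float = 5.0
    width_px_sd: float = 0.8
    orientation_mu_rad: float = math.pi / 3
    orientation_kappa: float = 2.0
    curvature_sd_rad: float = 0.05
    fiber_amplitude: float = 50.0
    background_level: float = 5.0
    noise_sd: float = 8.0
    psf_sigma_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range_px[0] > self.length_range_px[1]:
            raise ValueError("length_range_px must be (min, max) with min <= max")
        for name in ("width_px_sd", "curvature_sd_rad", "noise_sd",
                     "orientation_kappa", "psf_sigma_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True vector geometry of a phantom: polylines, widths, crossings, and
    the feature vector computed analytically from them."""

    polylines: list[np.ndarray]  # per fiber: (n, 2) float (row, col)
    widths_px: list[float]
    crossings: list[tuple[tuple[float, float], tuple[int, int]]]
    true_features: FeatureVector


def _axial_angle(rng: np.random.Generator, mu: float, kappa: float) -> float:
    """Draw an axial angle in [0, pi) from a doubled-angle von Mises."""
    if kappa == 0:
        return float(rng.uniform(0, math.pi))
    phi = rng.vonmises(2.0 * mu, kappa)
    return float((phi / 2.0) % math.pi)


def _grow_polyline(
    rng: np.random.Generator, spec: PhantomSpec
) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    m = min(_BORDER_MARGIN_PX, h // 4, w // 4)
    r = rng.uniform(m, h - 1 - m)
    c = rng.uniform(m, w - 1 - m)
    theta = _axial_angle(rng, spec.orientation_mu_rad, spec.orientation_kappa)
    if rng.random() < 0.5:  # axial angle: either travel direction
        theta += math.pi
    target = rng.uniform(*spec.length_range_px)
    pts = [(r, c)]
    length = 0.0
    while length < target:
        theta += rng.normal(0.0, spec.curvature_sd_rad)
        nr = r + math.cos(theta)
        nc = c + math.sin(theta)
        if not (0 <= nr <= h - 1 and 0 <= nc <= w - 1):
            break  # clipped at the field bounds
        r, c = nr, nc
        pts.append((r, c))
        length += 1.0
    return np.asarray(pts, dtype=float)


def _pairwise_crossings(
    polylines: list[np.ndarray],
) -> list[tuple[tuple[float, float], tuple[int, int]]]:
    """All pairwise polyline intersection points via segment intersection."""
    geoms = [LineString(p) for p in polylines if len(p) >= 2]
    idx = [i for i, p in enumerate(polylines) if len(p) >= 2]
    if len(geoms) < 2:
        return []
    tree = STRtree(geoms)
    crossings: list[tuple[tuple[float, float], tuple[int, int]]] = []
    for a_pos, ga in enumerate(geoms):
        for b_pos in tree.query(ga):
            b_pos = int(b_pos)
            if b_pos <= a_pos:
                continue
            inter = ga.intersection(geoms[b_pos])
            if inter.is_empty:
                continue
            pts: list[Point] = []
            if inter.geom_type == "Point":
                pts = [inter]
            elif inter.geom_type == "MultiPoint":
                pts = list(inter.geoms)
            else:  # collinear overlap: take representative points
                pts = [inter.representative_point()]
            for p in pts:
                crossings.append(((p.x, p.y), (idx[a_pos], idx[b_pos])))
    return crossings


def _distance_patch(
    polyline: np.ndarray, shape: tuple[int, int], margin: int
) -> tuple[slice, slice, np.ndarray]:
    """Local Euclidean distance (px) to the rasterized polyline."""
    r0 = max(int(np.floor(polyline[:, 0].min())) - margin, 0)
    r1 = min(int(np.ceil(polyline[:, 0].max())) + margin + 1, shape[0])
    c0 = max(int(np.floor(polyline[:, 1].min())) - margin, 0)
    c1 = min(int(np.ceil(polyline[:, 1].max())) + margin + 1, shape[1])
    patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    pr = np.clip(np.round(polyline[:, 0]).astype(int) - r0, 0, patch.shape[0] - 1)
    pc = np.clip(np.round(polyline[:, 1]).astype(int) - c0, 0, patch.shape[1] - 1)
    for i in range(len(pr) - 1):
        rr, cc = draw_line(pr[i], pc[i], pr[i + 1], pc[i + 1])
        patch[rr, cc] = True
    patch[pr, pc] = True
    dist = ndi.distance_transform_edt(~patch)
    return slice(r0, r1), slice(c0, c1), dist


def _true_area_fraction(
    gt_polylines: list[np.ndarray],
    widths: list[float],
    shape: tuple[int, int],
) -> float:
    """Fraction of the field within width/2 of any centerline."""
    support = np.zeros(shape, dtype=bool)
    for poly, wd in zip(gt_polylines, widths):
        if len(poly) < 2:
            continue
        sr, sc, dist = _distance_patch(poly, shape, margin=int(math.ceil(wd)) + 2)
        support[sr, sc] |= dist <= wd / 2.0
    return float(support.mean())


def _arc_length(poly: np.ndarray) -> float:
    return float(np.sqrt(((poly[1:] - poly[:-1]) ** 2).sum(axis=1)).sum())


def _chord_angle(poly: np.ndarray) -> float:
    dr = poly[-1, 0] - poly[0, 0]
    dc = poly[-1, 1] - poly[0, 1]
    return math.atan2(dc, dr) % math.pi


def sample_network(spec: PhantomSpec) -> GroundTruth:
    """Draw a phantom fiber network and compute its true feature vector.

    Fibers start at uniform interior points, take an initial axial direction
    from the doubled-angle von Mises, grow in 1-px steps with Gaussian
    turning noise to a total length uniform in ``length_range_px``, and are
    clipped at the field bounds.  Crossings are exact pairwise polyline
    intersections.  True features use the same formulas as the measurement
    path: density from count/area, coherence from chord angles,
    straightness from chord/arc, cross-link metrics from the crossings.
    """
    rng = np.random.default_rng(spec.seed)
    polylines: list[np.ndarray] = []
    widths: list[float] = []
    for _ in range(spec.n_fibers):
        poly = _grow_polyline(rng, spec)
        polylines.append(poly)
        widths.append(float(max(1.0, rng.normal(spec.width_px_mean, spec.width_px_sd))))
    crossings = _pairwise_crossings(polylines)

    shape = (spec.height_px, spec.width_px)
    px_um = spec.pixel_size_um
    valid = [p for p in polylines if len(p) >= 2]
    n_fib = len(valid)
    roi_mm2 = shape[0] * shape[1] * (px_um / 1000.0) ** 2
    if n_fib == 0:
        nan = float("nan")
        tf = FeatureVector(0.0, 0.0, nan, nan, nan, nan, nan, nan)
        return GroundTruth(polylines, widths, crossings, tf)

    area = _true_area_fraction(polylines, widths, shape)
    lengths = [_arc_length(p) for p in valid]
    angles = [_chord_angle(p) for p in valid]
    chords = [float(np.linalg.norm(p[-1] - p[0])) for p in valid]
    straight = float(np.mean([ch / ln for ch, ln in zip(chords, lengths)]))

    # cross-link arc positions per fiber, via projection onto the polyline
    geoms = {i: LineString(p) for i, p in enumerate(polylines) if len(p) >= 2}
    arcs: dict[int, list[float]] = {i: [] for i in geoms}
    for (x, y), (ia, ib) in crossings:
        pt = Point(x, y)
        for i in (ia, ib):
            if i in geoms:
                arcs[i].append(float(geoms[i].project(pt)))
    cl_space = crosslink_space([sorted(v) for v in arcs.values()], px_um)
    total_len_um = float(np.sum(lengths) * px_um)
    tf = FeatureVector(
        fiber_area=area,
        fiber_density=n_fib / roi_mm2,
        fiber_length_um=float(np.mean(lengths) * px_um),
        fiber_width_um=float(np.mean([w for p, w in zip(polylines, widths)
                                      if len(p) >= 2]) * px_um),
        orientation=orientation_coherence(angles),
        straightness=straight,
        crosslink_space_um=cl_space,
        crosslink_density=100.0 * len(crossings) / total_len_um,
    )
    return GroundTruth(polylines, widths, crossings, tf)


def render_phantom(gt: GroundTruth, spec: PhantomSpec) -> IntensityImage:
    """Rasterize a ground-truth network into a noisy SHG-like image.

    Each centerline gets a Gaussian cross-profile (SD = width/2.355, so the
    FWHM equals the fiber width; peak = ``fiber_amplitude``), composited by
    maximum.  The background level is added, the field is blurred with the
    PSF, and Poisson photon noise (intensities are photon counts) plus
    Gaussian read noise is applied.  Deterministic under ``spec.seed``.
    """
    shape = (spec.height_px, spec.width_px)
    clean = np.zeros(shape, dtype=float)
    for poly, wd in zip(gt.polylines, gt.widths_px):
        if len(poly) < 2:
            continue
        sd = wd / 2.355
        sr, sc, dist = _distance_patch(poly, shape, margin=int(math.ceil(3 * sd)) + 2)
        profile = spec.fiber_amplitude * np.exp(-(dist**2) / (2.0 * sd**2))
        np.maximum(clean[sr, sc], profile, out=clean[sr, sc])
    clean += spec.background_level
    if spec.psf_sigma_px > 0:
        clean = ndi.gaussian_filter(clean, spec.psf_sigma_px)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0FFEE]))
    noisy = clean.astype(float)
    if spec.noise_sd > 0:  # noise_sd = 0 requests a noise-free render
        noisy = rng.poisson(np.clip(clean, 0, None)).astype(float)
        noisy += rng.normal(0.0, spec.noise_sd, size=shape)
    out = np.clip(noisy, 0.0, None)
    return IntensityImage(
        pixels=out, pixel_size_um=spec.pixel_size_um, channel_tag=Channel.SHG
    )


def nm_preset(**overrides) -> PhantomSpec:
    """Normal-muscularis-like field: dense, aligned, highly cross-linked."""
    base = dict(
        height_px=512, width_px=512, pixel_size_um=0.5,
        n_fibers=70, length_range_px=(150.0, 400.0),
        width_px_mean=5.0, width_px_sd=0.8,
        orientation_mu_rad=math.pi / 3, orientation_kappa=8.0,
        curvature_sd_rad=0.02,
        fiber_amplitude=50.0, background_level=5.0, noise_sd=8.0,
        psf_sigma_px=1.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def gist_preset(**overrides) -> PhantomSpec:
    """GIST-stroma-like field: sparse, short, disordered fibers."""
    base = dict(
        height_px=512, width_px=512, pixel_size_um=0.5,
        n_fibers=8, length_range_px=(30.0, 100.0),
        width_px_mean=4.0, width_px_sd=0.8,
        orientation_mu_rad=math.pi / 3, orientation_kappa=0.5,
        curvature_sd_rad=0.08,
        fiber_amplitude=50.0, background_level=5.0, noise_sd=8.0,
        psf_sigma_px=1.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def null_preset(**overrides) -> PhantomSpec:
    """Intermediate field; identical for both groups it gives a null cohort."""
    base = dict(
        height_px=512, width_px=512, pixel_size_um=0.5,
        n_fibers=25, length_range_px=(100.0, 250.0),
        width_px_mean=4.5, width_px_sd=0.8,
        orientation_mu_rad=math.pi / 3, orientation_kappa=2.0,
        curvature_sd_rad=0.05,
        fiber_amplitude=50.0, background_level=5.0, noise_sd=8.0,
        psf_sigma_px=1.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def _sample_seed(master_seed: int, group: str, index: int) -> int:
    group_code = int.from_bytes(group.encode()[:4].ljust(4, b"\0"), "big")
    ss = np.random.SeedSequence([int(master_seed), group_code, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    nm_spec: PhantomSpec,
    gist_spec: PhantomSpec,
    n_per_group: int,
    master_seed: int,
    group_labels: tuple[str, str] = ("NM", "GIST"),
) -> tuple[list[tuple[IntensityImage, GroundTruth]], list[tuple[IntensityImage, GroundTruth]]]:
    """Generate a two-group phantom cohort with derived per-sample seeds.

    Per-sample seeds are derived deterministically from
    ``(master_seed, group label, index)`` so cohorts are reproducible and
    samples independent.  Passing identical specs for both groups yields an
    exchangeable null cohort.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    out: list[list[tuple[IntensityImage, GroundTruth]]] = []
    for label, spec in zip(group_labels, (nm_spec, gist_spec)):
        group: list[tuple[IntensityImage, GroundTruth]] = []
        for i in range(n_per_group):
            s = replace(spec, seed=_sample_seed(master_seed, label, i))
            gt = sample_network(s)
            group.append((render_phantom(gt, s), gt))
        out.append(group)
    return out[0], out[1]
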