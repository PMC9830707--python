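"""End-to-end orchestration: image → ROI → enhance → segment → refine →
network → features, and the two-group study driver.

``run_sample`` executes the stages in pipeline order on one image and can
persist per-stage artifacts (enhanced map, masks before/after refinement,
network JSON, feature row, resolved config).  ``run_study`` maps a manifest
of (sample_id, group, image_path) rows to a feature table, per-group
summaries, and a comparison table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from collafiber import image_io, segmentation, fiber_network, features, statistics
from collafiber.image_io import IntensityImage

__all__ = ["PipelineConfig", "run_sample", "run_study", "StudyResult"]

logger = logging.getLogger("collafiber")


@dataclass
class PipelineConfig:
    """All pipeline knobs; only the physical pixel size has no default.

    The ROI policy matches quantification practice: a fixed default window
    of 1500x1500 px, center-cropped unless ``roi_origin`` pins the corner;
    images smaller than the window are used whole (with a warning).
    """

    pixel_size_um: float
    roi_size: tuple[int, int] = (1500, 1500)
    roi_origin: tuple[int, int] | None = None  # None -> center crop
    clip_percentiles: tuple[float, float] | None = None  # e.g. (0.5, 99.5)
    frangi_scales: tuple[float, ...] = segmentation.DEFAULT_SCALES
    frangi_beta: float = segmentation.DEFAULT_BETA
    frangi_c: float | str = "auto"
    gmm_subsample: int = segmentation.DEFAULT_GMM_SUBSAMPLE
    closing_radius_px: int = segmentation.DEFAULT_CLOSING_RADIUS
    min_segment_px: int = segmentation.DEFAULT_MIN_SEGMENT_PX
    spur_prune_px: int = fiber_network.DEFAULT_SPUR_PRUNE_PX
    max_join_angle_deg: float = fiber_network.DEFAULT_MAX_JOIN_ANGLE_DEG
    min_fiber_length_px: float = fiber_network.DEFAULT_MIN_FIBER_LENGTH_PX
    alpha: float = statistics.DEFAULT_ALPHA
    welch: bool = False
    correction: str = "none"
    seed: int = 0
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"]) if d["out_dir"] else None
        return d


def _select_roi(img: IntensityImage, cfg: PipelineConfig) -> IntensityImage:
    h, w = img.height_px, img.width_px
    rh, rw = cfg.roi_size
    if h < rh or w < rw:
        logger.warning(
            "image %dx%d smaller than ROI %dx%d; using the full image", h, w, rh, rw
        )
        return img
    if cfg.roi_origin is not None:
        return image_io.extract_roi(img, cfg.roi_origin, cfg.roi_size)
    origin = ((h - rh) // 2, (w - rw) // 2)
    return image_io.extract_roi(img, origin, cfg.roi_size)


def _normalize(img: IntensityImage, cfg: PipelineConfig) -> IntensityImage:
    if cfg.clip_percentiles is not None:
        lo, hi = np.percentile(img.pixels, cfg.clip_percentiles)
        if hi > lo:
            img = dataclasses.replace(
                img, pixels=np.clip(img.pixels, lo, hi)
            )
    return image_io.normalize_intensity(img)


def run_sample(
    image: IntensityImage | str | Path,
    cfg: PipelineConfig,
    sample_id: str = "sample",
):
    """Run the full quantification pipeline on one SHG image.

    Returns ``(FeatureVector, artifacts)`` where ``artifacts`` maps stage
    names to in-memory objects (and files when ``cfg.out_dir`` is set).
    Stage errors propagate with the failing stage named.
    """
    artifacts: dict = {}
    stage = "read"
    try:
        if not isinstance(image, IntensityImage):
            image = image_io.read_image(image, cfg.pixel_size_um)
        stage = "roi"
        roi = _select_roi(image, cfg)
        stage = "normalize"
        norm = _normalize(roi, cfg)
        stage = "enhance"
        enh = segmentation.frangi_enhance(
            norm, scales=cfg.frangi_scales, beta=cfg.frangi_beta, c=cfg.frangi_c
        )
        stage = "segment"
        raw_mask = segmentation.gmm_segment(
            enh, seed=cfg.seed, subsample=cfg.gmm_subsample
        )
        if raw_mask.warning:
            logger.warning("[%s] segment: %s", sample_id, raw_mask.warning)
        n_before = _component_count(raw_mask.pixels)
        stage = "refine"
        mask = segmentation.refine_mask(
            raw_mask,
            closing_radius_px=cfg.closing_radius_px,
            min_segment_px=cfg.min_segment_px,
        )
        n_after = _component_count(mask.pixels)
        stage = "network"
        graph = fiber_network.skeletonize_mask(mask, spur_prune_px=cfg.spur_prune_px)
        net = fiber_network.extract_fibers(
            graph,
            max_join_angle_deg=cfg.max_join_angle_deg,
            min_fiber_length_px=cfg.min_fiber_length_px,
        )
        net = fiber_network.detect_cross_links(net)
        net = fiber_network.estimate_widths(net, graph)
        stage = "features"
        fv = features.compute_feature_vector(mask, net)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed for {sample_id!r}") from exc

    logger.info(
        "[%s] fg_px=%d components=%d->%d fibers=%d cross_links=%d",
        sample_id, int(mask.pixels.sum()), n_before, n_after,
        len(net.fibers), len(net.cross_links),
    )
    artifacts.update(roi=roi, enhanced=enh, mask_raw=raw_mask, mask=mask,
                     graph=graph, network=net)

    if cfg.out_dir is not None:
        out = cfg.out_dir / sample_id
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "enhanced.tif", enh.pixels.astype(np.float32))
        image_io.write_mask(raw_mask.pixels, out / "mask_raw.tif")
        image_io.write_mask(mask.pixels, out / "mask_refined.tif")
        image_io.write_network_json(net, out / "network.json")
        image_io.write_feature_table([(sample_id, "", fv)], out / "features.csv")
        (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    return fv, artifacts


def _component_count(mask_px: np.ndarray) -> int:
    from scipy import ndimage as ndi

    _, n = ndi.label(mask_px, structure=np.ones((3, 3), int))
    return int(n)


@dataclass
class StudyResult:
    feature_table: pd.DataFrame
    summaries: dict[str, statistics.GroupSummary]
    comparison: list[statistics.ComparisonRow]

    @property
    def comparison_table(self) -> pd.DataFrame:
        return statistics.comparison_table(self.comparison)


def run_study(
    manifest: pd.DataFrame | str | Path,
    cfg: PipelineConfig,
    images: dict[str, IntensityImage] | None = None,
) -> StudyResult:
    """Quantify every sample in a two-group manifest and compare the groups.

    ``manifest`` needs columns sample_id, group, image_path (image_path may
    be omitted when ``images`` maps sample ids to in-memory images).
    Exactly two group labels are required, each with at least two samples.
    Writes the per-sample feature table, group summaries, and the
    comparison table to ``cfg.out_dir`` when set.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, dtype=str)
    groups = list(dict.fromkeys(manifest["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {groups}")
    counts = manifest["group"].value_counts()
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 samples")

    rows: list[tuple[str, str, features.FeatureVector]] = []
    by_group: dict[str, list[features.FeatureVector]] = {g: [] for g in groups}
    for rec in manifest.itertuples(index=False):
        sid, grp = str(rec.sample_id), str(rec.group)
        img = images[sid] if images is not None and sid in images else rec.image_path
        fv, _ = run_sample(img, cfg, sample_id=sid)
        rows.append((sid, grp, fv))
        by_group[grp].append(fv)

    summaries = {
        g: statistics.summarize_group(v, g) for g, v in by_group.items()
    }
    comparison = statistics.compare_groups(
        by_group[groups[0]], by_group[groups[1]],
        alpha=cfg.alpha, welch=cfg.welch, correction=cfg.correction,
    )
    table = pd.DataFrame(
        [
            dict(sample_id=s, group=g, **fv.as_dict())
            for s, g, fv in rows
        ]
    )
    if cfg.out_dir is not None:
        cfg.out_dir.mkdir(parents=True, exist_ok=True)
        image_io.write_feature_table(rows, cfg.out_dir / "features.csv")
        statistics.comparison_table(comparison).to_csv(
            cfg.out_dir / "comparison.csv", index=False
        )
        (cfg.out_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    return StudyResult(feature_table=table, summaries=summaries, comparison=comparison)
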