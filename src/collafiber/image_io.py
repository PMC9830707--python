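"""Image and table I/O, ROI extraction, and intensity normalization.

Conventions used throughout the package: images are row-major 2D arrays,
coordinates are (row, col), 0-based, origin at the top-left, and ROIs are
half-open ``[r, r+h) x [c, c+w)``.  The physical pixel size (µm/px) is a
required user input — it is never read from TIFF resolution tags, which are
unreliable across microscope vendors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Channel",
    "IntensityImage",
    "read_image",
    "write_image",
    "write_mask",
    "normalize_intensity",
    "extract_roi",
    "write_feature_table",
    "read_feature_table",
    "write_network_json",
    "read_network_json",
]


class Channel(str, Enum):
    """Acquisition channel of a two-photon image."""

    SHG = "SHG"
    TPAF = "TPAF"
    OTHER = "OTHER"


@dataclass(frozen=True)
class IntensityImage:
    """A 2D grayscale field with a physical calibration.

    Parameters
    ----------
    pixels : ndarray
        2D array of finite, non-negative intensities (float64).
    pixel_size_um : float
        Physical size of one pixel in µm; must be positive.
    channel_tag : Channel
        Which acquisition channel the image comes from (SHG by default).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_tag: Channel = Channel.SHG

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={px.ndim}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel per axis")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if np.any(px < 0):
            raise ValueError("image intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])


def read_image(
    path: str | Path,
    pixel_size_um: float,
    channel_tag: Channel | str = Channel.SHG,
) -> IntensityImage:
    """Read a single-plane grayscale 8/16-bit TIFF as an :class:`IntensityImage`.

    Raw integer values are cast to float64 without rescaling.  Multi-channel
    (RGB) or 3D stacks are rejected as unsupported layouts: the pipeline
    quantifies one SHG plane at a time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not (pixel_size_um > 0):
        raise ValueError("pixel_size_um must be positive")
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(
            f"unsupported layout: expected a single-plane grayscale image, "
            f"got shape {data.shape}"
        )
    return IntensityImage(
        pixels=data.astype(np.float64),
        pixel_size_um=float(pixel_size_um),
        channel_tag=Channel(channel_tag),
    )


def write_image(img: IntensityImage, path: str | Path, dtype: str = "uint16") -> None:
    """Write an image as an 8- or 16-bit grayscale TIFF (values cast, not scaled)."""
    if dtype not in ("uint8", "uint16"):
        raise ValueError("dtype must be 'uint8' or 'uint16'")
    tifffile.imwrite(Path(path), img.pixels.astype(dtype))


def write_mask(mask_pixels: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit 0/255 TIFF."""
    tifffile.imwrite(Path(path), (np.asarray(mask_pixels, bool) * 255).astype(np.uint8))


def normalize_intensity(img: IntensityImage) -> IntensityImage:
    """Linearly rescale intensities to [0, 1] by ``(x - min) / (max - min)``.

    A constant image maps to all zeros (the defined degenerate case), so the
    operation never divides by zero and downstream enhancement parameters
    are scale-free.
    """
    px = img.pixels
    lo = float(px.min())
    hi = float(px.max())
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    return replace(img, pixels=out)


def extract_roi(
    img: IntensityImage,
    origin_rc: tuple[int, int],
    size_rc: tuple[int, int],
) -> IntensityImage:
    """Extract the half-open sub-image ``[r, r+h) x [c, c+w)``.

    An ROI exceeding the image bounds raises — the caller must place the ROI
    explicitly; nothing is silently clipped.
    """
    r, c = int(origin_rc[0]), int(origin_rc[1])
    h, w = int(size_rc[0]), int(size_rc[1])
    if r < 0 or c < 0:
        raise ValueError(f"ROI origin must be non-negative, got {(r, c)}")
    if h < 1 or w < 1:
        raise ValueError(f"ROI size must be positive, got {(h, w)}")
    if r + h > img.height_px or c + w > img.width_px:
        raise ValueError(
            f"ROI [{r}:{r + h}, {c}:{c + w}] exceeds image bounds "
            f"{img.height_px}x{img.width_px}"
        )
    return replace(img, pixels=img.pixels[r : r + h, c : c + w].copy())


# CSV column order for feature tables; the two id columns come first.
_TABLE_COLUMNS = [
    "sample_id",
    "group",
    "area",
    "density",
    "length",
    "width",
    "orientation",
    "straightness",
    "crosslink_space",
    "crosslink_density",
]


def write_feature_table(
    rows: Sequence[tuple[str, str, "FeatureVector"]],
    path: str | Path,
) -> None:
    """Write (sample_id, group, FeatureVector) rows as a CSV feature table.

    Columns are fixed: sample_id, group, then the eight morphometrics in
    their canonical order.  Undefined feature values are serialized as empty
    fields.
    """
    if len(rows) == 0:
        raise ValueError("feature table must have at least one row")
    records = []
    for sample_id, group, fv in rows:
        rec = {"sample_id": sample_id, "group": group}
        rec.update(zip(_TABLE_COLUMNS[2:], fv.as_tuple()))
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=_TABLE_COLUMNS)
    df.to_csv(Path(path), index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV back into a DataFrame (missing -> NaN)."""
    return pd.read_csv(Path(path), dtype={"sample_id": str, "group": str})


def write_network_json(net: "FiberNetwork", path: str | Path) -> None:
    """Export a fiber network as line-geometry JSON.

    Per fiber: ordered (row, col) vertex list; per cross-link: (row, col)
    position plus incident fiber ids.
    """
    payload = {
        "roi_area_px2": net.roi_area_px2,
        "pixel_size_um": net.pixel_size_um,
        "fibers": [
            {
                "id": f.fiber_id,
                "vertices": [[float(r), float(c)] for r, c in f.vertices],
            }
            for f in net.fibers
        ],
        "cross_links": [
            {
                "position": [float(cl.position[0]), float(cl.position[1])],
                "fiber_ids": sorted(cl.incident_fiber_ids),
            }
            for cl in net.cross_links
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_network_json(path: str | Path) -> dict:
    """Read a line-geometry network JSON back as a plain dict."""
    return json.loads(Path(path).read_text())
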