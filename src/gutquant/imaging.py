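"""Shared image substrate for the pipeline.

Confocal-style data enter as multi-channel z-stacks (one 2-D plane per
channel and z position).  This module provides the in-memory containers
(:class:`ImagePlane`, :class:`ChannelStack`, :class:`RegionOfInterest`),
maximum projection, percentile level adjustment, median denoising, polygon
ROI rasterisation, and mean-intensity ranking of reporter images.

Conventions used everywhere downstream:

* coordinates are ``(row, col)``, 0-based, with pixel-centre semantics
  (the vertex ``(0, 0)`` is the centre of the top-left pixel);
* pixel size is isotropic, in micrometres per pixel; areas are reported in
  µm² via ``pixel_size_um ** 2``;
* intensities are non-negative floats; the nominal full scale for rendered
  and level-adjusted images is 1.0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "CHANNEL_NAMES",
    "ImagePlane",
    "ChannelStack",
    "RegionOfInterest",
    "MissingChannelError",
    "EmptyROIError",
    "RankResult",
    "max_project",
    "adjust_levels",
    "denoise",
    "roi_mask",
    "rank_by_intensity",
    "read_stack",
    "write_stack",
]

#: Channel labels understood by the pipeline.  DAPI/GFP/RFP/PH3 are the
#: fluorescence channels of the lineage-tracing stacks; R/G/B are the
#: colour planes of bright-field images (Oil Red O, TLC scans).
CHANNEL_NAMES = ("DAPI", "GFP", "RFP", "PH3", "R", "G", "B")

FULL_SCALE = 1.0


class MissingChannelError(KeyError):
    """A requested channel is not present in the stack."""


class EmptyROIError(ValueError):
    """A region of interest contains no pixels of the target image."""


@dataclass
class ImagePlane:
    """A single 2-D intensity image with physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities.
    pixel_size_um
        Micrometres per pixel (isotropic, > 0).
    channel_name
        One of :data:`CHANNEL_NAMES`.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_name: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.channel_name not in CHANNEL_NAMES:
            raise ValueError(
                f"unknown channel {self.channel_name!r}; expected one of {CHANNEL_NAMES}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ImagePlane":
        return ImagePlane(pixels, self.pixel_size_um, self.channel_name)


@dataclass
class ChannelStack:
    """Named multi-channel z-stack.

    ``channels`` maps a channel name to a 3-D array ``(z, rows, cols)``.
    All channels must share the same plane shape and plane count.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        shape = None
        for name, arr in list(self.channels.items()):
            if name not in CHANNEL_NAMES:
                raise ValueError(f"unknown channel {name!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                arr = arr[None, ...]
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} must be (z, rows, cols)")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("all channels must share plane shape and count")
            self.channels[name] = arr

    @property
    def plane_shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[1:]

    @property
    def n_planes(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise MissingChannelError(
                f"channel {name!r} not in stack (has {sorted(self.channels)})"
            )
        return self.channels[name]


@dataclass
class RegionOfInterest:
    """Simple polygon ROI given as ordered (row, col) vertices."""

    vertices: Sequence[tuple[float, float]]
    closed: bool = True

    def __post_init__(self) -> None:
        self.vertices = [(float(r), float(c)) for r, c in self.vertices]
        if len(self.vertices) < 3:
            raise ValueError("ROI needs at least 3 vertices")
        poly = self.polygon()
        if not poly.is_simple:
            raise ValueError("ROI polygon must be simple (non-self-intersecting)")

    def polygon(self) -> shapely.Polygon:
        # shapely works in (x, y); we feed (row, col) consistently so areas
        # and containment are unaffected by the axis naming.
        return shapely.Polygon(self.vertices)

    @property
    def area_px2(self) -> float:
        """Shoelace area in pixel² units."""
        return self.polygon().area

    @classmethod
    def from_json(cls, path) -> "RegionOfInterest":
        with open(path) as fh:
            vertices = json.load(fh)
        return cls(vertices)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([list(v) for v in self.vertices], fh)


def max_project(stack: ChannelStack, channel: str) -> ImagePlane:
    """Maximum-intensity projection of one channel over z.

    Each output pixel is the maximum over all z planes at that position;
    the physical pixel size is preserved.
    """
    arr = stack.channel(channel)
    return ImagePlane(arr.max(axis=0), stack.pixel_size_um, channel)


def adjust_levels(
    img: ImagePlane,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
    full_scale: float = FULL_SCALE,
) -> ImagePlane:
    """Linear percentile rescale: ``low_pct`` maps to 0, ``high_pct`` to full scale.

    Output is clipped to ``[0, full_scale]``.  A constant input cannot be
    stretched; it is returned as an all-zero plane with a warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(img.pixels, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("constant image: levels adjustment returns all zeros")
        return img.with_pixels(np.zeros_like(img.pixels))
    out = (img.pixels - lo) / (hi - lo) * full_scale
    return img.with_pixels(np.clip(out, 0.0, full_scale))


def denoise(img: ImagePlane, radius_px: int = 1) -> ImagePlane:
    """Median filter with a square window of side ``2 * radius_px + 1``.

    Radius 0 is the identity.  Median filtering is the default noise removal
    because it suppresses salt noise without eroding nucleus edges.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        return img.with_pixels(img.pixels.copy())
    size = 2 * int(radius_px) + 1
    return img.with_pixels(ndi.median_filter(img.pixels, size=size))


def roi_mask(roi: RegionOfInterest, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a polygon ROI onto an image grid.

    A pixel is inside if its centre lies inside the polygon (even-odd rule);
    pixels whose centres fall exactly on the boundary are included.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive")
    poly = roi.polygon()
    if poly.area == 0:
        raise ValueError("degenerate ROI polygon with zero area")
    mask = np.zeros((rows, cols), dtype=bool)
    minr, minc, maxr, maxc = poly.bounds
    r0 = max(int(np.floor(minr)), 0)
    c0 = max(int(np.floor(minc)), 0)
    r1 = min(int(np.ceil(maxr)) + 1, rows)
    c1 = min(int(np.ceil(maxc)) + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    # intersects == inside-or-on-boundary for points vs a polygon
    inside = shapely.intersects_xy(poly, rr.ravel(), cc.ravel())
    mask[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return mask


@dataclass
class RankResult:
    """Ascending mean-intensity ranking of reporter images."""

    order: list[int]  # input indices, ascending mean ROI intensity
    means: list[float]  # mean ROI intensity per input image (input order)
    tied: bool  # True when any two images share a mean
    tie_groups: list[list[int]] = field(default_factory=list)


def rank_by_intensity(
    images: Sequence[tuple[ImagePlane, RegionOfInterest]],
) -> RankResult:
    """Order reporter images by mean intensity inside their ROI, ascending.

    Automates the manual intensity ranking of reporter experiments; the
    resulting ranks feed a rank-based test (Mann-Whitney).  Ties are broken
    by input order and flagged.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images to rank")
    channels = {img.channel_name for img, _ in images}
    if len(channels) != 1:
        raise ValueError(f"all images must share one channel, got {sorted(channels)}")
    means: list[float] = []
    for img, roi in images:
        mask = roi_mask(roi, img.shape)
        if not mask.any():
            raise EmptyROIError("ROI selects no pixels")
        means.append(float(img.pixels[mask].mean()))
    arr = np.asarray(means)
    order = list(np.argsort(arr, kind="stable"))
    uniq, inverse, counts = np.unique(arr, return_inverse=True, return_counts=True)
    tie_groups = [
        [i for i in range(len(arr)) if inverse[i] == u]
        for u in range(len(uniq))
        if counts[u] > 1
    ]
    return RankResult(order=order, means=means, tied=bool(tie_groups), tie_groups=tie_groups)


# ---------------------------------------------------------------------------
# TIFF I/O.  Layout: multi-page, one page per (channel, z), channel-major.
# Channel names, z count and pixel size live in a JSON sidecar next to the
# TIFF (vendor metadata is unreliable; an explicit sidecar is unambiguous).
# ---------------------------------------------------------------------------


def _sidecar_path(path) -> str:
    return str(path) + ".json"


def write_stack(stack: ChannelStack, path) -> None:
    """Write a stack as a channel-major multi-page TIFF plus JSON sidecar."""
    names = list(stack.channels)
    pages = np.concatenate([stack.channels[n] for n in names], axis=0)
    tifffile.imwrite(str(path), pages.astype(np.float32), photometric="minisblack")
    sidecar = {
        "channels": names,
        "n_z": stack.n_planes,
        "pixel_size_um": stack.pixel_size_um,
        "metadata": stack.metadata,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_stack(
    path,
    channels: Iterable[str] | None = None,
    n_z: int | None = None,
    pixel_size_um: float | None = None,
) -> ChannelStack:
    """Read a multi-page TIFF written by :func:`write_stack`.

    When no sidecar is present, ``channels``, ``n_z`` and ``pixel_size_um``
    must be supplied explicitly.
    """
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None, ...]
    metadata: Mapping[str, str] = {}
    try:
        with open(_sidecar_path(path)) as fh:
            sidecar = json.load(fh)
        channels = channels or sidecar["channels"]
        n_z = n_z or sidecar["n_z"]
        pixel_size_um = pixel_size_um or sidecar["pixel_size_um"]
        metadata = sidecar.get("metadata", {})
    except FileNotFoundError:
        if channels is None or n_z is None or pixel_size_um is None:
            raise ValueError(
                "no sidecar found; pass channels, n_z and pixel_size_um explicitly"
            )
    channels = list(channels)
    if pages.shape[0] != len(channels) * n_z:
        raise ValueError(
            f"page count {pages.shape[0]} != n_channels({len(channels)}) * n_z({n_z})"
        )
    data = {
        name: pages[i * n_z : (i + 1) * n_z].astype(float)
        for i, name in enumerate(channels)
    }
    return ChannelStack(data, pixel_size_um, dict(metadata))
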