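"""Neutral-lipid quantification: Oil Red O channel subtraction and
thin-layer-chromatography band densitometry.

Oil Red O stains neutral lipid red on an essentially grey background; the
red signal is isolated by subtracting the green channel from the red, which
cancels any achromatic (grey) component exactly.  TLC plates are scanned,
inverted so bands are bright, and each lane's bands are integrated over a
row window after subtracting a linear baseline interpolated from the window
edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .imaging import EmptyROIError, ImagePlane, RegionOfInterest, roi_mask

__all__ = [
    "RGBImage",
    "TLCLaneProfile",
    "BandMeasurement",
    "oro_score",
    "tlc_quantify",
    "read_rgb",
]


@dataclass
class RGBImage:
    """Three co-registered colour planes of a bright-field image."""

    r: ImagePlane
    g: ImagePlane
    b: ImagePlane

    def __post_init__(self) -> None:
        if not (self.r.shape == self.g.shape == self.b.shape):
            raise ValueError("R, G and B planes must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    @classmethod
    def from_array(cls, arr: np.ndarray, pixel_size_um: float = 1.0) -> "RGBImage":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError("expected an (rows, cols, >=3) colour array")
        return cls(
            ImagePlane(arr[..., 0], pixel_size_um, "R"),
            ImagePlane(arr[..., 1], pixel_size_um, "G"),
            ImagePlane(arr[..., 2], pixel_size_um, "B"),
        )


def read_rgb(path, pixel_size_um: float = 1.0) -> RGBImage:
    """Read a PNG/TIFF colour image into an :class:`RGBImage`."""
    return RGBImage.from_array(iio.imread(str(path)), pixel_size_um)


def oro_score(
    img: RGBImage,
    roi: RegionOfInterest,
    min_particle_area_px: int = 0,
) -> float:
    """Mean Oil Red O signal inside the ROI.

    Per pixel ``s = max(R - G, 0)``: the grey background cancels, and
    negative residues (green/blue artefacts) are clipped so they cannot
    produce negative lipid signal.  ``min_particle_area_px`` optionally
    drops connected signal particles below that area before averaging
    (off by default).
    """
    mask = roi_mask(roi, img.shape)
    if not mask.any():
        raise EmptyROIError("ROI selects no pixels")
    s = np.clip(img.r.pixels - img.g.pixels, 0.0, None)
    if min_particle_area_px > 0:
        labels, n = ndi.label(s > 0)
        if n:
            sizes = ndi.sum_labels(
                np.ones_like(labels), labels, index=np.arange(1, n + 1)
            )
            small = np.isin(labels, np.nonzero(sizes < min_particle_area_px)[0] + 1)
            s = np.where(small, 0.0, s)
    return float(s[mask].mean())


@dataclass
class BandMeasurement:
    row_start: int
    row_end: int  # half-open window [row_start, row_end)
    integrated_intensity: float
    background: float


@dataclass
class TLCLaneProfile:
    """Column-summed intensity profile of one TLC lane with band integrals."""

    lane_bounds: tuple[int, int]  # half-open column window
    profile: np.ndarray
    bands: list[BandMeasurement] = field(default_factory=list)


def tlc_quantify(
    img: ImagePlane,
    lanes: Sequence[tuple[int, int]],
    band_windows: Sequence[tuple[int, int]],
    edge_margin: int = 3,
) -> list[TLCLaneProfile]:
    """Densitometry of TLC lanes on an inverted bright-field image.

    Per lane, intensity is summed across columns into a row profile; per
    band window, the integral of the profile above a linear baseline is
    reported.  The baseline interpolates between the medians of the first
    and last ``edge_margin`` rows of the window, so a constant pedestal
    cancels exactly; negative integrals are clipped to zero.
    """
    n_rows, n_cols = img.shape
    lanes = [(int(a), int(b)) for a, b in lanes]
    for c0, c1 in lanes:
        if not (0 <= c0 < c1 <= n_cols):
            raise ValueError(f"lane ({c0}, {c1}) outside image")
    for (a0, a1), (b0, b1) in zip(lanes, lanes[1:]):
        if b0 < a1:
            raise ValueError("lanes overlap")
    for r0, r1 in band_windows:
        if not (0 <= r0 < r1 <= n_rows):
            raise ValueError(f"band window ({r0}, {r1}) outside image")

    out: list[TLCLaneProfile] = []
    for c0, c1 in lanes:
        profile = img.pixels[:, c0:c1].sum(axis=1)
        bands = []
        for r0, r1 in band_windows:
            m = min(edge_margin, max(1, (r1 - r0) // 4))
            lo = float(np.median(profile[r0 : r0 + m]))
            hi = float(np.median(profile[r1 - m : r1]))
            baseline = np.linspace(lo, hi, r1 - r0)
            integral = float(np.sum(profile[r0:r1] - baseline))
            bands.append(
                BandMeasurement(
                    row_start=r0,
                    row_end=r1,
                    integrated_intensity=max(integral, 0.0),
                    background=float(baseline.sum()),
                )
            )
        out.append(TLCLaneProfile(lane_bounds=(c0, c1), profile=profile, bands=bands))
    return out
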