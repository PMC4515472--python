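"""ReDDM lineage-tracing quantification and gut morphometry.

The dual-marker tracing system labels intestinal progenitors (ISCs and
enteroblasts) with both a membrane GFP and a persistent nuclear histone RFP.
Post-mitotic progeny born during the tracing window inherit the stable RFP
but lose GFP expression, so an RFP-only nucleus dates cell birth to the
window.  This module turns a multi-channel gut image into the per-gut
report: tissue area, segmented DAPI nuclei, size-based ploidy calls
(polyploid enterocytes vs diploid progenitors/enteroendocrine cells),
RFP/GFP positivity, lineage class per nucleus, nucleus density and gut
diameter, plus a generic supra-threshold spot counter usable for mitotic
(pH3) figures.

Class logic per nucleus:

=============  =====  =====  ==========================================
cell_class      RFP    GFP    interpretation
=============  =====  =====  ==========================================
progenitor       +      +    ISC or enteroblast (actively traced)
new_progeny      +      -    progeny born during the tracing window
preexisting      -     any   cell predating the window
=============  =====  =====  ==========================================

GFP+/RFP- nuclei are anomalies (usually segmentation failures); they are
counted and reported, never silently reassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .imaging import ChannelStack, ImagePlane, max_project

__all__ = [
    "SegmentationParams",
    "NucleusRecord",
    "CellClassReport",
    "NoTissueError",
    "detect_gut_area",
    "segment_nuclei",
    "classify_ploidy",
    "assign_cell_classes",
    "measure_diameter",
    "count_spots",
    "quantify_gut",
    "records_to_frame",
]

PLOIDY = ("diploid", "polyploid")
CELL_CLASSES = ("progenitor", "new_progeny", "preexisting")


class NoTissueError(ValueError):
    """No tissue foreground could be found in the image."""


class SegmentationParams(BaseModel):
    """All knobs of the segmentation / classification stage.

    Attributes
    ----------
    dapi_threshold_method, fixed_threshold
        Nucleus foreground threshold on the smoothed DAPI projection:
        Otsu (default) or a fixed intensity.
    min_nucleus_area_um2
        Objects smaller than this are discarded as debris.
    smoothing_sigma_px
        Gaussian pre-smoothing before thresholding.
    split_touching
        Watershed-split touching nuclei using distance-transform maxima.
    ploidy_area_threshold_um2
        Area above which a nucleus is called polyploid; ``None`` selects the
        automatic two-class split of log-areas (Otsu on log area, i.e. the
        boundary minimising within-class variance).
    channel_positive_rule, overlap_fraction
        RFP positivity: either the fraction of nucleus pixels inside the
        segmented RFP mask must reach ``overlap_fraction`` (``mask_overlap``,
        the default — the histone RFP is nuclear) or the mean nuclear RFP
        must exceed the channel threshold (``intensity``).
    gfp_annulus_px
        The membrane GFP is compared to nuclei through an annulus of this
        width dilated around each nucleus.
    gfp_threshold_scale
        GFP positivity threshold as a multiple of the Otsu threshold of the
        GFP plane (annulus mean must exceed it); exposed as a knob for
        images where membrane signal is unusually dim or bright.
    """

    dapi_threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float = 0.2
    min_nucleus_area_um2: float = 6.0
    smoothing_sigma_px: float = 1.0
    split_touching: bool = True
    ploidy_area_threshold_um2: Optional[float] = None  # None -> auto
    channel_positive_rule: Literal["mask_overlap", "intensity"] = "mask_overlap"
    overlap_fraction: float = 0.5
    gfp_annulus_px: int = 3
    gfp_threshold_method: Literal["otsu", "fixed"] = "otsu"
    gfp_threshold_scale: float = 1.0
    gfp_fixed_threshold: float = 0.2
    rfp_threshold_method: Literal["otsu", "fixed"] = "otsu"
    rfp_fixed_threshold: float = 0.2
    gut_blur_sigma_px: float = 8.0
    spot_threshold_method: Literal["otsu", "fixed"] = "otsu"
    spot_fixed_threshold: float = 0.2
    min_spot_area_px: int = 4
    diameter_orientation: Literal["vertical", "horizontal"] = "vertical"

    @model_validator(mode="after")
    def _check(self) -> "SegmentationParams":
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.fixed_threshold < 0 or self.rfp_fixed_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if (
            self.ploidy_area_threshold_um2 is not None
            and self.ploidy_area_threshold_um2 <= self.min_nucleus_area_um2
        ):
            raise ValueError(
                "ploidy_area_threshold_um2 must exceed min_nucleus_area_um2"
            )
        return self


@dataclass
class NucleusRecord:
    """One segmented nucleus with its measurements and class labels."""

    label: int
    centroid: tuple[float, float]  # (row, col)
    area_um2: float
    mean_intensity: dict[str, float]
    ploidy: Optional[str] = None
    cell_class: Optional[str] = None
    # pixel coordinates of the nucleus (row idx, col idx); internal geometry
    # needed by the annulus rule, excluded from tabular output.
    pixels_rc: Optional[tuple[np.ndarray, np.ndarray]] = field(
        default=None, repr=False, compare=False
    )


@dataclass
class CellClassReport:
    """Per-gut summary: total nuclei, enterocytes (large DAPI nuclei),
    RFP+ nuclei (progenitors + traced progeny), GFP+ progenitors, newly
    generated progeny, tissue area, nucleus density and optional diameter."""

    n_total_nuclei: int
    n_ec: int
    n_rfp: int
    n_gfp: int
    n_new_progeny: int
    gut_area_um2: float
    density_per_mm2: float
    diameter_um: Optional[float] = None
    n_anomalous_gfp_only: int = 0

    def __post_init__(self) -> None:
        if not (self.n_gfp <= self.n_rfp <= self.n_total_nuclei):
            raise ValueError("invariant n_gfp <= n_rfp <= n_total violated")
        if self.n_new_progeny != self.n_rfp - self.n_gfp:
            raise ValueError("n_new_progeny must equal n_rfp - n_gfp")
        if self.n_ec > self.n_total_nuclei:
            raise ValueError("n_ec cannot exceed n_total_nuclei")

    def to_dict(self) -> dict:
        return {
            "n_total_nuclei": self.n_total_nuclei,
            "n_ec": self.n_ec,
            "n_rfp": self.n_rfp,
            "n_gfp": self.n_gfp,
            "n_new_progeny": self.n_new_progeny,
            "gut_area_um2": self.gut_area_um2,
            "density_per_mm2": self.density_per_mm2,
            "diameter_um": self.diameter_um,
            "n_anomalous_gfp_only": self.n_anomalous_gfp_only,
        }


def _channel_threshold(pixels: np.ndarray, method: str, fixed: float,
                       mask: np.ndarray | None = None) -> float:
    """Foreground threshold for one channel; +inf for a constant image so a
    blank channel yields no positives instead of an error."""
    values = pixels[mask] if mask is not None else pixels.ravel()
    if method == "fixed":
        return fixed
    if values.size == 0 or values.max() == values.min():
        return np.inf
    return float(threshold_otsu(values))


def detect_gut_area(stack: ChannelStack, params: SegmentationParams) -> np.ndarray:
    """Locate the tissue as the largest connected low-frequency foreground
    region of the blurred DAPI channel (tissue background staining plus
    nuclei), holes filled.  Returns a boolean mask."""
    dapi = max_project(stack, "DAPI")
    if dapi.pixels.max() == 0:
        raise NoTissueError("DAPI channel is empty; no tissue found")
    raw = dapi.pixels
    # Saturate the image before blurring so the low-frequency split
    # separates tissue from background rather than nuclei from tissue:
    # a first Otsu isolates bright nuclei, a second Otsu on the remainder
    # finds the tissue-floor level, and capping there makes the tissue
    # nearly uniform.
    if raw.max() > raw.min():
        t1 = threshold_otsu(raw)
        rest = raw[raw < t1]
        if rest.size and rest.max() > rest.min():
            t1 = max(threshold_otsu(rest), 1e-12)
        capped = np.minimum(raw, t1)
    else:
        capped = raw
    blurred = ndi.gaussian_filter(capped, params.gut_blur_sigma_px)
    if blurred.max() == blurred.min():
        # uniform non-zero signal: the whole frame is tissue
        return np.ones(dapi.shape, dtype=bool)
    thr = threshold_otsu(blurred)
    fg = blurred > thr
    if not fg.any():
        raise NoTissueError("no foreground above threshold")
    labels, n = ndi.label(fg)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndi.binary_fill_holes(mask)


def segment_nuclei(
    dapi: ImagePlane,
    mask: np.ndarray,
    params: SegmentationParams,
    channels: dict[str, ImagePlane] | None = None,
) -> list[NucleusRecord]:
    """Segment DAPI nuclei within the tissue mask.

    Gaussian smoothing → threshold (Otsu or fixed) → optional watershed split
    of touching objects seeded from distance-transform maxima → discard
    objects below ``min_nucleus_area_um2`` or outside the mask.  Records
    carry centroid, area in µm² and mean intensity per supplied channel.
    """
    if dapi.shape != mask.shape:
        raise ValueError("dapi and mask shapes differ")
    px = dapi.pixel_size_um
    smoothed = (
        ndi.gaussian_filter(dapi.pixels, params.smoothing_sigma_px)
        if params.smoothing_sigma_px > 0
        else dapi.pixels
    )
    if params.dapi_threshold_method == "otsu":
        vals = smoothed[mask]
        if vals.size == 0 or vals.max() == vals.min():
            warnings.warn("no DAPI foreground; returning empty nucleus list")
            return []
        thr = threshold_otsu(vals)
    else:
        thr = params.fixed_threshold
    fg = (smoothed > thr) & mask
    if not fg.any():
        warnings.warn("threshold selected zero foreground pixels")
        return []

    min_area_px = params.min_nucleus_area_um2 / px**2
    if params.split_touching:
        distance = ndi.distance_transform_edt(fg)
        # peaks closer than roughly one small-nucleus radius are merged so
        # single convex nuclei are not oversplit
        min_sep = max(3, int(round(np.sqrt(min_area_px / np.pi))) + 2)
        from skimage.feature import peak_local_max

        coords = peak_local_max(
            distance, min_distance=min_sep, labels=fg, exclude_border=False
        )
        markers = np.zeros(fg.shape, dtype=int)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        if markers.max() == 0:
            labels = sk_label(fg)
        else:
            labels = watershed(-distance, markers, mask=fg)
    else:
        labels = sk_label(fg)

    channels = channels or {}
    records: list[NucleusRecord] = []
    next_label = 1
    for prop in regionprops(labels):
        area_um2 = prop.area * px**2
        if area_um2 < params.min_nucleus_area_um2:
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        means = {
            name: float(plane.pixels[rr, cc].mean()) for name, plane in channels.items()
        }
        records.append(
            NucleusRecord(
                label=next_label,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_um2=float(area_um2),
                mean_intensity=means,
                pixels_rc=(rr, cc),
            )
        )
        next_label += 1
    return records


def _two_class_midpoint(sorted_values: np.ndarray) -> float:
    """Exact 1-D two-class split minimising total within-class variance;
    returns the midpoint between the two class means."""
    x = np.asarray(sorted_values, dtype=float)
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    ks = np.arange(1, n)  # split after index k-1
    ss0 = csq[ks - 1] - csum[ks - 1] ** 2 / ks
    ss1 = (csq[-1] - csq[ks - 1]) - (csum[-1] - csum[ks - 1]) ** 2 / (n - ks)
    k = int(ks[np.argmin(ss0 + ss1)])
    return float((x[:k].mean() + x[k:].mean()) / 2)


def classify_ploidy(
    nuclei: Sequence[NucleusRecord], params: SegmentationParams
) -> list[NucleusRecord]:
    """Set ploidy per nucleus by area threshold.

    A nucleus is polyploid iff its area reaches the threshold.  With no
    fixed threshold configured, the threshold is the two-class split of
    log-areas minimising within-class variance (nucleus areas of the midgut
    are strongly bimodal: diploid progenitors/enteroendocrine cells vs
    polyploid enterocytes).
    """
    nuclei = list(nuclei)
    if params.ploidy_area_threshold_um2 is not None:
        thr = params.ploidy_area_threshold_um2
    else:
        if len(nuclei) < 4:
            raise ValueError(
                "auto ploidy threshold needs >= 4 nuclei; set "
                "ploidy_area_threshold_um2 explicitly"
            )
        log_areas = np.sort(np.log([n.area_um2 for n in nuclei]))
        thr = float(np.exp(_two_class_midpoint(log_areas)))
    for n in nuclei:
        n.ploidy = "polyploid" if n.area_um2 >= thr else "diploid"
    return nuclei


def _annulus_mask_local(
    rr: np.ndarray, cc: np.ndarray, width: int, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of the annulus of given width around a nucleus."""
    r0 = max(rr.min() - width, 0)
    c0 = max(cc.min() - width, 0)
    r1 = min(rr.max() + width + 1, shape[0])
    c1 = min(cc.max() + width + 1, shape[1])
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[rr - r0, cc - c0] = True
    dilated = ndi.binary_dilation(local, structure=disk(width))
    ring = dilated & ~local
    lr, lc = np.nonzero(ring)
    return lr + r0, lc + c0


def assign_cell_classes(
    nuclei: Sequence[NucleusRecord],
    rfp: ImagePlane,
    gfp: ImagePlane,
    params: SegmentationParams,
    gut_mask: np.ndarray | None = None,
    diameter_um: float | None = None,
) -> tuple[list[NucleusRecord], CellClassReport]:
    """Assign lineage classes from RFP/GFP positivity and build the report.

    RFP positivity follows ``params.channel_positive_rule``; GFP positivity
    uses the mean GFP inside an annulus around the nucleus (the GFP is a
    membrane marker, so its signal surrounds rather than fills nuclei).
    """
    if rfp.shape != gfp.shape:
        raise ValueError("rfp and gfp shapes differ")
    nuclei = list(nuclei)
    if any(n.ploidy is None for n in nuclei):
        raise ValueError("nuclei must have ploidy assigned first")
    shape = rfp.shape
    rfp_thr = _channel_threshold(
        rfp.pixels, params.rfp_threshold_method, params.rfp_fixed_threshold, gut_mask
    )
    if params.gfp_threshold_method == "fixed":
        gfp_thr = params.gfp_fixed_threshold
    else:
        gfp_thr = _channel_threshold(gfp.pixels, "otsu", 0.0, gut_mask)
        if np.isfinite(gfp_thr):
            gfp_thr *= params.gfp_threshold_scale
    rfp_mask = rfp.pixels > rfp_thr if np.isfinite(rfp_thr) else np.zeros(shape, bool)

    n_anom = 0
    for n in nuclei:
        if n.pixels_rc is None:
            raise ValueError("nucleus records lack pixel coordinates")
        rr, cc = n.pixels_rc
        if params.channel_positive_rule == "mask_overlap":
            rfp_pos = rfp_mask[rr, cc].mean() >= params.overlap_fraction
        else:
            rfp_pos = rfp.pixels[rr, cc].mean() > rfp_thr
        ar, ac = _annulus_mask_local(rr, cc, params.gfp_annulus_px, shape)
        gfp_pos = bool(ar.size) and gfp.pixels[ar, ac].mean() > gfp_thr
        if rfp_pos and gfp_pos:
            n.cell_class = "progenitor"
        elif rfp_pos:
            n.cell_class = "new_progeny"
        else:
            n.cell_class = "preexisting"
            if gfp_pos:
                n_anom += 1

    n_total = len(nuclei)
    n_gfp = sum(1 for n in nuclei if n.cell_class == "progenitor")
    n_rfp = n_gfp + sum(1 for n in nuclei if n.cell_class == "new_progeny")
    n_ec = sum(1 for n in nuclei if n.ploidy == "polyploid")
    if gut_mask is not None:
        gut_area_um2 = float(gut_mask.sum()) * rfp.pixel_size_um**2
    else:
        gut_area_um2 = float(np.prod(shape)) * rfp.pixel_size_um**2
    density = n_total / (gut_area_um2 * 1e-6) if gut_area_um2 > 0 else 0.0
    report = CellClassReport(
        n_total_nuclei=n_total,
        n_ec=n_ec,
        n_rfp=n_rfp,
        n_gfp=n_gfp,
        n_new_progeny=n_rfp - n_gfp,
        gut_area_um2=gut_area_um2,
        density_per_mm2=density,
        diameter_um=diameter_um,
        n_anomalous_gfp_only=n_anom,
    )
    return nuclei, report


def measure_diameter(
    mask: np.ndarray,
    pixel_size_um: float,
    orientation: Literal["vertical", "horizontal"] = "vertical",
) -> float:
    """Gut width along the line through the image centre.

    Counts tissue pixels on the central column (``vertical``) or row
    (``horizontal``) and converts to µm.  Reproduces the manual line-tool
    width measurement, deterministically.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if orientation == "vertical":
        line = mask[:, mask.shape[1] // 2]
    else:
        line = mask[mask.shape[0] // 2, :]
    n = int(line.sum())
    if n == 0:
        raise ValueError(
            "central line does not cross the tissue; re-centre the ROI or "
            "switch orientation"
        )
    return n * pixel_size_um


def count_spots(
    plane: ImagePlane, mask: np.ndarray, params: SegmentationParams
) -> int:
    """Count connected supra-threshold objects within the mask.

    Generic spot counter for punctate channels (e.g. mitotic-marker
    stainings); objects smaller than ``min_spot_area_px`` are ignored.
    """
    if plane.shape != mask.shape:
        raise ValueError("plane and mask shapes differ")
    smoothed = ndi.gaussian_filter(plane.pixels, 1.0)
    thr = _channel_threshold(
        smoothed, params.spot_threshold_method, params.spot_fixed_threshold, mask
    )
    if not np.isfinite(thr):
        return 0
    fg = (smoothed > thr) & mask
    labels, n = ndi.label(fg)
    if n == 0:
        return 0
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return int((sizes >= params.min_spot_area_px).sum())


def quantify_gut(
    stack: ChannelStack, params: SegmentationParams | None = None
) -> tuple[list[NucleusRecord], CellClassReport]:
    """Full pipeline: project channels, detect tissue, segment nuclei,
    classify ploidy and lineage classes, measure diameter, build report."""
    params = params or SegmentationParams()
    dapi = max_project(stack, "DAPI")
    rfp = max_project(stack, "RFP") if "RFP" in stack.channels else dapi.with_pixels(
        np.zeros(dapi.shape)
    )
    rfp = ImagePlane(rfp.pixels, stack.pixel_size_um, "RFP")
    if "GFP" in stack.channels:
        gfp = max_project(stack, "GFP")
    else:
        gfp = ImagePlane(np.zeros(dapi.shape), stack.pixel_size_um, "GFP")
    gut = detect_gut_area(stack, params)
    nuclei = segment_nuclei(
        dapi, gut, params, channels={"DAPI": dapi, "RFP": rfp, "GFP": gfp}
    )
    if not nuclei:
        report = CellClassReport(0, 0, 0, 0, 0,
                                 float(gut.sum()) * stack.pixel_size_um**2, 0.0)
        return [], report
    nuclei = classify_ploidy(nuclei, params)
    diameter = measure_diameter(
        gut, stack.pixel_size_um, params.diameter_orientation
    )
    return assign_cell_classes(
        nuclei, rfp, gfp, params, gut_mask=gut, diameter_um=diameter
    )


def records_to_frame(records: Sequence[NucleusRecord]) -> pd.DataFrame:
    """Per-nucleus table (one row per nucleus) for CSV export."""
    rows = []
    for n in records:
        row = {
            "label": n.label,
            "centroid_row": n.centroid[0],
            "centroid_col": n.centroid[1],
            "area_um2": n.area_um2,
            "ploidy": n.ploidy,
            "cell_class": n.cell_class,
        }
        for ch, v in n.mean_intensity.items():
            row[f"mean_{ch}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
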