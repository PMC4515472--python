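"""Synthetic ground-truth data for every stage of the pipeline.

Every generator here is a pure function of its parameters and a seed:
identical inputs give bit-identical outputs.  The scene generator emulates a
confocal field of the posterior midgut under the dual-marker tracing
system: a horizontal tissue band with faint background staining, a mixture
of small diploid nuclei (progenitors, enteroendocrine cells) and large
polyploid enterocyte nuclei rendered in DAPI, nuclear RFP in traced cells,
membrane-GFP rings around progenitors, Gaussian optics blur, a linear
background gradient and additive Gaussian noise.

Class flags are consistent by construction: progenitors are GFP+ and RFP+,
newly generated progeny are RFP+ only, pre-existing cells carry neither
marker.  Mating multiplies the mean number of new progeny (x3 by default)
and progenitors (x1.5) — the direction and magnitude knobs the image
pipeline and count statistics are benchmarked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .dartms import MassSpectrum
from .imaging import ChannelStack
from .lipids import RGBImage
from .reddm import CellClassReport, NucleusRecord
from .stats import CountData, CtTable

__all__ = [
    "SceneParams",
    "CellTruth",
    "GroundTruthScene",
    "PlacementError",
    "generate_scene",
    "generate_oro_image",
    "generate_spectrum",
    "generate_ct_table",
    "generate_counts",
    "generate_hatch_table",
    "match_records",
    "class_f1_scores",
]

LINEAGE_CLASSES = (
    "preexisting_ec",
    "preexisting_diploid",
    "progenitor",
    "new_ec",
    "new_eec",
)
#: lineage class -> (ploidy, rfp_pos, gfp_pos, reported cell_class)
CLASS_DEFS = {
    "preexisting_ec": ("polyploid", False, False, "preexisting"),
    "preexisting_diploid": ("diploid", False, False, "preexisting"),
    "progenitor": ("diploid", True, True, "progenitor"),
    "new_ec": ("polyploid", True, False, "new_progeny"),
    "new_eec": ("diploid", True, False, "new_progeny"),
}


class PlacementError(RuntimeError):
    """Cell density too high for non-overlapping placement."""


class SceneParams(BaseModel):
    """Geometry, composition and noise model of a synthetic midgut field.

    Defaults describe a 20x-objective-like field: 512 px at 0.5 µm/px with a
    tissue band spanning 60 % of the frame.  The virgin composition per
    field (means of Poisson draws) is 60 pre-existing enterocytes, 25
    pre-existing diploid cells, 12 progenitors, 4 new enterocytes and 2 new
    enteroendocrine cells; mating multiplies progenitors by
    ``mated_progenitor_factor`` and both new-progeny classes by
    ``mated_new_factor``.
    """

    field_size_px: int = 512
    pixel_size_um: float = 0.5
    class_means: dict[str, float] = {
        "preexisting_ec": 60.0,
        "preexisting_diploid": 25.0,
        "progenitor": 12.0,
        "new_ec": 4.0,
        "new_eec": 2.0,
    }
    mated_progenitor_factor: float = 1.5
    mated_new_factor: float = 3.0
    diploid_radius_um: tuple[float, float] = (2.5, 0.25)  # mean, sd
    polyploid_radius_um: tuple[float, float] = (6.0, 0.6)
    psf_sigma_px: float = 1.0
    noise_sd_fraction: float = 0.1
    background_gradient: float = 0.03
    tissue_background: float = 0.12
    gut_band_fraction: float = 0.6
    dapi_amplitude: dict[str, float] = {"diploid": 1.0, "polyploid": 1.0}
    rfp_amplitude: float = 1.0
    gfp_amplitude: float = 1.0
    gfp_ring_width_px: int = 3
    min_gap_px: float = 1.0
    max_placement_attempts: int = 5000
    deterministic_counts: bool = False  # rounded means instead of Poisson draws
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SceneParams":
        if set(self.class_means) != set(LINEAGE_CLASSES):
            raise ValueError(f"class_means must have keys {LINEAGE_CLASSES}")
        if any(v < 0 for v in self.class_means.values()):
            raise ValueError("class means must be >= 0")
        if self.diploid_radius_um[0] <= 0 or self.polyploid_radius_um[0] <= 0:
            raise ValueError("radii must be positive")
        if self.polyploid_radius_um[0] <= self.diploid_radius_um[0]:
            raise ValueError("polyploid mean radius must exceed diploid")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise fraction must be >= 0")
        if not (0 < self.gut_band_fraction <= 1):
            raise ValueError("gut_band_fraction must be in (0, 1]")
        return self


@dataclass
class CellTruth:
    """Ground-truth cell: position (px), nucleus radius and class flags."""

    centre: tuple[float, float]  # (row, col) in px
    radius_um: float
    ploidy: str
    lineage: str
    rfp_pos: bool
    gfp_pos: bool

    @property
    def cell_class(self) -> str:
        return CLASS_DEFS[self.lineage][3]


@dataclass
class GroundTruthScene:
    """Generated cells with known classes plus the tissue mask."""

    cells: list[CellTruth]
    gut_mask: np.ndarray
    params: SceneParams
    condition: str
    seed: int

    def validate(self) -> None:
        """Re-check class-flag consistency and geometric invariants."""
        for c in self.cells:
            ploidy, rfp, gfp, _ = CLASS_DEFS[c.lineage]
            assert c.ploidy == ploidy and c.rfp_pos == rfp and c.gfp_pos == gfp, (
                f"inconsistent flags for {c.lineage}"
            )
            r, col = int(round(c.centre[0])), int(round(c.centre[1]))
            assert self.gut_mask[r, col], "cell centre outside gut mask"
        px = self.params.pixel_size_um
        centres = np.array([c.centre for c in self.cells])
        radii = np.array([c.radius_um / px for c in self.cells])
        if len(self.cells) > 1:
            tree = cKDTree(centres)
            pairs = tree.query_pairs(2 * radii.max() + self.params.min_gap_px)
            for i, j in pairs:
                d = np.hypot(*(centres[i] - centres[j]))
                assert d >= radii[i] + radii[j], "nuclei overlap"

    def expected_report(self) -> CellClassReport:
        """The report the image pipeline should reproduce (count fields are
        exact; area/density/diameter come from the true mask geometry)."""
        n_by = {cls: sum(1 for c in self.cells if c.lineage == cls) for cls in CLASS_DEFS}
        n_total = len(self.cells)
        n_gfp = n_by["progenitor"]
        n_new = n_by["new_ec"] + n_by["new_eec"]
        px = self.params.pixel_size_um
        area = float(self.gut_mask.sum()) * px**2
        return CellClassReport(
            n_total_nuclei=n_total,
            n_ec=n_by["preexisting_ec"] + n_by["new_ec"],
            n_rfp=n_gfp + n_new,
            n_gfp=n_gfp,
            n_new_progeny=n_new,
            gut_area_um2=area,
            density_per_mm2=n_total / (area * 1e-6) if area else 0.0,
            diameter_um=float(self.gut_mask[:, self.gut_mask.shape[1] // 2].sum()) * px,
        )


def _render_disk(img: np.ndarray, centre, radius_px: float, amplitude: float) -> None:
    r0 = max(int(np.floor(centre[0] - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(centre[0] + radius_px)) + 2, img.shape[0])
    c0 = max(int(np.floor(centre[1] - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(centre[1] + radius_px)) + 2, img.shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2
    patch = img[r0:r1, c0:c1]
    np.maximum(patch, amplitude * (d2 <= radius_px**2), out=patch)


def _render_ring(
    img: np.ndarray, centre, r_inner_px: float, width_px: float, amplitude: float
) -> None:
    r_out = r_inner_px + width_px
    r0 = max(int(np.floor(centre[0] - r_out)) - 1, 0)
    r1 = min(int(np.ceil(centre[0] + r_out)) + 2, img.shape[0])
    c0 = max(int(np.floor(centre[1] - r_out)) - 1, 0)
    c1 = min(int(np.ceil(centre[1] + r_out)) + 2, img.shape[1])
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    d2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2
    ring = (d2 >= r_inner_px**2) & (d2 <= r_out**2)
    patch = img[r0:r1, c0:c1]
    np.maximum(patch, amplitude * ring, out=patch)


def generate_scene(
    params: SceneParams | None = None,
    condition: Literal["virgin", "mated"] = "virgin",
    seed: Optional[int] = None,
) -> tuple[GroundTruthScene, ChannelStack]:
    """Generate one ground-truth midgut scene and its rendered stack.

    Class counts are Poisson draws around condition-specific means; nuclei
    are placed hard-core (no overlap) inside the tissue band by rejection
    sampling, large nuclei first.  DAPI renders every nucleus plus a faint
    tissue background, RFP renders nuclei of traced cells, GFP renders
    membrane rings just outside progenitor nuclei.  Each channel is blurred
    by the optics PSF, then a linear background gradient and clipped
    Gaussian noise are added.
    """
    params = params or SceneParams()
    if condition not in ("virgin", "mated"):
        raise ValueError("condition must be 'virgin' or 'mated'")
    seed = params.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    size = params.field_size_px
    px = params.pixel_size_um

    means = dict(params.class_means)
    if condition == "mated":
        means["progenitor"] *= params.mated_progenitor_factor
        means["new_ec"] *= params.mated_new_factor
        means["new_eec"] *= params.mated_new_factor
    if params.deterministic_counts:
        counts = {cls: int(round(m)) for cls, m in means.items()}
    else:
        counts = {cls: int(rng.poisson(m)) for cls, m in means.items()}

    band_half = int(round(size * params.gut_band_fraction / 2))
    centre_row = size // 2
    gut_mask = np.zeros((size, size), dtype=bool)
    gut_mask[centre_row - band_half : centre_row + band_half, :] = True

    # radii first (polyploid before diploid eases hard-core packing)
    queue: list[tuple[str, float]] = []
    for cls in ("preexisting_ec", "new_ec"):
        mu, sd = params.polyploid_radius_um
        for _ in range(counts[cls]):
            queue.append((cls, max(float(rng.normal(mu, sd)), 0.5)))
    for cls in ("preexisting_diploid", "progenitor", "new_eec"):
        mu, sd = params.diploid_radius_um
        for _ in range(counts[cls]):
            queue.append((cls, max(float(rng.normal(mu, sd)), 0.5)))

    cells: list[CellTruth] = []
    placed_rc: list[tuple[float, float]] = []
    placed_r_px: list[float] = []
    for cls, radius_um in queue:
        r_px = radius_um / px
        lo_row = centre_row - band_half + r_px + 1
        hi_row = centre_row + band_half - r_px - 1
        for attempt in range(params.max_placement_attempts):
            row = rng.uniform(lo_row, hi_row)
            col = rng.uniform(r_px + 1, size - r_px - 1)
            ok = True
            for (pr, pc), prad in zip(placed_rc, placed_r_px):
                if (row - pr) ** 2 + (col - pc) ** 2 < (
                    r_px + prad + params.min_gap_px
                ) ** 2:
                    ok = False
                    break
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place a {cls} nucleus after "
                f"{params.max_placement_attempts} attempts "
                f"({len(placed_rc)} placed); lower the class means or enlarge the field"
            )
        placed_rc.append((row, col))
        placed_r_px.append(r_px)
        ploidy, rfp_pos, gfp_pos, _ = CLASS_DEFS[cls]
        cells.append(
            CellTruth(
                centre=(row, col),
                radius_um=radius_um,
                ploidy=ploidy,
                lineage=cls,
                rfp_pos=rfp_pos,
                gfp_pos=gfp_pos,
            )
        )

    dapi = np.zeros((size, size))
    rfp = np.zeros((size, size))
    gfp = np.zeros((size, size))
    for c in cells:
        r_px = c.radius_um / px
        _render_disk(dapi, c.centre, r_px, params.dapi_amplitude[c.ploidy])
        if c.rfp_pos:
            _render_disk(rfp, c.centre, r_px, params.rfp_amplitude)
        if c.gfp_pos:
            _render_ring(
                gfp, c.centre, r_px + 1, params.gfp_ring_width_px, params.gfp_amplitude
            )
    dapi = np.where(gut_mask, np.maximum(dapi, params.tissue_background), dapi)

    gradient = params.background_gradient * np.linspace(0, 1, size)[None, :]
    channels = {}
    for name, raw, amp in (
        ("DAPI", dapi, max(params.dapi_amplitude.values())),
        ("RFP", rfp, params.rfp_amplitude),
        ("GFP", gfp, params.gfp_amplitude),
    ):
        img = ndi.gaussian_filter(raw, params.psf_sigma_px) if params.psf_sigma_px else raw
        img = img + gradient
        if params.noise_sd_fraction > 0:
            img = img + rng.normal(0, params.noise_sd_fraction * amp, img.shape)
        channels[name] = np.clip(img, 0, None)[None, ...]

    stack = ChannelStack(
        channels,
        pixel_size_um=px,
        metadata={"condition": condition, "seed": str(seed), "generator": "gutquant.synth"},
    )
    scene = GroundTruthScene(
        cells=cells, gut_mask=gut_mask, params=params, condition=condition, seed=seed
    )
    scene.validate()
    return scene, stack


# ---------------------------------------------------------------------------
# evaluation helpers: match segmented records to truth cells and score classes
# ---------------------------------------------------------------------------


def match_records(
    scene: GroundTruthScene,
    records: Sequence[NucleusRecord],
    max_dist_um: float = 4.0,
) -> list[tuple[Optional[int], Optional[int]]]:
    """Greedy nearest-centroid matching of truth cells to segmented records.

    Returns (truth index, record index) pairs; unmatched truth cells appear
    as ``(i, None)`` and unmatched records as ``(None, j)``.
    """
    px = scene.params.pixel_size_um
    if not records:
        return [(i, None) for i in range(len(scene.cells))]
    t_xy = np.array([c.centre for c in scene.cells])
    r_xy = np.array([r.centroid for r in records])
    d = np.linalg.norm(t_xy[:, None, :] - r_xy[None, :, :], axis=2) * px
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    used_t: set[int] = set()
    used_r: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ti, ri in order:
        if d[ti, ri] > max_dist_um:
            break
        if ti in used_t or ri in used_r:
            continue
        used_t.add(int(ti))
        used_r.add(int(ri))
        pairs.append((int(ti), int(ri)))
    pairs.extend((i, None) for i in range(len(scene.cells)) if i not in used_t)
    pairs.extend((None, j) for j in range(len(records)) if j not in used_r)
    return pairs


def class_f1_scores(
    scene: GroundTruthScene,
    records: Sequence[NucleusRecord],
    max_dist_um: float = 4.0,
) -> dict[str, dict[str, float]]:
    """Per-cell-class precision/recall/F1 of the segmentation+classification.

    A matched pair counts as a true positive of a class only when the truth
    and the assigned class agree; unmatched truth cells are false negatives
    of their class, unmatched records false positives of theirs.  Returns
    per class ``{"tp", "fp", "fn", "precision", "recall", "f1"}``.
    """
    counts = {cls: {"tp": 0, "fp": 0, "fn": 0} for cls in ("progenitor", "new_progeny", "preexisting")}
    for ti, ri in match_records(scene, records, max_dist_um):
        truth_cls = scene.cells[ti].cell_class if ti is not None else None
        pred_cls = records[ri].cell_class if ri is not None else None
        if truth_cls is not None and pred_cls == truth_cls:
            counts[truth_cls]["tp"] += 1
        else:
            if truth_cls is not None:
                counts[truth_cls]["fn"] += 1
            if pred_cls is not None:
                counts[pred_cls]["fp"] += 1
    out: dict[str, dict[str, float]] = {}
    for cls, c in counts.items():
        tp, fp, fn = c["tp"], c["fp"], c["fn"]
        prec = tp / (tp + fp) if tp + fp else 1.0
        rec = tp / (tp + fn) if tp + fn else 1.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[cls] = {**c, "precision": prec, "recall": rec, "f1": f1}
    return out


# ---------------------------------------------------------------------------
# non-image generators
# ---------------------------------------------------------------------------


def generate_oro_image(
    droplet_fraction: float,
    droplet_rg_delta: float = 100.0,
    size: tuple[int, int] = (256, 256),
    grey_level: float = 80.0,
    droplet_radius_px: tuple[float, float] = (4.0, 9.0),
    seed: int = 0,
) -> tuple[RGBImage, dict]:
    """Grey bright-field image with red circular lipid droplets.

    Droplets (R = grey + delta, G = B = grey) are placed uniformly (overlap
    allowed) until the covered fraction reaches ``droplet_fraction``.  The
    truth dict records the exact realised coverage and the per-pixel R-G
    delta, so the expected channel-subtraction score is
    ``coverage * droplet_rg_delta``.
    """
    if not (0 <= droplet_fraction <= 1):
        raise ValueError("droplet_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, cols = size
    covered = np.zeros(size, dtype=bool)
    if droplet_fraction >= 1.0:
        covered[:] = True
    else:
        target = droplet_fraction * covered.size
        guard = 0
        while covered.sum() < target and guard < 100000:
            guard += 1
            r = rng.uniform(*droplet_radius_px)
            cr = rng.uniform(0, rows - 1)
            cc = rng.uniform(0, cols - 1)
            rr, ccg = np.meshgrid(
                np.arange(max(int(cr - r) - 1, 0), min(int(cr + r) + 2, rows)),
                np.arange(max(int(cc - r) - 1, 0), min(int(cc + r) + 2, cols)),
                indexing="ij",
            )
            disk = (rr - cr) ** 2 + (ccg - cc) ** 2 <= r**2
            covered[rr[disk], ccg[disk]] = True
    coverage = float(covered.mean())
    base = np.full(size, grey_level)
    arr = np.stack(
        [base + droplet_rg_delta * covered, base, base], axis=-1
    )
    truth = {
        "coverage": coverage,
        "rg_delta": float(droplet_rg_delta),
        "expected_score": coverage * float(droplet_rg_delta),
        "droplet_mask": covered,
        "seed": seed,
    }
    return RGBImage.from_array(arr), truth


def generate_spectrum(
    peaks: Sequence[tuple[float, float]],
    fwhm_th: float = 0.04,
    noise_sd: float = 0.0,
    mz_range: tuple[float, float] = (60.0, 1000.0),
    step: float = 0.01,
    seed: int = 0,
) -> MassSpectrum:
    """Sum of Gaussian peaks on a uniform m/z grid plus clipped noise.

    The default FWHM of 0.04 Th mimics a resolving power of ~6000 at
    m/z 250.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = mz_range
    for mz, _ in peaks:
        if not (lo <= mz <= hi):
            raise ValueError(f"peak at {mz} outside range {mz_range}")
    rng = np.random.default_rng(seed)
    grid = np.arange(lo, hi + step / 2, step)
    intensity = np.zeros_like(grid)
    sigma = fwhm_th / (2 * np.sqrt(2 * np.log(2)))
    for mz, amp in peaks:
        window = np.abs(grid - mz) < 6 * sigma
        intensity[window] += amp * np.exp(-((grid[window] - mz) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        intensity = np.clip(intensity + rng.normal(0, noise_sd, grid.shape), 0, None)
    return MassSpectrum(grid, intensity)


def generate_ct_table(
    fold_changes: dict[str, float],
    ct_base: float = 25.0,
    housekeeping_ct: float = 20.0,
    sd: float = 0.2,
    n_batches: int = 6,
    n_replicates: int = 3,
    housekeeping_gene: str = "rp49",
    seed: int = 0,
) -> CtTable:
    """Ct table under multiplicative fold-change models.

    Per gene, the mated ΔCt is shifted by -log2(fold) relative to virgin;
    the housekeeping gene has the same expected Ct in both conditions.
    ``sd`` is the technical noise per replicate Ct.
    """
    if any(f <= 0 for f in fold_changes.values()):
        raise ValueError("fold changes must be positive")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for batch in range(n_batches):
        for condition in ("virgin", "mated"):
            sample = f"b{batch}_{condition}"
            for rep in range(n_replicates):
                rows.append(
                    {
                        "gene": housekeeping_gene,
                        "sample_id": sample,
                        "condition": condition,
                        "batch_id": f"b{batch}",
                        "ct": housekeeping_ct + rng.normal(0, sd),
                    }
                )
            for gene, fold in fold_changes.items():
                shift = -np.log2(fold) if condition == "mated" else 0.0
                for rep in range(n_replicates):
                    rows.append(
                        {
                            "gene": gene,
                            "sample_id": sample,
                            "condition": condition,
                            "batch_id": f"b{batch}",
                            "ct": ct_base + shift + rng.normal(0, sd),
                        }
                    )
    return CtTable(pd.DataFrame(rows), housekeeping_gene=housekeeping_gene)


def generate_counts(
    group_means: dict[str, float],
    dispersion: float = 2.0,
    n_per_group: int = 30,
    seed: int = 0,
) -> CountData:
    """Negative-binomially distributed per-gut counts.

    ``dispersion`` is theta in the var = mu + mu^2/theta parameterisation;
    large theta approaches Poisson.
    """
    if any(m <= 0 for m in group_means.values()):
        raise ValueError("group means must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, mu in group_means.items():
        p = dispersion / (dispersion + mu)
        draws = rng.negative_binomial(dispersion, p, size=n_per_group)
        for i, c in enumerate(draws):
            rows.append({"unit_id": f"{group}_{i}", "group": group, "count": int(c)})
    return CountData(pd.DataFrame(rows))


def generate_hatch_table(
    groups: dict[str, tuple[int, float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-vial fecundity table: ``groups`` maps a group name to
    (n_vials, mean eggs laid, hatch probability).  Eggs laid are Poisson,
    hatched eggs binomial."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, (n_vials, mean_laid, p_hatch) in groups.items():
        if not (0 <= p_hatch <= 1):
            raise ValueError("hatch probability must be in [0, 1]")
        laid = rng.poisson(mean_laid, size=n_vials)
        hatched = rng.binomial(laid, p_hatch)
        for i in range(n_vials):
            rows.append(
                {
                    "vial_id": f"{group}_{i}",
                    "group": group,
                    "eggs_laid": int(laid[i]),
                    "eggs_hatched": int(hatched[i]),
                }
            )
    return pd.DataFrame(rows)
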