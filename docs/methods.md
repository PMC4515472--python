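# Methods

This note documents the models, defaults and numerical choices behind
`gutquant`, and what the synthetic benchmarks do and do not establish about
real data.

## Image conventions

Coordinates are `(row, col)`, 0-based, pixel-centre semantics; pixel size is
isotropic in µm/pixel; areas are `pixel count × pixel_size_um²`. Rendered
and level-adjusted intensities use a nominal full scale of 1.0. Level
adjustment defaults to the (1, 99) percentile window (robust to hot pixels);
noise filtering defaults to a radius-1 median filter, which removes salt
noise without eroding nucleus edges. Both are knobs, not inferences: the
upstream acquisition protocol they mimic specifies the operations but not
their parameters.

ROI polygons are validated with shapely (simple, non-zero area) and
rasterised by pixel-centre containment with boundary pixels included; the
rasterised area converges to the shoelace area with resolution (checked at
two scales in the tests).

## Tissue detection and nucleus segmentation

The gut occupies part of the frame; it is located from the DAPI channel as
the largest connected low-frequency foreground region. Because nuclei are
much brighter than the tissue floor, a naive threshold of the blurred image
separates nuclei from tissue instead of tissue from background. The
implementation therefore saturates the image first: one Otsu split isolates
the bright nuclei, a second Otsu on the remainder finds the tissue-floor
level, and the image is capped there before Gaussian blurring (default
sigma 8 px) and the final Otsu threshold. Holes are filled and the largest
connected component returned. On synthetic bands this recovers the true
mask with IoU ≥ 0.95 at both zero and 10 % noise.

Nuclei are segmented from the smoothed DAPI projection (sigma 1 px) by Otsu
or fixed threshold, optionally watershed-split from distance-transform
maxima (peaks closer than roughly one small-nucleus radius are merged so
single convex nuclei are not over-split), and filtered at a minimum area of
6 µm² (well below the smallest plausible diploid nucleus of ~20 µm²).

## Ploidy and lineage classes

Midgut nucleus areas are strongly bimodal: diploid progenitors and
enteroendocrine cells versus polyploid enterocytes. The default ploidy
threshold is automatic: the exact two-class split of log-areas minimising
within-class variance, with the threshold placed at the midpoint of the two
class means. The midpoint rule matters — a binned histogram threshold can
land inside the tail of the diploid cluster, whereas the midpoint falls in
the gap between the modes. Auto mode requires ≥ 4 nuclei; below that a
fixed threshold must be supplied.

RFP (nuclear histone marker) positivity uses mask overlap by default: a
nucleus is RFP⁺ when ≥ 50 % of its pixels fall inside the Otsu-thresholded
RFP mask. GFP is a membrane marker, so nuclear overlap is meaningless;
instead the mean GFP inside a 3-px annulus dilated around each nucleus is
compared to the Otsu threshold of the GFP plane. On synthetic scenes the
annulus means separate cleanly (positives ≥ 0.6 of ring amplitude,
negatives — including leakage from adjacent membrane rings — ≤ 0.22, Otsu
≈ 0.35), and the scale of the threshold is exposed as a parameter for dimmer
real-world membrane signal.

Classes follow the dual-marker logic: GFP⁺RFP⁺ → progenitor, GFP⁻RFP⁺ →
new progeny, RFP⁻ → pre-existing. GFP⁺RFP⁻ nuclei are biologically
impossible under the tracing system and diagnose segmentation failure; they
are counted and reported (`n_anomalous_gfp_only`), never reassigned. Gut
diameter is measured on the detected tissue mask along the central image
column (configurable to horizontal), reproducing the manual line-tool
measurement deterministically.

## Lipid quantification

Oil Red O: per pixel `s = max(R − G, 0)`, averaged over the ROI. Clipping
at zero means achromatic offsets cancel exactly and green/blue artefacts
cannot produce negative lipid signal; the score is invariant to adding a
constant to all three channels and monotone in droplet coverage. An
optional minimum-particle-area filter (off by default) mimics
particle-analysis pre-filtering whose use upstream is ambiguous.

TLC densitometry: lanes are column-summed into row profiles; each band
window is integrated above a linear baseline interpolated between the
medians of the first/last few rows of the window (so a constant pedestal
cancels exactly); negative integrals clip to zero. Lane normalisation to a
loading control is left to the caller, since it happens upstream per
sample. A Gaussian band of amplitude A and width s integrates to
`lane_width · A · s · √(2π)` within 2 %.

## DART-MS quantification

Signature ions are computed from monoisotopic atomic masses (CODATA/AME
values embedded as constants) plus the proton mass: [M+H]⁺, and
[M−H₂O+H]⁺ for the water-loss channel used for JH III because its parent
ion suffers interference. The protonated/water-loss difference equals the
monoisotopic water mass (18.0106) for every oxygen-bearing formula, which
is asserted as a property test.

Peak abundance is the window **maximum** within ±0.05 Th (a resolving power
of ~6000 at m/z 250 gives ≈ 0.04 Th FWHM), robust to window width, not an
integral. Calibration is ordinary least squares with free intercept
(forcing the origin is not assumed); amounts below the intercept clip to
zero with a below-LOD flag. Replicates are averaged on the intensity scale
before inversion; for a linear curve this equals inverting per replicate
and averaging amounts.

## Statistics

* Comparative Ct: technical replicates are averaged per (sample, gene)
  before ΔCt; ΔCt = Ct_gene − Ct_housekeeping per sample;
  ΔΔCt = mean ΔCt(mated) − mean ΔCt(virgin) per batch; fold = 2^(−ΔΔCt).
  No amplification-efficiency correction (plain 2^−ΔΔCt model). Fold
  changes are invariant to per-sample additive Ct shifts.
* Counts: negative-binomial GLM, log link, variance μ + μ²/θ. θ is
  estimated by maximum likelihood on the full (group) model and held fixed
  for the intercept-only null, mirroring the standard `glm.nb` + LRT
  workflow; the group term is tested by 2·Δllf against χ²(groups − 1).
  Monte-Carlo calibration: the type-I error at α = 0.05 over 1000 null
  simulations (two groups, mean 5, θ = 2, n = 50/group) lies in
  [0.03, 0.07]. A moments-based θ fallback (flagged in the result) covers
  ML non-convergence.
* Welch t with Satterthwaite df for measurements; paired t (one- or
  two-tailed) on within-batch ΔCt differences, with zero-variance inputs
  flagged rather than raised.
* Mann–Whitney: exact two-sided p by full enumeration of group assignments
  when combined n ≤ 12 — enumeration handles ties naturally through
  mid-ranks, which off-the-shelf exact implementations do not — otherwise
  the tie- and continuity-corrected normal approximation.
* Holm: step-down adjustment of one explicitly declared family; the tool
  never guesses family membership because comparison families are a design
  choice of the analysis, not of the data.

## Synthetic data: what it emulates, and what it does not

Scene defaults describe a realistic 20×-objective field: 512 px at
0.5 µm/px, a horizontal tissue band covering 60 % of the frame, diploid
nuclei of radius 2.5 ± 0.25 µm and polyploid 6.0 ± 0.6 µm, PSF sigma 1 px,
additive Gaussian noise at 10 % of signal amplitude, a 3 % linear
background gradient, and a tissue background floor of 0.12 (the faint
staining by which real tissue outlines are found). Virgin composition per
field is 60 pre-existing ECs, 25 pre-existing diploid cells, 12
progenitors, 4 new ECs and 2 new enteroendocrine cells (Poisson-drawn;
`deterministic_counts` rounds instead for fixtures); mating multiplies
new-progeny means ×3 and progenitor means ×1.5. These compositions are
declared knobs chosen to be realistic — absolute per-field counts are not a
claim about any particular dataset. Placement is hard-core (no nucleus
overlap, 1-px minimum gap), so the watershed splitter is exercised only by
dedicated touching-disk fixtures.

Consequences for interpretation: passing the closed-loop benchmarks shows
the pipeline is internally consistent and robust to the modelled noise
(Gaussian noise, gradient, blur, Poisson composition), not that it handles
everything real midguts produce — out-of-focus planes, touching and
deformed nuclei at high density, autofluorescence, uneven staining or
folded tissue. The per-class F1 ≥ 0.95 guarantee is with respect to this
generative model.

Problem sizes used by the benchmark suite: exact recovery on 4 zero-noise
scenes; pooled per-class F1 over 20 scenes at 10 % noise; virgin/mated
discrimination over 100 meta-replicates of 10 scenes per condition,
NB-LRT at α = 0.05 (observed power ≥ 90 %); 1000 null simulations for
type-I calibration. Every generator draw flows from a single
`numpy.random.default_rng(seed)` per call, so all results are reproducible
bit-for-bit per seed.

## Known limitations

* 2-D only: stacks are maximum-projected; no 3-D segmentation,
  deconvolution or stitching, and no vendor confocal formats (TIFF + JSON
  sidecar only).
* No sub-classification of diploid cells (EEC vs progenitor) beyond the
  marker logic, and no midgut region segmentation.
* TLC lane/band positions are caller-supplied; there is no automatic lane
  detection.
* The Mann–Whitney exact path is exponential in combined n; the default
  switch to the normal approximation at n > 12 keeps it instant.
* Whether the original workflow counted GFP⁺ cells or GFP⁺ nuclei is
  ambiguous; the nucleus-annulus rule is this package's operationalisation
  of comparing membrane signal to the nuclear pattern.
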