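# gutquant

A tested, reusable quantification stack for studies of mating-induced
intestinal remodelling in adult *Drosophila*. After mating, the female
midgut grows: intestinal stem cells (ISCs) proliferate more, newly born
enterocytes (ECs) and enteroendocrine cells accumulate, and enterocyte lipid
metabolism is reprogrammed. `gutquant` implements the measurement side of
such a study end to end:

* **ReDDM lineage-tracing image quantification** (`gutquant.reddm`) — in the
  dual-marker tracing system, progenitors (ISCs + enteroblasts) express a
  membrane GFP and a persistent nuclear H2B::RFP; progeny born during the
  tracing window retain only the RFP. From a DAPI/GFP/RFP confocal stack the
  pipeline detects the tissue, segments nuclei, calls ploidy from nucleus
  size (polyploid ECs vs diploid cells), assigns each nucleus a lineage
  class (GFP⁺RFP⁺ progenitor, RFP-only new progeny, RFP⁻ pre-existing) and
  emits the per-gut report: total nuclei, ECs, RFP⁺, GFP⁺, new progeny,
  tissue area, nucleus density and gut diameter.
* **Lipid quantification** (`gutquant.lipids`) — Oil Red O scoring by
  per-pixel `max(R − G, 0)` channel subtraction (the grey background cancels
  exactly), and TLC band densitometry with linear baseline subtraction.
* **DART-MS juvenoid titres** (`gutquant.dartms`) — signature-ion m/z from
  molecular formulas and monoisotopic masses (JH III [M+H]⁺ 267.20 and
  [M−H₂O+H]⁺ 249.18; methylfarnesoate [M+H]⁺ 251.20; JH III bisepoxide
  [M+H]⁺ 283.19), windowed peak extraction, replicate averaging,
  haemolymph-weight normalisation and linear calibration inversion.
* **Statistics** (`gutquant.stats`) — comparative-Ct qPCR analysis
  (fold = 2^(−ΔΔCt) against *rp49*), negative-binomial GLM + likelihood-ratio
  tests for over-dispersed mitosis counts, Welch and paired t-tests, an
  exact (enumeration) Mann–Whitney test for small rank experiments, Holm
  correction of declared comparison families, and hatch-fraction summaries.
* **Synthetic ground truth** (`gutquant.synth`) — seeded generators for
  every input: midgut scenes with known cell classes (virgin vs mated
  compositions, the mated condition multiplying new progeny ×3 and
  progenitors ×1.5), Oil Red O images with known droplet coverage, DART
  spectra obeying a linear concentration–intensity law, Ct tables under
  multiplicative fold-change models, and negative-binomial count tables.
  Every analysis stage is benchmarked against these closed loops: at zero
  noise the pipeline must reproduce the programmed truth exactly.

## Worked example

```python
from gutquant.synth import SceneParams, generate_scene
from gutquant.reddm import quantify_gut

scene, stack = generate_scene(SceneParams(), condition="mated", seed=7)
records, report = quantify_gut(stack)
print(report.to_dict())
```

prints (noise at the default 10 % of signal amplitude):

```
{'n_total_nuclei': 129, 'n_ec': 78, 'n_rfp': 37, 'n_gfp': 15,
 'n_new_progeny': 22, 'gut_area_um2': 39019.75,
 'density_per_mm2': 3306.02, 'diameter_um': 152.5,
 'n_anomalous_gfp_only': 0}
```

which matches the scene's ground truth (129 nuclei, 78 ECs, 37 RFP⁺, 15
progenitors, 22 new progeny) exactly on every count field: this mated gut
carries 22 cells born during the tracing window, versus ~6 expected for a
virgin. The same objects drive the statistics layer:

```python
from gutquant.synth import generate_ct_table
from gutquant.stats import comparative_ct

table = generate_ct_table({"bgm": 2.0}, sd=0.2, n_batches=6, seed=7)
print(comparative_ct(table, "bgm").round(3))
```

```
batch_id  delta_ct_virgin  delta_ct_mated   ddct  fold
      b0            4.842           3.955 -0.888 1.851
      b1            4.983           4.253 -0.730 1.658
      b2            5.138           4.162 -0.976 1.967
      b3            4.986           3.948 -1.038 2.054
      b4            4.822           4.067 -0.755 1.688
      b5            4.878           3.809 -1.069 2.098
```

— six batches of a gene programmed at fold 2 with 0.2-cycle technical
noise recover per-batch folds scattered around 2, ready for a paired t-test
on the housekeeping-subtracted ΔCt values.

A `gutquant` console script exposes each stage
(`gutquant simulate scene`, `gutquant reddm quantify`, `gutquant lipid oro`,
`gutquant dartms quantify`, `gutquant stats qpcr`, ...); run
`gutquant --help` for the full tree.

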