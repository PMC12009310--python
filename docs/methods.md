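# Methods

## The analysis

`ciliascreen` re-implements, as a tested pipeline, the statistical core of a
multi-tier high-content screen for ciliogenesis modulators: cells in 96-well
plates are reverse-transfected with an siRNA that abolishes ciliogenesis,
treated with a library of compounds (or, in the reverse-genetics arm, with a
genome-wide siRNA library), imaged, and summarized per well as a cell count
and a count of ciliated cells. The screen's two phenotypes are **cell
number** (a cytotoxicity readout) and **cilia incidence**, the percentage of
cells bearing a single primary cilium.

Because the raw plate and image data behind the published screens are not
distributed, the pipeline is exercised end to end on a synthetic screen
generator whose structure and control effect sizes match the published
assay. The generator is first-class, tested code: every downstream claim
(calibration, recall, QC behaviour) is measured against its ground truth.

## Robust z-scores

Each well's phenotype x is scored against a pooled control distribution:

    z = (x − median(pool)) / (c · MAD(pool)),   MAD = median|xᵢ − median|

with c = 1.4826 by default so that the denominator is a consistent estimate
of a normal sd and control z's are N(0,1)-comparable; c = 1.0 reproduces the
unscaled convention. A zero-MAD pool raises a hard error carrying the batch
id — a zero-spread control set indicates an assay failure and the batch is
excluded, never patched with an epsilon.

**Pool membership and scope.** The default pool is the negative controls
(scrambled siRNA, an siRNA with no target in the assay genome, and mock
transfection); pooling over all cilia controls (negatives plus the
ciliogenesis-abolishing positives) is available as `pool="all_controls"`.
The default was chosen on statistical grounds: with the strong positives
(−9.8 to −17.1 incidence points) in the pool, the pool median falls between
the control classes and the MAD inflates roughly threefold, compressing all
z's — a +15-point effect then scores z ≈ 2.4 and is indistinguishable from
the cutoff. The published control z magnitudes are likewise only consistent
with a negative-control-scaled denominator. Pooling scope is per 4-plate
batch within each replicate (default, matching batch-wise processing) or per
experimental replicate; the scope is always explicit, never inferred.

Duplicated control wells (columns 1 and 12) are averaged into one record per
(condition, replicate, plate) before plate QC and hit calling. Applied
per-well, the ±2 negative-control window would fail ~1 − 0.954⁶ ≈ 25% of
plates by construction, since each of the six negative wells is marginally
N(0,1) under any self-normalized score.

## Screen quality

* **SSMD** between negative and positive controls is the method-of-moments
  estimate (mean(neg) − mean(pos)) / √(s²neg + s²pos) with sample (n−1)
  variances. Effect-size classes follow the standard banding on |SSMD|:
  ≥5 extremely strong, [3,5) very strong, [2,3) strong, [1,2) fairly
  strong, (0,1) moderate/weak, 0 no effect.
* **Replicate concordance** is the squared Pearson correlation of matched
  per-condition z's between the two experimental replicates. It is only
  meaningful when conditions genuinely differ; on a null screen it measures
  the noise floor (~0), so the quality experiment plants a heterogeneous
  library (per-condition incidence deltas ~ N(0, 4 points), clipped to ±20).
* **Plate QC**: a plate passes iff every positive control has z_cilia ≤ −2
  and every negative control has −2 ≤ z_cilia ≤ +2, with each violating
  record enumerated as a reason.

## Hit calling

* **Primary (drug) tier.** Per-batch cutoffs from the batch's negative
  controls: z_cilia_cutoff = median + 2, z_cell_cutoff = median − 2. A
  condition is a hit iff its mean z_cilia over all plates and both runs
  reaches the cutoff; it is excluded as cytotoxic iff z_cell ≤ z_cell_cutoff
  on strictly more than 2 of the batch's 4 plates. The source does not state
  how the two runs combine for the exclusion count; it is evaluated per run,
  and tripping it in either run excludes the condition.
* **Secondary/tertiary confirmation.** Hit iff z_cilia − z_cilia(matched
  same-knockdown vehicle control) ≥ 2 (secondary) or ≥ 1.5 (tertiary), and
  z_cell > −2; z_cell ≤ −2 excludes as cytotoxic.
* **Genome-screen re-analysis.** Candidate iff z_cilia ≥ +2 in *every*
  replicate, −2 ≤ z_cell ≤ +2 in every replicate, the siRNA pool targets all
  annotated transcripts, and a human orthologue exists. Annotation flags are
  explicit inputs; a surviving condition without flags is an error, never
  defaulted. The secondary genome tier calls hits on the across-replicate
  mean z_cilia ≥ 2.

All thresholds are encoded with the printed boundary semantics (inclusive ≥
and ≤, strictly "more than 2 of 4") and each has an exact boundary test.
Every non-hit carries machine-readable reason codes; conditions with missing
required z's are reported `not_evaluable`, separately from `not_hit`.

## The synthetic screen generator

Layout: 8 rows × 12 columns; 8 control roles, each duplicated once in
column 1 and once in column 12 (16 control wells), 80 test wells in columns
2–11. Batches are 4 plates sharing a condition layout; the default screen
has 2 experimental replicates. Test conditions are named `c<batch>_<row><col>`.

Generative model, per well:

* `cell_count ~ Poisson(Gamma(k, m/k))` — a negative binomial with mean
  m = baseline_cells × role/hit multiplier × plate factor and dispersion
  k (`cell_dispersion`). Overdispersion is universal in imaging cell
  counts; k = 50 gives a realistic ~15% CV at the default 2,000 cells.
* The plate factor is log-normal: exp(plate_sigma · N(0,1)) per plate,
  multiplied by a batch-level factor of the same scale so plates of a batch
  co-vary (default plate_sigma 0.05).
* `ciliated_count ~ Binomial(cell_count, p)` with
  logit(p) = logit(baseline_incidence + delta/100) + well_sigma · N(0,1),
  so probabilities stay in (0,1). A delta that pushes the target probability
  outside (0,1) is a configuration error naming the condition.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| baseline_incidence | 0.40 | synthetic choice; the source does not print the negative-control incidence |
| baseline_cells | 2000 | imaged cells per well at ~8000 seeded, 20× fields |
| cell_dispersion | 50 | ~15% CV in cell counts |
| plate_sigma | 0.05 | ±5% plate-to-plate cell yield |
| well_sigma | 0.08 | incidence noise sd ≈ 2 percentage points, placing the −9.8-point positive control ≈ 4.4 z units below negatives |
| control effects | plk1 ×0.216 cells; ift88 −9.8, mks1 −12.0, rpgrip1l −17.1 points | published magnitudes; the mks1 value is synthetic (none printed) |

One RNG stream is derived per (replicate, plate) from the master seed via
`SeedSequence`, so identical (config, seed) give byte-identical tables and
any plate can be regenerated independently.

What the generator emulates and what it does not: it reproduces the layout,
replication structure, control effect sizes, overdispersed counts and
plate/batch effects, but not spatial (edge/gradient) artifacts, pipetting
failures, segmentation errors, or condition-correlated cytotoxicity beyond
what is planted. Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under the stated noise model — not that
the pipeline is robust to every artifact of real plates (notably, no
spatial normalization such as B-scoring is implemented or needed here).

Printed control z magnitudes from the source (e.g. z_cell −57.36 for the
transfection control) cannot be reproduced because control MADs are not
published; the simulator's noise defaults are chosen for qualitative
plausibility and give the same ordering and sign structure.

## Phenotype quantifications

* **Basal-body docking**: a cell is docked iff the peak-intensity slice of
  the distal-appendage channel lies within 2 slices (1 µm at 0.5 µm
  spacing) of the apical-channel peak. Argmax ties take the lowest slice.
  Per-ROI profiles (not whole-image) are classified. All-zero channels are
  unclassifiable and excluded from rates; an all-unclassifiable set is an
  error with the count.
* **RAB8A trafficking**: per-ROI maximum over the z-stack, then the mean of
  per-ROI maxima as the image summary (the whole-image mean over all slices
  is also reported, the sentence describing the original measurement being
  ambiguous between the two).
* **SMO occupancy**: total SMO-positive area divided by cilia number —
  additive over fields of view; zero cilia yields NaN, not an exception.
* **Gabor fibre score**: a bank of `n_angles` = 8 quadrature Gabor kernels
  (envelope sd 2 px, wavelength 8 px, orientations uniform over [0, π)).
  The regional mean is subtracted from the image and the even kernels are
  DC-corrected, so a constant image scores exactly 0 and the response is
  offset-invariant; per pixel the quadrature magnitude is maximized over
  orientations, averaged over the mask, and divided by the mean regional
  intensity (`normalization="regional_intensity"`; `"none"` gives the raw,
  strictly offset-invariant response). Kernel support is truncated at 4
  envelope sds: the conventional 3-sd truncation makes the bank visibly
  anisotropic (≈5% score spread over orientations at 64×64; 4 sds gives
  ≈2%). The original analysis ran in proprietary software whose exact
  normalization is not public; this implementation is declared, not claimed
  identical.
* **Tubule area**: the printed ellipse formula πab is used literally, with
  a the longest axis and b the perpendicular axis treated as semi-axes
  (for full diameters the area would be πab/4).
* **Cyst counting**: surface anomalies are graded 0 (normal) to 3 (uneven
  cyst-like, broken borders); grades ≥ 2 count as cysts; the per-organoid
  mean divides by the number of distinct graded organoids.
* **Luciferase**: (firefly/Renilla) per well divided by the unstimulated
  vehicle-control ratio.
* **Dose-response**: per (genotype, compound, dose), the mean per-well
  robust z against the genotype's vehicle wells, plus the fold-change of
  mean incidence over the vehicle mean.

## Numerical and degenerate-input choices

* Zero-cell wells have undefined incidence: flagged NaN, excluded from z
  tables, logged by count.
* MAD = 0 or < 4 pool values: hard `DegenerateControlsError` with batch id.
* SSMD with both variances zero: error, unless the means are also equal
  (identical groups), which is exactly 0 / "no effect".
* R² needs ≥ 3 matched conditions and nonzero variance in both replicates.
* All operations are pure; the only randomness is the generator's, fully
  determined by the seed.

## Validation experiments (what the acceptance script recomputes)

* **Null calibration** (`null_calibration`): 48 batches × 2 replicates with
  no planted effects — 30,720 test wells. Reports the fraction of wells
  with |z_cilia| ≥ 2 (expected ≈ 4.6% for calibrated z's) and the plate-QC
  pass rate under the published control magnitudes. Both use per-replicate
  pooling (~1,150 negative wells per pool): the normal-approximation
  expectations assume a well-estimated MAD, and 24-well per-batch pools
  inflate both tail rates by ~50% through MAD estimation noise alone.
* **Planted recovery** (`planted_recovery`): 8 batches, 5% of the 640 test
  conditions planted — half clean +15-point activators, half the same with
  an 80% cell kill. Reports primary and primary→secondary recall of the
  clean activators, the cytotoxic exclusion rate, and the null
  false-positive rate (the 8-well mean z makes the upper-tail probability
  at the cutoff ≪ 1%).
* **Screen quality** (`screen_quality`): 4 batches with a heterogeneous
  library; reports SSMD and replicate R².

Problem sizes were chosen so each experiment finishes in seconds while the
binomial and MAD-estimation error bands stay well inside the asserted
ranges.
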