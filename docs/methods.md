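# Methods

`periscore` implements the quantitative core of a spatial immune-scoring
workflow for colorectal-cancer tissue microarrays (TMAs) stained with two
brightfield triple panels (PanCK/CD8/CD68 and PanCK/GZMB/CD163, each with
a haematoxylin counterstain). Because the tissue data such studies rest
on are typically access-restricted, the package pairs every analysis
stage with a synthetic cohort generator that carries full ground truth,
so all claims are tested against known answers rather than against a
fixed dataset.

## Stain unmixing

Brightfield transmission follows the Beer–Lambert law: per colour channel
`I_c = I0 · 10^(−OD_c)` with `OD = Σ_s a_s d_s`, where `d_s` is the
unit-norm RGB absorbance vector of stain `s` and `a_s ≥ 0` its
concentration. Four stains observed through three colour channels are
underdetermined, so concentrations are recovered per pixel by the
group-sparse program

    min_{a ≥ 0}  ½‖od − D a‖² + λ Σ_g ‖a_g‖ ,   one stain per group,

which, with singleton groups, is a non-negative lasso over the four
concentrations. Defaults: `λ = 0.1`; pixels with total OD below
`od_floor = 0.02` are treated as glass background and skipped.

The solver is cyclic coordinate descent, vectorised across pixels
(coordinate minimiser = soft-thresholded residual correlation clipped at
zero), stopping when the largest per-sweep coefficient change falls below
`1e-8` (at most 1,000 sweeps). At `λ = 0` the solution coincides with
non-negative least squares; the suite verifies this against
`scipy.optimize.nnls` on pixels of rendered cores to `< 1e-6`.

Whether deconvolution should operate on raw RGB or OD is a genuine
choice; this package works in OD space, where the mixing model is linear.

**Identifiability.** With `D ∈ R^{3×4}` the exact-fit solution set can be
a polytope, so not every 4-stain mixture is recoverable. Numerical
analysis of the default basis shows that all singleton supports, all
haematoxylin+chromogen pairs and the DAB+marker pairs are uniquely
recovered, while three-stain mixtures and fast-red+green pairs are not.
The generator therefore renders chromogens mutually exclusively per pixel
(marker discs clipped to the stroma; where the two marker chromogen discs
would overlap, the stronger wins). This mirrors how such panels are
designed in practice — markers expected not to colocalise are paired in
one staining precisely because co-deposited chromogens behave
non-linearly — and it is the condition under which the render→unmix
round-trip is exact (`< 1e-6` relative, measured `~5e-10`).

The stain vectors themselves are inputs, not contributions: haematoxylin
and DAB use the standard published brightfield vectors; fast red and
PermaGreen were measured from rendered reference patches. All are
configurable.

## Synthetic TMA cohort generator

The generator defines the study conditions; its defaults are fixed and
are not tuned per experiment.

* **Geometry.** A core is a disc of diameter 0.6 mm (primary-cohort
  style) or 1.0 mm (validation style), rasterised at `pixel_size`
  (default 0.25 µm/px; the test suite and acceptance script use 1–2 µm/px
  to keep runtimes in seconds — the model is scale-free apart from raster
  resolution). The tumour compartment is a thresholded smooth Gaussian
  random field (correlation length 50 µm) occupying `tumour_fraction`
  (default 0.3) of tissue in CT/FR cores, half of that in ME cores and
  none in NE cores, where a PanCK-positive normal epithelium of the same
  construction takes its geometric place.
* **Cells.** Stromal cells follow an inhomogeneous Poisson process:
  intensity `base_densities[marker]` (defaults 300 CD8, 150 GZMB,
  400 CD68, 350 CD163, 1000 double-negative per mm² — order-of-magnitude
  choices in the tens-to-thousands range reported for colorectal TMA
  stroma; the source study shows these distributions only graphically),
  multiplied by `proximity_enrichment[marker]` within 25 µm of the
  tumour. Counts are drawn per stratum (exact for piecewise-constant
  intensity), positions uniformly within stratum pixels. Tumour cells
  (1500/mm²) populate the tumour mask.
* **Rendering.** Nuclei are smooth plateau discs (`exp(−(r/4 µm)⁴)`) of
  haematoxylin; marker chromogens perinuclear discs of radius 5 µm; PanCK
  a uniform DAB concentration over the tumour/epithelium mask; plus a
  faint diffuse haematoxylin background (concentration 0.3) over all
  tissue, which is what makes automated tissue detection meaningful.
  Optional Gaussian noise is added on optical density. Rendering returns
  float RGB in [0, 255]; quantisation to 8-bit happens only when writing
  PNG, so noiseless renders are exactly invertible.
* **Outcomes.** Each patient carries a balanced latent low/high group.
  Survival is exponential with hazard
  `baseline_hazard · HR^{1{high}}` (defaults 0.02/month, HR 0.25);
  censoring is an independent exponential clock with rate
  `h·q/(1−q)` given the group (q = `censor_rate` = 0.2, so a fraction q
  of each group is censored in expectation — independence of the
  censoring and event times is what keeps the Cox estimate unbiased),
  with administrative censoring at 120 months. High
  patients receive proximity-enriched scenes; low patients do not, so the
  spatial signal and the survival signal are linked the way a prognostic
  biomarker links them. Clinical covariates are drawn at the marginal
  frequencies of the published cohorts (TNM I–IV 17.5/39.2/23.7/19.6%,
  pT4 16.2%, venous invasion 13.3%) and are independent of the latent
  group unless `confound_covariates` is set.

What the generator does **not** emulate: nuclear texture and pleomorphism,
staining gradients and edge artefacts, chromogen co-deposition, tissue
folds, non-exponential hazards. Passing tests therefore demonstrate
correctness of the computational pipeline under a clean, known model —
not robustness to real histology.

## Segmentation

All steps run on the unmixed 4-channel image with per-cohort manual
thresholds (`ThresholdSet`), mirroring practice where thresholds are
re-tuned per staining run:

* tissue: total concentration ≥ 0.05, morphological closing (5 µm disc),
  hole filling;
* tumour/stroma: PanCK (DAB) channel ≥ 0.25 within tissue, closing with a
  10 µm disc to merge gland profiles; stroma is the remainder;
* cells: Gaussian smoothing (σ 1 µm) of the haematoxylin channel,
  nucleus threshold 0.5, Euclidean distance transform, local maxima at
  ≥ 4 µm separation as markers, marker-controlled watershed; objects
  outside 6–250 µm² discarded;
* classification: compartment by nucleus centroid in the tumour mask (a
  common digital-pathology convention; the measurement disc below is this
  package's convention, chosen because cytoplasm-to-nucleus signal
  allocation for macrophage markers is genuinely ambiguous). Stromal
  cells are typed by mean chromogen concentration in a 3 µm disc around
  the centroid versus per-marker thresholds; double positives resolve to
  the larger threshold-normalised intensity; neither → double-negative;
* artefacts: deterministic rules replace a trained object classifier —
  objects saturated (OD ≥ 2) in ≥ 3 channels or with solidity < 0.5 are
  removed. The rules cover exactly the artefact modes the generator can
  plant; they are not a general artefact detector.

On noiseless rendered cores: tissue area within 0.5% of truth, tumour
mask Jaccard ≥ 0.99, stromal count recovery 94–97%, phenotype confusion
~3%.

## Proximity zones and densities

The tumour-proximity zone of radius r is the set of stromal pixels with
Euclidean distance to the nearest tumour pixel in (0, r]; zones are
cumulative discs (the natural reading of a TP25-versus-remaining-stroma
dichotomy), not annuli, with radii 10/25/50/100 µm plus the total stroma.
Distances are computed by exact Euclidean distance transform on the
raster; in NE cores distances are measured from the normal epithelium.
Zone areas intersect the stroma mask (whether published areas excluded
background within the dilation is unstated; intersecting is the choice
here). Cells are counted by half-open pixel membership of the nucleus
centroid, which makes raster counts equal brute-force point-to-mask
distance counts exactly.

Core-level QC admits a core when **more than** 10 stromal cells were
detected and the tumour occupies **more than** 1% of tissue (both
strict). Patient-level pooling is the area-weighted mean — pooled counts
over pooled areas — the unique convention under which pooling commutes
with merging cores. Patients with no included core for a stratum are
missing (treated as missing at random downstream).

## Scoring

Per cohort, region and radius stratum, each marker density is
dichotomised at the median of non-missing patients; *high* means strictly
above the median, so ties at the median are *low* (the only reading under
which "at least one below the median" is the exact complement of "both
above"). The combined GZMB/CD68 score is *high* iff both single-marker
groups are *high*. Ratio scores (GZMB:CD8, CD68:CD163) add +1 to
numerator and denominator, matching the +1 offset used for log
transforms; the CD68−CD163 difference is plain subtraction.

## Statistics

All tests two-sided at α = 0.05 with no multiplicity correction —
matching the analysis convention this package reproduces; with dozens of
association tests per cohort this inflates family-wise error, a caveat
any user should carry.

* **Association:** Pearson χ² with Yates continuity correction on 2×2
  tables (recomputing the five published 2×2 p-values — 0.036, 0.037,
  0.004, 0.006, 0.001 — matches the corrected statistic, not the
  uncorrected one, which pins the convention), uncorrected for larger
  tables; Fisher's exact test whenever any expected count is below 5.
  For r×c tables the exact two-sided p is the sum of probabilities of all
  fixed-margin tables no more probable than the observed one, by full
  enumeration (cross-checked against R's `fisher.test`); supports too
  large to enumerate fall back to Monte-Carlo over Patefield-sampled
  tables with the simulation error reported.
* **Densities:** log(x+1) transforms; paired t-test for near-versus-far
  comparisons; Pearson correlation on log values; pooled-variance t-test
  for parametric scale variables (age), Kruskal–Wallis for
  non-parametric ones.
* **Survival:** Kaplan–Meier (lifelines), median follow-up by reverse
  Kaplan–Meier, two-group log-rank. Cox proportional hazards is this
  package's own Newton–Raphson maximiser of the Efron partial likelihood
  (Breslow available), tolerance 1e-9, ≤ 50 iterations with step-halving,
  Wald CIs and p-values; covariates are centred for conditioning.
  Monotone likelihood and non-convergence are flagged, not raised. The
  implementation is cross-checked against lifelines and against
  R `survival::coxph` under both tie schemes, and the score test at β = 0
  equals the log-rank statistic on tie-free data.

### Calibration caveat

Exact and continuity-corrected tests on discrete tables are conservative
by construction, so their null rejection rate sits at or below 5% rather
than at it; the calibration checks assert ≈5% within binomial error for
the continuous tests and no anti-conservatism for the discrete ones.

## Problem sizes used in tests and the acceptance script

Rendered-core checks use 0.6 mm cores at 1–2 µm/px (single cores up to
600×600 px); the zone oracle uses 50 cores; survival recovery uses 50
replicate cohorts of n = 500 (Cox bias) and n = 200 (log-rank power);
type-I calibration uses 2,000 null cohorts of n = 100. These sizes give
Monte-Carlo error comfortably inside the asserted bounds while keeping
the whole suite in minutes.

## Known limitations

* The artefact filter only covers the two planted artefact modes.
* Stain vectors for fast red and PermaGreen are synthetic-reference
  measurements, not spectrophotometric calibrations.
* Cohort-level survival findings of the source setting (specific hazard
  ratios per region/zone) are not reproducible without the restricted
  patient data; the package instead demonstrates parameter recovery on
  simulated cohorts with known hazards.
* The Monte-Carlo Fisher fallback yields a stochastic p; its standard
  error is attached to the result.
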