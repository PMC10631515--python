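# Methods

This note documents the models, algorithms, and numerical choices behind
`rnflt`: what is computed, under which assumptions, and what the
synthetic-data results do and do not demonstrate.

## Problem setting

Spectral-domain OCT devices export peripapillary retinal nerve fiber
layer thickness (RNFLT) maps — dense grids of thickness values in µm
(200 × 200 over a 6 × 6 mm field in the Cirrus convention this package
defaults to, pixel pitch 0.03 mm). Automated layer segmentation fails
often enough to matter clinically; failed regions show up as physically
implausible thickness values. The package adopts the floor rule: a
pixel is an **artifact** iff its value is below 50 µm (the established
physiological floor of measurable RNFLT) and it lies outside the optic
disc. The **artifact ratio** (AR) of a map is the artifact area divided
by the non-disc map area. Quality classes follow the AR: **high**
(AR < 2%, usable as ground truth), **low** (AR > 5%, used as artifact
donors), intermediate otherwise. Boundary ARs of exactly 10% and 20%
are assigned to the `≤` stratum in stratified reporting, and the >20%
stratum is nested inside >10%.

Artifact values are flagged, never zeroed or pre-modified: downstream
code always sees the measured values plus a mask.

## Circle-scan geometry

The circumpapillary profile is sampled on the standard 3.46-mm-diameter
circle centered on the optic disc (disc-mask centroid; grid center when
no disc mask is given), by bilinear interpolation with pixel centers at
integer coordinates. 256 angular samples are taken in TSNIT order
(start temporal, sweep temporal → superior → nasal → inferior), the
conventional display order for these profiles. Neither the disc
delineation nor the angular sample count is standardized by device
vendors; both are configuration, with the defaults above. The default
disc mask is a filled circle of radius 0.8 mm (area ≈ 2 mm², a typical
optic-disc size).

## Synthetic data model

Clinical RNFLT maps and Humphrey visual-field (VF) exports are not
redistributable, so the package ships a generator that reproduces the
features the pipeline actually depends on. Each claim the test suite
makes should be read as "on data with these features", not as a
clinical result.

**Maps.** Thickness is a smooth background (70 µm) plus two arcuate
nerve-fiber bundles modeled as Gaussian ridges in polar coordinates
about the disc: radial profile peaked at 1.73 mm (σ = 0.85 mm), angular
humps at the superior and inferior poles (σ = 0.55 rad), peak amplitude
45 µm. A `severity` parameter in [0, 1] scales the bundles down,
emulating glaucomatous bundle loss; cohort severities are drawn from a
Beta(1.3, 1.8). I.i.d. Gaussian pixel noise (σ = 3 µm) is added, and
non-disc values are clipped to the 50 µm floor — so generated maps are
artifact-free by construction and classify as high quality. The disc
interior is filled with low "cup" values (~20 µm). This reproduces the
double-hump TSNIT profile and a realistic mean-thickness range
(~60–110 µm across severities). It does **not** model vessel shadows,
peripapillary atrophy, tilt, media opacity, or inter-eye asymmetries.

**Artifacts.** Segmentation failures are unions of random ellipses
(Gamma-distributed semi-axes, scale 0.55 mm) and, with probability 0.5
per shape, annular wedges crossing the scan circle — mimicking runs of
failed B-scans. Shapes accumulate until the target AR is reached, then
excess pixels are trimmed at random, so the achieved AR matches the
target to one pixel. Masked pixels are overwritten with values drawn
uniformly from 5–45 µm (all below the floor).

**VF series.** Exams are evenly spaced over the follow-up span; mean
deviation follows MD(t) = intercept + slope·t + ε with exam noise
σ = 0.5 dB by default, each of the 52 total deviations (TDs) follows
its own linear trend, and the visual field index (VFI) is an affine
function of MD (100% at 0 dB, slope 3.3 %/dB) clipped to [0, 100] — the
package treats VFI only as a progression endpoint, so an affine link
suffices. Reliability indices are drawn uniformly inside the passing
region; with probability 0.1 an exam is pushed past one cutoff, so
~90% of exams pass the filter and the filter is testable. Exam dates
are whole calendar days, which quantizes the time axis; trend tests
that sit exactly on a slope boundary use 4-year spacings (1461 days),
which are exact in floating point.

**Structure–function link.** Baseline MD is tied to the eye's mean
circle-scan thickness: MD = 0.2 dB/µm × (mean thickness − 95 µm) +
noise. The slope and pivot put MD at 0 dB for a healthy ~95 µm profile
and near −7 dB for a severely thinned one, a realistic glaucoma span.

## Pseudo-artifact supervision

Real artifacts have no ground truth, so training pairs are built by
transplantation: the artifact pattern of a low-quality donor map — its
mask **and** its sub-floor values, so the model sees realistic corrupted
intensities — is superimposed onto a high-quality map, whose untouched
values become the target. Patterns are rigidly jittered (shifts up to
20 px, rotations up to 15°, nearest-neighbor resampling) to decorrelate
artifact location from donor anatomy; pattern pixels landing on the
disc or outside the grid are dropped. One donor pattern (sampled
uniformly with replacement) is used per high-quality map. Train/test
splits are at patient level (70/30): all images of a patient fall on
one side.

## The correction network

The corrector is a model-based prior plus a learned refinement.

**Polar-harmonic prior.** Peripapillary thickness is, to first order,
a smooth function of polar position around the disc — the classic
double-hump pattern. Before the network runs, a low-order field
(angular Fourier harmonics k = 0…4 crossed with six Gaussian radial
bumps spanning 0.4–3.0 mm, plus a global offset; 63 coefficients) is
fitted by least squares to the clean (non-disc, non-artifact) pixels,
and its prediction fills the artifact region of the thickness channel.
This is classical normative-field smoothing; on the synthetic anatomy
it already recovers most of the structure, and the network learns
residual corrections on top of it. A map so heavily corrupted that
fewer clean pixels remain than coefficients falls back to a
mean-valued fill.

**Network.** A four-level convolutional encoder–decoder with skip
connections (widths c, 2c, 4c, 8c with c = 12 by default; one 3 × 3
conv + ReLU per block, average-pool downsampling, nearest-neighbor
upsampling). Inputs are the prior-filled map (scaled by 1/100), the
artifact mask, and three fixed conditioning channels (r/3 mm, sin θ,
cos θ about the disc center) — handing the network its polar position
makes the anatomy's organization directly learnable. Two auxiliary
heads sit on the globally pooled bottleneck: an L2-normalized embedding
for the contrastive term, and a global feature vector broadcast into
every decoder level, which carries map-wide state (overall bundle
loss) to pixels far from any clean context. The output head is a
1 × 1 convolution **blended through the mask channel**: off-artifact
pixels pass through exactly unchanged, and in the artifact region the
network output is a residual added to the prior fill. This makes the
identity mapping exact where data are measured and focuses all
gradient on inpainting.

The network and its backpropagation are implemented directly in numpy
(`rnflt._nn`), verified against central finite differences for every
parameter tensor; training uses Adam (learning rate 3 × 10⁻³, batch 8).

### Composite loss

    L_overall = L_correct + w_contrast · L_contrast + w_consistency · L_consistency

- **L_correct**: global L1 plus a mask-weighted term over the pseudo-
  artifact region (weight λ = 5). The mask term is squared-error by
  default: a pure L1 objective drives predictions toward the
  conditional median and systematically under-predicts the rare thick
  bundle peaks, which shows up as shrinkage (regression slope < 1) of
  predicted vs true thickness; the squared penalty keeps gradient on
  those large errors. An L1 mask term remains available
  (`LossConfig.mask_norm`).
- **L_contrast**: NT-Xent (temperature 0.5) on bottleneck embeddings of
  each map and a rigidly perturbed copy (shifts ≤ 6 px, rotations
  ≤ 10°, reflected boundaries); positives are map/perturbed-map pairs,
  negatives the rest of the batch. This regularizes the encoder toward
  acquisition-jitter-invariant features.
- **L_consistency**: first-two-moment matching — |Δmean| + |Δsd| of
  predicted vs input values over the clean (non-disc, non-artifact)
  region, keeping the corrected map distributionally faithful to the
  measured map.

The weights w_contrast = w_consistency = 0.1 are defaults exposed in
configuration, chosen so the auxiliary terms contribute visibly without
dominating the reconstruction term.

### Inference

`correct()` detects artifacts by the floor rule, runs the network, and
replaces only the detected region with network output clipped to
[floor, 500 µm]; a second pass therefore finds no sub-floor pixels and
changes nothing (idempotence). Full-map regeneration is available
behind a flag but off by default: measured pixels are data and are
preserved. Predictions are averaged over the identity and the two
mirror flips of the input (test-time augmentation), exploiting the
superior/inferior and nasal/temporal symmetry of the anatomy; this
assumes mirror-symmetric anatomy statistics, which holds for the
generator and approximately for real eyes (OD/OS mirroring). Maps
whose grid differs from the model resolution are bilinearly resampled
through the network and back; blending keeps off-artifact pixels exact
at native resolution regardless.

## Evaluation

Accuracy is measured in the pseudo-artifact region only: MAE and
Pearson r between corrected and target values, pooled across maps
within each AR stratum (pooling pixels matches reporting a single
scatter per stratum; per-map aggregates are emitted alongside for
diagnostics, since the two can differ). Circle-scan metrics restrict
to angular samples whose nearest pixel is masked — masks are
pixel-level while samples are continuous. Empty strata are reported as
absent, not zero; zero-variance regions flag r as undefined (NaN)
rather than fabricating a value. Both r and r² are reported.

## Clinical-utility harness

- **Reliability filter**: fixation loss ≤ 33%, false positives ≤ 20%,
  false negatives ≤ 20% (inclusive); missing indices fail the filter.
- **Pairing**: each map pairs with the nearest reliable VF exam within
  30 days; ties go to the earlier exam (the tie rule is a convention,
  not a claim).
- **Trend fits**: OLS of MD/VFI/each TD on years since first reliable
  exam, with a two-sided t-test on the slope — the standard reading of
  a "significant slope" criterion; numerically perfect fits get p = 0.
- **Progression criteria** (eligibility: ≥ 5 reliable exams spanning
  ≥ 4 years): (1) MD slope < 0 with p < 0.05; (2) ≥ 3 TD locations
  with slope ≤ −1 dB/yr and p < 0.05; (3) VFI slope < 0 with p < 0.05;
  (4) fast progression, MD slope ≤ −1 dB/yr with p < 0.05. All
  thresholds are applied with exactly the printed inequality
  directions.
- **Predictors**: linear regression (MD, TDs) and logistic regression
  (progression) on circle-scan profiles by default; the predictor slot
  accepts any scikit-learn-style estimator, so heavier map-level models
  can be plugged in without changing the harness.
- **Comparison**: patient-disjoint 3-fold cross-validation produces
  paired per-fold metrics (plus a paired t-test across folds), and a
  paired bootstrap over evaluation units (eyes; 1000 resamples by
  default) gives the difference, percentile CI, and two-sided p for
  raw vs corrected inputs. The bootstrap p is the studentized
  (bootstrap-t) test with the add-one correction
  (1 + #extreme)/(B + 1): second-order accurate, and noticeably better
  calibrated at small unit counts than the raw percentile rule (whose
  true level sits near 0.06 at 40 units). Both tools are provided;
  neither is claimed to be uniquely correct for fold-level inference.

## Problem sizes and defaults

The canonical desk-scale experiment uses 300 high-quality maps at
64 × 64 (pixel pitch 6/64 mm, preserving the 6 mm field), 60 donors
with target ARs drawn from 5–30%, one pseudo-artifact pair per map, a
70/30 patient split (210/90), and 10 training epochs — sizes chosen so
the full pipeline runs in minutes on one CPU while leaving all
qualitative behavior intact. Progression-label recovery uses 200
series per condition; bootstrap calibration uses 200 replicates of 40
units with 400 resamples.

## Known limitations

- The generator's anatomy is stylized; transfer of the trained network
  to clinical maps is untested here and would require retraining on
  real high-quality/low-quality map corpora.
- On the synthetic anatomy the polar-harmonic prior is a very strong
  baseline (the generator's field is itself smooth in polar
  coordinates), so the network's learned residual contributes little
  there; on real maps with vessels, atrophy, and local defects the
  division of labor would shift toward the network.
- Inpainting accuracy is bounded by the generator's pixel noise
  (σ = 3 µm): even a perfect structural prediction reaches r ≈ 0.95
  against noisy targets on this data.
- The correction model cannot attribute artifacts to a cause
  (vitreous opacity, epiretinal membrane, ...); it only repairs
  sub-floor regions.
- Severity is partially unidentifiable when artifacts cover both
  bundles; predictions there regress toward the cohort mean.
- VFI is simulated as an affine function of MD, adequate for testing
  the progression endpoint logic but not a perimetric model.
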