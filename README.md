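# rnflt

Artifact detection and inpainting for peripapillary retinal nerve fiber
layer thickness (RNFLT) maps, with a clinical-utility harness for
visual-field (VF) prediction and glaucoma progression forecasting.

## The problem

OCT-derived RNFLT maps are the primary structural measurement in
glaucoma care, but automated layer segmentation fails often; failed
regions report physically impossible thickness. `rnflt` treats any
non-disc pixel below the 50 µm physiological floor as a
segmentation-failure artifact, quantifies map quality by the **artifact
ratio** (AR = artifact area / non-disc map area), and repairs artifact
regions with a learned inpainting model so that downstream structural
measures — the full map and the circumpapillary circle scan — remain
usable.

Because true thickness under an artifact is unknown, supervision is
built by **pseudo-artifact transplantation**: artifact patterns (masks
*and* their sub-floor values) sampled from low-quality maps (AR > 5%)
are superimposed onto high-quality maps (AR < 2%), whose untouched
values are the reconstruction target. The correction model is a small
convolutional encoder–decoder with skip connections trained with a
composite objective

    L_overall = L_correct + w_contrast · L_contrast + w_consistency · L_consistency

combining masked reconstruction error, a contrastive (NT-Xent) term
that makes encoder features invariant to rigid acquisition jitter, and
a first-two-moment consistency term that keeps corrected maps
distributionally faithful to the measured ones. At inference only the
detected artifact region is replaced (floor-clipped), so measured
pixels are never altered and correction is idempotent.

The clinical-utility harness implements the standard trend-based VF
machinery: reliability filtering (FL ≤ 33%, FP ≤ 20%, FN ≤ 20%),
OCT–VF pairing within 30 days, OLS slopes with two-sided t-tests, four
progression criteria (MD slope < 0; ≥ 3 TD locations ≤ −1 dB/yr; VFI
slope < 0; MD fast ≤ −1 dB/yr — each with p < 0.05), patient-disjoint
3-fold cross-validation, and a paired bootstrap over eyes for
raw-vs-corrected comparisons.

Everything runs on synthetic cohorts generated by the package itself
(arcuate-bundle anatomy, segmentation-failure artifacts, linked VF
series), so the full pipeline is testable without clinical data. See
`docs/methods.md` for models, assumptions, and limitations.

## Worked example

```python
from rnflt import (
    MapModelParams, ArtifactModelParams, generate_rnflt_map,
    generate_segmentation_failure, compute_artifact_mask,
    compute_artifact_ratio, classify_quality,
)

params = MapModelParams(shape=(64, 64), pixel_pitch=6 / 64,
                        severity=0.3, seed=1)
clean, disc = generate_rnflt_map(params)
low = generate_segmentation_failure(
    clean, disc, ArtifactModelParams(target_ar=0.15, seed=2))
ar = compute_artifact_ratio(compute_artifact_mask(low, disc), disc)
print(f"AR = {ar:.3f} -> {classify_quality(ar)}")
```

prints

```
AR = 0.150 -> low
```

— the corrupted map has 15.0% of its non-disc area below the floor,
classifying it as a low-quality (artifact-donor) map.

The full benchmark — generate 300 maps and 60 donors, transplant
pseudo-artifacts, split 70/30 by patient, train, evaluate held-out —
is one call:

```python
from rnflt.workflows import inpainting_experiment

res = inpainting_experiment(n_maps=300, n_donors=60, epochs=10,
                            base_channels=12, learning_rate=3e-3, seed=7)
print(f"input  MAE {res['input_metrics'].mae:.1f} um")
print(f"output MAE {res['corrected_metrics'].mae:.1f} um, "
      f"r = {res['corrected_metrics'].pearson_r:.2f}")
```

prints (a few minutes on one CPU)

```
input  MAE 51.7 um
output MAE 2.4 um, r = 0.94
```

— on held-out maps the artifact regions, which start ~52 µm away from
the truth, are reconstructed to within ~2.5 µm on average, and the
reconstructed values track the true thickness with Pearson r ≈ 0.94
(the generator's 3 µm pixel noise caps attainable r near 0.95).

A command-line interface mirrors the pipeline stages
(`rnflt simulate | corrupt | train | correct | evaluate |
label-progression | predict-vf | compare`); every stage writes a run
log with its config snapshot and seeds.

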