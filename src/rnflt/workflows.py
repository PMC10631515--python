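"""End-to-end experiment recipes tying the modules together.

Each function here is a seeded, desk-scale pipeline used by the CLI,
the test suite, and the reproduction script:

* :func:`build_training_pairs` — donor patterns -> pseudo-artifact pairs.
* :func:`inpainting_experiment` — generate maps and donors, corrupt,
  split at patient level, train the correction net, and report
  artifact-region accuracy (corrected vs corrupted baseline).
* :func:`structure_function_experiment` — held-out R^2 of circle-scan
  linear regression for MD under increasing structure-function noise.
* :func:`raw_vs_corrected_experiment` — the clinical comparison: corrupt
  cohort maps with native-style artifacts, correct them, and compare MD
  prediction from raw vs corrected circle scans (patient-level CV plus
  paired bootstrap).
* :func:`progression_label_recovery` — how often trend labels computed
  from noisy series match the noiseless truth.
* :func:`bootstrap_null_calibration` — type-I error of the paired
  bootstrap under a simulated null.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .clinical import bootstrap_compare, crossval_compare, patient_folds
from .evaluation import _region_metrics_from_values, stratified_report
from .maps import CircleGeometry, DiscMask, RNFLTMap, extract_circle_scan
from .model import CorrectionNet, ModelConfig, TrainConfig, correct, train
from .pseudo import (
    ArtifactPattern,
    TrainingPair,
    extract_pattern,
    patient_level_split,
    random_superimpose,
)
from .synthetic import (
    ArtifactModelParams,
    Cohort,
    MapModelParams,
    StructureFunctionLink,
    VFSimParams,
    generate_cohort,
    generate_rnflt_map,
    generate_segmentation_failure,
    generate_vf_series,
)
from .vf import label_progression


def build_training_pairs(
    high_maps: Sequence[tuple[RNFLTMap, DiscMask]],
    patterns: Sequence[ArtifactPattern],
    seed: int = 0,
    max_shift_px: int = 20,
    max_rotation_deg: float = 15.0,
) -> list[TrainingPair]:
    """One pseudo-artifact pair per high-quality map.

    Donor patterns are sampled uniformly with replacement; each is
    rigidly jittered before superimposition so pattern location is
    decorrelated from donor anatomy.
    """
    if not patterns:
        raise ValueError("need at least one donor pattern")
    rng = np.random.default_rng(seed)
    pairs = []
    for m, disc in high_maps:
        pattern = patterns[int(rng.integers(len(patterns)))]
        pairs.append(
            random_superimpose(
                m, pattern, disc, seed=int(rng.integers(2**31)),
                max_shift_px=max_shift_px, max_rotation_deg=max_rotation_deg,
            )
        )
    return pairs


def inpainting_experiment(
    n_maps: int = 300,
    n_donors: int = 60,
    resolution: int = 64,
    donor_ar_range: tuple[float, float] = (0.05, 0.30),
    epochs: int = 8,
    base_channels: int = 8,
    learning_rate: float = 2e-3,
    batch_size: int = 8,
    pairs_per_map: int = 1,
    seed: int = 0,
    severity_range: tuple[float, float] = (0.0, 1.0),
) -> dict:
    """Full pseudo-artifact inpainting benchmark on synthetic maps.

    Generates ``n_maps`` high-quality maps (one per synthetic patient)
    and corrupts ``n_donors`` of them into low-quality donors with
    target ARs drawn from ``donor_ar_range``; splits patients 70/30,
    builds ``pairs_per_map`` pseudo-artifact pairs per training map
    (one by default; more diversifies the supervision) and one held-out
    pair per test map, trains the correction network, and evaluates on
    the held-out pairs.

    Returns a dict with the trained model, training history, the
    stratified accuracy report, and pooled artifact-region metrics for
    both the corrupted inputs (baseline) and the corrected outputs.
    """
    rng = np.random.default_rng(seed)
    pitch = 6.0 / resolution      # keep the 6 mm physical field
    base_params = MapModelParams(shape=(resolution, resolution), pixel_pitch=pitch)

    high: list[tuple[RNFLTMap, DiscMask]] = []
    pids: list[str] = []
    for i in range(n_maps):
        sev = float(rng.uniform(*severity_range))
        mp = replace(base_params, severity=sev, seed=int(rng.integers(2**31)))
        pid = f"P{i:05d}"
        m, disc = generate_rnflt_map(mp, patient_id=pid, eye_id=f"{pid}-OD")
        high.append((m, disc))
        pids.append(pid)

    donor_idx = rng.choice(n_maps, size=n_donors, replace=False)
    patterns = []
    for i in donor_idx:
        ap = ArtifactModelParams(
            target_ar=float(rng.uniform(*donor_ar_range)),
            seed=int(rng.integers(2**31)),
        )
        m, disc = high[i]
        low = generate_segmentation_failure(m, disc, ap)
        patterns.append(extract_pattern(low, disc))

    train_ids, test_ids = patient_level_split(pids, (0.70, 0.30),
                                              seed=int(rng.integers(2**31)))
    train_set = set(train_ids)
    train_high = [h for h, pid in zip(high, pids) if pid in train_set]
    test_high = [h for h, pid in zip(high, pids) if pid not in train_set]
    train_pairs = []
    for _ in range(pairs_per_map):
        train_pairs.extend(
            build_training_pairs(train_high, patterns,
                                 seed=int(rng.integers(2**31)))
        )
    test_pairs = build_training_pairs(test_high, patterns,
                                      seed=int(rng.integers(2**31)))

    model = CorrectionNet(ModelConfig(resolution=resolution,
                                      base_channels=base_channels,
                                      seed=int(rng.integers(2**31))))
    tc = TrainConfig(epochs=epochs, learning_rate=learning_rate,
                     batch_size=batch_size, seed=int(rng.integers(2**31)))
    model, history = train(model, train_pairs, tc)

    report = stratified_report(test_pairs, model)
    # corrupted-input baseline over the same pooled pixels
    inp, tgt = [], []
    for p in test_pairs:
        m = p.pseudo_mask.mask
        inp.append(p.input_map.values[m])
        tgt.append(p.target_map.values[m])
    input_metrics = _region_metrics_from_values(np.concatenate(inp),
                                                np.concatenate(tgt))
    return {
        "model": model,
        "history": history,
        "report": report,
        "input_metrics": input_metrics,
        "corrected_metrics": report.map_metrics["overall"],
        "n_train_pairs": len(train_pairs),
        "n_test_pairs": len(test_pairs),
        "test_pairs": test_pairs,
    }


def structure_function_experiment(
    n_patients: int = 120,
    sf_noise_sds: Sequence[float] = (0.0, 1.0, 3.0),
    circle_samples: int = 64,
    k: int = 3,
    seed: int = 0,
    resolution: int = 64,
) -> pd.DataFrame:
    """Held-out R^2 of MD-from-circle-scan regression vs link noise.

    For each structure-function noise level, a fresh cohort is generated
    (VF exam noise off, so baseline MD is exactly the link output),
    circle-scan profiles are regressed on MD with patient-level k-fold
    CV, and the mean held-out R^2 is recorded.
    """
    from .clinical import evaluate_vf_predictor, predict_vf

    rows = []
    for noise in sf_noise_sds:
        cohort = generate_cohort(
            n_patients,
            map_params=MapModelParams(shape=(resolution, resolution),
                                      pixel_pitch=6.0 / resolution),
            vf_params=VFSimParams(noise_sd=0.0, unreliable_prob=0.0),
            sf_link=StructureFunctionLink(noise_sd=float(noise)),
            donor_prob=0.0,
            circle_samples=circle_samples,
            seed=seed,
        )
        feats = np.stack([
            extract_circle_scan(
                e.rnflt_map,
                CircleGeometry.for_map(e.rnflt_map, e.disc, n_samples=circle_samples),
            ).thickness
            for e in cohort.eyes
        ])
        md = np.array([e.vf.exams[0].md for e in cohort.eyes])
        pids = [e.patient_id for e in cohort.eyes]

        folds = patient_folds(pids, k=k, seed=seed + 1)
        r2s = []
        pid_arr = np.asarray(pids)
        for test_patients in folds:
            test = np.isin(pid_arr, test_patients)
            est = predict_vf(feats[~test], md[~test])
            r2s.append(evaluate_vf_predictor(est, feats[test], md[test])["r2"])
        rows.append({"sf_noise_sd": float(noise), "r2": float(np.mean(r2s)),
                     "n_eyes": len(cohort.eyes)})
    return pd.DataFrame(rows)


def raw_vs_corrected_experiment(
    cohort: Cohort,
    model: CorrectionNet,
    artifact_ar_range: tuple[float, float] = (0.05, 0.25),
    circle_samples: int = 64,
    k: int = 3,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Does artifact correction improve circle-scan MD prediction?

    Every cohort map is corrupted with native-style artifacts (random
    target AR), then corrected with the model. MD is predicted from the
    circle scans of the raw-corrupted and corrected maps under
    patient-level k-fold CV; per-eye absolute errors feed the paired
    bootstrap.
    """
    rng = np.random.default_rng(seed)
    feats_raw, feats_cor, md, pids = [], [], [], []
    for e in cohort.eyes:
        ap = ArtifactModelParams(target_ar=float(rng.uniform(*artifact_ar_range)),
                                 seed=int(rng.integers(2**31)))
        corrupted = generate_segmentation_failure(e.rnflt_map, e.disc, ap)
        corrected, _ = correct(model, corrupted, e.disc)
        geom = CircleGeometry.for_map(e.rnflt_map, e.disc, n_samples=circle_samples)
        feats_raw.append(extract_circle_scan(corrupted, geom).thickness)
        feats_cor.append(extract_circle_scan(corrected, geom).thickness)
        md.append(e.vf.exams[0].md)
        pids.append(e.patient_id)

    feats_raw = np.stack(feats_raw)
    feats_cor = np.stack(feats_cor)
    md = np.array(md)
    cv = crossval_compare(feats_raw, feats_cor, md, pids, k=k, seed=seed + 1)

    # per-eye absolute errors from the CV held-out predictions
    from .clinical import predict_vf

    err_raw = np.zeros(len(md))
    err_cor = np.zeros(len(md))
    pid_arr = np.asarray(pids)
    for test_patients in patient_folds(pids, k=k, seed=seed + 1):
        test = np.isin(pid_arr, test_patients)
        for feats, err in ((feats_raw, err_raw), (feats_cor, err_cor)):
            est = predict_vf(feats[~test], md[~test])
            err[test] = np.abs(est.predict(feats[test]) - md[test])
    boot = bootstrap_compare(err_raw, err_cor, n_boot=n_boot, seed=seed + 2)
    return {"cv": cv, "bootstrap": boot,
            "mae_raw": float(err_raw.mean()), "mae_corrected": float(err_cor.mean())}


def progression_label_recovery(
    slopes: Sequence[float] = (0.0, -1.5),
    n_series: int = 200,
    noise_sd: float = 0.5,
    n_exams: int = 5,
    span_years: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of noisy series whose labels match the noiseless truth.

    For each true MD slope, ``n_series`` eligible series are simulated
    with exam noise ``noise_sd``; the noiseless truth is the label of
    the same series with noise off.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for slope in slopes:
        base = VFSimParams(
            n_exams=n_exams, span_years=span_years, md_slope=float(slope),
            md_intercept=-2.0, noise_sd=noise_sd, unreliable_prob=0.0,
        )
        truth = label_progression(
            generate_vf_series(replace(base, noise_sd=0.0, seed=0), eye_id="truth")
        )
        hits = {"md_fast": 0, "md_prog": 0}
        for _ in range(n_series):
            labels = label_progression(
                generate_vf_series(replace(base, seed=int(rng.integers(2**31))))
            )
            hits["md_fast"] += labels.md_fast == truth.md_fast
            hits["md_prog"] += labels.md_prog == truth.md_prog
        rows.append({
            "true_slope": float(slope),
            "md_fast_truth": truth.md_fast,
            "md_fast_accuracy": hits["md_fast"] / n_series,
            "md_prog_accuracy": hits["md_prog"] / n_series,
            "n_series": n_series,
        })
    return pd.DataFrame(rows)


def bootstrap_null_calibration(
    n_replicates: int = 200,
    n_units: int = 40,
    n_boot: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the paired bootstrap under a simulated null.

    Raw and corrected per-unit metrics are drawn i.i.d. from the same
    distribution (no true difference); the rejection rate at ``alpha``
    should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a = rng.normal(2.0, 1.0, size=n_units)
        b = rng.normal(2.0, 1.0, size=n_units)
        res = bootstrap_compare(a, b, n_boot=n_boot, seed=int(rng.integers(2**31)))
        rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}
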