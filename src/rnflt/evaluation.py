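"""Correction-accuracy metrics in the artifact region, stratified by AR.

Accuracy is measured where it matters: only over the pseudo-artifact
pixels, comparing the corrected prediction with the artifact-free
target. Metrics are reported for the full map and for the circle scan,
overall and within the artifact-ratio strata (AR <= 10%, > 10%, > 20%;
the > 20% stratum is nested inside > 10%). Pixels are pooled across
maps within a stratum (one scatter per stratum); per-map aggregates are
also emitted for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedRegionError
from .maps import (
    ArtifactMask,
    CircleGeometry,
    RNFLTMap,
    stratum,
)
from .model import CorrectionNet, correct
from .pseudo import TrainingPair

STRATA = ("overall", "le10", "gt10", "gt20")


@dataclass
class RegionMetrics:
    """MAE and Pearson correlation over a pixel region."""

    mae: float
    pearson_r: float           # NaN when the region has no variance
    n_pixels: int

    @property
    def r2(self) -> float:
        return self.pearson_r**2


def _region_metrics_from_values(pred: np.ndarray, truth: np.ndarray) -> RegionMetrics:
    mae = float(np.abs(pred - truth).mean())
    if len(pred) >= 2 and np.std(pred) > 0 and np.std(truth) > 0:
        r = float(stats.pearsonr(pred, truth).statistic)
    else:
        r = float("nan")       # zero variance: correlation undefined, flagged
    return RegionMetrics(mae=mae, pearson_r=r, n_pixels=len(pred))


def artifact_region_metrics(
    pred: np.ndarray,
    truth: np.ndarray,
    mask: np.ndarray,
) -> RegionMetrics:
    """MAE and Pearson r over the pixels where ``mask`` is true."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != truth.shape or pred.shape != mask.shape:
        raise UndefinedRegionError("pred/truth/mask shapes differ")
    if not mask.any():
        raise UndefinedRegionError("artifact mask is empty")
    return _region_metrics_from_values(pred[mask], truth[mask])


def circle_region_values(
    pred_map: RNFLTMap,
    truth_map: RNFLTMap,
    mask: ArtifactMask,
    geom: CircleGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Pred/truth thickness at circle samples whose nearest pixel is masked.

    Masks are pixel-level while circle samples are continuous, so each
    angular sample is kept iff the mask is true at its nearest pixel.
    Returns empty arrays when the artifact misses the circle entirely.
    """
    rows, cols = geom.sample_coordinates(pred_map.pixel_pitch)
    ri = np.clip(np.rint(rows).astype(int), 0, pred_map.height - 1)
    ci = np.clip(np.rint(cols).astype(int), 0, pred_map.width - 1)
    on = mask.mask[ri, ci]
    if not on.any():
        return np.array([]), np.array([])
    from .maps import extract_circle_scan

    pred = extract_circle_scan(pred_map, geom).thickness[on]
    truth = extract_circle_scan(truth_map, geom).thickness[on]
    return pred, truth


def circle_region_metrics(
    pred_map: RNFLTMap,
    truth_map: RNFLTMap,
    mask: ArtifactMask,
    geom: CircleGeometry,
) -> RegionMetrics:
    """Metrics restricted to artifact-crossing circle samples."""
    pred, truth = circle_region_values(pred_map, truth_map, mask, geom)
    if len(pred) == 0:
        raise UndefinedRegionError("no artifact pixel touches the scan circle")
    return _region_metrics_from_values(pred, truth)


@dataclass
class StratifiedReport:
    """Four-column map/circle accuracy report (pooled pixels per stratum)."""

    map_metrics: dict[str, RegionMetrics] = field(default_factory=dict)
    circle_metrics: dict[str, RegionMetrics] = field(default_factory=dict)
    n_maps: dict[str, int] = field(default_factory=dict)
    per_map: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in STRATA:
            if s not in self.n_maps or self.n_maps[s] == 0:
                continue     # empty stratum: absent, not zero
            row = {"stratum": s, "n_maps": self.n_maps[s]}
            mm = self.map_metrics.get(s)
            if mm is not None:
                row.update(map_mae=mm.mae, map_r=mm.pearson_r,
                           map_r2=mm.r2, map_n_pixels=mm.n_pixels)
            cm = self.circle_metrics.get(s)
            if cm is not None:
                row.update(circle_mae=cm.mae, circle_r=cm.pearson_r,
                           circle_r2=cm.r2, circle_n_samples=cm.n_pixels)
            rows.append(row)
        return pd.DataFrame(rows)


def stratified_report(
    pairs: Sequence[TrainingPair],
    model: CorrectionNet,
    n_circle_samples: int = 256,
) -> StratifiedReport:
    """Correct every test pair and report stratified artifact-region accuracy.

    Each pair's corrupted input is passed through the correction model;
    predictions and targets are compared over the pair's pseudo mask.
    Strata are assigned from the input's artifact ratio. Circle metrics
    pool the artifact-crossing circle samples (pairs whose artifact
    misses the circle contribute nothing there).
    """
    if len(pairs) == 0:
        raise UndefinedRegionError("empty test set")
    pooled_map: dict[str, list[np.ndarray]] = {s: [] for s in STRATA}
    pooled_circ: dict[str, list[np.ndarray]] = {s: [] for s in STRATA}
    n_maps = {s: 0 for s in STRATA}
    diag_rows = []

    for k, pair in enumerate(pairs):
        corrected, _ = correct(
            model, pair.input_map, pair.disc, pair.pseudo_mask.floor_um
        )
        mask = pair.pseudo_mask.mask
        pv = corrected.values[mask]
        tv = pair.target_map.values[mask]
        ar = pair.input_ar
        flags = stratum(ar)
        member = ["overall"] + [s for s in ("le10", "gt10", "gt20") if flags[s]]

        geom = CircleGeometry.for_map(pair.input_map, pair.disc,
                                      n_samples=n_circle_samples)
        cp, ct = circle_region_values(corrected, pair.target_map,
                                      pair.pseudo_mask, geom)
        for s in member:
            n_maps[s] += 1
            pooled_map[s].append(np.column_stack([pv, tv]))
            if len(cp):
                pooled_circ[s].append(np.column_stack([cp, ct]))

        m = _region_metrics_from_values(pv, tv)
        diag_rows.append(
            {"pair": k, "input_ar": ar, "mae": m.mae,
             "pearson_r": m.pearson_r, "n_pixels": m.n_pixels}
        )

    report = StratifiedReport(n_maps=n_maps, per_map=pd.DataFrame(diag_rows))
    for s in STRATA:
        if pooled_map[s]:
            arr = np.concatenate(pooled_map[s])
            report.map_metrics[s] = _region_metrics_from_values(arr[:, 0], arr[:, 1])
        if pooled_circ[s]:
            arr = np.concatenate(pooled_circ[s])
            report.circle_metrics[s] = _region_metrics_from_values(arr[:, 0], arr[:, 1])
    return report
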