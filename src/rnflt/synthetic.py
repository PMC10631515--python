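"""Synthetic RNFLT maps, segmentation-failure artifacts, and VF series.

Clinical OCT thickness maps and Humphrey visual-field (VF) exports are not
generally redistributable, so every downstream stage of this package is
exercised on synthetic data with the salient anatomy built in:

* **Maps** — a smooth background plus two arcuate nerve-fiber bundles
  modeled as Gaussian ridges (in polar coordinates around the disc) that
  peak superiorly and inferiorly at the scan-circle radius, reproducing
  the classic double-hump TSNIT profile. A ``severity`` knob in [0, 1]
  attenuates the bundles, emulating glaucomatous thinning. A low-valued
  optic-disc region sits at the grid center; outside the disc, values are
  clipped to the measurement floor so a freshly generated map is always
  artifact-free ("high quality", AR < 2%).
* **Artifacts** — unions of random ellipses and annular wedges crossing
  the scan circle are overwritten with sub-floor values, emulating B-scan
  segmentation dropouts, with the achieved artifact ratio steered to a
  requested target.
* **VF series** — time-ordered exams whose mean deviation (MD) and 52
  pointwise total deviations (TDs) follow linear trends plus noise, with
  reliability indices (fixation loss, false positives/negatives) drawn so
  that a configurable fraction of exams fails the reliability filter.
* **Cohorts** — patients with 1-2 eyes, each carrying a high-quality map,
  optionally a low-quality artifact-donor map, and a VF series whose MD
  baseline is an affine function of the eye's mean circle-scan thickness,
  so a structure-function signal exists by construction.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .errors import GenerationError
from .maps import (
    DEFAULT_FLOOR_UM,
    CircleGeometry,
    DiscMask,
    RNFLTMap,
    classify_quality,
    compute_artifact_mask,
    compute_artifact_ratio,
    extract_circle_scan,
)
from .vf import VFExam, VFSeries


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class MapModelParams:
    """Parameters of the synthetic RNFLT map model.

    The thickness surface is::

        T(r, theta) = base + (1 - severity) * amplitude * radial(r) *
                      [hump(theta - theta_sup) + hump(theta - theta_inf)]
                      + noise

    with Gaussian ``radial`` and ``hump`` profiles; ``theta_sup/inf`` are
    the superior and inferior poles. ``severity`` = 1 removes the bundles
    entirely (maximal loss).
    """

    base_thickness: float = 70.0        # um, background far from the bundles
    bundle_amplitude: float = 45.0      # um, bundle peak height above base
    bundle_angle_spread: float = 0.55   # radians, angular sigma of each hump
    severity: float = 0.0               # [0, 1], 1 = complete bundle loss
    noise_sd: float = 3.0               # um, i.i.d. Gaussian measurement noise
    floor_um: float = DEFAULT_FLOOR_UM
    seed: int = 0
    shape: tuple[int, int] = (200, 200)
    pixel_pitch: float = 0.03           # mm/px (6 mm field at 200 px)
    bundle_radius_mm: float = 1.73      # ridge peak radius = scan-circle radius
    bundle_radial_spread_mm: float = 0.85
    disc_radius_mm: float = 0.8
    disc_fill_um: float = 20.0          # thin "cup" values inside the disc

    def __post_init__(self) -> None:
        if self.bundle_amplitude < 0:
            raise ValueError("bundle_amplitude must be >= 0")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError("severity must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ArtifactModelParams:
    """Parameters of the segmentation-failure artifact generator."""

    n_blobs: int = 6                    # elliptical dropouts per attempt
    blob_scale: float = 0.55            # mm, typical ellipse semi-axis
    wedge_prob: float = 0.5             # chance of an annular wedge dropout
    target_ar: float = 0.10             # requested artifact ratio
    fill_range: tuple[float, float] = (5.0, 45.0)  # um, both below the floor
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fill_range
        if not 0 <= lo <= hi:
            raise ValueError("fill_range must satisfy 0 <= lo <= hi")
        if hi >= DEFAULT_FLOOR_UM:
            raise ValueError("fill values must stay below the 50 um floor")
        if not 0.0 <= self.target_ar <= 1.0:
            raise ValueError("target_ar must be in [0, 1]")


@dataclass
class VFSimParams:
    """Parameters of the linear-trend VF series simulator."""

    n_exams: int = 6
    span_years: float = 5.0
    md_slope: float = -0.3              # dB/year
    md_intercept: float = -2.0          # dB at the first exam
    td_slopes: Optional[np.ndarray] = None   # dB/year, length 52
    td_intercepts: Optional[np.ndarray] = None
    noise_sd: float = 0.5               # dB, exam-level noise on MD and TDs
    unreliable_prob: float = 0.1        # chance an exam fails reliability
    start_date: date = date(2015, 1, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exams < 2:
            raise ValueError("n_exams must be >= 2")
        if self.span_years <= 0:
            raise ValueError("span_years must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# map generation
# ---------------------------------------------------------------------------

def _polar_grids(shape: tuple[int, int], pixel_pitch: float):
    h, w = shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    rr, cc_ = np.mgrid[0:h, 0:w].astype(float)
    x_mm = (cc_ - cc) * pixel_pitch
    y_mm = (cr - rr) * pixel_pitch          # row axis points down; flip to y-up
    r_mm = np.hypot(x_mm, y_mm)
    theta = np.arctan2(y_mm, x_mm)
    return r_mm, theta


def _angular_gaussian(theta: np.ndarray, center: float, sigma: float) -> np.ndarray:
    d = np.angle(np.exp(1j * (theta - center)))   # wrapped angular distance
    return np.exp(-0.5 * (d / sigma) ** 2)


def generate_rnflt_map(
    params: MapModelParams,
    patient_id: str = "",
    eye_id: str = "",
    laterality: str = "OD",
    acquisition_date: Optional[date] = None,
) -> tuple[RNFLTMap, DiscMask]:
    """Generate one artifact-free ("high quality") map plus its disc mask.

    Outside the disc the map is clipped to the measurement floor, so the
    returned map always classifies as high quality (AR < 2%).
    """
    rng = np.random.default_rng(params.seed)
    r_mm, theta = _polar_grids(params.shape, params.pixel_pitch)

    radial = np.exp(
        -0.5 * ((r_mm - params.bundle_radius_mm) / params.bundle_radial_spread_mm) ** 2
    )
    humps = _angular_gaussian(theta, np.pi / 2, params.bundle_angle_spread) + \
        _angular_gaussian(theta, -np.pi / 2, params.bundle_angle_spread)
    bundles = (1.0 - params.severity) * params.bundle_amplitude * radial * humps

    values = params.base_thickness + bundles
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=params.shape)

    disc = DiscMask.circular(params.shape, params.pixel_pitch, params.disc_radius_mm)
    values = np.clip(values, params.floor_um, 500.0)
    disc_vals = params.disc_fill_um + (
        rng.normal(0.0, params.noise_sd, size=disc.n_pixels) if params.noise_sd > 0 else 0.0
    )
    values[disc.mask] = np.clip(disc_vals, 0.0, params.floor_um - 1.0)

    m = RNFLTMap(
        values=values,
        pixel_pitch=params.pixel_pitch,
        patient_id=patient_id,
        eye_id=eye_id,
        laterality=laterality,
        acquisition_date=acquisition_date,
    )
    ar = compute_artifact_ratio(
        compute_artifact_mask(m, disc, params.floor_um), disc
    )
    if classify_quality(ar) != "high":
        raise GenerationError(f"generated map has AR {ar:.3f}, not high quality")
    return m, disc


# ---------------------------------------------------------------------------
# artifact generation
# ---------------------------------------------------------------------------

def _random_ellipse(rng, shape, pixel_pitch, blob_scale) -> np.ndarray:
    h, w = shape
    cy = rng.uniform(0, h - 1)
    cx = rng.uniform(0, w - 1)
    a = max(1.5, rng.gamma(2.0, 0.5 * blob_scale / pixel_pitch))
    b = max(1.5, rng.gamma(2.0, 0.5 * blob_scale / pixel_pitch))
    phi = rng.uniform(0, np.pi)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = rr - cy, cc - cx
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _random_wedge(rng, shape, pixel_pitch) -> np.ndarray:
    """Annular sector crossing the scan-circle radius, like a run of
    failed B-scans."""
    r_mm, theta = _polar_grids(shape, pixel_pitch)
    theta0 = rng.uniform(-np.pi, np.pi)
    width = rng.uniform(0.15, 0.7)                    # radians
    r_lo = rng.uniform(0.9, 1.6)                      # mm
    r_hi = r_lo + rng.uniform(0.4, 1.6)
    d = np.abs(np.angle(np.exp(1j * (theta - theta0))))
    return (d <= width) & (r_mm >= r_lo) & (r_mm <= r_hi)


def generate_segmentation_failure(
    rnflt_map: RNFLTMap,
    disc: DiscMask,
    params: ArtifactModelParams,
) -> RNFLTMap:
    """Corrupt a map with sub-floor segmentation-failure artifacts.

    Random ellipses (and, with probability ``wedge_prob``, annular wedges)
    outside the disc are overwritten with values drawn uniformly from
    ``fill_range``. Shapes are accumulated until the artifact ratio
    reaches the target, then trimmed pixel-by-pixel, so the achieved AR
    matches ``target_ar`` to within one pixel (well inside the +/-20%
    contract). ``target_ar`` = 0 returns an unmodified copy.
    """
    rng = np.random.default_rng(params.seed)
    if params.target_ar == 0.0:
        return rnflt_map.copy_with(rnflt_map.values)

    non_disc = rnflt_map.values.size - disc.n_pixels
    target_px = int(round(params.target_ar * non_disc))
    if target_px < 1 or target_px > non_disc:
        raise GenerationError(
            f"target AR {params.target_ar} unreachable on this grid/disc"
        )

    mask = np.zeros(rnflt_map.shape, dtype=bool)
    for _ in range(200):  # accumulation attempts; plenty even for AR > 0.5
        if mask.sum() >= target_px:
            break
        if rng.uniform() < params.wedge_prob:
            shape_mask = _random_wedge(rng, rnflt_map.shape, rnflt_map.pixel_pitch)
        else:
            shape_mask = _random_ellipse(
                rng, rnflt_map.shape, rnflt_map.pixel_pitch, params.blob_scale
            )
        mask |= shape_mask & ~disc.mask
    else:
        raise GenerationError("could not accumulate enough artifact area")

    # trim random excess pixels back to the exact target count
    excess = int(mask.sum()) - target_px
    if excess > 0:
        on = np.flatnonzero(mask.ravel())
        drop = rng.choice(on, size=excess, replace=False)
        flat = mask.ravel()
        flat[drop] = False
        mask = flat.reshape(rnflt_map.shape)

    values = rnflt_map.values.copy()
    values[mask] = rng.uniform(*params.fill_range, size=int(mask.sum()))
    return rnflt_map.copy_with(values)


# ---------------------------------------------------------------------------
# VF series generation
# ---------------------------------------------------------------------------

#: Affine map from MD (dB) to the visual field index (%), clipped to [0, 100].
VFI_SLOPE_PER_DB = 3.3
VFI_AT_ZERO_MD = 100.0


def vfi_from_md(md: float | np.ndarray) -> np.ndarray:
    return np.clip(VFI_AT_ZERO_MD + VFI_SLOPE_PER_DB * np.asarray(md), 0.0, 100.0)


def generate_vf_series(params: VFSimParams, eye_id: str = "") -> VFSeries:
    """Simulate a time-ordered series of VF exams with linear MD/TD trends.

    Exam dates are evenly spread over ``span_years``; MD follows
    ``intercept + slope * t + noise``, TDs analogously, VFI is an affine
    function of the (noisy) MD clipped to [0, 100]. Reliability indices
    are uniform inside the passing region for reliable exams; with
    probability ``unreliable_prob`` one index is pushed past its cutoff.
    """
    rng = np.random.default_rng(params.seed)
    t = np.linspace(0.0, params.span_years, params.n_exams)
    td_slopes = (
        np.full(52, params.md_slope)
        if params.td_slopes is None
        else np.asarray(params.td_slopes, dtype=float)
    )
    td_intercepts = (
        np.full(52, params.md_intercept)
        if params.td_intercepts is None
        else np.asarray(params.td_intercepts, dtype=float)
    )
    if td_slopes.shape != (52,) or td_intercepts.shape != (52,):
        raise ValueError("td_slopes/td_intercepts must have length 52")

    exams = []
    for i, ti in enumerate(t):
        md = params.md_intercept + params.md_slope * ti
        td = td_intercepts + td_slopes * ti
        if params.noise_sd > 0:
            md += rng.normal(0.0, params.noise_sd)
            td = td + rng.normal(0.0, params.noise_sd, size=52)
        if rng.uniform() < params.unreliable_prob:
            which = rng.integers(3)
            fl = rng.uniform(0.34, 0.8) if which == 0 else rng.uniform(0.0, 0.33)
            fp = rng.uniform(0.21, 0.6) if which == 1 else rng.uniform(0.0, 0.20)
            fn = rng.uniform(0.21, 0.6) if which == 2 else rng.uniform(0.0, 0.20)
        else:
            fl = rng.uniform(0.0, 0.33)
            fp = rng.uniform(0.0, 0.20)
            fn = rng.uniform(0.0, 0.20)
        exams.append(
            VFExam(
                exam_date=params.start_date + timedelta(days=round(ti * 365.25)),
                md=float(md),
                vfi=float(vfi_from_md(md)),
                td=np.asarray(td, dtype=float),
                fixation_loss=float(fl),
                false_pos=float(fp),
                false_neg=float(fn),
            )
        )
    return VFSeries(eye_id=eye_id, exams=exams)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class StructureFunctionLink:
    """Affine link from mean circle-scan thickness (um) to MD (dB):
    ``MD = slope_db_per_um * (mean_thickness - pivot_um) + noise``.

    Defaults put MD at 0 dB for a healthy ~95 um profile and around
    -7 dB for a severely thinned ~60 um profile, a realistic span.
    """

    slope_db_per_um: float = 0.2
    pivot_um: float = 95.0
    noise_sd: float = 0.0


@dataclass
class EyeRecord:
    patient_id: str
    eye_id: str
    laterality: str
    severity: float
    rnflt_map: RNFLTMap
    disc: DiscMask
    vf: VFSeries
    mean_circle_um: float
    donor_map: Optional[RNFLTMap] = None
    donor_ar: Optional[float] = None


@dataclass
class Cohort:
    eyes: list[EyeRecord]
    seed: int

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.eyes:
            seen.setdefault(e.patient_id, None)
        return list(seen)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for e in self.eyes:
            rows.append(
                {
                    "patient_id": e.patient_id,
                    "eye_id": e.eye_id,
                    "laterality": e.laterality,
                    "severity": e.severity,
                    "mean_circle_um": e.mean_circle_um,
                    "has_donor": e.donor_map is not None,
                    "donor_ar": e.donor_ar if e.donor_ar is not None else np.nan,
                    "n_vf_exams": len(e.vf.exams),
                    "baseline_md": e.vf.exams[0].md,
                }
            )
        return pd.DataFrame(rows)


def generate_cohort(
    n_patients: int,
    map_params: Optional[MapModelParams] = None,
    vf_params: Optional[VFSimParams] = None,
    artifact_params: Optional[ArtifactModelParams] = None,
    sf_link: Optional[StructureFunctionLink] = None,
    donor_prob: float = 0.25,
    donor_ar_range: tuple[float, float] = (0.06, 0.30),
    two_eye_prob: float = 0.5,
    md_slope_sd: float = 0.4,
    md_slope_mean: float = -0.3,
    circle_samples: int = 256,
    seed: int = 0,
) -> Cohort:
    """Generate a full synthetic cohort.

    Each patient contributes one or two eyes. Per eye: a high-quality map
    whose bundle loss is governed by a random severity; with probability
    ``donor_prob`` a low-quality copy corrupted to a random AR in
    ``donor_ar_range`` (an artifact-pattern donor); and a VF series whose
    baseline MD follows the structure-function link applied to the eye's
    mean circle-scan thickness, with a random MD slope for progression.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    map_params = map_params or MapModelParams()
    vf_params = vf_params or VFSimParams()
    artifact_params = artifact_params or ArtifactModelParams()
    sf_link = sf_link or StructureFunctionLink()
    rng = np.random.default_rng(seed)

    eyes: list[EyeRecord] = []
    for p in range(n_patients):
        pid = f"P{p:05d}"
        n_eyes = 2 if rng.uniform() < two_eye_prob else 1
        lats = ["OD", "OS"][:n_eyes]
        for lat in lats:
            severity = float(rng.beta(1.3, 1.8))
            mp = replace(
                map_params,
                severity=severity,
                seed=int(rng.integers(2**31)),
            )
            eye_id = f"{pid}-{lat}"
            m, disc = generate_rnflt_map(
                mp, patient_id=pid, eye_id=eye_id, laterality=lat,
                acquisition_date=vf_params.start_date,
            )
            scan = extract_circle_scan(
                m, CircleGeometry.for_map(m, disc, n_samples=circle_samples)
            )
            mean_um = scan.mean_um
            md0 = sf_link.slope_db_per_um * (mean_um - sf_link.pivot_um)
            if sf_link.noise_sd > 0:
                md0 += float(rng.normal(0.0, sf_link.noise_sd))
            slope = float(rng.normal(md_slope_mean, md_slope_sd))
            vp = replace(
                vf_params,
                md_intercept=float(md0),
                md_slope=slope,
                td_slopes=np.clip(
                    slope + rng.normal(0.0, 0.3, size=52), -3.0, 1.0
                ),
                td_intercepts=np.full(52, float(md0)),
                seed=int(rng.integers(2**31)),
            )
            vf = generate_vf_series(vp, eye_id=eye_id)

            donor_map = None
            donor_ar = None
            if rng.uniform() < donor_prob:
                ap = replace(
                    artifact_params,
                    target_ar=float(rng.uniform(*donor_ar_range)),
                    seed=int(rng.integers(2**31)),
                )
                donor_map = generate_segmentation_failure(m, disc, ap)
                donor_ar = compute_artifact_ratio(
                    compute_artifact_mask(donor_map, disc), disc
                )
            eyes.append(
                EyeRecord(
                    patient_id=pid,
                    eye_id=eye_id,
                    laterality=lat,
                    severity=severity,
                    rnflt_map=m,
                    disc=disc,
                    vf=vf,
                    mean_circle_um=mean_um,
                    donor_map=donor_map,
                    donor_ar=donor_ar,
                )
            )
    return Cohort(eyes=eyes, seed=seed)
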