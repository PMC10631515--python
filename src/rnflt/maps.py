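"""Core grid types for peripapillary RNFL thickness (RNFLT) maps.

An RNFLT map is a dense 2-D grid of retinal nerve fiber layer thickness
values in micrometers, as exported by spectral-domain OCT devices
(typically 200 x 200 samples over a 6 x 6 mm peripapillary region).
This module provides:

* the :class:`RNFLTMap` container and its optic-disc / artifact masks,
* floor-rule artifact detection (`values < floor`, 50 um by default,
  the physiological floor below which measured thickness is attributed
  to segmentation failure rather than anatomy),
* the artifact ratio (AR) — artifact area over non-disc map area — and
  the quality / AR-stratum classifications built on it,
* circumpapillary circle-scan extraction: bilinear sampling of the map
  on the standard 3.46-mm-diameter circle centered on the optic disc,
  in TSNIT (temporal-superior-nasal-inferior-temporal) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ShapeError, UndefinedRegionError

#: Physiological floor (um): measured RNFLT below this is treated as a
#: segmentation-failure artifact.
DEFAULT_FLOOR_UM = 50.0

#: Standard circumpapillary scan-circle diameter (mm).
CIRCLE_DIAMETER_MM = 3.46

#: Upper bound for physically plausible RNFLT (um).
MAX_THICKNESS_UM = 500.0

#: Quality cutoffs on the artifact ratio.
HIGH_QUALITY_AR = 0.02   # AR < 2%  -> usable as ground truth
LOW_QUALITY_AR = 0.05    # AR > 5%  -> artifact donor


@dataclass
class RNFLTMap:
    """Dense RNFLT grid with physical geometry and identity metadata.

    Parameters
    ----------
    values
        2-D array of thickness values in um. All entries must be finite
        and within [0, 500].
    pixel_pitch
        Physical pixel size in mm/pixel. The default 0.03 corresponds to
        a 6 x 6 mm field sampled at 200 x 200.
    """

    values: np.ndarray
    pixel_pitch: float = 0.03
    patient_id: str = ""
    eye_id: str = ""
    laterality: str = "OD"
    acquisition_date: Optional[date] = None
    signal_strength: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"map values must be 2-D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        if self.values.min() < 0 or self.values.max() > MAX_THICKNESS_UM:
            raise ValueError(
                f"thickness outside [0, {MAX_THICKNESS_UM}] um: "
                f"range [{self.values.min():.1f}, {self.values.max():.1f}]"
            )
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """Physical (height, width) of the field in mm."""
        return (self.height * self.pixel_pitch, self.width * self.pixel_pitch)

    def copy_with(self, values: np.ndarray) -> "RNFLTMap":
        """New map sharing this map's metadata with replaced values."""
        return RNFLTMap(
            values=np.array(values, dtype=float),
            pixel_pitch=self.pixel_pitch,
            patient_id=self.patient_id,
            eye_id=self.eye_id,
            laterality=self.laterality,
            acquisition_date=self.acquisition_date,
            signal_strength=self.signal_strength,
        )


@dataclass
class DiscMask:
    """Boolean mask of optic-disc pixels (True inside the disc)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ShapeError("disc mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid of the disc; grid center if the mask is empty."""
        if self.mask.any():
            r, c = ndimage.center_of_mass(self.mask)
            return float(r), float(c)
        h, w = self.mask.shape
        return (h - 1) / 2.0, (w - 1) / 2.0

    @classmethod
    def circular(
        cls,
        shape: tuple[int, int],
        pixel_pitch: float,
        radius_mm: float = 0.8,
        center: Optional[tuple[float, float]] = None,
    ) -> "DiscMask":
        """Filled-circle disc mask (default radius 0.8 mm at grid center,
        i.e. disc area ~2 mm^2, a typical optic-disc size)."""
        h, w = shape
        if center is None:
            center = ((h - 1) / 2.0, (w - 1) / 2.0)
        rr, cc = np.mgrid[0:h, 0:w]
        radius_px = radius_mm / pixel_pitch
        dist2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        return cls(mask=dist2 <= radius_px**2)

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "DiscMask":
        return cls(mask=np.zeros(shape, dtype=bool))


@dataclass
class ArtifactMask:
    """Boolean mask of artifact pixels (sub-floor thickness outside the disc)."""

    mask: np.ndarray
    floor_um: float = DEFAULT_FLOOR_UM

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ShapeError("artifact mask must be 2-D")
        if self.floor_um <= 0:
            raise ValueError("floor_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def compute_artifact_mask(
    rnflt_map: RNFLTMap,
    disc: Optional[DiscMask] = None,
    floor_um: float = DEFAULT_FLOOR_UM,
) -> ArtifactMask:
    """Floor-rule artifact detection.

    A pixel is an artifact iff its thickness is strictly below ``floor_um``
    and it lies outside the optic disc. Map values are left untouched:
    sub-floor values are flagged, not zeroed or modified.
    """
    if floor_um <= 0:
        raise ValueError("floor_um must be positive")
    if disc is None:
        disc = DiscMask.empty(rnflt_map.shape)
    if disc.shape != rnflt_map.shape:
        raise ShapeError(f"disc shape {disc.shape} != map shape {rnflt_map.shape}")
    mask = (rnflt_map.values < floor_um) & ~disc.mask
    return ArtifactMask(mask=mask, floor_um=floor_um)


def compute_artifact_ratio(artifact: ArtifactMask, disc: DiscMask) -> float:
    """Artifact ratio: artifact area over map area excluding the disc."""
    if artifact.shape != disc.shape:
        raise ShapeError(f"artifact shape {artifact.shape} != disc shape {disc.shape}")
    denom = artifact.mask.size - disc.n_pixels
    if denom <= 0:
        raise UndefinedRegionError("disc covers the entire grid; AR undefined")
    return artifact.n_pixels / denom


def classify_quality(ar: float) -> str:
    """Map-quality class from the artifact ratio.

    ``high`` (AR < 2%) maps serve as inpainting ground truth; ``low``
    (AR > 5%) maps serve as artifact-pattern donors; anything between is
    ``intermediate`` and used for neither.
    """
    if not 0.0 <= ar <= 1.0:
        raise ValueError(f"AR must be in [0, 1], got {ar}")
    if ar < HIGH_QUALITY_AR:
        return "high"
    if ar > LOW_QUALITY_AR:
        return "low"
    return "intermediate"


def stratum(ar: float) -> dict[str, bool]:
    """AR-stratum membership flags used in stratified evaluation.

    ``le10`` and ``gt10`` partition [0, 1] (the 10% boundary belongs to
    ``le10``); ``gt20`` is nested inside ``gt10``.
    """
    if not 0.0 <= ar <= 1.0:
        raise ValueError(f"AR must be in [0, 1], got {ar}")
    return {"le10": ar <= 0.10, "gt10": ar > 0.10, "gt20": ar > 0.20}


@dataclass
class CircleGeometry:
    """Sampling geometry of the circumpapillary scan circle.

    Angles follow the TSNIT convention: sampling starts temporally
    (angle pi, i.e. the left edge for a right eye in standard map
    orientation) and proceeds temporal -> superior -> nasal -> inferior.
    ``angles`` are standard math angles (counterclockwise from +col axis,
    row axis pointing up), so the TSNIT sweep decreases the angle.
    """

    center: tuple[float, float]  # (row, col), continuous pixel coordinates
    diameter_mm: float = CIRCLE_DIAMETER_MM
    n_samples: int = 256
    start_angle: float = np.pi
    clockwise: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")

    @classmethod
    def for_map(
        cls,
        rnflt_map: RNFLTMap,
        disc: Optional[DiscMask] = None,
        n_samples: int = 256,
        diameter_mm: float = CIRCLE_DIAMETER_MM,
    ) -> "CircleGeometry":
        """Circle centered on the disc centroid (grid center without a disc)."""
        if disc is not None and disc.shape != rnflt_map.shape:
            raise ShapeError("disc shape does not match map shape")
        if disc is not None:
            center = disc.centroid()
        else:
            h, w = rnflt_map.shape
            center = ((h - 1) / 2.0, (w - 1) / 2.0)
        return cls(center=center, n_samples=n_samples, diameter_mm=diameter_mm)

    def angles(self) -> np.ndarray:
        step = 2.0 * np.pi / self.n_samples
        k = np.arange(self.n_samples)
        sign = -1.0 if self.clockwise else 1.0
        return self.start_angle + sign * step * k

    def sample_coordinates(self, pixel_pitch: float) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the angular samples in pixel coordinates."""
        radius_px = (self.diameter_mm / 2.0) / pixel_pitch
        theta = self.angles()
        rows = self.center[0] - radius_px * np.sin(theta)
        cols = self.center[1] + radius_px * np.cos(theta)
        return rows, cols


@dataclass
class CircleScan:
    """Thickness profile on the scan circle."""

    thickness: np.ndarray  # um, length n_samples
    angles: np.ndarray     # radians, length n_samples

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.thickness.shape != self.angles.shape:
            raise ShapeError("thickness and angles must have equal length")
        if not np.all(np.isfinite(self.thickness)):
            raise ValueError("circle scan contains non-finite values")

    @property
    def mean_um(self) -> float:
        return float(self.thickness.mean())


def extract_circle_scan(rnflt_map: RNFLTMap, geom: CircleGeometry) -> CircleScan:
    """Sample the map on the scan circle by bilinear interpolation.

    Pixel centers sit at integer coordinates (row-major, origin top-left).
    Raises :class:`GeometryError` if any sample falls outside the grid.
    """
    rows, cols = geom.sample_coordinates(rnflt_map.pixel_pitch)
    h, w = rnflt_map.shape
    if rows.min() < 0 or rows.max() > h - 1 or cols.min() < 0 or cols.max() > w - 1:
        raise GeometryError(
            f"scan circle (diameter {geom.diameter_mm} mm) exits the "
            f"{h}x{w} grid at pitch {rnflt_map.pixel_pitch} mm/px"
        )
    thickness = ndimage.map_coordinates(
        rnflt_map.values, np.vstack([rows, cols]), order=1, mode="nearest"
    )
    return CircleScan(thickness=thickness, angles=geom.angles())
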