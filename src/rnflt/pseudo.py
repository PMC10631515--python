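"""Pseudo-artifact synthesis: supervised training pairs for inpainting.

Real sub-floor artifacts have no ground truth, so supervision is built by
transplantation: the artifact pattern (mask + its sub-floor values) of a
low-quality donor map (AR > 5%) is superimposed onto a high-quality map
(AR < 2%), whose untouched values become the reconstruction target.
Donor *values* are transplanted, not just masks, so the model sees
realistic corrupted intensities rather than a constant fill.

Also provides the patient-level train/test split: all images of a
patient land on the same side of the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import DegeneratePatternError, EligibilityError, ShapeError, SplitError
from .maps import (
    ArtifactMask,
    DiscMask,
    RNFLTMap,
    classify_quality,
    compute_artifact_mask,
    compute_artifact_ratio,
)


@dataclass
class ArtifactPattern:
    """An artifact mask plus the donor's sub-floor values on it."""

    mask: np.ndarray           # boolean grid
    values: np.ndarray         # um, one per True pixel (row-major order)
    donor_id: str = ""
    floor_um: float = 50.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (int(self.mask.sum()),):
            raise ShapeError("values must have one entry per masked pixel")
        if self.values.size and self.values.max() >= self.floor_um:
            raise ValueError("pattern values must all lie below the floor")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def as_image(self) -> np.ndarray:
        """Dense image with pattern values on the mask and NaN elsewhere."""
        img = np.full(self.mask.shape, np.nan)
        img[self.mask] = self.values
        return img


@dataclass
class TrainingPair:
    """A corrupted input, its artifact-free target, and the written mask."""

    input_map: RNFLTMap
    target_map: RNFLTMap
    pseudo_mask: ArtifactMask
    disc: DiscMask

    def __post_init__(self) -> None:
        if not (
            self.input_map.shape
            == self.target_map.shape
            == self.pseudo_mask.shape
            == self.disc.shape
        ):
            raise ShapeError("training-pair grids must share one shape")
        off = ~self.pseudo_mask.mask
        if not np.array_equal(self.input_map.values[off], self.target_map.values[off]):
            raise ValueError("input must equal target off the pseudo mask")

    @property
    def input_ar(self) -> float:
        """Artifact ratio of the corrupted input (floor rule, non-disc area)."""
        am = compute_artifact_mask(self.input_map, self.disc, self.pseudo_mask.floor_um)
        return compute_artifact_ratio(am, self.disc)


def extract_pattern(
    low_map: RNFLTMap,
    disc: DiscMask,
    floor_um: float = 50.0,
) -> ArtifactPattern:
    """Extract the artifact pattern of a low-quality (AR > 5%) donor map."""
    artifact = compute_artifact_mask(low_map, disc, floor_um)
    ar = compute_artifact_ratio(artifact, disc)
    if classify_quality(ar) != "low":
        raise EligibilityError(
            f"donor {low_map.eye_id!r} has AR {ar:.3f}; donors need AR > 5%"
        )
    return ArtifactPattern(
        mask=artifact.mask,
        values=low_map.values[artifact.mask],
        donor_id=low_map.eye_id or low_map.patient_id,
        floor_um=floor_um,
    )


def _transform_pattern(
    pattern: ArtifactPattern,
    shift_px: tuple[int, int],
    rotation_deg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigidly move a pattern (nearest-neighbor, about the grid center).

    Returns the moved boolean mask and the dense value image; pixels
    transported from outside the original mask are dropped.
    """
    img = pattern.as_image()
    mask = pattern.mask.astype(float)
    if rotation_deg != 0.0:
        img = ndimage.rotate(img, rotation_deg, reshape=False, order=0,
                             mode="constant", cval=np.nan)
        mask = ndimage.rotate(mask, rotation_deg, reshape=False, order=0,
                              mode="constant", cval=0.0)
    dr, dc = int(shift_px[0]), int(shift_px[1])
    if (dr, dc) != (0, 0):
        img = ndimage.shift(img, (dr, dc), order=0, mode="constant", cval=np.nan)
        mask = ndimage.shift(mask, (dr, dc), order=0, mode="constant", cval=0.0)
    moved = (mask > 0.5) & np.isfinite(img)
    return moved, img


def superimpose(
    high_map: RNFLTMap,
    pattern: ArtifactPattern,
    disc: DiscMask,
    shift_px: tuple[int, int] = (0, 0),
    rotation_deg: float = 0.0,
    floor_um: float = 50.0,
) -> TrainingPair:
    """Write a (possibly rigidly moved) donor pattern onto a high-quality map.

    The untouched ``high_map`` is the target; the written region is
    recorded as the pseudo mask. Moved pattern pixels that land on the
    disc or outside the grid are dropped.
    """
    am = compute_artifact_mask(high_map, disc, floor_um)
    ar = compute_artifact_ratio(am, disc)
    if classify_quality(ar) != "high":
        raise EligibilityError(
            f"target map has AR {ar:.3f}; ground-truth maps need AR < 2%"
        )
    if pattern.mask.shape != high_map.shape:
        raise ShapeError("pattern and map shapes differ")

    moved_mask, moved_img = _transform_pattern(pattern, shift_px, rotation_deg)
    moved_mask &= ~disc.mask
    if not moved_mask.any():
        raise DegeneratePatternError("pattern is empty after the transform")

    values = high_map.values.copy()
    values[moved_mask] = moved_img[moved_mask]
    return TrainingPair(
        input_map=high_map.copy_with(values),
        target_map=high_map.copy_with(high_map.values),
        pseudo_mask=ArtifactMask(mask=moved_mask, floor_um=floor_um),
        disc=disc,
    )


def random_superimpose(
    high_map: RNFLTMap,
    pattern: ArtifactPattern,
    disc: DiscMask,
    seed: int,
    max_shift_px: int = 20,
    max_rotation_deg: float = 15.0,
    floor_um: float = 50.0,
) -> TrainingPair:
    """Superimpose with a seeded random rigid transform.

    Decorrelates pattern location from donor anatomy. Shifts are integer
    pixels in [-max_shift, max_shift]; rotation uniform in
    [-max_rotation, max_rotation] degrees. A draw that moves the whole
    pattern off-grid or onto the disc is rejected and redrawn (up to 10
    attempts, still fully determined by ``seed``).
    """
    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for _ in range(10):
        shift = tuple(int(s) for s in rng.integers(-max_shift_px,
                                                   max_shift_px + 1, 2))
        rot = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
        try:
            return superimpose(high_map, pattern, disc, shift, rot, floor_um)
        except DegeneratePatternError as err:
            last_err = err
    raise last_err


def patient_level_split(
    patient_ids: Sequence[str],
    fractions: tuple[float, ...] = (0.70, 0.30),
    seed: int = 0,
) -> tuple[list[str], ...]:
    """Partition unique patient ids into groups with the given fractions.

    Every image of a patient inherits the patient's group, so the groups
    are disjoint at the patient level. Group sizes are the rounded
    fraction targets (within one patient of exact).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    unique = list(dict.fromkeys(patient_ids))
    if len(unique) < len(fractions):
        raise SplitError(
            f"{len(unique)} patients cannot fill {len(fractions)} groups"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(unique)))
    shuffled = [unique[i] for i in order]

    sizes = [int(round(f * len(unique))) for f in fractions[:-1]]
    sizes.append(len(unique) - sum(sizes))
    if min(sizes) < 1:  # guarantee non-empty groups
        raise SplitError("a split group would be empty; add patients")
    groups, start = [], 0
    for s in sizes:
        groups.append(sorted(shuffled[start:start + s]))
        start += s
    return tuple(groups)
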