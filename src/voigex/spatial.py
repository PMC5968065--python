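"""VOI construction and spatial filtering of tissue samples.

Probabilistic region maps are thresholded into binary VOI masks, and tissue
samples are assigned to VOIs by mapping their MNI world coordinate to the
nearest voxel (inverse affine, round-half-away-from-zero per axis). Inputs
are assumed co-registered in a common reference space; no registration is
performed here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from .types import (
    ProbabilityVolume,
    TissueSample,
    ValidationError,
    VoiAssignment,
    VoiMask,
    VOI_THRESHOLD_MAX,
    VOI_THRESHOLD_MIN,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_probability_volume",
    "write_probability_volume",
    "write_mask",
    "threshold_map",
    "merge_masks",
    "world_to_voxel",
    "sample_in_mask",
    "assign_samples",
]


def read_probability_volume(path, space_tag: str = "MNI152") -> ProbabilityVolume:
    """Read a probabilistic map from a NIfTI-1 file.

    Maps stored on a [0, 1] scale (max voxel value <= 1) are rescaled to
    percent; the rescaling is logged.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if data.size and float(np.nanmax(data)) <= 1.0:
        logger.info("%s: values in [0, 1]; rescaling to percent", path)
        data = data * 100.0
    return ProbabilityVolume(voxels=data, affine=np.asarray(img.affine), space_tag=space_tag)


def write_probability_volume(vol: ProbabilityVolume, path) -> None:
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def write_mask(mask: VoiMask, path) -> None:
    """Export a VOI mask as NIfTI with 0/1 voxels."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def threshold_map(vol: ProbabilityVolume, threshold_pct: float, name: str) -> VoiMask:
    """Binary mask of voxels whose probability is >= ``threshold_pct``.

    The larger the threshold, the smaller the VOI; thresholds are restricted
    to the 10-100% range.
    """
    t = float(threshold_pct)
    if not (VOI_THRESHOLD_MIN <= t <= VOI_THRESHOLD_MAX):
        raise ValidationError(
            f"threshold must lie in [{VOI_THRESHOLD_MIN:g}, {VOI_THRESHOLD_MAX:g}], got {t:g}"
        )
    return VoiMask(
        voxels=vol.voxels >= t,
        affine=vol.affine,
        source_threshold_pct=t,
        name=name,
    )


def _same_grid(a: VoiMask, b: VoiMask) -> bool:
    return a.voxels.shape == b.voxels.shape and np.allclose(a.affine, b.affine)


def merge_masks(masks: Sequence[VoiMask], name: str) -> VoiMask:
    """Voxelwise union of masks on an identical grid (e.g. neighboring areas)."""
    if not masks:
        raise ValidationError("merge_masks requires at least one mask")
    first = masks[0]
    union = first.voxels.copy()
    for m in masks[1:]:
        if not _same_grid(first, m):
            raise ValidationError(
                f"mask {m.name!r} has a different shape or affine than {first.name!r}"
            )
        union |= m.voxels
    return VoiMask(
        voxels=union,
        affine=first.affine,
        source_threshold_pct=min(m.source_threshold_pct for m in masks),
        name=name,
    )


def _round_half_away(v: np.ndarray) -> np.ndarray:
    # round-half-away-from-zero, fixed for reproducibility (np.round halves to even)
    return np.trunc(v + np.copysign(0.5, v)).astype(int)


def world_to_voxel(affine: np.ndarray, xyz: Sequence[float]) -> tuple[int, int, int]:
    """Nearest 0-based voxel index for a world coordinate in mm."""
    inv = np.linalg.inv(affine)
    hom = inv @ np.array([xyz[0], xyz[1], xyz[2], 1.0])
    i, j, k = _round_half_away(hom[:3])
    return int(i), int(j), int(k)


def _in_bounds(idx: tuple[int, int, int], shape: tuple[int, ...]) -> bool:
    return all(0 <= idx[d] < shape[d] for d in range(3))


def sample_in_mask(sample: TissueSample, mask: VoiMask) -> bool:
    """True iff the sample's nearest voxel lies inside the mask.

    Coordinates whose nearest voxel falls outside the array bounds are
    simply outside the mask (no error).
    """
    idx = world_to_voxel(mask.affine, sample.mni_xyz)
    return _in_bounds(idx, mask.voxels.shape) and bool(mask.voxels[idx])


def assign_samples(
    samples: Iterable[TissueSample],
    voi1: VoiMask,
    voi2: VoiMask,
    prob1: ProbabilityVolume,
    prob2: ProbabilityVolume,
) -> VoiAssignment:
    """Assign VOI-specific labels (TSLs) to tissue samples.

    A sample inside exactly one mask gets that VOI's label. A sample inside
    both masks gets the label of the VOI whose probability map has the
    higher value at the sample's voxel; equal probabilities exclude the
    sample as ``"ambiguous"``. Samples in neither mask are excluded as
    ``"outside"``.
    """
    labels: dict[str, str] = {}
    excluded: list[tuple[str, str]] = []
    for s in samples:
        in1 = sample_in_mask(s, voi1)
        in2 = sample_in_mask(s, voi2)
        if in1 and in2:
            idx = world_to_voxel(prob1.affine, s.mni_xyz)
            p1 = float(prob1.voxels[idx])
            p2 = float(prob2.voxels[idx])
            if p1 > p2:
                labels[s.sample_id] = voi1.name
            elif p2 > p1:
                labels[s.sample_id] = voi2.name
            else:
                logger.warning(
                    "sample %s lies in both VOIs with equal probability; excluded",
                    s.sample_id,
                )
                excluded.append((s.sample_id, "ambiguous"))
        elif in1:
            labels[s.sample_id] = voi1.name
        elif in2:
            labels[s.sample_id] = voi2.name
        else:
            excluded.append((s.sample_id, "outside"))
    return VoiAssignment(labels=labels, excluded=excluded)
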