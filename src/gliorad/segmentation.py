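"""Iso-contour tumor segmentation within a confining volume.

The tumor volume in each modality is the set of voxels whose
tumor-to-background ratio reaches a fixed clinically motivated cut
(default 1.6; 1.3 and 1.8 serve as sensitivity settings for TSPO PET),
intersected with a manually drawn confining volume that excludes vessels,
ventricles and extracerebral structures. An empty result is legal and means
the tumor is not visible in that modality. The whole-tumor T2 mask (active
tumor + necrosis + edema) can be routed to every modality instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Mask, Volume, check_congruent

logger = logging.getLogger(__name__)

__all__ = ["SegmentationSpec", "isocontour_mask", "visibility_check", "t2_volume_for"]

DEFAULT_THRESHOLD = 1.6
SENSITIVITY_THRESHOLDS = (1.3, 1.8)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class SegmentationSpec:
    threshold: float = DEFAULT_THRESHOLD
    min_voxels: int = 10          # visibility floor; "not visible" below this
    use_connectivity_filter: bool = False

    def __post_init__(self) -> None:
        if not self.threshold > 1.0:
            raise ValueError(f"iso-contour threshold must exceed 1, got {self.threshold}")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


def isocontour_mask(tbr: Volume, confining: Mask,
                    spec: SegmentationSpec = SegmentationSpec()) -> Mask:
    """Threshold a TBR image at ``spec.threshold`` inside the confining volume.

    With ``use_connectivity_filter`` set, only 26-connected components of at
    least ``min_voxels`` voxels are retained (guards texture matrices against
    stray suprathreshold noise voxels).
    """
    check_congruent(tbr, confining)
    with np.errstate(invalid="ignore"):
        mask = (tbr.values >= spec.threshold) & confining.values
    if spec.use_connectivity_filter and mask.any():
        labels, n = ndimage.label(mask, structure=_STRUCT_26)
        if n:
            counts = np.bincount(labels.ravel())
            keep = np.flatnonzero(counts >= spec.min_voxels)
            keep = keep[keep != 0]
            mask = np.isin(labels, keep)
    return Mask(mask, tbr.spacing_mm, provenance="modality_isocontour")


def visibility_check(mask: Mask, spec: SegmentationSpec = SegmentationSpec()) -> bool:
    """True iff the mask is large enough for feature extraction."""
    visible = mask.n_voxels >= spec.min_voxels
    if not visible:
        logger.info("mask (%s) has %d voxels, below visibility floor %d",
                    mask.provenance, mask.n_voxels, spec.min_voxels)
    return visible


def t2_volume_for(subject) -> Mask:
    """The whole-tumor T2 mask of a subject, applicable to every modality.

    Covers the active rim, the necrotic core and the surrounding
    edematous/invaded tissue. For synthetic subjects this is generator
    ground truth; externally produced masks with the same provenance are
    accepted interchangeably.
    """
    mask = getattr(subject, "t2_truth_mask", None)
    if mask is None:
        raise ValueError("subject carries no whole-tumor T2 mask")
    if mask.provenance != "t2_whole_tumor":
        raise ValueError(f"expected provenance 't2_whole_tumor', got {mask.provenance!r}")
    return mask
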