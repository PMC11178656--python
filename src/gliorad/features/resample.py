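"""Isotropic grid resampling for feature extraction.

Intensities are interpolated trilinearly, masks by nearest neighbor (so
they stay binary). The voxel-center convention maps output voxel ``k`` to
world coordinate ``(k + 0.5) * target_spacing``; when the input is already
at the target spacing the operation is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..core import Mask, Volume

__all__ = ["ResamplingSpec", "resample"]


@dataclass(frozen=True)
class ResamplingSpec:
    target_spacing_mm: tuple[float, float, float] = (2.036, 2.036, 2.036)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError(f"degenerate target spacing {self.target_spacing_mm}")


def _resample_array(values: np.ndarray, spacing: tuple[float, ...],
                    target: tuple[float, ...], order: int) -> np.ndarray:
    new_shape = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(values.shape, spacing, target)
    )
    coords = np.meshgrid(
        *[( (np.arange(m) + 0.5) * t / s - 0.5) for m, s, t in zip(new_shape, spacing, target)],
        indexing="ij",
    )
    return ndimage.map_coordinates(values, coords, order=order, mode="nearest")


def resample(image: Volume | Mask, spec: ResamplingSpec = ResamplingSpec()):
    """Re-grid a volume (trilinear) or mask (nearest-neighbor) to the target
    spacing; returns the same kind of object."""
    target = spec.target_spacing_mm
    if np.allclose(image.spacing_mm, target, rtol=1e-9, atol=1e-12):
        if isinstance(image, Mask):
            return Mask(image.values.copy(), image.spacing_mm, image.provenance)
        return Volume(image.values.copy(), image.spacing_mm, image.modality_tag)
    if isinstance(image, Mask):
        out = _resample_array(image.values.astype(np.uint8), image.spacing_mm, target, order=0)
        return Mask(out > 0, target, image.provenance)
    out = _resample_array(image.values, image.spacing_mm, target, order=1)
    return Volume(out, target, image.modality_tag)
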