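"""End-to-end drivers: phantom cohort -> parametric maps -> masks -> features.

Maps one subject's multimodal images to the nine analysis images
(TBR_GE-180, TBR_FET5-15, TBR_FET20-40, TBR_T1CE, TBR_T2, TTP_SUV,
TTP_TBR, Slope_SUV, Slope_TBR), builds the tumor mask for each under the
chosen volume-definition mode, and assembles the cohort feature table.

Volume-definition modes:

* ``modality`` — iso-contour mask per modality: TSPO images use the
  TBR_GE-180 iso-contour, all FET-derived images (static averages and
  kinetic maps) use the clinically established TBR_FET20-40 iso-contour,
  and the MRI-like images use the whole-tumor T2 mask.
* ``t2`` — the whole-tumor T2 mask routed to every modality.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortSpec, SubjectImages, iter_cohort
from .core import Mask, Volume
from .features.resample import ResamplingSpec, resample
from .features.table import (
    ROI,
    FeatureTable,
    SubjectROIs,
    extract_feature_table,
    freeze_discretization,
)
from .kinetics import (
    compute_slope_map,
    compute_tbr,
    compute_ttp_map,
    static_average,
    tbr_dynamic,
)
from .segmentation import SegmentationSpec, isocontour_mask, t2_volume_for

__all__ = ["derive_maps", "subject_rois", "cohort_feature_table", "ALL_MODALITIES"]

ALL_MODALITIES = (
    "TBR_GE-180", "TBR_FET5-15", "TBR_FET20-40", "TBR_T1CE", "TBR_T2",
    "TTP_SUV", "TTP_TBR", "Slope_SUV", "Slope_TBR",
)

_FET_DERIVED = ("TBR_FET5-15", "TBR_FET20-40", "TTP_SUV", "TTP_TBR",
                "Slope_SUV", "Slope_TBR")
_MRI = ("TBR_T1CE", "TBR_T2")


def derive_maps(subject: SubjectImages,
                modalities: tuple[str, ...] = ALL_MODALITIES) -> dict[str, Volume]:
    """Compute the requested TBR and kinetic parametric images."""
    wanted = set(modalities)
    bg = subject.background_mask
    out: dict[str, Volume] = {}

    if "TBR_GE-180" in wanted:
        out["TBR_GE-180"] = compute_tbr(subject.static_tspo, bg)
    if "TBR_T1CE" in wanted:
        out["TBR_T1CE"] = compute_tbr(subject.t1ce, bg)
    if "TBR_T2" in wanted:
        out["TBR_T2"] = compute_tbr(subject.t2, bg)

    need_dyn_tbr = wanted & {"TBR_FET5-15", "TBR_FET20-40", "TTP_TBR", "Slope_TBR"}
    dyn = subject.dynamic_fet
    dyn_tbr = tbr_dynamic(dyn, bg) if need_dyn_tbr else None

    if "TBR_FET5-15" in wanted:
        out["TBR_FET5-15"] = static_average(dyn_tbr, (5, 15), "TBR_FET5-15")
    if "TBR_FET20-40" in wanted:
        out["TBR_FET20-40"] = static_average(dyn_tbr, (20, 40), "TBR_FET20-40")
    if "TTP_SUV" in wanted:
        out["TTP_SUV"] = compute_ttp_map(dyn)
    if "Slope_SUV" in wanted:
        out["Slope_SUV"] = compute_slope_map(dyn)
    if "TTP_TBR" in wanted:
        out["TTP_TBR"] = compute_ttp_map(dyn_tbr)
    if "Slope_TBR" in wanted:
        out["Slope_TBR"] = compute_slope_map(dyn_tbr)
    return out


def _modality_masks(subject: SubjectImages, maps: dict[str, Volume],
                    volume_mode: str, seg: SegmentationSpec) -> dict[str, Mask]:
    t2_mask = t2_volume_for(subject)
    if volume_mode == "t2":
        return {m: t2_mask for m in maps}
    if volume_mode != "modality":
        raise ValueError(f"unknown volume mode {volume_mode!r}")
    masks: dict[str, Mask] = {}
    conf = subject.confining_mask
    if any(m in maps for m in ("TBR_GE-180",)):
        masks["TBR_GE-180"] = isocontour_mask(maps["TBR_GE-180"], conf, seg)
    if any(m in maps for m in _FET_DERIVED):
        # the FET tumor volume is defined on the late static TBR image
        fet_tbr = maps.get("TBR_FET20-40")
        if fet_tbr is None:
            fet_tbr = static_average(
                tbr_dynamic(subject.dynamic_fet, subject.background_mask),
                (20, 40), "TBR_FET20-40",
            )
        fet_mask = isocontour_mask(fet_tbr, conf, seg)
        for m in _FET_DERIVED:
            if m in maps:
                masks[m] = fet_mask
    for m in _MRI:
        if m in maps:
            masks[m] = t2_mask
    return masks


def _crop_pair(volume: Volume, mask: Mask) -> ROI:
    nz = np.nonzero(mask.values)
    if len(nz[0]) == 0:
        return ROI(np.zeros((1, 1, 1)), np.zeros((1, 1, 1), bool), volume.spacing_mm)
    sl = tuple(slice(int(c.min()), int(c.max()) + 1) for c in nz)
    return ROI(volume.values[sl].copy(), mask.values[sl].copy(), volume.spacing_mm)


def subject_rois(
    subject: SubjectImages,
    volume_mode: str = "modality",
    modalities: tuple[str, ...] = ALL_MODALITIES,
    seg: SegmentationSpec = SegmentationSpec(),
    resampling: ResamplingSpec | None = None,
) -> SubjectROIs:
    """Derive maps and masks for one subject and crop them to ROIs."""
    maps = derive_maps(subject, modalities)
    masks = _modality_masks(subject, maps, volume_mode, seg)
    rois = {}
    for modality in modalities:
        vol, mask = maps[modality], masks[modality]
        if resampling is not None:
            vol = resample(vol, resampling)
            mask = resample(mask, resampling)
        rois[modality] = _crop_pair(vol, mask)
    return SubjectROIs(metadata=subject.metadata, rois=rois)


def cohort_feature_table(
    spec: CohortSpec,
    volume_mode: str = "modality",
    modalities: tuple[str, ...] = ALL_MODALITIES,
    seg: SegmentationSpec = SegmentationSpec(),
    resampling: ResamplingSpec | None = ResamplingSpec(),
    include_shape: bool = False,
    weights: tuple[float, float] = (0.6, 0.4),
    anchor: str = "roi_min",
) -> FeatureTable:
    """Generate the cohort, freeze bin widths, and extract the feature table.

    Subjects are generated one at a time and only cropped ROIs are kept, so
    cohort-scale runs stay in modest memory.
    """
    all_rois = [
        subject_rois(s, volume_mode, modalities, seg, resampling)
        for s in iter_cohort(spec)
    ]
    disc = freeze_discretization(all_rois, weights=weights, anchor=anchor,
                                 min_voxels=seg.min_voxels)
    return extract_feature_table(all_rois, disc, volume_mode, include_shape,
                                 min_voxels=seg.min_voxels)
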