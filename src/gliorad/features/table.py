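"""Cohort feature-table assembly.

One row per included subject; columns named ``<modality>__<family>__<feature>``
with the subject metadata (label, age, sex, ring enhancement) joined on.
Subjects whose tumor is not visible in a modality (mask below the
visibility floor) are excluded from that modality's columns and the
exclusion is logged in the table's exclusion record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import Mask, SubjectMetadata
from .discretize import DiscretizationSpec, discretize, weighted_bin_width
from .firstorder import first_order_features
from .shape import shape_features
from .texture import TEXTURE_FAMILIES, texture_features

logger = logging.getLogger(__name__)

__all__ = ["ROI", "SubjectROIs", "FeatureTable", "freeze_discretization",
           "extract_feature_table", "METADATA_COLUMNS"]

METADATA_COLUMNS = ("label", "age_years", "sex", "ring_enhancing")


@dataclass
class ROI:
    """A (cropped) image region paired with its mask, ready for extraction."""

    values: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class SubjectROIs:
    metadata: SubjectMetadata
    rois: dict[str, ROI]  # modality tag -> ROI


@dataclass
class FeatureTable:
    data: pd.DataFrame
    volume_mode: str
    disc: DiscretizationSpec
    exclusions: list[dict] = field(default_factory=list)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if "__" in c]

    def modality_columns(self, modality: str) -> list[str]:
        return [c for c in self.feature_columns if c.startswith(f"{modality}__")]


#: Time-to-peak maps take only the six eligible frame-midpoint values, so an
#: IQR-based width degenerates; their bin width is fixed a priori at 5.1 min,
#: which keeps all six acquisition categories in distinct bins.
TTP_BIN_WIDTH_MIN = 5.1
DEFAULT_FIXED_WIDTHS = {"TTP_SUV": TTP_BIN_WIDTH_MIN, "TTP_TBR": TTP_BIN_WIDTH_MIN}


def freeze_discretization(
    subject_rois: list[SubjectROIs],
    weights: tuple[float, float] = (0.6, 0.4),
    anchor: str = "roi_min",
    min_voxels: int = 10,
    fixed_widths: dict[str, float] | None = None,
) -> DiscretizationSpec:
    """Fix one bin width per modality from class-averaged ROI IQR / 4.

    Uses subject-wise ROI interquartile ranges averaged within each class,
    combined with the prevalence weights. Computed once on the full cohort
    and treated as fixed preprocessing (the widths depend on both classes'
    intensity distributions, so they cannot be refit inside CV folds).
    Modalities listed in ``fixed_widths`` (by default the TTP maps, at
    5.1 min) bypass the IQR rule.
    """
    if fixed_widths is None:
        fixed_widths = dict(DEFAULT_FIXED_WIDTHS)
    iqrs: dict[str, dict[str, list[float]]] = {}
    for srec in subject_rois:
        for modality, roi in srec.rois.items():
            if modality in fixed_widths or roi.n_voxels < min_voxels:
                continue
            vals = roi.masked_values()
            q75, q25 = np.percentile(vals, [75, 25])
            iqrs.setdefault(modality, {"IDH_wildtype": [], "IDH_mutant": []})[
                srec.metadata.label
            ].append(float(q75 - q25))
    widths = {m: w for m, w in fixed_widths.items()
              if any(m in s.rois for s in subject_rois)}
    for modality, per_class in iqrs.items():
        widths[modality] = weighted_bin_width(
            per_class["IDH_wildtype"], per_class["IDH_mutant"], weights
        )
    return DiscretizationSpec(bin_width=widths, class_weights=weights, anchor=anchor)


def compute_roi_features(
    roi: ROI,
    bin_width: float,
    anchor: str = "roi_min",
    include_shape: bool = False,
) -> dict[str, float]:
    """First-order + texture (+ shape) features of one ROI, flat-named."""
    vals = roi.masked_values()
    voxel_volume = float(np.prod(roi.spacing_mm))
    out = {}
    for name, v in first_order_features(vals, bin_width, voxel_volume, anchor).items():
        out[f"firstorder__{name}"] = v
    levels_flat, _ = discretize(vals, bin_width, anchor)
    grid = np.zeros(roi.mask.shape, dtype=np.int64)
    grid[roi.mask] = levels_flat
    for family in TEXTURE_FAMILIES:
        for name, v in texture_features(grid, family).items():
            out[f"{family}__{name}"] = v
    if include_shape:
        mask = Mask(roi.mask, roi.spacing_mm, provenance="modality_isocontour")
        for name, v in shape_features(mask).items():
            out[f"shape__{name}"] = v
    return out


def extract_feature_table(
    subject_rois: list[SubjectROIs],
    disc: DiscretizationSpec,
    volume_mode: str = "modality",
    include_shape: bool = False,
    min_voxels: int = 10,
) -> FeatureTable:
    """Assemble the cohort feature table; deterministic given its inputs.

    Discretization widths must be frozen in ``disc`` beforehand. Rows with
    a sub-threshold mask in some modality get NaN in that modality's
    columns (and the exclusion is logged); a subject visible nowhere is
    dropped entirely.
    """
    seen: set[str] = set()
    exclusions: list[dict] = []
    rows = []
    for srec in subject_rois:
        meta = srec.metadata
        if meta.subject_id in seen:
            raise ValueError(f"duplicate subject id {meta.subject_id!r}")
        seen.add(meta.subject_id)
        row: dict[str, object] = {
            "subject_id": meta.subject_id,
            "label": meta.label,
            "age_years": meta.age_years,
            "sex": meta.sex,
            "ring_enhancing": meta.ring_enhancing,
        }
        any_visible = False
        for modality, roi in srec.rois.items():
            if roi.n_voxels < min_voxels:
                exclusions.append(
                    {"subject_id": meta.subject_id, "modality": modality,
                     "n_voxels": roi.n_voxels, "reason": "tumor not visible"}
                )
                logger.info("excluding %s from %s (mask %d voxels < %d)",
                            meta.subject_id, modality, roi.n_voxels, min_voxels)
                continue
            any_visible = True
            feats = compute_roi_features(
                roi, disc.bin_width[modality], disc.anchor_for(modality), include_shape
            )
            for name, v in feats.items():
                row[f"{modality}__{name}"] = v
        if any_visible:
            rows.append(row)
    data = pd.DataFrame(rows)
    if data.columns.duplicated().any():
        raise ValueError("duplicate feature column names")
    return FeatureTable(data=data, volume_mode=volume_mode, disc=disc,
                        exclusions=exclusions)
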