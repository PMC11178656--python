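"""Core volumetric data model and NIfTI / table I/O.

All images belonging to one subject live on a single co-registered grid:
the same shape and voxel spacing. Registration across native grids is a
scanner-side preprocessing step and is deliberately not modelled here; the
constructors validate congruence instead.

Raw PET values are treated as arbitrary activity-concentration units.
Body-weight SUV scaling cancels in tumor-to-background ratios and does not
affect time-to-peak or slope signs, so it is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "ScheduleError",
    "VolumeIOError",
    "FrameSchedule",
    "Volume",
    "DynamicVolume",
    "Mask",
    "SubjectMetadata",
    "frame_midpoints",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_congruent",
    "FET_FRAME_DURATIONS_S",
]

#: Dynamic FET reconstruction frame durations in seconds:
#: 6 x 10 s, 4 x 30 s, 1 x 2 min, 3 x 5 min, 2 x 10 min (0-40 min p.i.).
FET_FRAME_DURATIONS_S: tuple[float, ...] = (
    (10.0,) * 6 + (30.0,) * 4 + (120.0,) + (300.0,) * 3 + (600.0,) * 2
)

#: Sentinel for voxels where a quantity is undefined (e.g. outside a
#: restriction mask in a parametric map).
INVALID_VOXEL = np.nan


class ScheduleError(ValueError):
    """A frame schedule violates contiguity/positivity invariants."""


class VolumeIOError(IOError):
    """A volume file or its sidecar schedule is inconsistent."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered reconstruction frames (start_s, end_s) in seconds.

    Invariants: frames are contiguous and non-overlapping
    (``end_i == start_{i+1}``), the first frame starts at 0 and every
    duration is positive.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ScheduleError("schedule has no frames")
        frames = tuple((float(s), float(e)) for s, e in self.frames)
        object.__setattr__(self, "frames", frames)
        if frames[0][0] != 0.0:
            raise ScheduleError(f"first frame starts at {frames[0][0]} s, expected 0")
        for i, (start, end) in enumerate(frames):
            if not end > start:
                raise ScheduleError(f"frame {i} has non-positive duration ({start}, {end})")
            if i > 0 and frames[i - 1][1] != start:
                raise ScheduleError(
                    f"frame {i} starts at {start} s but frame {i - 1} ends at {frames[i - 1][1]} s"
                )

    @classmethod
    def from_durations(cls, durations_s: Iterable[float]) -> "FrameSchedule":
        frames = []
        t = 0.0
        for d in durations_s:
            frames.append((t, t + float(d)))
            t += float(d)
        return cls(tuple(frames))

    @classmethod
    def fet_standard(cls) -> "FrameSchedule":
        """The 16-frame 0-40 min dynamic FET schedule."""
        return cls.from_durations(FET_FRAME_DURATIONS_S)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def total_seconds(self) -> float:
        return self.frames[-1][1]

    def midpoints_min(self) -> np.ndarray:
        """Frame midpoints in minutes, strictly increasing."""
        return np.array([(s + e) / 2.0 / 60.0 for s, e in self.frames])

    def to_dict(self) -> dict:
        return {"frames_s": [[s, e] for s, e in self.frames]}

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(tuple((s, e) for s, e in d["frames_s"]))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FrameSchedule":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Midpoint time of each frame, in minutes.

    The midpoint is the unbiased representative of a uniform-within-frame
    sample and is the time coordinate used by every kinetic computation.
    """
    return schedule.midpoints_min()


def _check_spacing(spacing_mm: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing_mm}")
    return spacing


@dataclass
class Volume:
    """A 3-D scalar grid with voxel spacing and a modality tag.

    ``modality_tag`` identifies the derivation, e.g. ``FET20-40``,
    ``TBR_GE-180``, ``TTP_SUV``, ``Slope_TBR``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"Volume requires a 3-D grid, got ndim={self.values.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class DynamicVolume:
    """A 4-D grid (3 spatial axes x frames) with its frame schedule."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    schedule: FrameSchedule
    modality_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 4:
            raise ValueError(f"DynamicVolume requires a 4-D grid, got ndim={self.values.ndim}")
        if self.values.shape[3] != self.schedule.n_frames:
            raise VolumeIOError(
                f"4th axis has {self.values.shape[3]} frames but the schedule "
                f"defines {self.schedule.n_frames}"
            )
        self.spacing_mm = _check_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape[:3]

    def frame(self, i: int) -> np.ndarray:
        return self.values[..., i]


MASK_PROVENANCES = ("modality_isocontour", "t2_whole_tumor", "confining", "background")


@dataclass
class Mask:
    """A binary 3-D grid tagged with how it was produced."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"Mask requires a 3-D grid, got ndim={self.values.ndim}")
        self.spacing_mm = _check_spacing(self.spacing_mm)
        if self.provenance not in MASK_PROVENANCES:
            raise ValueError(
                f"unknown mask provenance {self.provenance!r}; expected one of {MASK_PROVENANCES}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


LABELS = ("IDH_wildtype", "IDH_mutant")


@dataclass
class SubjectMetadata:
    subject_id: str
    label: str
    age_years: float
    sex: str
    ring_enhancing: bool

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.sex not in ("f", "m"):
            raise ValueError(f"sex must be 'f' or 'm', got {self.sex!r}")


def check_congruent(*images: Volume | DynamicVolume | Mask) -> None:
    """Raise if images do not share grid shape and spacing."""
    ref = images[0]
    for img in images[1:]:
        if img.shape != ref.shape:
            raise ValueError(f"grid shapes differ: {img.shape} vs {ref.shape}")
        if not np.allclose(img.spacing_mm, ref.spacing_mm, rtol=1e-6):
            raise ValueError(f"voxel spacings differ: {img.spacing_mm} vs {ref.spacing_mm}")


def _affine(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_volume(vol: Volume | DynamicVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), _affine(vol.spacing_mm))
    nib.save(img, str(path))


def read_volume(
    path: str | Path,
    schedule: FrameSchedule | None = None,
    modality_tag: str = "",
) -> Volume | DynamicVolume:
    """Read a NIfTI volume; a 4-D file requires a sidecar frame schedule.

    Raises ``VolumeIOError`` when the 4th axis length disagrees with the
    supplied schedule.
    """
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if values.ndim == 3:
        return Volume(values, spacing, modality_tag)
    if values.ndim == 4:
        if schedule is None:
            raise VolumeIOError(f"{path}: 4-D volume requires a frame schedule")
        if values.shape[3] != schedule.n_frames:
            raise VolumeIOError(
                f"{path}: axis 3 has {values.shape[3]} frames but the schedule "
                f"defines {schedule.n_frames}"
            )
        return DynamicVolume(values, spacing, schedule, modality_tag)
    raise VolumeIOError(f"{path}: expected 3-D or 4-D data, got ndim={values.ndim}")


def write_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing_mm))
    nib.save(img, str(path))


def read_mask(path: str | Path, provenance: str) -> Mask:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj) > 0
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Mask(values, spacing, provenance)
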