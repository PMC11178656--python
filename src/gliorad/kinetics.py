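"""Tumor-to-background ratio images and voxel-wise kinetic parametric maps.

Dynamic amino-acid PET is parametrized semi-quantitatively per voxel:

* **TTP** (time-to-peak): the time coordinate of the maximal time-activity
  curve (TAC) value after 3 min post-injection, excluding the initial
  blood-pool phase. A TAC that keeps rising to the end of the acquisition
  receives the final frame midpoint (it falls in the 30-40 min category).
* **Late slope**: the ordinary least-squares slope of the TAC over the last
  three reconstruction frames (15-40 min p.i.), expressed per hour.

Applying the slope/TTP operators to the raw dynamic volume yields the SUV
variants; applying them to the background-normalized dynamic volume yields
the TBR variants. All time coordinates are frame midpoints in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    INVALID_VOXEL,
    DynamicVolume,
    FrameSchedule,
    Mask,
    Volume,
    check_congruent,
)

__all__ = [
    "NormalizationError",
    "KineticComputationError",
    "BackgroundStats",
    "TTP_CATEGORY_EDGES_MIN",
    "compute_background_stats",
    "compute_tbr",
    "tbr_dynamic",
    "static_average",
    "compute_ttp_map",
    "compute_slope_map",
    "ttp_category",
    "ttp_category_label",
]


class NormalizationError(ValueError):
    """Background normalization is impossible (empty mask, nonpositive mean)."""


class KineticComputationError(ValueError):
    """The frame schedule does not support the requested kinetic quantity."""


#: Half-open TTP category edges in minutes: (0,5], (5,10], (10,15],
#: (15,20], (20,30], (30,40]. They coincide with frame boundaries of the
#: standard 0-40 min schedule.
TTP_CATEGORY_EDGES_MIN: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0)

TTP_CATEGORY_LABELS = ("<5 min", "5-10 min", "10-15 min", "15-20 min", "20-30 min", "30-40 min")

#: Minimum number of voxels accepted in a healthy-background region.
MIN_BACKGROUND_VOXELS = 50


@dataclass(frozen=True)
class BackgroundStats:
    """Mean healthy-background signal used for TBR normalization."""

    mean_background: float
    n_voxels: int


def compute_background_stats(
    volume: Volume, background_mask: Mask, min_voxels: int = MIN_BACKGROUND_VOXELS
) -> BackgroundStats:
    check_congruent(volume, background_mask)
    n = background_mask.n_voxels
    if n == 0:
        raise NormalizationError("background mask is empty")
    if n < min_voxels:
        raise NormalizationError(f"background mask has {n} voxels, below the floor of {min_voxels}")
    mean = float(volume.values[background_mask.values].mean())
    if mean <= 0:
        raise NormalizationError(f"background mean {mean} is not positive")
    return BackgroundStats(mean, n)


def compute_tbr(volume: Volume, background_mask: Mask,
                min_voxels: int = MIN_BACKGROUND_VOXELS) -> Volume:
    """Divide every voxel by the mean signal over the healthy background.

    The output's mean over the background mask equals 1 by construction, and
    the result is invariant to rescaling the input by any positive constant.
    """
    stats = compute_background_stats(volume, background_mask, min_voxels)
    tag = volume.modality_tag or "volume"
    return Volume(volume.values / stats.mean_background, volume.spacing_mm,
                  modality_tag=f"TBR_{tag}")


def tbr_dynamic(dyn: DynamicVolume, background_mask: Mask,
                min_voxels: int = MIN_BACKGROUND_VOXELS) -> DynamicVolume:
    """Background-normalize a dynamic volume frame by frame.

    Each frame is divided by its own background mean, so every frame of the
    output has background mean 1 (the background TAC is flattened; tumor
    TACs become TAC_TBR).
    """
    if background_mask.shape != dyn.shape:
        raise ValueError(f"grid shapes differ: {background_mask.shape} vs {dyn.shape}")
    out = np.empty_like(dyn.values)
    for i in range(dyn.schedule.n_frames):
        frame = Volume(dyn.values[..., i], dyn.spacing_mm)
        stats = compute_background_stats(frame, background_mask, min_voxels)
        out[..., i] = dyn.values[..., i] / stats.mean_background
    tag = dyn.modality_tag or "dyn"
    return DynamicVolume(out, dyn.spacing_mm, dyn.schedule, modality_tag=f"TBR_{tag}")


def static_average(dyn: DynamicVolume, window_min: tuple[float, float],
                   modality_tag: str = "") -> Volume:
    """Frame-duration-weighted time average over an acquisition window.

    Used for the early (5-15 min) and late (20-40 min) summation images.
    Frames are included when fully inside the window.
    """
    lo, hi = (60.0 * window_min[0], 60.0 * window_min[1])
    idx = [i for i, (s, e) in enumerate(dyn.schedule.frames) if s >= lo and e <= hi]
    if not idx:
        raise KineticComputationError(f"no frames fall inside window {window_min} min")
    durations = np.array([dyn.schedule.frames[i][1] - dyn.schedule.frames[i][0] for i in idx])
    weights = durations / durations.sum()
    values = np.tensordot(dyn.values[..., idx], weights, axes=([3], [0]))
    tag = modality_tag or f"{dyn.modality_tag}{window_min[0]:g}-{window_min[1]:g}"
    return Volume(values, dyn.spacing_mm, modality_tag=tag)


def _late_frame_indices(schedule: FrameSchedule, cutoff_min: float) -> np.ndarray:
    mid = schedule.midpoints_min()
    return np.nonzero(mid > cutoff_min)[0]


def compute_ttp_map(dyn: DynamicVolume, restrict: Mask | None = None,
                    cutoff_min: float = 3.0) -> Volume:
    """Voxel-wise time-to-peak in minutes.

    Only frames whose midpoint lies after ``cutoff_min`` are candidates
    (excluding the initial blood-pool frames); ties break toward the
    earliest frame; a curve that is maximal at the final frame receives the
    final midpoint. Voxels outside ``restrict`` are set to NaN.
    """
    idx = _late_frame_indices(dyn.schedule, cutoff_min)
    if len(idx) < 2:
        raise KineticComputationError(
            f"schedule has {len(idx)} frames with midpoint > {cutoff_min} min; need >= 2"
        )
    mids = dyn.schedule.midpoints_min()[idx]
    late = dyn.values[..., idx]
    # argmax returns the first occurrence -> earliest-frame tie-break
    ttp = mids[np.argmax(late, axis=-1)]
    if restrict is not None:
        check_congruent(dyn, restrict)
        ttp = np.where(restrict.values, ttp, INVALID_VOXEL)
    return Volume(ttp, dyn.spacing_mm, modality_tag=_paramtag(dyn, "TTP"))


def compute_slope_map(dyn: DynamicVolume, restrict: Mask | None = None,
                      n_last_frames: int = 3) -> Volume:
    """Voxel-wise OLS slope over the last ``n_last_frames`` frames, per hour."""
    if dyn.schedule.n_frames < n_last_frames:
        raise KineticComputationError(
            f"schedule has {dyn.schedule.n_frames} frames; need >= {n_last_frames}"
        )
    t_h = dyn.schedule.midpoints_min()[-n_last_frames:] / 60.0
    y = dyn.values[..., -n_last_frames:]
    t_c = t_h - t_h.mean()
    slope = np.tensordot(y, t_c, axes=([3], [0])) / np.sum(t_c**2)
    if restrict is not None:
        check_congruent(dyn, restrict)
        slope = np.where(restrict.values, slope, INVALID_VOXEL)
    return Volume(slope, dyn.spacing_mm, modality_tag=_paramtag(dyn, "Slope"))


def _paramtag(dyn: DynamicVolume, kind: str) -> str:
    suffix = "TBR" if dyn.modality_tag.startswith("TBR") else "SUV"
    return f"{kind}_{suffix}"


def ttp_category(ttp_minutes: float,
                 edges: tuple[float, ...] = TTP_CATEGORY_EDGES_MIN) -> int:
    """Map a TTP value to its half-open category index ``(edges[i], edges[i+1]]``."""
    t = float(ttp_minutes)
    if not edges[0] < t <= edges[-1]:
        raise ValueError(f"TTP {t} min outside ({edges[0]}, {edges[-1]}]")
    return int(np.searchsorted(np.asarray(edges), t, side="left")) - 1


def ttp_category_label(ttp_minutes: float) -> str:
    return TTP_CATEGORY_LABELS[ttp_category(ttp_minutes)]
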