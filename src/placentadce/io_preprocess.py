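"""Imaging I/O and pre-analysis filtering.

Volumes travel as NIfTI-1 files with a JSON sidecar carrying the acquisition
metadata (frame interval, injection frame, TR/TE, flip angle, voxel size).
Before any quantitative mapping, the dynamic series is cleaned with a
per-voxel temporal median filter plus 1-D grayscale morphological closing
along time (suppresses respiration spikes and transient mis-registrations),
and each frame is smoothed with a 3x3x3 spatial median.  A mean-removed
maximum-intensity projection over the uptake phase serves as the reference
image for segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from pydantic import BaseModel, field_validator, model_validator
from scipy import ndimage

from .errors import (
    GridMismatchError,
    InvalidInputError,
    InvalidParameterError,
    MetadataError,
)

__all__ = [
    "AcquisitionMeta",
    "DCESeries",
    "SegmentationLabelMap",
    "load_series",
    "save_series",
    "load_label_map",
    "save_map",
    "load_map",
    "temporal_denoise",
    "spatial_median3",
    "mean_removed_mip",
]


class AcquisitionMeta(BaseModel):
    """Acquisition metadata for one dynamic series.

    ``injection_frame`` is the 0-based index of the first post-injection
    frame; the bolus is administered between ``injection_frame - 1`` and
    ``injection_frame``.
    """

    frame_interval: float  # seconds between frames
    injection_frame: int
    tr_ms: float
    te_ms: float
    flip_angle_deg: float
    voxel_size: tuple[float, float, float]  # mm
    n_slices: int
    n_frames: int

    @field_validator("frame_interval", "tr_ms")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @model_validator(mode="after")
    def _frame_bounds(self) -> "AcquisitionMeta":
        if not (1 <= self.injection_frame < self.n_frames):
            raise ValueError(
                f"injection_frame {self.injection_frame} outside [1, {self.n_frames})"
            )
        return self

    @property
    def voxel_volume_ml(self) -> float:
        vx, vy, vz = self.voxel_size
        return float(vx * vy * vz) / 1000.0  # mm^3 -> mL

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class DCESeries:
    """4-D dynamic contrast-enhanced series, axes (x, y, slice, frame)."""

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidInputError(f"expected 4-D array, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("series contains non-finite values")
        nx, ny, nz, nt = self.data.shape
        if nz != self.meta.n_slices or nt != self.meta.n_frames:
            raise GridMismatchError(
                f"data shape {self.data.shape} inconsistent with metadata "
                f"(n_slices={self.meta.n_slices}, n_frames={self.meta.n_frames})"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "DCESeries":
        return DCESeries(data=data, meta=self.meta)


@dataclass
class SegmentationLabelMap:
    """Integer label volume plus a table mapping label -> role.

    Roles are ``"placenta"``, ``"aif"`` or ``"background"``; label 0 is
    implicitly background.
    """

    labels: np.ndarray
    roles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidInputError("label map must be an integer volume")
        if self.labels.min() < 0:
            raise InvalidInputError("label map contains negative labels")

    @property
    def placenta_labels(self) -> list[int]:
        return sorted(k for k, v in self.roles.items() if v == "placenta")

    @property
    def aif_label(self) -> int | None:
        for k, v in self.roles.items():
            if v == "aif":
                return k
        return None

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------

_REQUIRED_SIDECAR_KEYS = (
    "frame_interval",
    "injection_frame",
    "tr_ms",
    "te_ms",
    "flip_angle_deg",
    "voxel_size",
    "n_slices",
    "n_frames",
)


def _affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([*voxel_size, 1.0])
    return aff


def save_series(series: DCESeries, path: str | Path, sidecar: str | Path) -> None:
    """Write a 4-D series as NIfTI plus a JSON metadata sidecar."""
    img = nib.Nifti1Image(series.data, _affine(series.meta.voxel_size))
    nib.save(img, str(path))
    Path(sidecar).write_text(json.dumps(series.meta.model_dump(), indent=2))


def load_series(path: str | Path, sidecar: str | Path) -> DCESeries:
    """Load a 4-D NIfTI series and its JSON sidecar into a :class:`DCESeries`."""
    raw = json.loads(Path(sidecar).read_text())
    missing = [k for k in _REQUIRED_SIDECAR_KEYS if k not in raw]
    if missing:
        raise MetadataError(f"sidecar {sidecar} missing keys: {missing}")
    meta = AcquisitionMeta(**{k: raw[k] for k in _REQUIRED_SIDECAR_KEYS})
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return DCESeries(data=data, meta=meta)


def save_map(
    volume: np.ndarray, path: str | Path, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> None:
    """Write a 3-D map (perfusion, R1, labels, ...) as NIfTI-1."""
    volume = np.asarray(volume)
    img = nib.Nifti1Image(volume, _affine(voxel_size))
    nib.save(img, str(path))


def load_map(path: str | Path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj)
    return arr


def save_label_map(
    label_map: SegmentationLabelMap,
    path: str | Path,
    roles_path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> None:
    img = nib.Nifti1Image(label_map.labels.astype(np.int16), _affine(voxel_size))
    nib.save(img, str(path))
    Path(roles_path).write_text(
        json.dumps({str(k): v for k, v in label_map.roles.items()}, indent=2)
    )


def load_label_map(path: str | Path, roles_path: str | Path) -> SegmentationLabelMap:
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    roles = {int(k): v for k, v in json.loads(Path(roles_path).read_text()).items()}
    return SegmentationLabelMap(labels=labels, roles=roles)


def check_grids(series: DCESeries, label_map: SegmentationLabelMap) -> None:
    if label_map.labels.shape != series.data.shape[:3]:
        raise GridMismatchError(
            f"label map grid {label_map.labels.shape} != series grid {series.data.shape[:3]}"
        )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _check_odd(name: str, value: int, n_frames: int) -> None:
    if value < 1 or value % 2 == 0:
        raise InvalidParameterError(f"{name} must be odd and >= 1, got {value}")
    if value > n_frames:
        raise InvalidParameterError(f"{name}={value} exceeds n_frames={n_frames}")


def temporal_denoise(
    series: DCESeries, time_window: int = 3, closing_length: int = 3
) -> DCESeries:
    """Temporal median filter followed by grayscale morphological closing.

    Both operate voxelwise along the frame axis with replicate edge padding.
    The median suppresses single-frame respiration spikes; the closing fills
    short downward dropouts from transient large translations.
    """
    nt = series.meta.n_frames
    _check_odd("time_window", time_window, nt)
    _check_odd("closing_length", closing_length, nt)
    out = series.data
    if time_window > 1:
        out = ndimage.median_filter(out, size=(1, 1, 1, time_window), mode="nearest")
    if closing_length > 1:
        out = ndimage.grey_closing(out, size=(1, 1, 1, closing_length), mode="nearest")
    return series.with_data(out)


def spatial_median3(volume: np.ndarray) -> np.ndarray:
    """3x3x3 spatial median with replicate edge padding.

    Accepts a single 3-D volume or a 4-D (x, y, slice, frame) series, in which
    case every frame is filtered independently.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim == 3:
        if min(volume.shape) < 3:
            raise InvalidInputError("need at least 3 voxels per spatial axis")
        return ndimage.median_filter(volume, size=(3, 3, 3), mode="nearest")
    if volume.ndim == 4:
        if min(volume.shape[:3]) < 3:
            raise InvalidInputError("need at least 3 voxels per spatial axis")
        return ndimage.median_filter(volume, size=(3, 3, 3, 1), mode="nearest")
    raise InvalidInputError(f"expected 3-D or 4-D array, got {volume.ndim}-D")


def preprocess_series(
    series: DCESeries, time_window: int = 3, closing_length: int = 3
) -> DCESeries:
    """Standard pre-analysis chain: temporal denoise then spatial 3x3x3 median."""
    out = temporal_denoise(series, time_window=time_window, closing_length=closing_length)
    return out.with_data(spatial_median3(out.data))


def mean_removed_mip(series: DCESeries, uptake_frames: tuple[int, int]) -> np.ndarray:
    """Mean-removed maximum intensity projection along time.

    ``uptake_frames`` is a half-open (start, stop) frame range over which the
    mean kinetic image is computed; the projection is, per voxel, the maximum
    over all frames of (signal - uptake mean).  Used as the segmentation
    reference image.
    """
    start, stop = uptake_frames
    nt = series.meta.n_frames
    if not (0 <= start < stop <= nt):
        raise InvalidParameterError(
            f"uptake_frames {uptake_frames} not a nonempty range within [0, {nt}]"
        )
    mean_kinetic = series.data[..., start:stop].mean(axis=-1)
    return (series.data - mean_kinetic[..., None]).max(axis=-1)
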