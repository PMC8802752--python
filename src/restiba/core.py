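"""Core in-memory containers shared across the pipeline.

A :class:`BoldSeries` is a masked 4D BOLD volume with its repetition time and a
set of provenance flags that record which temporal-preprocessing stages have
been applied.  The flags are monotone: a stage never un-sets a flag acquired by
an earlier stage, and each stage checks the flags of its input so that the
canonical order (discard -> detrend -> nuisance regression -> band-pass) cannot
be violated silently.

A :class:`MetricMap` is a 3D per-voxel metric (ALFF, fALFF, PerAF, ReHo or DC)
with its own state flags for standardization and smoothing, mirroring the
order constraint that smoothing happens after metric computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BoldSeries",
    "MotionTrace",
    "MetricMap",
    "PipelineOrderError",
    "default_affine",
    "load_bold",
    "save_nifti",
    "load_mask",
]

METRIC_NAMES = ("ALFF", "fALFF", "PerAF", "ReHo", "DC")


class PipelineOrderError(RuntimeError):
    """Raised when a stage is applied to data in the wrong preprocessing state."""


def default_affine(voxel_size_mm: float | tuple[float, float, float] = 3.0) -> np.ndarray:
    """Diagonal affine for an isotropic (or per-axis) voxel size in mm."""
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (voxel_size_mm,) * 3  # type: ignore[assignment]
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm  # type: ignore[misc]
    return aff


@dataclass
class BoldSeries:
    """Masked 4D BOLD time series (x, y, z, t) with provenance flags.

    ``voxel_mean`` holds the per-voxel temporal mean captured just before
    detrending removes it; it is what the PerAF formula's mu refers to and is
    added back when PerAF is computed on the filtered series.
    """

    data: np.ndarray
    tr_s: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: default_affine(3.0))
    voxel_mean: np.ndarray | None = None
    volumes_discarded: bool = False
    detrended: bool = False
    nuisance_regressed: bool = False
    filtered: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[-1] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        if self.tr_s <= 0:
            raise ValueError("repetition time must be positive")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != spatial shape {self.data.shape[:3]}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3])

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def with_data(self, data: np.ndarray, **flag_updates) -> "BoldSeries":
        """Copy with new data and updated flags; flags may only be turned on."""
        for name, value in flag_updates.items():
            if getattr(self, name) and not value:
                raise PipelineOrderError(f"flag {name!r} cannot be un-set")
        return replace(self, data=np.asarray(data, dtype=np.float64), **flag_updates)


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 3 translations (mm), 3 rotations (radians)."""

    params: np.ndarray  # (n_volumes, 6)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion parameters must have shape (n_volumes, 6)")
        if self.params.shape[0] < 1:
            raise ValueError("motion trace must cover at least one volume")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]

    def discard_initial(self, n_discard: int) -> "MotionTrace":
        if n_discard >= self.n_volumes:
            raise ValueError("cannot discard all volumes of a motion trace")
        return MotionTrace(self.params[n_discard:])

    @classmethod
    def from_file(cls, path: str | Path) -> "MotionTrace":
        return cls(np.loadtxt(path, ndmin=2))

    def to_file(self, path: str | Path) -> None:
        np.savetxt(path, self.params, fmt="%.10e")


@dataclass
class MetricMap:
    """3D per-voxel metric map with standardization/smoothing state."""

    data: np.ndarray
    name: str
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: default_affine(3.0))
    standardized: bool = False
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("metric map must be 3D")
        if self.mask.shape != self.data.shape:
            raise ValueError("metric mask shape must match data shape")
        if self.name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.name!r}; expected one of {METRIC_NAMES}")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.abs(np.diag(self.affine)[:3])

    def in_mask(self) -> np.ndarray:
        return self.data[self.mask]

    def suffix(self) -> str:
        """File-name suffix encoding the map state, e.g. ``ALFF_std_sm``."""
        s = self.name
        if self.standardized:
            s += "_std"
        if self.smoothed:
            s += "_sm"
        return s


# ---------------------------------------------------------------------------
# NIfTI round-trips (nibabel)
# ---------------------------------------------------------------------------

def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_bold(path: str | Path, tr_s: float, mask: np.ndarray, **flags) -> BoldSeries:
    img = nib.load(str(path))
    return BoldSeries(np.asarray(img.dataobj, dtype=np.float64), tr_s, mask,
                      affine=img.affine, **flags)


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0.5
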