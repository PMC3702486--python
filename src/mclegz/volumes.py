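"""Shared image containers: geometry, label/intensity volumes, TI series, fit maps.

All volumes are plain 3D numpy arrays indexed ``(x, y, slice)`` with 0-based
voxel indices; physical units are millimetres in-plane and through-plane and
milliseconds for times.  Containers validate their own invariants on
construction so downstream stages can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class Tissue(IntEnum):
    """Voxel tissue classes used by both ground-truth labels and classifiers."""

    BACKGROUND = 0
    BLOOD = 1
    HEALTHY = 2
    GRAY_ZONE = 3
    CORE = 4
    PM_HEALTHY = 5
    PM_INFARCT = 6
    EXCLUDED = 7  # classification output only: unfittable / out-of-mask voxels


#: Labels that make up the LV-wall myocardium (papillary muscles excluded).
MYOCARDIUM_LABELS = (Tissue.HEALTHY, Tissue.GRAY_ZONE, Tissue.CORE)


@dataclass(frozen=True)
class Geometry:
    """Voxel geometry: isotropic in-plane resolution and slice thickness, in mm."""

    resolution: float = 1.5
    slice_thickness: float = 8.0

    def __post_init__(self) -> None:
        if self.resolution <= 0 or self.slice_thickness <= 0:
            raise ValueError("resolution and slice_thickness must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.resolution * self.resolution * self.slice_thickness

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def affine(self) -> np.ndarray:
        """NIfTI-style affine mapping voxel indices to mm coordinates."""
        return np.diag([self.resolution, self.resolution, self.slice_thickness, 1.0])


def _as_3d(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 3:
        raise ValueError(f"{name} must be a 3D array, got shape {a.shape}")
    return a


@dataclass
class ImageVolume:
    """A single real-valued intensity volume (arbitrary units)."""

    data: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.data = _as_3d(self.data, "data").astype(float, copy=False)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """Integer tissue label per voxel plus geometry.

    Every voxel carries exactly one label; the myocardium is the union of
    healthy, gray-zone and core labels and is disjoint from blood and
    background by construction of the label code.
    """

    labels: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.labels = _as_3d(self.labels, "labels").astype(np.int16, copy=False)
        valid_codes = {int(t) for t in Tissue}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid_codes:
            raise ValueError(f"unknown label codes: {sorted(present - valid_codes)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *tissues: Tissue) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        for t in tissues:
            out |= self.labels == int(t)
        return out

    @property
    def myocardium_mask(self) -> np.ndarray:
        return self.mask(*MYOCARDIUM_LABELS)

    @property
    def blood_mask(self) -> np.ndarray:
        return self.mask(Tissue.BLOOD)

    @property
    def pm_mask(self) -> np.ndarray:
        return self.mask(Tissue.PM_HEALTHY, Tissue.PM_INFARCT)

    def counts(self) -> dict[Tissue, int]:
        return {t: int(np.sum(self.labels == int(t))) for t in Tissue}


@dataclass
class MCLESeries:
    """Stack of co-registered volumes acquired at strictly increasing inversion times.

    ``data`` is 4D, ``(x, y, slice, frame)``, one frame per TI (ms).
    """

    data: np.ndarray
    tis: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.tis = np.asarray(self.tis, dtype=float).ravel()
        if self.data.ndim != 4:
            raise ValueError(f"series data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] != self.tis.size:
            raise ValueError("need exactly one TI per frame")
        if self.tis.size == 0:
            raise ValueError("series must contain at least one frame")
        if np.any(np.diff(self.tis) <= 0):
            raise ValueError("inversion times must be strictly increasing")
        if np.any(self.tis <= 0):
            raise ValueError("inversion times must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.tis.size

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def frame(self, i: int) -> ImageVolume:
        return ImageVolume(self.data[..., i], self.geometry)


@dataclass
class ParameterMaps:
    """Per-voxel inversion-recovery parameters.

    The signal model is ``S(t) = A - B * exp(-t / T1*)``: ``a`` is the
    steady-state amplitude the voxel recovers toward, ``b`` the inversion
    depth (2A for a perfect inversion) and ``t1star`` the apparent relaxation
    time in ms under the readout.  ``valid`` marks voxels with a trustworthy
    fit; maps are NaN outside it.
    """

    t1star: np.ndarray
    a: np.ndarray
    b: np.ndarray
    residual_rms: np.ndarray
    valid: np.ndarray
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        self.t1star = _as_3d(self.t1star, "t1star").astype(float, copy=False)
        self.a = _as_3d(self.a, "a").astype(float, copy=False)
        self.b = _as_3d(self.b, "b").astype(float, copy=False)
        self.residual_rms = _as_3d(self.residual_rms, "residual_rms").astype(
            float, copy=False
        )
        self.valid = _as_3d(self.valid, "valid").astype(bool, copy=False)
        shapes = {
            self.t1star.shape,
            self.a.shape,
            self.b.shape,
            self.residual_rms.shape,
            self.valid.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")
        v = self.valid
        if np.any(self.t1star[v] <= 0):
            raise ValueError("T1* must be positive wherever valid")
        if not np.all(np.isfinite(self.a[v])):
            raise ValueError("A must be finite wherever valid")
        if np.any(self.residual_rms[v] < 0):
            raise ValueError("residual RMS must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1star.shape


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom
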