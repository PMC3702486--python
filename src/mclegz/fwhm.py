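"""Full-width-half-maximum infarct-heterogeneity segmentation for conventional LGE.

Given a single late-enhancement magnitude image, a myocardium mask and a
remote healthy-myocardium ROI, the candidate infarct is every myocardial
voxel brighter than the remote peak; the infarct core is everything above
half the candidate region's peak intensity, and the gray zone is the band
between the remote peak and that half-maximum cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volumes import ImageVolume

__all__ = ["RemoteROIStats", "FWHMResult", "remote_stats", "fwhm_segment"]


@dataclass(frozen=True)
class RemoteROIStats:
    """Mean, peak and standard deviation of remote healthy-myocardium signal."""

    mean: float
    peak: float
    sd: float

    def __post_init__(self) -> None:
        if self.peak < self.mean:
            raise ValueError("remote peak cannot be below the remote mean")
        if self.sd < 0:
            raise ValueError("remote sd must be >= 0")


@dataclass
class FWHMResult:
    """Core / gray-zone masks plus the thresholds that produced them.

    ``peak_infarct`` is NaN and ``empty`` is True when no myocardial voxel
    exceeds the remote peak (no detectable enhancement).
    """

    core: np.ndarray
    gray_zone: np.ndarray
    peak_infarct: float
    peak_remote: float
    core_threshold: float = field(default=np.nan)
    empty: bool = False

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=bool)
        self.gray_zone = np.asarray(self.gray_zone, dtype=bool)
        if np.logical_and(self.core, self.gray_zone).any():
            raise ValueError("core and gray zone must be disjoint")


def remote_stats(
    image: ImageVolume | np.ndarray, remote_roi: np.ndarray, ddof: int = 1
) -> RemoteROIStats:
    """Signal statistics over the remote ROI.

    The standard deviation uses the sample convention (``ddof=1``), matching
    the mean ± SD reporting of cohort tables; a single-voxel ROI degrades to
    sd 0 with a warning.
    """
    data = image.data if isinstance(image, ImageVolume) else np.asarray(image, dtype=float)
    roi = np.asarray(remote_roi, dtype=bool)
    if roi.shape != data.shape:
        raise ValueError("ROI shape must match the image")
    vals = data[roi]
    if vals.size == 0:
        raise ValueError("remote ROI is empty")
    if vals.size == 1:
        warnings.warn("remote ROI contains a single voxel; sd set to 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(vals, ddof=ddof))
    return RemoteROIStats(mean=float(np.mean(vals)), peak=float(np.max(vals)), sd=sd)


def fwhm_segment(
    image: ImageVolume | np.ndarray,
    myo_mask: np.ndarray,
    stats: RemoteROIStats,
    gz_upper_inclusive: bool = True,
) -> FWHMResult:
    """Apply the FWHM core / gray-zone thresholds within the myocardium.

    Rules (SI = voxel signal intensity):

    * candidate infarct: myocardial voxels with SI > ``stats.peak`` (strict)
    * ``peak_infarct``: max SI over the candidate region
    * core: SI > 0.5 * peak_infarct (strict)
    * gray zone: peak_remote < SI <= 0.5 * peak_infarct; the upper bound is
      inclusive by default so the exact half-maximum voxel falls in the gray
      zone (set ``gz_upper_inclusive=False`` for a strict upper bound, which
      leaves that voxel healthy).

    An empty candidate region returns empty masks with ``empty=True`` and an
    undefined (NaN) peak.
    """
    data = image.data if isinstance(image, ImageVolume) else np.asarray(image, dtype=float)
    myo = np.asarray(myo_mask, dtype=bool)
    if myo.shape != data.shape:
        raise ValueError("myocardium mask shape must match the image")
    if not myo.any():
        raise ValueError("myocardium mask is empty")

    candidate = myo & (data > stats.peak)
    if not candidate.any():
        z = np.zeros_like(myo)
        return FWHMResult(
            core=z,
            gray_zone=z.copy(),
            peak_infarct=float("nan"),
            peak_remote=stats.peak,
            core_threshold=float("nan"),
            empty=True,
        )
    peak_infarct = float(data[candidate].max())
    half = 0.5 * peak_infarct
    core = myo & (data > half)
    if gz_upper_inclusive:
        gz = myo & (data > stats.peak) & (data <= half)
    else:
        gz = myo & (data > stats.peak) & (data < half)
    return FWHMResult(
        core=core,
        gray_zone=gz,
        peak_infarct=peak_infarct,
        peak_remote=stats.peak,
        core_threshold=half,
    )
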