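"""Mass, percentage, papillary-muscle-score and LV-function quantification.

Masses are voxel counts times voxel volume times myocardial density
(1.05 g/cm3, the standard CMR convention); heterogeneity measures are
expressed in grams and as percentages of LV myocardial mass.  Papillary
muscles are scored 2/1/0 by how many of the two are infarcted, either from
a classified tissue map (fraction of PM voxels labeled core or gray zone)
or from enhancement intensities (mean PM signal at or above the core
threshold).  LV volumes use summation of disks over short-axis slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fwhm import FWHMResult
from .volumes import Geometry, LabelVolume, Tissue

__all__ = [
    "MYOCARDIAL_DENSITY_G_PER_CM3",
    "tissue_mass",
    "HeterogeneityMeasures",
    "heterogeneity",
    "heterogeneity_from_classmap",
    "heterogeneity_from_fwhm",
    "PMScore",
    "pm_score_from_classmap",
    "pm_score_from_image",
    "LVFunction",
    "lv_function",
]

MYOCARDIAL_DENSITY_G_PER_CM3 = 1.05


def tissue_mass(
    mask: np.ndarray, geometry: Geometry, density: float = MYOCARDIAL_DENSITY_G_PER_CM3
) -> float:
    """Mass in grams of a boolean voxel mask."""
    count = int(np.asarray(mask, dtype=bool).sum())
    return count * geometry.voxel_volume_cm3 * density


@dataclass(frozen=True)
class HeterogeneityMeasures:
    """Core / gray-zone / total infarct masses and their % of LV mass."""

    core_g: float
    gz_g: float
    total_g: float
    lvm_g: float
    core_pct: float
    gz_pct: float
    total_pct: float

    def __post_init__(self) -> None:
        if abs(self.total_g - (self.core_g + self.gz_g)) > 1e-9:
            raise ValueError("total mass must equal core + gray zone")
        for v in (self.core_g, self.gz_g, self.lvm_g):
            if v < 0:
                raise ValueError("masses must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return {
            "core_g": self.core_g,
            "gz_g": self.gz_g,
            "total_g": self.total_g,
            "lvm_g": self.lvm_g,
            "core_pct": self.core_pct,
            "gz_pct": self.gz_pct,
            "total_pct": self.total_pct,
        }


def heterogeneity(
    core_mask: np.ndarray,
    gz_mask: np.ndarray,
    myo_mask: np.ndarray,
    geometry: Geometry,
    density: float = MYOCARDIAL_DENSITY_G_PER_CM3,
) -> HeterogeneityMeasures:
    """Masses and LV-mass percentages from core/gray-zone/myocardium masks.

    The gray zone counts toward the total infarct and toward LV mass.  The
    masks must be disjoint and contained in the myocardium.
    """
    core = np.asarray(core_mask, dtype=bool)
    gz = np.asarray(gz_mask, dtype=bool)
    myo = np.asarray(myo_mask, dtype=bool)
    if (core & gz).any():
        raise ValueError("core and gray-zone masks must be disjoint")
    if (core & ~myo).any() or (gz & ~myo).any():
        raise ValueError("core and gray zone must lie within the myocardium")
    lvm = tissue_mass(myo, geometry, density)
    if lvm <= 0:
        raise ValueError("LV myocardial mass is zero")
    core_g = tissue_mass(core, geometry, density)
    gz_g = tissue_mass(gz, geometry, density)
    return HeterogeneityMeasures(
        core_g=core_g,
        gz_g=gz_g,
        total_g=core_g + gz_g,
        lvm_g=lvm,
        core_pct=100.0 * core_g / lvm,
        gz_pct=100.0 * gz_g / lvm,
        total_pct=100.0 * (core_g + gz_g) / lvm,
    )


def heterogeneity_from_classmap(
    classmap: LabelVolume,
    myo_mask: np.ndarray,
    density: float = MYOCARDIAL_DENSITY_G_PER_CM3,
) -> HeterogeneityMeasures:
    """Heterogeneity measures from a classified tissue map.

    ``myo_mask`` defines the LV wall (the denominator); core and gray zone
    are the classified voxels of those labels inside it.
    """
    myo = np.asarray(myo_mask, dtype=bool)
    core = classmap.mask(Tissue.CORE) & myo
    gz = classmap.mask(Tissue.GRAY_ZONE) & myo
    return heterogeneity(core, gz, myo, classmap.geometry, density)


def heterogeneity_from_fwhm(
    result: FWHMResult,
    myo_mask: np.ndarray,
    geometry: Geometry,
    density: float = MYOCARDIAL_DENSITY_G_PER_CM3,
) -> HeterogeneityMeasures:
    myo = np.asarray(myo_mask, dtype=bool)
    return heterogeneity(result.core & myo, result.gray_zone & myo, myo, geometry, density)


@dataclass(frozen=True)
class PMScore:
    """Papillary-muscle infarct score: number of infarcted PMs (0, 1 or 2)."""

    score: int
    infarcted: tuple[bool, bool]
    fractions: tuple[float, float]

    def __post_init__(self) -> None:
        if self.score != sum(self.infarcted):
            raise ValueError("score must equal the number of infarcted PMs")


def _pm_pair(pm_masks: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if len(pm_masks) != 2:
        raise ValueError("exactly two papillary-muscle masks are required")
    return np.asarray(pm_masks[0], dtype=bool), np.asarray(pm_masks[1], dtype=bool)


def pm_score_from_classmap(
    classmap: LabelVolume,
    pm_masks: Sequence[np.ndarray],
    infarct_fraction_threshold: float = 0.5,
) -> PMScore:
    """Score PMs from a classified map.

    A papillary muscle counts as infarcted when at least
    ``infarct_fraction_threshold`` (inclusive) of its voxels are classified
    core or gray zone.  An empty PM mask scores not-infarcted with a warning.
    """
    infarct = classmap.mask(Tissue.CORE, Tissue.GRAY_ZONE, Tissue.PM_INFARCT)
    flags, fracs = [], []
    for i, pm in enumerate(_pm_pair(pm_masks)):
        n = int(pm.sum())
        if n == 0:
            warnings.warn(f"papillary muscle mask {i} is empty; scored 0", stacklevel=2)
            flags.append(False)
            fracs.append(0.0)
            continue
        frac = float((infarct & pm).sum()) / n
        flags.append(frac >= infarct_fraction_threshold)
        fracs.append(frac)
    return PMScore(score=int(sum(flags)), infarcted=tuple(flags), fractions=tuple(fracs))


def pm_score_from_image(
    image: np.ndarray,
    pm_masks: Sequence[np.ndarray],
    peak_infarct: float,
    factor: float = 0.5,
) -> PMScore:
    """Score PMs from enhancement intensities.

    Operationalizes "enhancement similar to adjacent infarct": a PM counts
    as infarcted when its mean signal reaches ``factor * peak_infarct`` (the
    FWHM core threshold by default).  ``fractions`` reports mean PM signal
    relative to the infarct peak.
    """
    data = np.asarray(image, dtype=float)
    if not np.isfinite(peak_infarct) or peak_infarct <= 0:
        raise ValueError("peak_infarct must be positive and finite")
    flags, fracs = [], []
    for i, pm in enumerate(_pm_pair(pm_masks)):
        if not pm.any():
            warnings.warn(f"papillary muscle mask {i} is empty; scored 0", stacklevel=2)
            flags.append(False)
            fracs.append(0.0)
            continue
        mean_si = float(data[pm].mean())
        flags.append(mean_si >= factor * peak_infarct)
        fracs.append(mean_si / peak_infarct)
    return PMScore(score=int(sum(flags)), infarcted=tuple(flags), fractions=tuple(fracs))


@dataclass(frozen=True)
class LVFunction:
    """Global LV function: volumes in ml, EF in %, mass in g."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    lvm_g: float
    ed_phase: int
    es_phase: int

    def __post_init__(self) -> None:
        if abs(self.sv_ml - (self.edv_ml - self.esv_ml)) > 1e-9:
            raise ValueError("SV must equal EDV - ESV")
        if self.edv_ml <= 0:
            raise ValueError("EDV must be positive")


def lv_function(
    endo_masks: Sequence[np.ndarray],
    epi_mask_ed: np.ndarray,
    geometry: Geometry,
    density: float = MYOCARDIAL_DENSITY_G_PER_CM3,
) -> LVFunction:
    """Summation-of-disks LV volumes, EF and mass.

    ``endo_masks`` is one endocardial (cavity) mask per cardiac phase; the
    phase with the largest cavity volume is end-diastole, the smallest
    end-systole.  ``epi_mask_ed`` is the epicardial mask at end-diastole;
    LV mass is the epi-minus-endo shell volume there times density.
    """
    if len(endo_masks) < 2:
        raise ValueError("need at least two cardiac phases")
    vol_per_voxel_ml = geometry.voxel_volume_cm3  # 1 cm3 == 1 ml
    volumes = np.array(
        [int(np.asarray(m, dtype=bool).sum()) * vol_per_voxel_ml for m in endo_masks]
    )
    ed = int(np.argmax(volumes))
    es = int(np.argmin(volumes))
    edv, esv = float(volumes[ed]), float(volumes[es])
    if edv <= 0:
        raise ValueError("end-diastolic volume is zero; check the endocardial masks")
    epi = np.asarray(epi_mask_ed, dtype=bool)
    endo_ed = np.asarray(endo_masks[ed], dtype=bool)
    shell = epi & ~endo_ed
    lvm = tissue_mass(shell, geometry, density)
    sv = edv - esv
    return LVFunction(
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=sv,
        ef_pct=100.0 * sv / edv,
        lvm_g=lvm,
        ed_phase=ed,
        es_phase=es,
    )
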