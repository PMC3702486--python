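"""NIfTI / CSV / JSON readers and writers for the pipeline's containers.

Volumes travel as NIfTI with the geometry in the affine (in-plane
resolution and slice thickness on the diagonal); a multi-TI series is a 4D
NIfTI with its inversion-time list in a JSON sidecar next to it; cohort
tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import Geometry, ImageVolume, LabelVolume, MCLESeries, ParameterMaps

__all__ = [
    "save_image",
    "load_image",
    "save_labels",
    "load_labels",
    "save_series",
    "load_series",
    "save_maps",
    "load_maps",
    "save_cohort",
    "load_cohort",
]


def _geometry_from_affine(affine: np.ndarray) -> Geometry:
    res = float(abs(affine[0, 0]))
    thick = float(abs(affine[2, 2]))
    return Geometry(resolution=res, slice_thickness=thick)


def _check_path(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input path does not exist: {p}")
    return p


def save_image(image: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(image.data.astype(np.float64), image.geometry.affine()), str(path))


def load_image(path: str | Path) -> ImageVolume:
    img = nib.load(str(_check_path(path)))
    return ImageVolume(np.asarray(img.dataobj, dtype=float), _geometry_from_affine(img.affine))


def save_labels(volume: LabelVolume, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(volume.labels.astype(np.int16), volume.geometry.affine()), str(path)
    )


def load_labels(path: str | Path) -> LabelVolume:
    img = nib.load(str(_check_path(path)))
    return LabelVolume(
        np.asarray(img.dataobj).astype(np.int16), _geometry_from_affine(img.affine)
    )


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name.split(".")[0] + "_tis.json")


def save_series(series: MCLESeries, path: str | Path) -> None:
    """4D NIfTI plus a ``*_tis.json`` sidecar holding the TI list (ms)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(series.data.astype(np.float64), series.geometry.affine()), str(path))
    _sidecar(path).write_text(json.dumps({"inversion_times_ms": series.tis.tolist()}))


def load_series(path: str | Path, tis_path: str | Path | None = None) -> MCLESeries:
    path = _check_path(path)
    sidecar = Path(tis_path) if tis_path is not None else _sidecar(path)
    tis = json.loads(_check_path(sidecar).read_text())["inversion_times_ms"]
    img = nib.load(str(path))
    return MCLESeries(
        np.asarray(img.dataobj, dtype=float), np.asarray(tis), _geometry_from_affine(img.affine)
    )


def save_maps(maps: ParameterMaps, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = maps.geometry.affine()
    for name, arr, dtype in (
        ("t1star", maps.t1star, np.float64),
        ("steady_state", maps.a, np.float64),
        ("b", maps.b, np.float64),
        ("residual_rms", maps.residual_rms, np.float64),
        ("valid", maps.valid, np.uint8),
    ):
        nib.save(nib.Nifti1Image(arr.astype(dtype), aff), str(out / f"{name}.nii.gz"))


def load_maps(in_dir: str | Path) -> ParameterMaps:
    d = _check_path(in_dir)

    def arr(name):
        img = nib.load(str(_check_path(d / f"{name}.nii.gz")))
        return np.asarray(img.dataobj, dtype=float), img.affine

    t1, aff = arr("t1star")
    return ParameterMaps(
        t1star=t1,
        a=arr("steady_state")[0],
        b=arr("b")[0],
        residual_rms=arr("residual_rms")[0],
        valid=arr("valid")[0] > 0,
        geometry=_geometry_from_affine(aff),
    )


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(_check_path(path))
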