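"""Color-map rendering of classified tissue maps.

Convention: yellow = peri-infarct gray zone, green = core infarct,
red = blood pool, blue = healthy myocardium; background black, papillary
muscles share the blood-pool region coloring in ground-truth renders,
excluded voxels gray.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
import numpy as np

from .volumes import LabelVolume, Tissue

__all__ = ["CLASS_COLORS", "classmap_to_rgb", "render_classmap"]

CLASS_COLORS: dict[Tissue, tuple[int, int, int]] = {
    Tissue.BACKGROUND: (0, 0, 0),
    Tissue.BLOOD: (255, 0, 0),
    Tissue.HEALTHY: (0, 0, 255),
    Tissue.GRAY_ZONE: (255, 255, 0),
    Tissue.CORE: (0, 200, 0),
    Tissue.PM_HEALTHY: (70, 70, 255),
    Tissue.PM_INFARCT: (0, 200, 0),
    Tissue.EXCLUDED: (128, 128, 128),
}

_LEGEND_NAMES = {
    Tissue.GRAY_ZONE: "peri-infarct gray zone",
    Tissue.CORE: "core infarct",
    Tissue.BLOOD: "blood pool",
    Tissue.HEALTHY: "healthy myocardium",
    Tissue.EXCLUDED: "excluded",
    Tissue.PM_HEALTHY: "papillary muscle (healthy)",
    Tissue.PM_INFARCT: "papillary muscle (infarct)",
}


def classmap_to_rgb(classmap: LabelVolume, slice_index: int) -> np.ndarray:
    """Exact per-voxel RGB array (ny, nx, 3) for one slice — one pixel per voxel."""
    sl = classmap.labels[:, :, slice_index]
    rgb = np.zeros(sl.shape + (3,), dtype=np.uint8)
    for tissue, color in CLASS_COLORS.items():
        rgb[sl == int(tissue)] = color
    # image convention: rows = y, columns = x
    return np.transpose(rgb, (1, 0, 2))


def render_classmap(classmap: LabelVolume, out_prefix: str | Path) -> list[Path]:
    """Write one legended PNG per slice; returns the written paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    present = {Tissue(int(v)) for v in np.unique(classmap.labels)}
    if present <= {Tissue.BACKGROUND}:
        warnings.warn("class map is empty; rendering blank slices", stacklevel=2)
    paths = []
    handles = [
        mpatches.Patch(color=np.array(CLASS_COLORS[t]) / 255.0, label=_LEGEND_NAMES[t])
        for t in _LEGEND_NAMES
        if t in present
    ]
    for k in range(classmap.shape[2]):
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(classmap_to_rgb(classmap, k), origin="lower", interpolation="nearest")
        ax.set_title(f"slice {k}")
        ax.axis("off")
        if handles:
            ax.legend(handles=handles, loc="upper right", fontsize=7, framealpha=0.8)
        path = out_prefix.with_name(f"{out_prefix.name}_slice{k:02d}.png")
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
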