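"""End-to-end orchestration: phantom → simulate → fit → segment → quantify.

One :class:`RunConfig` drives the whole chain.  All randomness derives from
a single seed through named substreams, so identical configurations produce
byte-identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .fwhm import fwhm_segment, remote_stats
from .io import save_image, save_labels, save_maps, save_series
from .mcle import build_features, classify, despeckle, fcm, label_clusters
from .phantom import (
    PhantomSpec,
    default_tis,
    healthy_null_ti,
    make_phantom,
    remote_roi_mask,
    simulate_ir_fgre,
    simulate_mcle,
)
from .quantify import (
    MYOCARDIAL_DENSITY_G_PER_CM3,
    heterogeneity_from_classmap,
    heterogeneity_from_fwhm,
    pm_score_from_classmap,
    pm_score_from_image,
)
from .relaxometry import InversionRecoveryModel
from .render import render_classmap
from .volumes import Tissue, dice

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "substream", "default_frame_indices"]

log = logging.getLogger(__name__)


def substream(seed: int, name: str) -> int:
    """Derive a named child seed (< 2**31) from the master seed."""
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


def default_frame_indices(n_frames: int, k: int | None = None) -> list[int]:
    """Fitting frames for motion-free simulated series.

    All frames by default: the clinical 6-8-diastolic-image restriction
    exists to avoid cardiac motion, which simulated series do not have, and
    the three-parameter exponential fit is poorly conditioned on a narrow
    late-TI window.  Pass ``k`` to take k frames spread evenly over the
    schedule instead.
    """
    if k is None:
        return list(range(n_frames))
    return sorted(set(np.round(np.linspace(0, n_frames - 1, k)).astype(int).tolist()))


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``frame_indices`` overrides frame selection for fitting; when None the
    spread default above is used.  The gray-zone band is the inclusive
    infarct-membership probability window.
    """

    out_dir: str = "run"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    tis_ms: list[float] = field(default_factory=lambda: default_tis().tolist())
    frame_indices: list[int] | None = None
    fcm_m: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    fcm_restarts: int = 5
    gz_band: tuple[float, float] = (0.25, 0.75)
    blood_override: float = 0.5
    pm_fraction: float = 0.5
    despeckle_min_size: int = 2
    density: float = MYOCARDIAL_DENSITY_G_PER_CM3
    seed: int = 0
    save_volumes: bool = True
    render: bool = True

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, Tissue):
                return int(o)
            raise TypeError(f"cannot encode {type(o)}")

        d = dataclasses.asdict(self)
        d["phantom"]["tissue_signals"] = {
            Tissue(k).name.lower(): {"a": v.a, "t1star": v.t1star} if hasattr(v, "a") else v
            for k, v in self.phantom.tissue_signals.items()
        }
        return json.dumps(d, indent=2, sort_keys=True, default=enc)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        from .phantom import PapillaryMuscle, TissueSignal

        d = json.loads(text)
        ph = d.pop("phantom", None)
        cfg = cls(**{k: v for k, v in d.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if ph is not None:
            sig = ph.pop("tissue_signals", None)
            pms = ph.pop("pms", None)
            kwargs = {k: v for k, v in ph.items() if k in {f.name for f in dataclasses.fields(PhantomSpec)}}
            if kwargs.get("shape"):
                kwargs["shape"] = tuple(kwargs["shape"])
            if kwargs.get("center"):
                kwargs["center"] = tuple(kwargs["center"])
            if sig:
                kwargs["tissue_signals"] = {
                    Tissue[k.upper()]: TissueSignal(**v) for k, v in sig.items()
                }
            if pms:
                kwargs["pms"] = tuple(
                    PapillaryMuscle(tuple(p["center"]), p["radius_mm"], p["infarcted"])
                    for p in pms
                )
            cfg.phantom = PhantomSpec(**kwargs)
        if cfg.gz_band is not None:
            cfg.gz_band = tuple(cfg.gz_band)
        return cfg


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is preserved."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full phantom analysis chain and write all outputs.

    Returns the results dictionary (also written to ``results.json`` in the
    run directory).  Any stage failure raises :class:`PipelineError` naming
    the stage; outputs written before the failure are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    results: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {},
    }
    try:
        stage = "phantom"
        truth_labels, truth_maps = make_phantom(config.phantom)
        geometry = truth_labels.geometry
        myo = truth_labels.myocardium_mask
        blood = truth_labels.blood_mask
        pm_masks = _pm_masks(truth_labels, config.phantom)

        stage = "simulate"
        seed_mcle = substream(config.seed, "mcle")
        seed_irfgre = substream(config.seed, "irfgre")
        results["stage_seeds"] = {"mcle": seed_mcle, "irfgre": seed_irfgre}
        series = simulate_mcle(
            truth_maps, config.tis_ms, noise_sd=config.phantom.noise_sd, seed=seed_mcle
        )
        lge = simulate_ir_fgre(
            truth_maps,
            ti=healthy_null_ti(config.phantom),
            noise_sd=config.phantom.noise_sd,
            seed=seed_irfgre,
        )
        if config.save_volumes:
            save_labels(truth_labels, out / "truth_labels.nii.gz")
            save_series(series, out / "mcle_series.nii.gz")
            save_image(lge, out / "ir_fgre.nii.gz")

        stage = "fit"
        frames = (
            config.frame_indices
            if config.frame_indices is not None
            else default_frame_indices(series.n_frames)
        )
        fit_mask = myo | blood | truth_labels.pm_mask
        fit = InversionRecoveryModel(series, mask=fit_mask, frames=frames).fit()
        if config.save_volumes:
            save_maps(fit.params, out / "maps")

        stage = "segment-mcle"
        seed_fcm = substream(config.seed, "fcm")
        results["stage_seeds"]["fcm"] = seed_fcm
        features = build_features(fit.params, fit_mask)
        memberships = fcm(
            features,
            m=config.fcm_m,
            tol=config.fcm_tol,
            max_iter=config.fcm_max_iter,
            seed=seed_fcm,
            restarts=config.fcm_restarts,
        )
        mapping = label_clusters(memberships)
        band_mask = myo | truth_labels.pm_mask  # papillae classified for scoring
        classmap = classify(
            memberships,
            mapping,
            band_mask,
            gz_band=config.gz_band,
            blood_override=config.blood_override,
        )
        classmap = despeckle(classmap, min_size=config.despeckle_min_size)
        if config.save_volumes:
            save_labels(classmap, out / "classmap_mcle.nii.gz")

        stage = "segment-fwhm"
        remote = remote_roi_mask(truth_labels, config.phantom)
        stats = remote_stats(lge, remote)
        fwhm_res = fwhm_segment(lge, myo, stats)
        results["fwhm_thresholds"] = {
            "peak_remote": stats.peak,
            "mean_remote": stats.mean,
            "sd_remote": stats.sd,
            "peak_infarct": fwhm_res.peak_infarct,
            "core_threshold": fwhm_res.core_threshold,
        }

        stage = "quantify"
        het_mcle = heterogeneity_from_classmap(classmap, myo, density=config.density)
        het_fwhm = heterogeneity_from_fwhm(fwhm_res, myo, geometry, density=config.density)
        pm_mcle = pm_score_from_classmap(
            classmap, pm_masks, infarct_fraction_threshold=config.pm_fraction
        )
        pm_int = (
            pm_score_from_image(lge.data, pm_masks, fwhm_res.peak_infarct)
            if not fwhm_res.empty
            else None
        )
        truth_het = heterogeneity_from_classmap(truth_labels, myo, density=config.density)
        results["mcle"] = het_mcle.as_dict()
        results["ir_fgre"] = het_fwhm.as_dict()
        results["ground_truth"] = truth_het.as_dict()
        results["pm_score_mcle"] = pm_mcle.score
        results["pm_fractions_mcle"] = list(pm_mcle.fractions)
        results["pm_score_intensity"] = None if pm_int is None else pm_int.score
        results["dice"] = {
            name: dice(classmap.mask(t) & myo, truth_labels.mask(t))
            for name, t in (
                ("core", Tissue.CORE),
                ("gray_zone", Tissue.GRAY_ZONE),
                ("healthy", Tissue.HEALTHY),
            )
        }
        results["n_valid_fits"] = fit.n_valid
        results["frame_indices"] = list(frames)

        stage = "render"
        if config.render:
            render_classmap(classmap, out / "classmap")

        stage = "write"
        (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        (out / "config.json").write_text(config.to_json())
        (out / "run.log").write_text(
            "\n".join(
                [
                    f"mclegz {__version__}",
                    f"numpy {np.__version__}",
                    f"seed {config.seed}",
                    f"stage seeds {results['stage_seeds']}",
                    f"frames {list(frames)}",
                ]
            )
            + "\n"
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context is the point
        raise PipelineError(stage, exc) from exc
    return results


def _pm_masks(truth_labels, spec: PhantomSpec):
    """Split the PM label voxels into the two individual muscles by distance."""
    pm_all = truth_labels.pm_mask
    nx, ny, _ = truth_labels.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    masks = []
    centers = [pm.center for pm in spec.pms]
    d = [
        (ii - c[0]) ** 2 + (jj - c[1]) ** 2 for c in centers
    ]  # in-plane squared distances
    nearest = np.argmin(np.stack(d), axis=0)
    for i in range(2):
        masks.append(pm_all & (nearest == i)[:, :, None])
    return masks
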