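"""Tissue classification from (T1*, steady-state) maps by fuzzy C-means.

Each analyzable voxel contributes a two-dimensional feature (T1* in ms,
steady-state amplitude in a.u.).  Features are z-scored, clustered into
three fuzzy classes with the standard FCM objective

    J = sum_i sum_k u_ik^m ||x_i - c_k||^2,    sum_k u_ik = 1,

and the clusters are named by their de-standardized centroids: blood is the
brightest steady-state centroid, and of the remaining two the shorter-T1*
centroid is infarct (fast post-contrast recovery) and the longer is healthy
myocardium.  Within the myocardium the infarct membership is banded: above
0.75 is core, 0.25-0.75 (inclusive) is peri-infarct gray zone, below 0.25
is healthy; voxels whose blood membership exceeds 0.5 are treated as
cavity partial volume and labeled blood.  A connected-component despeckle
step relabels isolated noise-driven core/gray-zone voxels inside healthy
myocardium, automating the manual cleanup used in practice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import Geometry, LabelVolume, ParameterMaps, Tissue

__all__ = [
    "FeatureTable",
    "Memberships",
    "build_features",
    "FuzzyCMeans",
    "FCMResults",
    "fcm",
    "label_clusters",
    "classify",
    "despeckle",
]

log = logging.getLogger(__name__)

GZ_BAND = (0.25, 0.75)
BLOOD_OVERRIDE = 0.5


@dataclass
class FeatureTable:
    """Per-voxel (T1*, steady-state) features over an analysis mask, z-scored.

    ``x`` holds raw features (N, 2) in (ms, a.u.); ``mean``/``sd`` are the
    standardization parameters, stored so the transform is reversible.
    """

    x: np.ndarray
    mask: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    geometry: Geometry

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def xz(self) -> np.ndarray:
        return (self.x - self.mean) / self.sd

    def destandardize(self, xz: np.ndarray) -> np.ndarray:
        return np.asarray(xz) * self.sd + self.mean


def build_features(maps: ParameterMaps, analysis_mask: np.ndarray) -> FeatureTable:
    """Collect valid-fit voxels of the analysis mask into a feature table.

    Invalid-fit voxels inside the mask are dropped (count logged).  Fewer
    than 3 usable voxels cannot support 3 clusters and raise.
    """
    mask = np.asarray(analysis_mask, dtype=bool)
    if mask.shape != maps.shape:
        raise ValueError("analysis mask shape must match the maps")
    usable = mask & maps.valid
    dropped = int(mask.sum() - usable.sum())
    if dropped:
        log.info("build_features: dropped %d invalid-fit voxels", dropped)
    n = int(usable.sum())
    if n < 3:
        raise ValueError(f"need >= 3 valid voxels to form 3 clusters, got {n}")
    x = np.column_stack([maps.t1star[usable], maps.a[usable]])
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant feature: leave it centred only
    return FeatureTable(x=x, mask=usable, mean=mean, sd=sd, geometry=maps.geometry)


def _kmeanspp_init(
    xz: np.ndarray, k: int, rng: np.random.Generator, n_candidates: int = 4
) -> np.ndarray:
    """Seeded greedy k-means++ centroid choice over data points.

    Each step draws several d²-weighted candidates and keeps the one that
    minimizes the resulting potential — markedly more robust than plain
    k-means++ when one cluster is much more dispersed than the others.
    """
    n = xz.shape[0]
    centroids = [xz[rng.integers(n)]]
    d2 = ((xz - centroids[0]) ** 2).sum(-1)
    for _ in range(k - 1):
        total = d2.sum()
        if total <= 0:
            centroids.append(xz[rng.integers(n)])
            continue
        cand_idx = rng.choice(n, size=n_candidates, p=d2 / total)
        best_pot, best = None, None
        for ci in cand_idx:
            nd2 = np.minimum(d2, ((xz - xz[ci]) ** 2).sum(-1))
            pot = nd2.sum()
            if best_pot is None or pot < best_pot:
                best_pot, best = pot, (xz[ci], nd2)
        centroids.append(best[0])
        d2 = best[1]
    return np.asarray(centroids)


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; exact-hit voxels get u=1."""
    zero = d2 <= 0
    u = np.zeros_like(d2)
    hit = zero.any(axis=1)
    if hit.any():
        # FCM singularity rule: a point on a centroid belongs to it entirely
        # (ties split equally).
        z = zero[hit]
        u[hit] = z / z.sum(axis=1, keepdims=True)
    rest = ~hit
    if rest.any():
        p = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = p / p.sum(axis=1, keepdims=True)
    return u


class FuzzyCMeans:
    """Fuzzy C-means estimator on a standardized feature matrix.

    Parameters follow the standard algorithm: fuzzifier ``m`` (> 1), squared
    Euclidean distance, alternating membership/centroid updates until the
    largest membership change drops below ``tol``.  ``restarts`` seeded
    k-means++ initializations are run and the lowest-objective solution kept,
    so results are deterministic given a seed.
    """

    def __init__(
        self,
        x: np.ndarray,
        n_clusters: int = 3,
        m: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 300,
        restarts: int = 5,
    ) -> None:
        self.x = np.asarray(x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("x must be (n_points, n_features)")
        if np.unique(self.x, axis=0).shape[0] < n_clusters:
            raise ValueError(f"need >= {n_clusters} distinct points")
        if m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        self.k = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.restarts = restarts

    def _run_once(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, list[float]]:
        for _attempt in range(10):
            c = _kmeanspp_init(self.x, self.k, rng)
            if np.unique(c, axis=0).shape[0] == self.k:
                break
        else:
            raise RuntimeError("could not draw distinct initial centroids")
        c = self._lloyd_refine(c)
        u_prev = None
        history: list[float] = []
        return self._fcm_iterate(c, u_prev, history)

    def _lloyd_refine(self, c: np.ndarray, n_iter: int = 20) -> np.ndarray:
        """A few hard k-means steps to pull the k-means++ draw to a good basin."""
        for _ in range(n_iter):
            d2 = ((self.x[:, None, :] - c[None, :, :]) ** 2).sum(-1)
            lab = np.argmin(d2, axis=1)
            new = c.copy()
            for j in range(self.k):
                pts = self.x[lab == j]
                if pts.shape[0]:
                    new[j] = pts.mean(axis=0)
            if np.allclose(new, c):
                break
            c = new
        return c

    def _fcm_iterate(
        self, c: np.ndarray, u_prev, history: list[float]
    ) -> tuple[np.ndarray, np.ndarray, list[float]]:
        for _ in range(self.max_iter):
            d2 = ((self.x[:, None, :] - c[None, :, :]) ** 2).sum(-1)
            u = _fcm_memberships(d2, self.m)
            um = u**self.m
            history.append(float((um * d2).sum()))
            c = (um.T @ self.x) / um.sum(axis=0)[:, None]
            if u_prev is not None and np.max(np.abs(u - u_prev)) < self.tol:
                u_prev = u
                break
            u_prev = u
        d2 = ((self.x[:, None, :] - c[None, :, :]) ** 2).sum(-1)
        u = _fcm_memberships(d2, self.m)
        history.append(float((u**self.m * d2).sum()))
        return u, c, history

    def fit(self, seed: int = 0) -> "FCMResults":
        ss = np.random.SeedSequence(seed)
        best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
        for child in ss.spawn(self.restarts):
            u, c, hist = self._run_once(np.random.default_rng(child))
            if best is None or hist[-1] < best[2][-1]:
                best = (u, c, hist)
        assert best is not None
        return FCMResults(
            model=self, u=best[0], centroids=best[1], objective_history=best[2]
        )


@dataclass
class FCMResults:
    """Converged memberships (N, k), centroids (k, d) and the objective trace."""

    model: FuzzyCMeans
    u: np.ndarray
    centroids: np.ndarray
    objective_history: list[float]

    @property
    def objective(self) -> float:
        return self.objective_history[-1]

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.u, axis=1)

    def summary(self) -> str:
        lines = [
            f"Fuzzy C-means: k={self.model.k}, m={self.model.m}, "
            f"n={self.model.x.shape[0]}",
            f"objective: {self.objective:.6g} after "
            f"{len(self.objective_history)} evaluations",
        ]
        for i, c in enumerate(self.centroids):
            share = float(self.u[:, i].mean())
            lines.append(
                f"cluster {i}: centroid {np.array2string(c, precision=3)}  "
                f"mean membership {share:.3f}"
            )
        return "\n".join(lines)


@dataclass
class Memberships:
    """Fuzzy memberships tied back to image space.

    ``u`` rows sum to 1; ``centroids`` are in raw feature units (ms, a.u.);
    ``mask`` maps rows to voxels.
    """

    u: np.ndarray
    centroids: np.ndarray
    m: float
    mask: np.ndarray
    geometry: Geometry
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.u.shape[1] != 3:
            raise ValueError("expected 3 clusters")
        s = self.u.sum(axis=1)
        if np.any(np.abs(s - 1.0) > 1e-9):
            raise ValueError("memberships must sum to 1 per voxel")


def fcm(
    features: FeatureTable,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    restarts: int = 5,
) -> Memberships:
    """Cluster a feature table into {infarct, healthy, blood} memberships."""
    res = FuzzyCMeans(
        features.xz, n_clusters=3, m=m, tol=tol, max_iter=max_iter, restarts=restarts
    ).fit(seed)
    return Memberships(
        u=res.u,
        centroids=features.destandardize(res.centroids),
        m=m,
        mask=features.mask,
        geometry=features.geometry,
        objective_history=res.objective_history,
    )


def label_clusters(memberships: Memberships) -> dict[str, int]:
    """Name the three clusters from their raw-unit centroids.

    Blood is the centroid with the highest steady-state amplitude (ties go to
    the shorter T1*, with a warning); of the remaining two, the shorter T1*
    is infarct and the longer is healthy.
    """
    c = memberships.centroids  # columns: (t1star, steady_state)
    amps = c[:, 1]
    t1s = c[:, 0]
    top = np.flatnonzero(amps == amps.max())
    if top.size > 1:
        warnings.warn(
            "steady-state tie between candidate blood clusters; "
            "breaking by shorter T1*",
            stacklevel=2,
        )
        blood = int(top[np.argmin(t1s[top])])
    else:
        blood = int(top[0])
    rest = [i for i in range(3) if i != blood]
    if t1s[rest[0]] == t1s[rest[1]]:
        warnings.warn("T1* tie between infarct/healthy; breaking by amplitude", stacklevel=2)
        rest.sort(key=lambda i: (-amps[i],))
        return {"blood": blood, "infarct": rest[0], "healthy": rest[1]}
    infarct, healthy = sorted(rest, key=lambda i: t1s[i])
    return {"blood": blood, "infarct": infarct, "healthy": healthy}


def classify(
    memberships: Memberships,
    mapping: dict[str, int],
    myo_mask: np.ndarray,
    gz_band: tuple[float, float] = GZ_BAND,
    blood_override: float = BLOOD_OVERRIDE,
) -> LabelVolume:
    """Convert memberships to a tissue class map.

    Within the myocardium mask the infarct membership ``u_inf`` decides the
    class: core for ``u_inf > hi``, gray zone for ``lo <= u_inf <= hi``
    (inclusive bounds), healthy below — except that voxels with blood
    membership above ``blood_override`` are labeled blood (cavity partial
    volume).  Analyzed voxels outside the myocardium are blood or excluded;
    masked-but-unanalyzed voxels are excluded.
    """
    if set(mapping) != {"blood", "infarct", "healthy"}:
        raise ValueError("mapping must name blood, infarct and healthy clusters")
    myo = np.asarray(myo_mask, dtype=bool)
    lo, hi = gz_band
    labels = np.full(memberships.mask.shape, int(Tissue.BACKGROUND), dtype=np.int16)
    labels[myo] = int(Tissue.EXCLUDED)  # myocardial voxels without a usable fit

    u_inf = np.zeros(memberships.mask.shape)
    u_blood = np.zeros(memberships.mask.shape)
    u_inf[memberships.mask] = memberships.u[:, mapping["infarct"]]
    u_blood[memberships.mask] = memberships.u[:, mapping["blood"]]

    analyzed_myo = memberships.mask & myo
    labels[analyzed_myo & (u_inf < lo)] = int(Tissue.HEALTHY)
    labels[analyzed_myo & (u_inf >= lo) & (u_inf <= hi)] = int(Tissue.GRAY_ZONE)
    labels[analyzed_myo & (u_inf > hi)] = int(Tissue.CORE)
    labels[analyzed_myo & (u_blood > blood_override)] = int(Tissue.BLOOD)

    outside = memberships.mask & ~myo
    labels[outside & (u_blood > blood_override)] = int(Tissue.BLOOD)
    labels[outside & (u_blood <= blood_override)] = int(Tissue.EXCLUDED)
    return LabelVolume(labels, memberships.geometry)


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def despeckle(
    classmap: LabelVolume, min_size: int = 2, connectivity: str = "face"
) -> LabelVolume:
    """Relabel isolated noise-driven infarct voxels inside healthy myocardium.

    Connected components of (core ∪ gray zone) smaller than ``min_size``
    whose myocardial neighbours are all healthy become healthy; everything
    else is untouched.  Components touching other infarct tissue, or sitting
    at the blood/background interface with no healthy neighbour, are kept.
    """
    if connectivity == "face":
        structure = _FACE_STRUCTURE
    elif connectivity == "full":
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 'face' or 'full'")
    labels = classmap.labels.copy()
    infarct = (labels == int(Tissue.CORE)) | (labels == int(Tissue.GRAY_ZONE))
    comp, n = ndimage.label(infarct, structure=structure)
    if n == 0:
        return LabelVolume(labels, classmap.geometry)
    healthy = labels == int(Tissue.HEALTHY)
    myo = healthy | infarct
    sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
    for i in np.flatnonzero(sizes < min_size):
        cid = i + 1
        mask = comp == cid
        neighbours = ndimage.binary_dilation(mask, structure=structure) & ~mask
        myo_neighbours = neighbours & myo
        if myo_neighbours.any() and bool(np.all(healthy[myo_neighbours])):
            labels[mask] = int(Tissue.HEALTHY)
    return LabelVolume(labels, classmap.geometry)
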