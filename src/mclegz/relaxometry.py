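"""Per-voxel inversion-recovery curve fitting: T1* and steady-state maps.

The three-parameter model ``S(t) = A - B exp(-t/T1*)`` is fitted to each
voxel of a multi-TI series by nonlinear least squares.  Initialization is a
coarse log-spaced grid over T1* with an exact linear solve for (A, B) at
each grid node; refinement is a damped Gauss-Newton (Levenberg-Marquardt)
iteration run vectorized across all voxels, accepting only steps that reduce
the residual.  Voxels that fail to converge, hit the T1* bounds
[10, 5000] ms, or carry no recovery information (B ~ 0) are marked invalid.

The model surface follows the estimator convention: build an
:class:`InversionRecoveryModel` from a series and a mask, call
:meth:`~InversionRecoveryModel.fit`, and read maps and diagnostics off the
returned :class:`InversionRecoveryResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes import Geometry, MCLESeries, ParameterMaps

__all__ = [
    "select_frames",
    "fit_recovery",
    "InversionRecoveryModel",
    "InversionRecoveryResults",
    "T1STAR_BOUNDS_MS",
]

T1STAR_BOUNDS_MS = (10.0, 5000.0)
_REL_TOL = 1e-8
_MAX_ITER = 200
# B below this fraction of the signal scale means the curve carries no
# recovery information and T1* is unidentifiable.
_MIN_B_FRACTION = 1e-6


def select_frames(
    series: MCLESeries, k: int | None = None, indices: list[int] | None = None
) -> MCLESeries:
    """Pick the fitting subset of frames.

    By default the last ``k`` frames (largest TIs) are kept — the diastolic
    end of a phase-resolved acquisition, where cardiac motion is minimal.
    An explicit ``indices`` override selects arbitrary frames (returned in
    TI order).
    """
    if indices is not None:
        idx = sorted(set(int(i) for i in indices))
        if not idx or idx[0] < 0 or idx[-1] >= series.n_frames:
            raise ValueError("frame indices out of range")
    else:
        if k is None:
            raise ValueError("provide k or indices")
        if not (2 <= k <= series.n_frames):
            raise ValueError(
                f"k must be between 2 and the number of frames ({series.n_frames})"
            )
        idx = list(range(series.n_frames - k, series.n_frames))
    return MCLESeries(series.data[..., idx], series.tis[idx], series.geometry)


def _linear_ab(y: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact least-squares (A, B) for fixed T1*: model A - B*e, e = exp(-t/T1*).

    ``y`` is (V, F); ``e`` is (F,).  Solves the 2x2 normal equations per voxel.
    """
    f = float(e.size)
    se = float(e.sum())
    see = float((e * e).sum())
    gy = y.sum(axis=1)
    gey = y @ e
    det = f * see - se * se
    if det <= 0:
        # all TIs equal is impossible (strictly increasing); det>0 unless F<2
        raise ValueError("degenerate design: need >= 2 distinct TIs")
    a = (see * gy - se * gey) / det
    b = (se * gy - f * gey) / det
    return a, b


def _ssr(y: np.ndarray, t: np.ndarray, a: np.ndarray, b: np.ndarray, tau: np.ndarray) -> np.ndarray:
    model = a[:, None] - b[:, None] * np.exp(-t[None, :] / tau[:, None])
    r = y - model
    return np.einsum("vf,vf->v", r, r)


def _grid_init(y: np.ndarray, t: np.ndarray, n_grid: int = 48) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coarse variable-projection grid over T1*; returns (a, b, tau, ssr)."""
    taus = np.geomspace(T1STAR_BOUNDS_MS[0], T1STAR_BOUNDS_MS[1], n_grid)
    v = y.shape[0]
    best_ssr = np.full(v, np.inf)
    best = (np.zeros(v), np.zeros(v), np.full(v, taus[0]))
    for tau in taus:
        e = np.exp(-t / tau)
        a, b = _linear_ab(y, e)
        r = y - (a[:, None] - b[:, None] * e[None, :])
        ssr = np.einsum("vf,vf->v", r, r)
        upd = ssr < best_ssr
        if upd.any():
            best_ssr = np.where(upd, ssr, best_ssr)
            best[0][upd] = a[upd]
            best[1][upd] = b[upd]
            best[2][upd] = tau
    return best[0], best[1], best[2], best_ssr


def _lm_refine(
    y: np.ndarray,
    t: np.ndarray,
    a0: np.ndarray,
    b0: np.ndarray,
    tau0: np.ndarray,
    rel_tol: float = _REL_TOL,
    max_iter: int = _MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Levenberg-Marquardt over (A, B, T1*) per voxel.

    Returns (a, b, tau, ssr, converged).  Steps are accepted per voxel only
    when they reduce the residual, so the final SSR never exceeds the grid
    start's.  T1* is kept inside its bounds and A at >= 0 by projection.
    """
    lo, hi = T1STAR_BOUNDS_MS
    a, b, tau = a0.copy(), b0.copy(), tau0.copy()
    ssr = _ssr(y, t, a, b, tau)
    lam = np.full(y.shape[0], 1e-3)
    converged = np.zeros(y.shape[0], dtype=bool)
    active = np.ones(y.shape[0], dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        ia = np.where(active)[0]
        ya, aa, ba, taua = y[ia], a[ia], b[ia], tau[ia]
        e = np.exp(-t[None, :] / taua[:, None])  # (v, F)
        model = aa[:, None] - ba[:, None] * e
        r = ya - model
        # Jacobian of the model wrt (A, B, tau)
        j = np.empty((ia.size, t.size, 3))
        j[:, :, 0] = 1.0
        j[:, :, 1] = -e
        j[:, :, 2] = -ba[:, None] * e * (t[None, :] / taua[:, None] ** 2)
        jtj = np.einsum("vfi,vfj->vij", j, j)
        g = np.einsum("vfi,vf->vi", j, r)

        accepted = np.zeros(ia.size, dtype=bool)
        step = np.zeros((ia.size, 3))
        lam_a = lam[ia].copy()
        for _try in range(25):
            todo = ~accepted
            if not todo.any():
                break
            # Marquardt scaling: damp by lambda * diag(JtJ)
            d = np.abs(np.diagonal(jtj[todo], axis1=1, axis2=2))
            m = jtj[todo] + lam_a[todo, None, None] * (
                np.eye(3)[None, :, :] * np.maximum(d, 1e-12)[:, None, :]
            )
            rhs = g[todo][:, :, None]
            try:
                delta = np.linalg.solve(m, rhs)[:, :, 0]
            except np.linalg.LinAlgError:  # pragma: no cover - singular damped system
                m = m + 1e-9 * np.eye(3)[None, :, :]
                delta = np.linalg.solve(m, rhs)[:, :, 0]
            cand_a = aa[todo] + delta[:, 0]
            cand_b = ba[todo] + delta[:, 1]
            cand_tau = np.clip(taua[todo] + delta[:, 2], lo, hi)
            cand_a = np.maximum(cand_a, 0.0)
            cand_ssr = _ssr(ya[todo], t, cand_a, cand_b, cand_tau)
            ok = cand_ssr <= ssr[ia[todo]]
            idx_todo = np.where(todo)[0]
            good = idx_todo[ok]
            if good.size:
                step[good, 0] = cand_a[ok] - aa[good]
                step[good, 1] = cand_b[ok] - ba[good]
                step[good, 2] = cand_tau[ok] - taua[good]
                a[ia[good]] = cand_a[ok]
                b[ia[good]] = cand_b[ok]
                tau[ia[good]] = cand_tau[ok]
                ssr[ia[good]] = cand_ssr[ok]
                lam_a[good] = np.maximum(lam_a[good] * 0.25, 1e-12)
                accepted[good] = True
            bad = idx_todo[~ok]
            lam_a[bad] *= 8.0
        lam[ia] = lam_a

        scale = np.maximum.reduce(
            [np.abs(a[ia]), np.abs(b[ia]), np.abs(tau[ia]), np.full(ia.size, 1e-12)]
        )
        relstep = np.max(np.abs(step), axis=1) / scale
        done = accepted & (relstep < rel_tol)
        stuck = ~accepted  # no step reduced the residual at any damping tried
        converged[ia[done | stuck]] = True
        active[ia[done | stuck]] = False
    return a, b, tau, ssr, converged


def _fit_voxels(y: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a0, b0, tau0, _ = _grid_init(y, t)
    return _lm_refine(y, t, a0, b0, tau0)


def _polarity_candidates(y: np.ndarray, n_frames: int) -> list[np.ndarray]:
    """Sign-restoration candidates for magnitude data: flip the first j frames."""
    out = []
    for j in range(n_frames):
        s = np.ones(n_frames)
        s[:j] = -1.0
        out.append(y * s[None, :])
    return out


def fit_recovery(
    series: MCLESeries,
    mask: np.ndarray | None = None,
    magnitude: bool = False,
) -> ParameterMaps:
    """Fit the inversion-recovery model to every masked voxel of a series.

    Parameters
    ----------
    series : MCLESeries
        Co-registered frames at >= 3 strictly increasing TIs.
    mask : bool array, optional
        Voxels to fit; defaults to all voxels.
    magnitude : bool
        If True, treat intensities as magnitude data and restore polarity by
        trying sign flips of the earliest frames, keeping the lowest-residual
        fit per voxel.

    Returns
    -------
    ParameterMaps
        T1*, A, B, residual RMS and a validity mask.  Unmasked voxels and
        voxels with unidentifiable or out-of-bounds fits are invalid.
    """
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames for a 3-parameter fit")
    shape = series.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape must match the series geometry")

    t = series.tis
    y = series.data[mask]  # (V, F)
    v = y.shape[0]
    t1 = np.full(shape, np.nan)
    a_map = np.full(shape, np.nan)
    b_map = np.full(shape, np.nan)
    rms = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    if v == 0:
        warnings.warn("empty fit mask: all voxels invalid", stacklevel=2)
        return ParameterMaps(t1, a_map, b_map, rms, valid, series.geometry)

    if magnitude:
        best = None
        for cand in _polarity_candidates(y, series.n_frames):
            a, b, tau, ssr, conv = _fit_voxels(cand, t)
            if best is None:
                best = [a, b, tau, ssr, conv]
            else:
                upd = ssr < best[3]
                for i, new in enumerate((a, b, tau, ssr, conv)):
                    best[i] = np.where(upd, new, best[i])
        a, b, tau, ssr, conv = best  # type: ignore[misc]
        conv = conv.astype(bool)
    else:
        a, b, tau, ssr, conv = _fit_voxels(y, t)

    scale = np.maximum(np.abs(a), np.abs(y).max(axis=1))
    lo, hi = T1STAR_BOUNDS_MS
    ok = (
        conv
        & (tau > lo * (1 + 1e-9))
        & (tau < hi * (1 - 1e-9))
        & (np.abs(b) > _MIN_B_FRACTION * np.maximum(scale, 1e-30))
        & np.isfinite(a)
    )
    t1[mask] = tau
    a_map[mask] = a
    b_map[mask] = b
    rms[mask] = np.sqrt(ssr / t.size)
    vtmp = np.zeros(v, dtype=bool)
    vtmp[:] = ok
    valid[mask] = vtmp
    # keep container invariants: invalid voxels carry NaN, not bad values
    t1[~valid] = np.nan
    if not valid.any():
        warnings.warn("no voxel produced a valid fit", stacklevel=2)
    return ParameterMaps(t1, a_map, b_map, rms, valid, series.geometry)


class InversionRecoveryModel:
    """Estimator wrapper around :func:`fit_recovery`.

    Parameters
    ----------
    series : MCLESeries
        The full multi-TI acquisition.
    mask : bool array, optional
        Analysis mask (e.g. myocardium plus blood pool).
    frames : int or list of int, optional
        Either ``k`` (keep the last k frames) or explicit frame indices.
        Default keeps the last 8 frames.
    """

    def __init__(
        self,
        series: MCLESeries,
        mask: np.ndarray | None = None,
        frames: int | list[int] | None = 8,
    ) -> None:
        if frames is None:
            self.series = series
        elif isinstance(frames, int):
            self.series = select_frames(series, k=min(frames, series.n_frames))
        else:
            self.series = select_frames(series, indices=list(frames))
        self.mask = mask

    def fit(self, magnitude: bool = False) -> "InversionRecoveryResults":
        params = fit_recovery(self.series, self.mask, magnitude=magnitude)
        return InversionRecoveryResults(self, params)


@dataclass
class InversionRecoveryResults:
    """Fitted maps plus convenience diagnostics and a text summary."""

    model: InversionRecoveryModel
    params: ParameterMaps

    @property
    def geometry(self) -> Geometry:
        return self.params.geometry

    @property
    def n_valid(self) -> int:
        return int(self.params.valid.sum())

    def summary(self) -> str:
        p = self.params
        v = p.valid
        n_masked = int(v.size if self.model.mask is None else np.sum(self.model.mask))
        lines = [
            "Inversion-recovery fit  S(t) = A - B exp(-t/T1*)",
            f"frames: {self.model.series.n_frames}  "
            f"TIs (ms): {np.array2string(self.model.series.tis, precision=1)}",
            f"voxels fitted: {n_masked}   valid: {self.n_valid}",
        ]
        if v.any():
            lines += [
                f"T1* (ms): median {np.median(p.t1star[v]):.1f}  "
                f"IQR [{np.percentile(p.t1star[v], 25):.1f}, "
                f"{np.percentile(p.t1star[v], 75):.1f}]",
                f"A (a.u.): median {np.median(p.a[v]):.2f}",
                f"residual RMS: median {np.median(p.residual_rms[v]):.4g}",
            ]
        return "\n".join(lines)
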