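"""T1 recovery from MOLLI samples: polarity restoration, three-parameter
fitting and Look-Locker correction.

Magnitude inversion-recovery data lose the sign of the early samples, so
each candidate null-crossing position is tried and the signing whose fit
residual is smallest wins.  The signed samples are then fitted with the
three-parameter model ``S(TI) = A - B exp(-TI/T1*)`` and the apparent
relaxation time corrected to ``T1 = T1* (B/A - 1)``.

Two fitting paths are provided:

* :func:`fit_ir_three_param` — a multi-start Levenberg-style least-squares
  fit of (A, B, T1*) for single signals; the reference implementation.
* :func:`fit_t1_map` — a whole-image fitter using variable projection
  (A and B are linear given T1*, so the search is one-dimensional in T1*),
  evaluated on a coarse T1* grid jointly over all voxels and flip
  candidates, then refined per voxel by golden-section search.  It is
  deterministic and agrees with the scalar path to numerical precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .molli import IRSignal, PhantomImageSeries

__all__ = [
    "IRFitResult",
    "RelaxationMap",
    "restore_polarity",
    "fit_ir_three_param",
    "fit_signal",
    "fit_t1_map",
    "save_map",
    "load_map",
]

logger = logging.getLogger(__name__)

_T1_STAR_STARTS = (200.0, 500.0, 1000.0, 2000.0)
_T1_STAR_BOUNDS = (20.0, 8000.0)


@dataclass(frozen=True)
class IRFitResult:
    """Parameters of one three-parameter inversion-recovery fit."""

    a_amp: float
    b_amp: float
    t1_star: float  # ms, apparent
    t1_corrected: float  # ms, Look-Locker corrected
    residual_rms: float
    converged: bool
    polarity_flip_index: int = 0


@dataclass(frozen=True)
class RelaxationMap:
    """2-D T1 map (ms) with a validity mask and per-voxel fit residuals."""

    t1_values: np.ndarray
    validity_mask: np.ndarray
    fit_quality: np.ndarray  # residual RMS per voxel
    time_label: str = ""

    def __post_init__(self) -> None:
        if not (self.t1_values.shape == self.validity_mask.shape == self.fit_quality.shape):
            raise ValueError("map layers must share one shape")
        if not np.all(np.isfinite(self.t1_values[self.validity_mask])):
            raise ValueError("valid voxels must hold finite T1 values")


def look_locker_correct(t1_star: float, a_amp: float, b_amp: float) -> float:
    """Apparent-to-true conversion T1 = T1* (B/A - 1)."""
    return t1_star * (b_amp / a_amp - 1.0)


# ---------------------------------------------------------------------------
# Variable-projection machinery (shared by polarity scoring and map fitting)
# ---------------------------------------------------------------------------


def _varpro_terms(tis: np.ndarray, t1_star: np.ndarray):
    """Basis sums for the linear subproblem at each T1* value."""
    e = np.exp(-tis[None, :] / np.asarray(t1_star, dtype=float)[:, None])
    return e, e.sum(axis=1), (e * e).sum(axis=1)


def _varpro_residual2_grid(tis: np.ndarray, signed: np.ndarray, t1_grid: np.ndarray) -> np.ndarray:
    """Squared fit residual for every (voxel, grid T1*) pair.

    ``signed``: (n_vox, n_ti).  Returns (n_vox, n_grid).
    """
    n = len(tis)
    e, s_e, s_ee = _varpro_terms(tis, t1_grid)
    c1 = signed.sum(axis=1)[:, None]  # (n_vox, 1)
    c2 = signed @ e.T  # (n_vox, n_grid)
    det = n * s_ee - s_e * s_e  # (n_grid,)
    a = (s_ee[None, :] * c1 - s_e[None, :] * c2) / det[None, :]
    b = (s_e[None, :] * c1 - n * c2) / det[None, :]
    ss = (signed * signed).sum(axis=1)[:, None]
    return ss - (a * c1 - b * c2)


def _varpro_solve(tis: np.ndarray, signed: np.ndarray, t1_star: np.ndarray):
    """Closed-form (A, B, residual²) at a per-voxel T1*."""
    n = len(tis)
    e = np.exp(-tis[None, :] / t1_star[:, None])
    s_e = e.sum(axis=1)
    s_ee = (e * e).sum(axis=1)
    c1 = signed.sum(axis=1)
    c2 = (signed * e).sum(axis=1)
    det = n * s_ee - s_e * s_e
    a = (s_ee * c1 - s_e * c2) / det
    b = (s_e * c1 - n * c2) / det
    ss = (signed * signed).sum(axis=1)
    resid2 = np.maximum(ss - (a * c1 - b * c2), 0.0)
    return a, b, resid2


def _golden_refine(
    tis: np.ndarray, signed: np.ndarray, lo: np.ndarray, hi: np.ndarray, n_iter: int = 60
) -> np.ndarray:
    """Vectorised golden-section minimisation of residual²(T1*) per voxel."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    _, _, f1 = _varpro_solve(tis, signed, x1)
    _, _, f2 = _varpro_solve(tis, signed, x2)
    for _ in range(n_iter):
        take1 = f1 < f2
        hi = np.where(take1, x2, hi)
        lo = np.where(take1, lo, x1)
        x1_new = hi - invphi * (hi - lo)
        x2_new = lo + invphi * (hi - lo)
        # only one bound moved per voxel; recompute both objective values
        x1, x2 = x1_new, x2_new
        _, _, f1 = _varpro_solve(tis, signed, x1)
        _, _, f2 = _varpro_solve(tis, signed, x2)
    return 0.5 * (lo + hi)


def _default_t1_grid(n_grid: int = 40) -> np.ndarray:
    return np.geomspace(_T1_STAR_BOUNDS[0], _T1_STAR_BOUNDS[1], n_grid)


# ---------------------------------------------------------------------------
# Scalar path
# ---------------------------------------------------------------------------


def restore_polarity(signal: IRSignal, n_grid: int = 40) -> tuple[np.ndarray, int]:
    """Recover signed samples from magnitudes.

    Every candidate flip index ``i`` (negating the ``i`` earliest-TI
    samples) is scored by its best variable-projection residual; the
    minimal-residual signing wins, ties going to the smaller index.
    Returns the signed samples in the original sample order and the chosen
    flip count.
    """
    mags = np.asarray(signal.magnitudes, dtype=float)
    tis = np.asarray(signal.inversion_times, dtype=float)
    if len(mags) < 5:
        raise ValueError("need at least 5 samples for polarity restoration")
    order = np.argsort(tis, kind="stable")
    mags_sorted = mags[order]
    tis_sorted = tis[order]
    n = len(mags)
    candidates = np.empty((n + 1, n))
    for i in range(n + 1):
        signs = np.ones(n)
        signs[:i] = -1.0
        candidates[i] = signs * mags_sorted
    # coarse grid brackets T1* per candidate; the refined residual decides,
    # since near-ambiguous polarities can rank differently at grid resolution
    grid = _default_t1_grid(n_grid)
    resid2 = _varpro_residual2_grid(tis_sorted, candidates, grid)
    idx = np.argmin(resid2, axis=1)
    lo = grid[np.maximum(idx - 1, 0)]
    hi = grid[np.minimum(idx + 1, len(grid) - 1)]
    t1_star = _golden_refine(tis_sorted, candidates, lo, hi)
    _, _, refined = _varpro_solve(tis_sorted, candidates, t1_star)
    # an exactly ambiguous polarity (single pre-null sample) ties at zero
    # residual: prefer the fewest flips within numerical tolerance
    tol = refined.min() + 1e-14 * float((mags_sorted**2).sum())
    best = int(np.flatnonzero(refined <= tol)[0])
    signed_sorted = candidates[best]
    signed = np.empty(n)
    signed[order] = signed_sorted
    return signed, best


def fit_ir_three_param(tis, signed, polarity_flip_index: int = 0) -> IRFitResult:
    """Multi-start least-squares fit of ``S = A - B exp(-TI/T1*)``.

    T1* starts span {200, 500, 1000, 2000} ms; A is initialised from the
    latest samples and B from A minus the earliest sample.  A degenerate
    (constant) signal yields ``converged=False`` rather than an exception.
    """
    tis = np.asarray(tis, dtype=float)
    signed = np.asarray(signed, dtype=float)
    if len(tis) != len(signed):
        raise ValueError("tis and signed must have equal length")
    if len(tis) < 4:
        raise ValueError("need at least 4 samples for a three-parameter fit")
    if np.ptp(signed) == 0.0:
        return IRFitResult(
            a_amp=float(signed[0]), b_amp=0.0, t1_star=np.nan, t1_corrected=np.nan,
            residual_rms=0.0, converged=False, polarity_flip_index=polarity_flip_index,
        )

    late = np.argsort(tis)[-3:]
    a0 = float(np.mean(signed[late]))
    b0 = a0 - float(signed[np.argmin(tis)])
    if b0 <= 0:
        b0 = max(abs(a0), 1e-3)

    def residual(p):
        a, b, t1s = p
        return a - b * np.exp(-tis / t1s) - signed

    best = None
    for t1s0 in _T1_STAR_STARTS:
        try:
            res = least_squares(
                residual,
                x0=[a0, b0, t1s0],
                bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, 1e7]),
                method="trf",
            )
        except Exception:  # pragma: no cover - optimiser failure path
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return IRFitResult(
            a_amp=np.nan, b_amp=np.nan, t1_star=np.nan, t1_corrected=np.nan,
            residual_rms=np.nan, converged=False, polarity_flip_index=polarity_flip_index,
        )
    a, b, t1s = (float(v) for v in best.x)
    rms = float(np.sqrt(np.mean(residual(best.x) ** 2)))
    physical = a > 0 and b / a > 1.0 and t1s > 0
    return IRFitResult(
        a_amp=a,
        b_amp=b,
        t1_star=t1s,
        t1_corrected=look_locker_correct(t1s, a, b),
        residual_rms=rms,
        converged=bool(physical),
        polarity_flip_index=polarity_flip_index,
    )


def fit_signal(signal: IRSignal) -> IRFitResult:
    """Polarity restoration followed by the three-parameter fit."""
    signed, flip = restore_polarity(signal)
    return fit_ir_three_param(signal.inversion_times, signed, polarity_flip_index=flip)


# ---------------------------------------------------------------------------
# Map path
# ---------------------------------------------------------------------------


def fit_t1_map(
    series: PhantomImageSeries,
    residual_threshold: float = 0.15,
    n_grid: int = 40,
) -> RelaxationMap:
    """Voxel-wise polarity restoration and T1 fitting of an image series.

    All-zero (background) voxels and voxels whose fit fails or whose
    residual RMS exceeds ``residual_threshold * A`` are masked invalid.
    The fraction of invalid voxels is logged.
    """
    images = np.asarray(series.images, dtype=float)
    tis = np.asarray(series.inversion_times, dtype=float)
    if images.shape[0] != len(tis):
        raise ValueError("image count does not match inversion-time count")
    n_ti = len(tis)
    shape = images.shape[1:]
    mags = images.reshape(n_ti, -1).T  # (n_vox, n_ti)
    active = mags.max(axis=1) > 0
    n_active = int(active.sum())

    t1 = np.full(mags.shape[0], np.nan)
    rms = np.full(mags.shape[0], np.nan)
    valid = np.zeros(mags.shape[0], dtype=bool)

    if n_active:
        order = np.argsort(tis, kind="stable")
        tis_sorted = tis[order]
        mags_sorted = mags[active][:, order]

        # Score every (flip candidate, T1*) pair per voxel on the coarse
        # grid, then golden-refine the two best candidates — polarity is
        # decided on refined residuals, since near-ambiguous signings can
        # rank differently at grid resolution.  Exact ties (single
        # pre-null sample) resolve to the fewest flips.
        grid = _default_t1_grid(n_grid)
        n_vox = mags_sorted.shape[0]
        n_cand = n_ti + 1
        sign_rows = np.ones((n_cand, n_ti))
        for flip in range(1, n_cand):
            sign_rows[flip, :flip] = -1.0
        stacked = (mags_sorted[:, None, :] * sign_rows[None, :, :]).reshape(
            n_vox * n_cand, n_ti
        )
        resid2_grid = _varpro_residual2_grid(tis_sorted, stacked, grid)
        grid_idx = np.argmin(resid2_grid, axis=1)
        coarse = resid2_grid[np.arange(len(stacked)), grid_idx].reshape(n_vox, n_cand)
        top2 = np.argsort(coarse, axis=1, kind="stable")[:, :2]  # (n_vox, 2)
        rows = (np.arange(n_vox)[:, None] * n_cand + top2).ravel()
        sub = stacked[rows]
        idx = grid_idx[rows]
        lo = grid[np.maximum(idx - 1, 0)]
        hi = grid[np.minimum(idx + 1, len(grid) - 1)]
        t1_star_sub = _golden_refine(tis_sorted, sub, lo, hi)
        _, _, resid2_sub = _varpro_solve(tis_sorted, sub, t1_star_sub)
        resid2_pair = resid2_sub.reshape(n_vox, 2)
        tol = resid2_pair.min(axis=1) + 1e-14 * (mags_sorted**2).sum(axis=1)
        # candidate column order by flip count, preferring fewer flips on ties
        flip_order = np.argsort(top2, axis=1)
        first_ok = np.where(
            resid2_pair[np.arange(n_vox), flip_order[:, 0]] <= tol,
            flip_order[:, 0],
            flip_order[:, 1],
        )
        pick = np.arange(n_vox) * 2 + first_ok
        signed = sub[pick]
        t1_star = t1_star_sub[pick]
        a, b, resid2 = _varpro_solve(tis_sorted, signed, t1_star)
        rms_active = np.sqrt(resid2 / n_ti)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1_active = t1_star * (b / a - 1.0)
        converged = np.isfinite(t1_active) & (a > 0) & (b > a) & (t1_star > 0)
        valid_active = converged & (rms_active <= residual_threshold * np.maximum(a, 0))

        t1[active] = np.where(converged, t1_active, np.nan)
        rms[active] = rms_active
        valid[active] = valid_active

    n_total = mags.shape[0]
    logger.info(
        "fit_t1_map[%s]: %d/%d voxels valid (%.1f%% invalid)",
        series.time_label,
        int(valid.sum()),
        n_total,
        100.0 * (1.0 - valid.sum() / n_total),
    )
    return RelaxationMap(
        t1_values=t1.reshape(shape),
        validity_mask=valid.reshape(shape),
        fit_quality=rms.reshape(shape),
        time_label=series.time_label,
    )


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------


def save_map(t1_map: RelaxationMap, stem) -> tuple:
    """Write a relaxation map as NIfTI: T1 (ms), validity mask, residual map."""
    import nibabel as nib
    from pathlib import Path

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = (
        stem.with_suffix(".nii.gz"),
        stem.parent / f"{stem.name}_mask.nii.gz",
        stem.parent / f"{stem.name}_residual.nii.gz",
    )
    t1 = np.where(np.isfinite(t1_map.t1_values), t1_map.t1_values, 0.0)
    resid = np.where(np.isfinite(t1_map.fit_quality), t1_map.fit_quality, 0.0)
    nib.save(nib.Nifti1Image(t1[:, :, None], np.eye(4)), str(paths[0]))
    nib.save(
        nib.Nifti1Image(t1_map.validity_mask.astype(np.uint8)[:, :, None], np.eye(4)),
        str(paths[1]),
    )
    nib.save(nib.Nifti1Image(resid[:, :, None], np.eye(4)), str(paths[2]))
    return paths


def load_map(stem, time_label: str = "") -> RelaxationMap:
    """Read a relaxation map written by :func:`save_map`."""
    import nibabel as nib
    from pathlib import Path

    stem = Path(stem)
    t1 = np.asarray(nib.load(str(stem.with_suffix(".nii.gz"))).dataobj, dtype=float)[:, :, 0]
    mask_path = stem.parent / f"{stem.name}_mask.nii.gz"
    resid_path = stem.parent / f"{stem.name}_residual.nii.gz"
    mask = (
        np.asarray(nib.load(str(mask_path)).dataobj)[:, :, 0].astype(bool)
        if mask_path.exists()
        else t1 > 0
    )
    resid = (
        np.asarray(nib.load(str(resid_path)).dataobj, dtype=float)[:, :, 0]
        if resid_path.exists()
        else np.zeros_like(t1)
    )
    t1 = np.where(mask, t1, np.nan)
    return RelaxationMap(t1_values=t1, validity_mask=mask, fit_quality=resid, time_label=time_label)
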