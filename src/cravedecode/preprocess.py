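"""Signal conditioning for block-design BOLD runs.

Temporal smoothing over three volumes, polynomial detrending, percent signal
change against a rest-defined baseline (volumes where the HRF-convolved
all-task regressor is at or below zero), blockwise GLM betas, automasking,
visual-region exclusion and framewise displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import CRAVE, NOCRAVE, Atlas, BoldRun, ExperimentDesign, hrf_regressor


class PreprocessError(ValueError):
    pass


def temporal_smooth(data: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average along time with truncated (renormalized) edges.

    ``data`` is (n_voxels, n_volumes) or (n_volumes,).  A window of 1 is the
    identity; a constant series is invariant.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    n = arr.shape[1]
    if window > n:
        raise PreprocessError(f"window {window} exceeds series length {n}")
    kernel = np.ones(window)
    sums = ndimage.convolve1d(arr, kernel, axis=1, mode="constant", cval=0.0)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    out = sums / counts
    return out if np.ndim(data) > 1 else out[0]


def detrend(data: np.ndarray, order: int = 1) -> np.ndarray:
    """Remove a per-voxel least-squares polynomial of the given order.

    Output has zero temporal mean per voxel (the polynomial includes the
    constant term).  order=0 is mean-centering.
    """
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    n = arr.shape[1]
    if n < order + 2:
        raise PreprocessError("too few volumes for the requested order")
    x = np.linspace(-1.0, 1.0, n)
    basis = np.vander(x, order + 1, increasing=True)  # 1, x, x^2, ...
    coef, *_ = np.linalg.lstsq(basis, arr.T, rcond=None)
    resid = arr - (basis @ coef).T
    return resid if np.ndim(data) > 1 else resid[0]


@dataclass
class PscRun:
    """Percent-signal-change data with the baseline it was computed against."""

    data: np.ndarray  # (n_voxels, n_volumes), %
    baseline: np.ndarray  # (n_voxels,)
    mask: np.ndarray  # bool, excludes non-positive-baseline voxels
    design: ExperimentDesign


def all_task_regressor(design: ExperimentDesign) -> np.ndarray:
    return hrf_regressor(design, (CRAVE, NOCRAVE))


def compute_psc(
    data: np.ndarray,
    design: ExperimentDesign,
    mask: np.ndarray | None = None,
    task_regressor: np.ndarray | None = None,
) -> PscRun:
    """Convert raw intensities to percent signal change.

    The per-voxel baseline is the mean intensity over volumes where the
    HRF-convolved all-task regressor is <= 0 — i.e. the fixation/rest state.
    Voxels with non-positive baseline are dropped from the output mask.
    """
    arr = np.asarray(data, dtype=float)
    reg = task_regressor if task_regressor is not None else all_task_regressor(design)
    rest = reg <= 0
    if not rest.any():
        raise PreprocessError("task regressor has no below-zero samples")
    baseline = arr[:, rest].mean(axis=1)
    out_mask = (np.ones(arr.shape[0], bool) if mask is None else mask.copy())
    bad = baseline <= 0
    out_mask &= ~bad
    safe = np.where(baseline > 0, baseline, 1.0)
    psc = 100.0 * (arr - baseline[:, None]) / safe[:, None]
    psc[bad] = 0.0
    return PscRun(data=psc, baseline=baseline, mask=out_mask, design=design)


@dataclass
class BetaMap:
    """Per-block GLM coefficients plus condition-level aggregates."""

    block_betas: np.ndarray  # (n_voxels, n_task_blocks)
    block_conditions: list[str]
    condition_betas: dict[str, np.ndarray]  # condition -> (n_voxels,)
    condition_t: dict[str, np.ndarray]  # t of the condition-level contrast
    residual_var: np.ndarray  # (n_voxels,)
    dof: int


def glm_betas(
    data: np.ndarray,
    design: ExperimentDesign,
    include_nuisance: bool = True,
) -> BetaMap:
    """OLS fit of one HRF-convolved regressor per task block.

    The design matrix holds one column per crave / nocrave block (its
    block-specific boxcar convolved with the HRF) plus, by default, an
    intercept and a linear trend as near-orthogonal safeguards.  The
    condition-level beta is the mean of that condition's block betas.
    """
    arr = np.asarray(data, dtype=float)
    T = design.n_volumes
    cols, conds = [], []
    for i, b in enumerate(design.blocks):
        if b.condition not in (CRAVE, NOCRAVE):
            continue
        single = ExperimentDesign(
            run_type=design.run_type,
            tr=design.tr,
            blocks=(b,),
            total_duration=design.total_duration,
            n_volumes=T,
        )
        cols.append(hrf_regressor(single, (b.condition,)))
        conds.append(b.condition)
    X = np.column_stack(cols)
    if include_nuisance:
        X = np.column_stack([X, np.ones(T), np.linspace(-1, 1, T)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate a dependent column for the error message
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(j)
        raise PreprocessError(f"rank-deficient GLM design; collinear columns {bad}")
    coef, _, _, _ = np.linalg.lstsq(X, arr.T, rcond=None)
    fitted = (X @ coef).T
    resid = arr - fitted
    dof = T - X.shape[1]
    res_var = (resid**2).sum(axis=1) / max(dof, 1)
    betas = coef[: len(conds)].T
    xtx_inv = np.linalg.inv(X.T @ X)
    cond_betas, cond_t = {}, {}
    for c in (CRAVE, NOCRAVE):
        idx = [i for i, cc in enumerate(conds) if cc == c]
        if not idx:
            continue
        contrast = np.zeros(X.shape[1])
        contrast[idx] = 1.0 / len(idx)
        cond_betas[c] = betas[:, idx].mean(axis=1)
        se = np.sqrt(res_var * float(contrast @ xtx_inv @ contrast))
        with np.errstate(divide="ignore", invalid="ignore"):
            cond_t[c] = np.where(se > 0, cond_betas[c] / se, 0.0)
    return BetaMap(
        block_betas=betas,
        block_conditions=conds,
        condition_betas=cond_betas,
        condition_t=cond_t,
        residual_var=res_var,
        dof=dof,
    )


def automask(
    data: np.ndarray,
    grid_shape: tuple[int, int, int],
    clip_fraction: float = 0.5,
) -> np.ndarray:
    """Intensity-threshold brain mask, reduced to its largest 6-connected
    component.

    The threshold is ``clip_fraction`` times a robust peak of the
    mean-intensity distribution (98th percentile, insensitive to isolated
    bright voxels).
    """
    mean_img = np.asarray(data, dtype=float).mean(axis=1)
    peak = np.percentile(mean_img, 98)
    mask = mean_img >= clip_fraction * peak
    if not mask.any():
        raise PreprocessError("automask produced an empty mask")
    vol = mask.reshape(grid_shape)
    labelled, n = ndimage.label(vol, structure=ndimage.generate_binary_structure(3, 1))
    if n > 1:
        sizes = ndimage.sum_labels(vol, labelled, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        vol = labelled == keep
    return vol.ravel()


def exclude_regions(
    mask: np.ndarray, atlas: Atlas, labels: tuple[str, ...] = ("visual",)
) -> np.ndarray:
    """Remove the named atlas regions from the mask (explicit exclusion mask)."""
    import warnings

    drop = np.zeros_like(mask)
    for name in labels:
        drop |= atlas.voxels(name)  # KeyError for unknown labels
    out = mask & ~drop
    if not out.any():
        warnings.warn("exclusion removed every in-mask voxel", stacklevel=2)
    return out


@dataclass
class FdTrace:
    fd: np.ndarray  # (n_volumes,), mm
    condition_means: dict[str, float]


def compute_fd(
    motion: np.ndarray,
    design: ExperimentDesign | None = None,
    rotation_radius: float = 50.0,
) -> FdTrace:
    """Framewise displacement: summed absolute backward differences of the six
    rigid-body parameters, rotations converted to arc length on a
    ``rotation_radius`` mm sphere.  FD[0] = 0.
    """
    m = np.asarray(motion, dtype=float)
    if m.shape[0] != 6:
        raise ValueError("motion must be 6 x n_volumes")
    d = np.abs(np.diff(m, axis=1))
    fd = np.zeros(m.shape[1])
    fd[1:] = d[:3].sum(axis=0) + rotation_radius * d[3:].sum(axis=0)
    cond_means: dict[str, float] = {}
    if design is not None:
        conds = design.volume_conditions()
        for c in (CRAVE, NOCRAVE):
            sel = conds == c
            if sel.any():
                cond_means[c] = float(fd[sel].mean())
    return FdTrace(fd=fd, condition_means=cond_means)


def preprocess_run(
    run: BoldRun,
    smooth_window: int = 3,
    detrend_order: int = 1,
) -> PscRun:
    """Standard offline conditioning: smooth, detrend, then PSC.

    Detrending removes only the drift component, keeping each voxel's mean
    intensity, and PSC is then referenced to the rest-state baseline (mean
    over volumes where the all-task regressor is <= 0).  Referencing to the
    rest volumes rather than the run mean matters: a run-mean reference
    forces the task samples of a run to sum to zero per voxel, which makes
    held-out sample means anti-correlate with training-fold means and drives
    cross-validated accuracy below chance on null data.
    """
    sm = temporal_smooth(run.data, smooth_window)
    trendless = detrend(sm, detrend_order) + sm.mean(axis=1, keepdims=True)
    reg = all_task_regressor(run.design)
    rest = reg <= 0
    baseline = trendless[:, rest].mean(axis=1)
    mask = run.mask & (baseline > 0)
    safe = np.where(baseline > 0, baseline, 1.0)
    psc = 100.0 * (trendless - baseline[:, None]) / safe[:, None]
    psc[~(baseline > 0)] = 0.0
    return PscRun(data=psc, baseline=baseline, mask=mask, design=run.design)
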