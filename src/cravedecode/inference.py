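"""Group inference on classifier weight maps.

Per-subject weight maps are pseudo z-scored over the in-mask voxels, then
tested voxelwise with a one-sample t-test (against zero) or a one-way
repeated-measures ANOVA across the three runs.  Family-wise-corrected
p-values come from a max-statistic permutation null (sign flips per subject
for the t-test; within-subject run-label permutations for the ANOVA), with
plain Bonferroni available as an alternative.  Significant voxels are
grouped into 6-connected ROIs labelled by atlas majority.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage, stats

from .synth import Atlas


class InferenceError(ValueError):
    pass


def pseudo_z(weights: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize a weight map to zero mean, unit variance over in-mask
    voxels (population sd, i.e. divide by n).  Out-of-mask voxels are zeroed.
    Scale-invariant: w and 10w normalize identically."""
    w = np.asarray(weights, dtype=float)
    m = np.asarray(mask, bool)
    if m.sum() < 2:
        raise InferenceError("need at least 2 in-mask voxels")
    mu = w[m].mean()
    sd = w[m].std()  # population convention
    if sd == 0:
        raise InferenceError("zero variance over in-mask voxels")
    out = np.zeros_like(w)
    out[m] = (w[m] - mu) / sd
    return out


@dataclass
class StatMap:
    statistic: np.ndarray  # per in-mask voxel
    p_raw: np.ndarray
    p_corrected: np.ndarray
    mask: np.ndarray  # in-mask voxel selector on the full grid
    alpha: float = 0.05
    stat_name: str = "t"

    @property
    def significant(self) -> np.ndarray:
        return self.p_corrected < self.alpha

    def to_grid(self, values: np.ndarray, grid_shape) -> np.ndarray:
        out = np.zeros(self.mask.size)
        out[self.mask] = values
        return out.reshape(grid_shape)


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t vs 0; zero-variance voxels get +/-inf sentinels."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    t[zero_var & (mean == 0)] = 0.0
    return t


def group_ttest(maps: np.ndarray, mask: np.ndarray, alpha: float = 0.05) -> StatMap:
    """One-sample t-test of subject weight maps against zero.

    ``maps`` is (n_subjects, n_in_mask_voxels); two-sided raw p with
    df = n - 1.  Run :func:`permutation_correct` for corrected p.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise InferenceError("need at least 3 subjects")
    t = _one_sample_t(maps)
    p = 2 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df=n - 1)
    p[np.isinf(t)] = 0.0
    return StatMap(statistic=t, p_raw=p, p_corrected=np.minimum(p * maps.shape[1], 1.0),
                   mask=np.asarray(mask, bool), alpha=alpha, stat_name="t")


def _rm_anova_f(maps: np.ndarray) -> np.ndarray:
    """Voxelwise repeated-measures F for (n_subjects, 3 runs, n_voxels)."""
    n, k, _ = maps.shape
    grand = maps.mean(axis=(0, 1))
    run_means = maps.mean(axis=0)  # (k, V)
    subj_means = maps.mean(axis=1)  # (n, V)
    ss_runs = n * ((run_means - grand) ** 2).sum(axis=0)
    resid = maps - run_means[None] - subj_means[:, None] + grand[None, None]
    ss_err = (resid**2).sum(axis=(0, 1))
    df1, df2 = k - 1, (k - 1) * (n - 1)
    # degenerate voxels: both sums at rounding level of the data's magnitude
    scale = (maps**2).sum(axis=(0, 1)) + 1e-300
    tiny = 1e-24 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_runs / df1) / (ss_err / df2)
    degenerate = ss_err <= tiny
    f[degenerate & (ss_runs > tiny)] = np.inf
    f[degenerate & (ss_runs <= tiny)] = 0.0
    f[~np.isfinite(f) & ~degenerate] = 0.0
    return f


def group_anova(maps: np.ndarray, mask: np.ndarray, alpha: float = 0.05) -> StatMap:
    """One-way repeated-measures ANOVA with run as the within-subject factor.

    ``maps`` is (n_subjects, 3, n_in_mask_voxels); df = (2, 2(n-1)).
    Subject-constant offsets are absorbed by the blocking term.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[1] != 3:
        raise InferenceError("expected maps of shape (n_subjects, 3 runs, n_voxels)")
    n, k, V = maps.shape
    f = _rm_anova_f(maps)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    p = stats.f.sf(np.where(np.isfinite(f), f, 0.0), df1, df2)
    p[np.isinf(f)] = 0.0
    return StatMap(statistic=f, p_raw=p, p_corrected=np.minimum(p * V, 1.0),
                   mask=np.asarray(mask, bool), alpha=alpha, stat_name="F")


def permutation_correct(
    maps: np.ndarray,
    mask: np.ndarray,
    stat: str = "t",
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    method: str = "max_stat",
) -> StatMap:
    """Permutation-based family-wise correction of voxelwise group statistics.

    The exchangeability unit is the subject: sign flips of whole maps for the
    one-sample t, independent within-subject permutations of the run labels
    for the repeated-measures ANOVA.  ``method='max_stat'`` uses the maximum
    statistic over voxels per permutation (FWE control); ``'bonferroni'``
    Bonferroni-corrects the per-voxel permutation p-values instead.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null", stacklevel=2)
    maps = np.asarray(maps, dtype=float)
    rng = np.random.default_rng(seed)
    if stat == "t":
        observed = _one_sample_t(maps)
        obs_mag = np.abs(observed)
        n, V = maps.shape
        sumsq = (maps**2).sum(axis=0)
        perm_stats = np.empty((n_perm, V))
        chunk = max(1, int(5e6 // V))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            signs = rng.choice((-1.0, 1.0), size=(m, n))
            means = signs @ maps / n
            var = (sumsq[None, :] - n * means**2) / (n - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ts = means / np.sqrt(var / n)
            ts[~np.isfinite(ts)] = 0.0
            perm_stats[done : done + m] = np.abs(ts)
            done += m
        df_note = "t"
    elif stat == "F":
        observed = _rm_anova_f(maps)
        obs_mag = observed
        n, k, V = maps.shape
        perm_stats = np.empty((n_perm, V))
        for p_i in range(n_perm):
            perm = np.argsort(rng.random((n, k)), axis=1)
            shuffled = np.take_along_axis(maps, perm[:, :, None], axis=1)
            perm_stats[p_i] = _rm_anova_f(shuffled)
        df_note = "F"
    else:
        raise ValueError(f"unknown stat {stat!r}")

    finite_obs = np.where(np.isfinite(obs_mag), obs_mag, np.nanmax(
        np.where(np.isfinite(obs_mag), obs_mag, 0.0)) + 1.0)
    p_raw = (1.0 + (perm_stats >= finite_obs[None, :]).sum(axis=0)) / (1.0 + n_perm)
    if method == "max_stat":
        max_null = perm_stats.max(axis=1)
        p_corr = (1.0 + (max_null[:, None] >= finite_obs[None, :]).sum(axis=0)) / (
            1.0 + n_perm
        )
    elif method == "bonferroni":
        p_corr = np.minimum(p_raw * obs_mag.size, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return StatMap(statistic=observed, p_raw=p_raw, p_corrected=p_corr,
                   mask=np.asarray(mask, bool), alpha=alpha, stat_name=df_note)


@dataclass
class Roi:
    label: str
    voxels: np.ndarray  # flat indices on the full grid
    centroid: tuple[float, float, float]
    mean_statistic: float


@dataclass
class ROISet:
    rois: list[Roi]

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)


def extract_rois(
    stat_map: StatMap,
    atlas: Atlas,
    alpha: float | None = None,
    min_extent: int = 3,
) -> ROISet:
    """6-connected components of the significance mask, size-filtered and
    labelled by the majority atlas region (component index appended when a
    region yields several clusters)."""
    alpha = stat_map.alpha if alpha is None else alpha
    grid = atlas.grid_shape
    sig = np.zeros(stat_map.mask.size, bool)
    sig[stat_map.mask] = stat_map.p_corrected < alpha
    vol = sig.reshape(grid)
    labelled, n = ndimage.label(vol, structure=ndimage.generate_binary_structure(3, 1))
    stat_full = np.zeros(stat_map.mask.size)
    stat_full[stat_map.mask] = np.where(
        np.isfinite(stat_map.statistic), stat_map.statistic, 0.0
    )
    rois: list[Roi] = []
    flat_labels = labelled.ravel()
    counts: dict[str, int] = {}
    for comp in range(1, n + 1):
        vox = np.flatnonzero(flat_labels == comp)
        if len(vox) < min_extent:
            continue
        region_codes = atlas.labels[vox]
        codes, freq = np.unique(region_codes, return_counts=True)
        majority = atlas.names[int(codes[np.argmax(freq)])]
        counts[majority] = counts.get(majority, 0) + 1
        label = majority if counts[majority] == 1 else f"{majority}_{counts[majority]}"
        coords = np.array(np.unravel_index(vox, grid)).T
        rois.append(
            Roi(
                label=label,
                voxels=vox,
                centroid=tuple(coords.mean(axis=0)),
                mean_statistic=float(stat_full[vox].mean()),
            )
        )
    return ROISet(rois=rois)
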