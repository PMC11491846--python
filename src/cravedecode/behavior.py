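"""Brain-behaviour association statistics.

A single smoking-severity score per subject is taken as the first principal
component of the z-scored smoking measures; associations between that score
and ROI-averaged classifier weights are tested per run with a permutation p
on |r| and a percentile bootstrap CI, after listwise MAD-based outlier
removal, and the three per-run correlations are compared with Cochran's Q
heterogeneity statistic on Fisher-z transformed coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import ROISet

logger = logging.getLogger(__name__)

MEASURE_COLUMNS = (
    "cigarettes_per_day",
    "cigarette_use_form",
    "ftnd_score",
    "sjws_smoking",
    "co_ppm",
    "co_hb_pct",
)


def pca_first_component(
    measures: pd.DataFrame, columns: tuple[str, ...] = MEASURE_COLUMNS
) -> pd.Series:
    """First-principal-component score per subject from z-scored measures.

    Rows with any missing value are dropped; constant columns are dropped
    with a log note.  The sign is fixed so the cigarettes-per-day loading is
    positive (severity increases with the score).
    """
    cols = [c for c in columns if c in measures.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 measure columns")
    sub = measures[cols].dropna(axis=0)
    keep = [c for c in cols if sub[c].std() > 0]
    for c in cols:
        if c not in keep:
            logger.info("dropping constant measure column %r", c)
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant measure columns")
    Z = (sub[keep] - sub[keep].mean()) / sub[keep].std(ddof=1)
    corr = np.corrcoef(Z.to_numpy().T)
    if np.any(np.abs(corr[np.triu_indices_from(corr, 1)]) > 0.95):
        logger.info("near-collinear measure columns present (kept)")
    cov = np.cov(Z.to_numpy().T)
    vals, vecs = np.linalg.eigh(cov)
    pc1 = vecs[:, np.argmax(vals)]
    if "cigarettes_per_day" in keep and pc1[keep.index("cigarettes_per_day")] < 0:
        pc1 = -pc1
    scores = Z.to_numpy() @ pc1
    return pd.Series(scores, index=sub.index, name="pc1")


def mad_outliers(x: np.ndarray, k: float = 2.5) -> np.ndarray:
    """Keep-mask flagging points more than k robust SDs from the median.

    The robust SD is 1.4826 * MAD.  Zero MAD flags nothing (with a warning):
    the scale is degenerate and no point can be distinguished.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; no outliers flagged", stacklevel=2)
        return np.ones(len(x), bool)
    z = np.abs(x - med) / (1.4826 * mad)
    return z <= k


@dataclass
class AssociationResult:
    roi: str
    run: int
    r: float
    slope: float
    intercept: float
    p_perm: float
    ci_low: float
    ci_high: float
    n_used: int


def regress_roi(
    scores: np.ndarray,
    roi_features: np.ndarray,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
    mad_k: float = 2.5,
    roi: str = "",
    run: int = 0,
) -> AssociationResult:
    """Association between behaviour scores and an ROI brain feature.

    Pairs flagged as MAD outliers in either variable are removed listwise.
    The permutation p is two-sided on |r| with the +1 correction; the 95% CI
    is a percentile bootstrap over subjects.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(roi_features, dtype=float)
    keep = mad_outliers(x, mad_k) & mad_outliers(y, mad_k)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 5:
        raise ValueError("fewer than 5 pairs after outlier removal")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate variance in one variable")
    rng = np.random.default_rng(seed)
    r = float(np.corrcoef(x, y)[0, 1])
    slope, intercept = np.polyfit(x, y, 1)

    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = (xc[perm_idx] * yc[None, :]).mean(axis=1)
    p_perm = float((1 + (np.abs(r_perm) >= abs(r) - 1e-12).sum()) / (1 + n_perm))

    boot_idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[boot_idx], y[boot_idx]
    xb = xb - xb.mean(axis=1, keepdims=True)
    yb = yb - yb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xb**2).sum(axis=1) * (yb**2).sum(axis=1))
    valid = denom > 0
    r_boot = (xb * yb).sum(axis=1)[valid] / denom[valid]
    ci_low, ci_high = np.percentile(r_boot, [2.5, 97.5])
    return AssociationResult(
        roi=roi, run=run, r=r, slope=float(slope), intercept=float(intercept),
        p_perm=p_perm, ci_low=float(ci_low), ci_high=float(ci_high), n_used=n,
    )


@dataclass
class HeterogeneityResult:
    roi: str
    Q: float
    df: int
    p: float


def q_heterogeneity(r: np.ndarray, n: np.ndarray, roi: str = "") -> HeterogeneityResult:
    """Cochran's Q for homogeneity of correlations across runs.

    Fisher z transform with inverse-variance weights n - 3:
    Q = sum w_i (z_i - z_bar)^2, chi-square with k - 1 df under homogeneity.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if np.any(n < 4):
        raise ValueError("each correlation needs n >= 4")
    z = np.arctanh(r)
    w = n - 3.0
    zbar = (w * z).sum() / w.sum()
    Q = float((w * (z - zbar) ** 2).sum())
    df = len(r) - 1
    return HeterogeneityResult(roi=roi, Q=Q, df=df, p=float(stats.chi2.sf(Q, df)))


def roi_mean_weights(weight_maps: np.ndarray, roi_voxels: np.ndarray) -> np.ndarray:
    """Mean weight inside an ROI per subject; maps are (n_subjects, n_grid)."""
    return np.asarray(weight_maps)[:, roi_voxels].mean(axis=1)


def run_association_stage(
    behavior: pd.DataFrame,
    weight_maps_by_run: np.ndarray,
    roi_set: ROISet,
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
    mad_k: float = 2.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI, per-run associations plus Q heterogeneity per ROI.

    ``weight_maps_by_run`` is (n_subjects, 3 runs, n_grid_voxels) of
    pseudo-z weight maps on the full grid; subjects whose behaviour row has
    missing values are dropped before scoring.
    """
    if len(roi_set) == 0:
        logger.info("empty ROI set; no associations computed")
        return pd.DataFrame(), pd.DataFrame()
    scores = pca_first_component(behavior)
    subj_idx = scores.index.to_numpy()
    assoc_rows, het_rows = [], []
    ss = np.random.SeedSequence(seed)
    for roi in roi_set:
        rs, ns = [], []
        for run in range(weight_maps_by_run.shape[1]):
            feats = roi_mean_weights(weight_maps_by_run[subj_idx, run], roi.voxels)
            child = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
            res = regress_roi(
                scores.to_numpy(), feats, n_perm=n_perm, n_boot=n_boot,
                seed=child, mad_k=mad_k, roi=roi.label, run=run,
            )
            assoc_rows.append(res.__dict__)
            rs.append(res.r)
            ns.append(res.n_used)
        het = q_heterogeneity(np.array(rs), np.array(ns), roi=roi.label)
        het_rows.append(het.__dict__)
    return pd.DataFrame(assoc_rows), pd.DataFrame(het_rows)
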