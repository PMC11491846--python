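"""Offline nested cross-validated decoding.

Individual-level decoding operates on volume-wise percent-signal-change
samples; group-level decoding on per-subject condition beta maps.  Both use
leakage-safe global min-max scaling fitted on the training folds only, a
nu-SVM grid search (nu = 0.1..0.8) chosen on the validation fold, and
rotating 10-fold train/validation/test partitions re-shuffled across repeats.
A fixed-C SVM (C = 200, the online parameterization) is available for the
online-vs-offline comparison, and frozen models can be re-tested across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC, NuSVC

from . import preprocess
from .online_nf import ClassifierModel
from .synth import CRAVE, NOCRAVE, Cohort, SubjectData

logger = logging.getLogger(__name__)

NU_GRID = tuple(np.round(np.arange(0.1, 0.81, 0.1), 10))


# ---------------------------------------------------------------------------
# Scaling and folds
# ---------------------------------------------------------------------------

def minmax_fit(train_matrix: np.ndarray) -> tuple[float, float]:
    """Global (min, max) over the entire training matrix — all voxels and all
    samples jointly.  Applying the transform to held-out data may produce
    values outside [0, 1]; that is the leakage-safe contract."""
    arr = np.asarray(train_matrix, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        raise ValueError("training matrix is constant; min-max scaling undefined")
    return lo, hi


def minmax_apply(x: np.ndarray, scaling: tuple[float, float]) -> np.ndarray:
    lo, hi = scaling
    return (np.asarray(x, dtype=float) - lo) / (hi - lo)


def minmax_fit_per_voxel(train_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel variant (columns scaled independently); non-default."""
    arr = np.asarray(train_matrix, dtype=float)
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    if np.any(hi <= lo):
        raise ValueError("constant voxel in training matrix")
    return lo, hi


@dataclass
class CvScheme:
    n_folds: int = 10
    n_repeats: int = 20
    seed: int = 0


@dataclass(frozen=True)
class FoldSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def make_folds(
    n_samples: int, n_folds: int = 10, rng: np.random.Generator | None = None
) -> FoldSplit:
    """One shuffled partition into near-equal folds with rotating roles.

    Fold sizes differ by at most one.  The test fold is drawn from the
    largest folds and the validation fold from the next largest, so the
    canonical sample counts are reproduced: 144 samples -> 114/15/15 and 31
    subjects -> 24/3/4 (train/validation/test).
    """
    if n_samples < n_folds:
        raise ValueError("need at least one sample per fold")
    rng = rng or np.random.default_rng(0)
    idx = rng.permutation(n_samples)
    base, extra = divmod(n_samples, n_folds)
    sizes = [base + 1] * extra + [base] * (n_folds - extra)
    folds, start = [], 0
    for s in sizes:
        folds.append(idx[start : start + s])
        start += s
    order = np.argsort([-len(f) for f in folds], kind="stable")
    test_fold = folds[order[0]]
    val_fold = folds[order[1]]
    train_idx = np.concatenate(
        [f for k, f in enumerate(folds) if k not in (order[0], order[1])]
    )
    return FoldSplit(train=train_idx, validation=val_fold, test=test_fold)


# ---------------------------------------------------------------------------
# Nested CV
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    test_acc: np.ndarray  # per repeat, percent
    train_acc: np.ndarray
    chosen: list  # per repeat selected hyperparameter
    model: ClassifierModel  # refit on all samples with the modal parameter

    @property
    def mean(self) -> float:
        return float(self.test_acc.mean())

    @property
    def sd(self) -> float:
        return float(self.test_acc.std(ddof=1)) if len(self.test_acc) > 1 else 0.0


def _fit_linear(model_family: str, param: float, X: np.ndarray, y: np.ndarray):
    if model_family == "nu_svm":
        clf = NuSVC(kernel="linear", nu=param, tol=1e-6)
    elif model_family == "c_svm":
        clf = SVC(kernel="linear", C=param, tol=1e-6)
    else:
        raise ValueError(f"unknown model family {model_family!r}")
    clf.fit(X, y)
    return clf


def nested_cv(
    samples: np.ndarray,
    labels: np.ndarray,
    scheme: CvScheme,
    model_family: str = "nu_svm",
    C: float = 200.0,
    nu_grid: tuple[float, ...] = NU_GRID,
    groups: np.ndarray | None = None,
) -> CvResult:
    """Nested cross-validation with validation-fold hyperparameter selection.

    When ``groups`` is given (group-level decoding), folding is over unique
    groups and every sample of a group follows its fold, so subjects never
    straddle the train/test boundary.  Infeasible nu values for a fold are
    skipped with a logged note.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    ss = np.random.SeedSequence(scheme.seed)
    test_accs, train_accs, chosen = [], [], []
    if groups is not None:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
    for rep, child in enumerate(ss.spawn(scheme.n_repeats)):
        rng = np.random.default_rng(child)
        if groups is None:
            split = make_folds(len(y), scheme.n_folds, rng)
            tr, va, te = split.train, split.validation, split.test
        else:
            gsplit = make_folds(len(uniq), scheme.n_folds, rng)
            tr = np.flatnonzero(np.isin(groups, uniq[gsplit.train]))
            va = np.flatnonzero(np.isin(groups, uniq[gsplit.validation]))
            te = np.flatnonzero(np.isin(groups, uniq[gsplit.test]))
        scaling = minmax_fit(X[tr])
        Xtr, Xva, Xte = (minmax_apply(X[s], scaling) for s in (tr, va, te))
        if model_family == "c_svm":
            clf = _fit_linear("c_svm", C, Xtr, y[tr])
            best_param, best_clf = C, clf
        else:
            best_param, best_clf, best_val = None, None, -np.inf
            for nu in nu_grid:
                try:
                    clf = _fit_linear("nu_svm", nu, Xtr, y[tr])
                except ValueError:
                    logger.debug("nu=%.1f infeasible in repeat %d; skipped", nu, rep)
                    continue
                val_acc = float((clf.predict(Xva) == y[va]).mean())
                if val_acc > best_val:
                    best_val, best_param, best_clf = val_acc, nu, clf
            if best_clf is None:
                raise ValueError("every nu value was infeasible")
        test_accs.append(100.0 * float((best_clf.predict(Xte) == y[te]).mean()))
        train_accs.append(100.0 * float((best_clf.predict(Xtr) == y[tr]).mean()))
        chosen.append(best_param)

    # refit on all samples with the modal selected parameter for weight maps
    vals, counts = np.unique(chosen, return_counts=True)
    modal = float(vals[np.argmax(counts)])
    scaling_all = minmax_fit(X)
    clf_all = _fit_linear(model_family, modal, minmax_apply(X, scaling_all), y)
    model = ClassifierModel(
        weights=clf_all.coef_.ravel().copy(),
        bias=float(clf_all.intercept_[0]),
        hyperparams={
            "kernel": "linear",
            ("nu" if model_family == "nu_svm" else "C"): modal,
        },
        scaling=scaling_all,
    )
    return CvResult(
        test_acc=np.array(test_accs),
        train_acc=np.array(train_accs),
        chosen=chosen,
        model=model,
    )


def retest(model: ClassifierModel, samples: np.ndarray, labels: np.ndarray) -> float:
    """Accuracy (%) of a frozen model on another run's samples.

    The model's own training scaling is applied; the feature dimension must
    match the training mask."""
    X = np.asarray(samples, dtype=float)
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError("feature dimension does not match the trained model")
    if model.scaling is not None:
        X = minmax_apply(X, model.scaling)
    d = X @ model.weights + model.bias
    pred = np.where(d > 0, 1, -1)
    y = np.asarray(labels)
    return 100.0 * float((pred == y).mean())


# ---------------------------------------------------------------------------
# Contrasts over a cohort
# ---------------------------------------------------------------------------

RUN_PAIRS = ((0, 1), (0, 2), (1, 2))
CONDITION_SELECTIONS = ("collapsed", "crave_only", "nocrave_only")


@dataclass(frozen=True)
class Contrast:
    axis: str  # "run_pair" | "condition"
    runs: tuple[int, ...]  # pair of run indices, or a single run
    condition_selection: str = "collapsed"
    mask_policy: str = "whole_brain"

    def __post_init__(self):
        if self.axis == "run_pair" and self.mask_policy != "exclude_visual":
            object.__setattr__(self, "mask_policy", "exclude_visual")

    @property
    def name(self) -> str:
        runs = "v".join(f"run{r + 1}" for r in self.runs)
        return f"{self.axis}:{runs}:{self.condition_selection}"


def run_pair_contrasts() -> list[Contrast]:
    """The nine run-pair contrasts: 3 run pairs x 3 condition selections."""
    return [
        Contrast("run_pair", pair, sel, "exclude_visual")
        for pair in RUN_PAIRS
        for sel in CONDITION_SELECTIONS
    ]


def condition_contrasts() -> list[Contrast]:
    return [Contrast("condition", (r,), "collapsed", "whole_brain") for r in range(3)]


def _contrast_mask(cohort: Cohort, contrast: Contrast) -> np.ndarray:
    if contrast.mask_policy == "exclude_visual":
        return preprocess.exclude_regions(cohort.mask, cohort.atlas, ("visual",))
    return cohort.mask


def psc_samples(
    subject: SubjectData,
    run_idx: int,
    mask: np.ndarray,
    condition_selection: str = "collapsed",
    _cache: dict | None = None,
    thin: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Volume-wise PSC samples and condition labels (+1 crave / -1 nocrave).

    First two volumes of every block are dropped; for feedback runs the
    first crave and nocrave blocks are excluded entirely.  ``thin`` keeps
    every thin-th retained volume: a stride of 3 (the smoothing window)
    decorrelates samples so CV accuracy reflects the evoked pattern rather
    than shared smoothed noise between temporally adjacent train and test
    volumes; the default 1 keeps every volume.
    """
    run = subject.runs[run_idx]
    key = (id(subject), run_idx)
    if _cache is not None and key in _cache:
        psc = _cache[key]
    else:
        psc = preprocess.preprocess_run(run)
        if _cache is not None:
            _cache[key] = psc
    keep = run.design.retained_task_volumes(
        drop_initial_volumes=2,
        drop_first_block_pair=(run.design.run_type == "feedback"),
    )
    conds = run.design.volume_conditions()
    if condition_selection == "crave_only":
        keep = keep & (conds == CRAVE)
    elif condition_selection == "nocrave_only":
        keep = keep & (conds == NOCRAVE)
    X = psc.data[np.asarray(mask, bool)][:, keep].T
    y = np.where(conds[keep] == CRAVE, 1, -1)
    if thin > 1:
        X, y = X[::thin], y[::thin]
    return X, y


def beta_maps(
    subject: SubjectData, run_idx: int, mask: np.ndarray, _cache: dict | None = None
) -> dict[str, np.ndarray]:
    """Condition-level GLM beta maps for one subject-run, restricted to mask."""
    key = (id(subject), run_idx, "beta")
    if _cache is not None and key in _cache:
        bm = _cache[key]
    else:
        run = subject.runs[run_idx]
        conditioned = preprocess.detrend(preprocess.temporal_smooth(run.data))
        bm = preprocess.glm_betas(conditioned, run.design)
        if _cache is not None:
            _cache[key] = bm
    m = np.asarray(mask, bool)
    return {c: v[m] for c, v in bm.condition_betas.items()}


def _balance_runs(
    Xa: np.ndarray, Xb: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the longer run's volumes so the two classes are balanced."""
    n = min(len(Xa), len(Xb))
    if len(Xa) > n:
        Xa = Xa[rng.choice(len(Xa), n, replace=False)]
    if len(Xb) > n:
        Xb = Xb[rng.choice(len(Xb), n, replace=False)]
    return Xa, Xb


@dataclass
class AccuracyCell:
    contrast: str
    level: str
    phase: str  # train | test
    values: np.ndarray  # percent; per subject (individual) or per repeat (group)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


@dataclass
class AccuracyTable:
    cells: list[AccuracyCell] = field(default_factory=list)
    models: dict = field(default_factory=dict)  # (contrast, level[, subject]) -> model

    def cell(self, contrast: str, level: str, phase: str = "test") -> AccuracyCell:
        for c in self.cells:
            if (c.contrast, c.level, c.phase) == (contrast, level, phase):
                return c
        raise KeyError((contrast, level, phase))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contrast": c.contrast,
                    "level": c.level,
                    "phase": c.phase,
                    "mean_acc": c.mean,
                    "sd_acc": c.sd,
                    "n": len(c.values),
                }
                for c in self.cells
            ]
        )


def run_contrasts(
    cohort: Cohort,
    contrasts: list[Contrast] | None = None,
    level: str = "individual",
    scheme: CvScheme | None = None,
    model_family: str = "nu_svm",
    thin: int = 1,
) -> AccuracyTable:
    """Evaluate every contrast at one level and assemble the accuracy table.

    Individual level: per-subject nested CV on volume-wise PSC; the stored
    cell values are per-subject mean test accuracies.  Group level: nested CV
    over subjects on condition beta maps; cell values are per-repeat test
    accuracies.
    """
    if contrasts is None:
        contrasts = run_pair_contrasts() + condition_contrasts()
    if scheme is None:
        scheme = CvScheme(n_repeats=20 if level == "individual" else 100)
    table = AccuracyTable()
    cache: dict = {}
    rng = np.random.default_rng(scheme.seed)
    for contrast in contrasts:
        mask = _contrast_mask(cohort, contrast)
        try:
            if level == "individual":
                _individual_cell(cohort, contrast, mask, scheme, model_family, table, cache, rng, thin)
            elif level == "group":
                _group_cell(cohort, contrast, mask, scheme, model_family, table, cache)
            else:
                raise ValueError(f"unknown level {level!r}")
        except ValueError as exc:
            warnings.warn(f"skipping {contrast.name} ({level}): {exc}", stacklevel=2)
    return table


def _individual_cell(cohort, contrast, mask, scheme, model_family, table, cache, rng, thin=1):
    subj_test, subj_train = [], []
    for s, subject in enumerate(cohort.subjects):
        if contrast.axis == "run_pair":
            i, j = contrast.runs
            Xa, _ = psc_samples(subject, i, mask, contrast.condition_selection, cache, thin)
            Xb, _ = psc_samples(subject, j, mask, contrast.condition_selection, cache, thin)
            Xa, Xb = _balance_runs(Xa, Xb, rng)
            X = np.vstack([Xa, Xb])
            y = np.concatenate([-np.ones(len(Xa)), np.ones(len(Xb))])
        else:
            (r,) = contrast.runs
            X, y = psc_samples(subject, r, mask, "collapsed", cache, thin)
        res = nested_cv(X, y, CvScheme(scheme.n_folds, scheme.n_repeats,
                                       scheme.seed + 1000 * s), model_family)
        subj_test.append(res.mean)
        subj_train.append(float(res.train_acc.mean()))
        table.models[(contrast.name, "individual", subject.spec.subject_id)] = res.model
    table.cells.append(AccuracyCell(contrast.name, "individual", "test", np.array(subj_test)))
    table.cells.append(AccuracyCell(contrast.name, "individual", "train", np.array(subj_train)))


def _group_cell(cohort, contrast, mask, scheme, model_family, table, cache):
    X_rows, y_rows, g_rows = [], [], []
    for s, subject in enumerate(cohort.subjects):
        if contrast.axis == "run_pair":
            for cls, r in enumerate(contrast.runs):
                maps = beta_maps(subject, r, mask, cache)
                if contrast.condition_selection == "crave_only":
                    v = maps[CRAVE]
                elif contrast.condition_selection == "nocrave_only":
                    v = maps[NOCRAVE]
                else:
                    v = 0.5 * (maps[CRAVE] + maps[NOCRAVE])
                X_rows.append(v)
                y_rows.append(2 * cls - 1)
                g_rows.append(s)
        else:
            (r,) = contrast.runs
            maps = beta_maps(subject, r, mask, cache)
            X_rows.extend([maps[NOCRAVE], maps[CRAVE]])
            y_rows.extend([-1, 1])
            g_rows.extend([s, s])
    res = nested_cv(
        np.array(X_rows), np.array(y_rows), scheme, model_family,
        groups=np.array(g_rows),
    )
    table.models[(contrast.name, "group")] = res.model
    table.cells.append(AccuracyCell(contrast.name, "group", "test", res.test_acc))
    table.cells.append(AccuracyCell(contrast.name, "group", "train", res.train_acc))


# ---------------------------------------------------------------------------
# Accuracy statistics
# ---------------------------------------------------------------------------

def compare_cells(
    a: np.ndarray, b: np.ndarray, paired: bool, bonferroni_n: int
) -> dict:
    """t-test between two accuracy vectors with Bonferroni correction.

    Paired for individual-level (per-subject) vectors, two-sample for
    group-level (per-repeat) vectors.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 observations per cell")
    if paired:
        if np.allclose(a, b):
            t, p, df = 0.0, 1.0, len(a) - 1
        else:
            t, p = stats.ttest_rel(a, b)
            df = len(a) - 1
    else:
        t, p = stats.ttest_ind(a, b)
        df = len(a) + len(b) - 2
    return {
        "t": float(t),
        "df": int(df),
        "p_raw": float(p),
        "p_corrected": float(min(1.0, p * bonferroni_n)),
    }


def trend_regression(vectors: list[np.ndarray], bonferroni_n: int | None = None) -> dict:
    """OLS of accuracy on ordered contrast index (0, 1, 2, ...)."""
    import statsmodels.api as sm

    x = np.concatenate([np.full(len(v), i, float) for i, v in enumerate(vectors)])
    y = np.concatenate([np.asarray(v, float) for v in vectors])
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    p = float(fit.pvalues[1])
    n = bonferroni_n if bonferroni_n is not None else len(y)
    return {
        "slope": float(fit.params[1]),
        "t": float(fit.tvalues[1]),
        "p_raw": p,
        "p_corrected": float(min(1.0, p * n)),
        "n": len(y),
    }


def compare_accuracies(table: AccuracyTable, level: str, bonferroni_n: int | None = None) -> dict:
    """The post-hoc battery over the three collapsed run-pair contrasts:
    pairwise t-tests plus a linear trend regression across the ordered
    contrasts, Bonferroni-corrected by the stated sample counts (100 for
    group per-repeat vectors, 31 for individual per-subject vectors)."""
    names = [f"run_pair:run{i + 1}vrun{j + 1}:collapsed" for i, j in RUN_PAIRS]
    cells = [table.cell(n, level) for n in names]
    paired = level == "individual"
    if bonferroni_n is None:
        bonferroni_n = len(cells[0].values)
    out = {"pairwise": {}, "trend": None}
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            out["pairwise"][f"{names[i]} vs {names[j]}"] = compare_cells(
                cells[i].values, cells[j].values, paired, bonferroni_n
            )
    out["trend"] = trend_regression([c.values for c in cells], bonferroni_n)
    return out


def motion_check(fd_table: pd.DataFrame, accuracies: np.ndarray,
                 bonferroni_n: int | None = None) -> dict:
    """Motion sanity statistics.

    ``fd_table`` has one row per subject with columns ``fd_crave`` and
    ``fd_nocrave`` (mean FD per condition, mm); ``accuracies`` are the
    per-subject individual condition-decoding accuracies (%).  Returns the
    paired condition t-test and the OLS of accuracy on the FD difference.
    """
    import statsmodels.api as sm

    a = fd_table["fd_crave"].to_numpy(float)
    b = fd_table["fd_nocrave"].to_numpy(float)
    n = len(a)
    bonf = bonferroni_n if bonferroni_n is not None else n
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    diff = a - b
    fit = sm.OLS(np.asarray(accuracies, float), sm.add_constant(diff)).fit()
    p_slope = float(fit.pvalues[1]) if fit.df_resid > 0 else 1.0
    return {
        "paired_t": {
            "t": float(t), "df": n - 1, "p_raw": float(p),
            "p_corrected": float(min(1.0, float(p) * bonf)),
        },
        "regression": {
            "slope": float(fit.params[1]),
            "t": float(fit.tvalues[1]),
            "p_raw": p_slope,
            "p_corrected": float(min(1.0, p_slope * bonf)),
        },
    }
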