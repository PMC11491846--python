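"""Reference experiments: recovery, calibration and oracle-agreement checks.

These functions run the package end to end on synthetic cohorts under the
study conditions and summarize what comes out: they back both the validation
suite and the reproduction script.  The quadratic-programming SVM solvers
here are deliberately independent reference implementations (generic
constrained optimisation on the primal/dual), used only to cross-check the
production libsvm path.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import minimize

from . import behavior, classify, inference, synth
from .classify import Contrast, CvScheme, run_contrasts

# ---------------------------------------------------------------------------
# Reference QP solvers
# ---------------------------------------------------------------------------

def qp_reference_csvm(X: np.ndarray, y: np.ndarray, C: float):
    """C-SVM via the box-constrained dual QP (SLSQP), for <=20-sample toys."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)
    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    pos, neg = y > 0, y < 0
    balanced = np.where(pos, 1.0 / pos.sum(), 1.0 / neg.sum())
    best = None
    for a0 in (np.zeros(n), balanced, 0.05 * C * balanced / balanced.max()):
        res = minimize(
            lambda a: 0.5 * a @ Q @ a - a.sum(),
            a0,
            jac=lambda a: Q @ a - 1.0,
            bounds=[(0.0, C)] * n,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 5000, "ftol": 1e-16},
        )
        if best is None or res.fun < best.fun:
            best = res
    a = best.x
    # KKT polish by active-set iteration: free SVs satisfy y_i f(x_i) = 1
    # exactly, alpha = C points have margin < 1, alpha = 0 points margin > 1;
    # re-solve the reduced linear system until the partition is consistent
    scale = max(a.max(), 1e-9)
    free = (a > 1e-5 * scale) & (a < C * (1 - 1e-6))
    upper = a >= C * (1 - 1e-6)
    fallback_w = (a * y) @ X
    on_margin = free
    fallback_b = (
        float(np.mean(y[on_margin] - X[on_margin] @ fallback_w))
        if on_margin.any()
        else 0.0
    )
    for _ in range(30):
        if not free.any():
            return fallback_w, fallback_b
        S = np.flatnonzero(free)
        B = np.flatnonzero(upper)
        k = len(S)
        A = np.zeros((k + 1, k + 1))
        A[:k, :k] = Q[np.ix_(S, S)]
        A[:k, k] = y[S]
        A[k, :k] = y[S]
        rhs = np.concatenate(
            [1.0 - Q[np.ix_(S, B)] @ np.full(len(B), C), [-C * y[B].sum()]]
        )
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return fallback_w, fallback_b
        a_new = np.zeros(n)
        a_new[S] = sol[:k]
        a_new[B] = C
        w = (a_new * y) @ X
        b = float(sol[k])
        margins = y * (X @ w + b)
        changed = False
        for i in range(n):
            if free[i] and a_new[i] < -1e-12:
                free[i] = False
                changed = True
            elif free[i] and a_new[i] > C:
                free[i], upper[i] = False, True
                changed = True
            elif upper[i] and margins[i] > 1 + 1e-10:
                upper[i], free[i] = False, True
                changed = True
            elif not free[i] and not upper[i] and margins[i] < 1 - 1e-10:
                free[i] = True
                changed = True
        if not changed:
            return w, b
    return fallback_w, fallback_b


def qp_reference_nusvm(X: np.ndarray, y: np.ndarray, nu: float):
    """nu-SVM via the dual QP; returns (w, b, rho).

    Dual: min 1/2 a'Qa subject to 0 <= a_i <= 1/n, a'y = 0, sum(a) = nu,
    with Q = yy' * XX'.  (b, rho) follow from the KKT conditions on the free
    support vectors.  libsvm reports decision values rescaled so the margin
    is 1, i.e. (w.x + b) / rho; callers must apply the same rescaling.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)
    cons = [
        {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y},
        {"type": "eq", "fun": lambda a: a.sum() - nu, "jac": lambda a: np.ones(n)},
    ]
    a0 = np.full(n, nu / n)
    # feasible start respecting a'y = 0: split nu equally between classes
    pos, neg = y > 0, y < 0
    a0[pos] = nu / 2 / pos.sum()
    a0[neg] = nu / 2 / neg.sum()
    res = minimize(
        lambda a: 0.5 * a @ Q @ a,
        a0,
        jac=lambda a: Q @ a,
        bounds=[(0.0, 1.0 / n)] * n,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 5000, "ftol": 1e-16},
    )
    a = res.x
    w = (a * y) @ X
    f = X @ w
    eps = 1e-8 / n
    free = (a > eps) & (a < 1.0 / n - eps)
    m_pos = f[free & pos].mean() if (free & pos).any() else f[pos].max()
    m_neg = f[free & neg].mean() if (free & neg).any() else f[neg].min()
    rho = (m_pos - m_neg) / 2.0
    b = -(m_pos + m_neg) / 2.0
    return w, float(b), float(rho)


def svm_qp_agreement(seed: int = 0, n_toys: int = 5) -> dict:
    """Max |decision difference| between the fitted SVMs and the QP reference
    on small random 2-D toys."""
    from sklearn.svm import SVC, NuSVC

    rng = np.random.default_rng(seed)
    worst_c, worst_nu = 0.0, 0.0
    done = 0
    while done < n_toys:
        # cleanly separable toys: with overlapping classes the nu-SVM margin
        # rho collapses and libsvm's dual stopping rule caps its attainable
        # decision precision near 1e-4, so neither side is well-posed there
        X = rng.standard_normal((12, 2))
        y = np.where(np.arange(12) % 2 == 0, 1.0, -1.0)
        X[:, 0] += 4.0 * y
        if X[y > 0, 0].min() <= X[y < 0, 0].max() + 1.0:
            continue
        done += 1
        svc = SVC(kernel="linear", C=200.0, tol=1e-8).fit(X, y)
        w, b = qp_reference_csvm(X, y, 200.0)
        worst_c = max(worst_c, float(np.abs(svc.decision_function(X) - (X @ w + b)).max()))
        nsv = NuSVC(kernel="linear", nu=0.3, tol=1e-8).fit(X, y)
        w2, b2, rho = qp_reference_nusvm(X, y, 0.3)
        d_ref = (X @ w2 + b2) / rho
        worst_nu = max(worst_nu, float(np.abs(nsv.decision_function(X) - d_ref).max()))
    return {"c_svm_max_abs_diff": worst_c, "nu_svm_max_abs_diff": worst_nu}


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

def individual_vs_group(
    shared_fraction: float,
    n_subjects: int = 8,
    n_seeds: int = 20,
    seed0: int = 0,
    run_idx: int = 1,
) -> dict:
    """Per-seed individual and group condition-decoding test accuracies.

    Individual level: nested CV on decorrelated volume-wise PSC per subject,
    averaged over subjects.  Group level: nested CV over subjects on
    condition beta maps.
    """
    contrast = [Contrast("condition", (run_idx,), "collapsed", "whole_brain")]
    ind, grp = [], []
    for k in range(n_seeds):
        seed = seed0 + k
        cohort = synth.simulate_cohort(
            n_subjects,
            synth.CohortSpec(shared_fraction=shared_fraction,
                             run_amplitudes=(2.5, 2.5, 2.5)),
            seed=seed,
        )
        t_ind = run_contrasts(cohort, contrast, "individual",
                              CvScheme(10, 2, seed), thin=3)
        t_grp = run_contrasts(cohort, contrast, "group", CvScheme(4, 8, seed))
        ind.append(t_ind.cell(contrast[0].name, "individual").mean)
        grp.append(t_grp.cell(contrast[0].name, "group").mean)
    ind, grp = np.array(ind), np.array(grp)
    t, p_two = stats.ttest_rel(ind, grp)
    p_one = p_two / 2 if t > 0 else 1 - p_two / 2
    return {
        "individual": ind,
        "group": grp,
        "mean_gap": float(ind.mean() - grp.mean()),
        "t": float(t),
        "p_one_sided": float(p_one),
    }


def learning_effect(
    n_seeds: int = 20,
    n_subjects: int = 8,
    seed0: int = 0,
    run_amplitudes: tuple[float, float, float] = (1.0, 2.0, 3.0),
) -> dict:
    """Per-run individual condition accuracy under increasing effect size.

    A seed counts as monotone when the per-run mean accuracy is
    non-decreasing across runs with a strict overall run-1 to run-3 gain.
    """
    monotone = 0
    curves = []
    for k in range(n_seeds):
        seed = seed0 + k
        cohort = synth.simulate_cohort(
            n_subjects,
            synth.CohortSpec(run_amplitudes=run_amplitudes),
            seed=seed,
        )
        accs = []
        for r in range(3):
            contrast = [Contrast("condition", (r,), "collapsed", "whole_brain")]
            t = run_contrasts(cohort, contrast, "individual",
                              CvScheme(10, 2, seed), thin=3)
            accs.append(t.cell(contrast[0].name, "individual").mean)
        curves.append(accs)
        if accs[0] <= accs[1] <= accs[2] and accs[2] > accs[0]:
            monotone += 1
    return {
        "curves": np.array(curves),
        "n_monotone": monotone,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Null calibration
# ---------------------------------------------------------------------------

def null_fwe_rate(
    n_cohorts: int = 50,
    n_subjects: int = 16,
    n_voxels: int = 680,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Fraction of pure-noise cohorts with any FWE-corrected detection."""
    rng = np.random.default_rng(seed)
    mask = np.ones(n_voxels, bool)
    rejections = 0
    for c in range(n_cohorts):
        maps = rng.standard_normal((n_subjects, n_voxels))
        sm = inference.permutation_correct(
            maps, mask, stat="t", n_perm=n_perm,
            seed=int(rng.integers(0, 2**31)), alpha=alpha,
        )
        rejections += int((sm.p_corrected < alpha).any())
    return {"fwe_rate": rejections / n_cohorts, "n_cohorts": n_cohorts}


def association_null_uniformity(
    n_sims: int = 100, n: int = 29, n_perm: int = 1000, seed: int = 0
) -> dict:
    """KS test of permutation-p uniformity for independent behaviour/ROI."""
    ps = []
    for k in range(n_sims):
        rng = np.random.default_rng(seed * 100_003 + k)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        res = behavior.regress_roi(
            x, y, n_perm=n_perm, n_boot=50, seed=seed + k, mad_k=1e9
        )
        ps.append(res.p_perm)
    ks = stats.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "mean_p": float(np.mean(ps))}
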