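"""Synthetic block-design BOLD cohorts for craving-decoding experiments.

This module generates everything the downstream stages consume without any
scanner data: jittered block designs for the no-feedback and feedback run
layouts, HRF-convolved condition regressors, and multi-subject voxel-by-volume
BOLD-like arrays carrying a known multivariate crave / don't-crave
discriminant pattern, low-frequency drift, autocorrelated noise and
motion-coupled artifacts.  Every generator is a pure function of its
parameters and a seed, so ground truth is always recoverable for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import gamma as gamma_dist

CRAVE = "crave"
NOCRAVE = "nocrave"
FIXATION = "fixation"

#: Canonical run layouts: block counts, jitter ranges (s) and exact totals (s).
RUN_LAYOUTS: dict[str, dict] = {
    "no_feedback": {
        "n_task_per_condition": 6,
        "task_range": (34.0, 46.0),
        "n_fixation": 13,
        "fixation_range": (12.0, 16.0),
        "total_duration": 684.0,
    },
    "feedback": {
        "n_task_per_condition": 7,
        "task_range": (28.0, 46.0),
        "n_fixation": 15,
        "fixation_range": (12.0, 16.0),
        "total_duration": 768.0,
    },
}


class DesignError(ValueError):
    """Raised when a run layout cannot tile the requested total duration."""


@dataclass(frozen=True)
class Block:
    condition: str
    onset: float
    duration: float


@dataclass(frozen=True)
class ExperimentDesign:
    """Block sequence for one run plus its sampling grid.

    Blocks tile ``[0, total_duration)`` with no gaps; onsets and durations
    are integer multiples of ``tr``.
    """

    run_type: str
    tr: float
    blocks: tuple[Block, ...]
    total_duration: float
    n_volumes: int

    def task_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.condition in (CRAVE, NOCRAVE)]

    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr

    def volume_conditions(self) -> np.ndarray:
        """Condition label of the block each volume's onset falls into."""
        labels = np.empty(self.n_volumes, dtype=object)
        t = self.volume_times()
        for b in self.blocks:
            in_block = (t >= b.onset) & (t < b.onset + b.duration)
            labels[in_block] = b.condition
        return labels

    def volume_block_ids(self) -> np.ndarray:
        """Index (into ``self.blocks``) of the block covering each volume."""
        ids = np.full(self.n_volumes, -1, dtype=int)
        t = self.volume_times()
        for i, b in enumerate(self.blocks):
            in_block = (t >= b.onset) & (t < b.onset + b.duration)
            ids[in_block] = i
        return ids

    def retained_task_volumes(
        self, drop_initial_volumes: int = 2, drop_first_block_pair: bool = False
    ) -> np.ndarray:
        """Boolean mask of analysed task volumes.

        The first ``drop_initial_volumes`` volumes of every task block are
        excluded (HRF rise / carry-over from the previous block).  For
        feedback runs the first crave and first nocrave blocks can also be
        dropped, mirroring the convention that unrewarded lead-in blocks are
        not analysed.
        """
        keep = np.zeros(self.n_volumes, dtype=bool)
        block_ids = self.volume_block_ids()
        seen: dict[str, int] = {CRAVE: 0, NOCRAVE: 0}
        for i, b in enumerate(self.blocks):
            if b.condition not in (CRAVE, NOCRAVE):
                continue
            seen[b.condition] += 1
            vols = np.flatnonzero(block_ids == i)
            if drop_first_block_pair and seen[b.condition] == 1:
                continue
            keep[vols[drop_initial_volumes:]] = True
        return keep


def _sample_durations_exact_sum(
    rng: np.random.Generator,
    ranges: list[tuple[float, float]],
    total: float,
    tr: float,
) -> list[float]:
    """Sample durations uniformly on the tr-grid subject to an exact sum.

    Candidates are drawn independently, then the residual is redistributed in
    +/- tr steps among randomly chosen blocks that still have slack.
    """
    lo = np.array([r[0] for r in ranges])
    hi = np.array([r[1] for r in ranges])
    if lo.sum() > total + 1e-9 or hi.sum() < total - 1e-9:
        raise DesignError(
            f"cannot reach total {total} s: feasible range "
            f"[{lo.sum()}, {hi.sum()}] s"
        )
    n_steps = np.round((hi - lo) / tr).astype(int)
    durations = lo + tr * rng.integers(0, n_steps + 1)
    residual = int(round((total - durations.sum()) / tr))
    step = tr if residual > 0 else -tr
    guard = 0
    while residual != 0:
        i = rng.integers(0, len(durations))
        new = durations[i] + step
        if lo[i] - 1e-9 <= new <= hi[i] + 1e-9:
            durations[i] = new
            residual -= int(np.sign(residual))
        guard += 1
        if guard > 100_000:  # pragma: no cover - cannot trigger for feasible configs
            raise DesignError("duration repair failed to converge")
    return durations.tolist()


def _condition_order(rng: np.random.Generator, n_per_condition: int) -> list[str]:
    """Pseudo-random counterbalanced order: at most two consecutive repeats."""
    base = [CRAVE] * n_per_condition + [NOCRAVE] * n_per_condition
    for _ in range(10_000):
        order = list(rng.permutation(base))
        runs = max(
            len(list(g))
            for g in _group_runs(order)
        )
        if runs <= 2:
            return order
    raise DesignError("could not counterbalance condition order")  # pragma: no cover


def _group_runs(seq: Sequence[str]):
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            yield seq[start:i]
            start = i


def make_run_design(
    run_type: str,
    tr: float = 2.0,
    seed: int = 0,
    layout: dict | None = None,
) -> ExperimentDesign:
    """Generate one jittered block design.

    Fixation blocks come first and last and separate every pair of task
    blocks; task-block durations are jittered on the tr grid inside the
    layout's range while the run total is held exactly at the layout's
    ``total_duration``.
    """
    if layout is None:
        if run_type not in RUN_LAYOUTS:
            raise ValueError(f"unknown run_type {run_type!r}")
        layout = RUN_LAYOUTS[run_type]
    rng = np.random.default_rng(seed)
    n_task = 2 * layout["n_task_per_condition"]
    n_fix = layout["n_fixation"]
    if n_fix != n_task + 1:
        raise DesignError("need one more fixation block than task blocks")
    ranges = [tuple(layout["task_range"])] * n_task + [
        tuple(layout["fixation_range"])
    ] * n_fix
    durations = _sample_durations_exact_sum(
        rng, ranges, layout["total_duration"], tr
    )
    task_durs, fix_durs = durations[:n_task], durations[n_task:]
    order = _condition_order(rng, layout["n_task_per_condition"])

    blocks: list[Block] = []
    t = 0.0
    for i in range(n_task):
        blocks.append(Block(FIXATION, t, fix_durs[i]))
        t += fix_durs[i]
        blocks.append(Block(order[i], t, task_durs[i]))
        t += task_durs[i]
    blocks.append(Block(FIXATION, t, fix_durs[-1]))
    t += fix_durs[-1]
    total = layout["total_duration"]
    assert abs(t - total) < 1e-6
    return ExperimentDesign(
        run_type=run_type,
        tr=tr,
        blocks=tuple(blocks),
        total_duration=total,
        n_volumes=int(round(total / tr)),
    )


# ---------------------------------------------------------------------------
# HRF
# ---------------------------------------------------------------------------

def double_gamma_hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF (response peak minus scaled undershoot)."""
    h = gamma_dist.pdf(t, 6.0, scale=peak / 5.0)
    h = h - gamma_dist.pdf(t, 16.0, scale=undershoot / 15.0) / ratio
    return h


def hrf_regressor(
    design: ExperimentDesign,
    condition_subset: Iterable[str] = (CRAVE,),
    oversample: int = 10,
    hrf_length: float = 32.0,
) -> np.ndarray:
    """HRF-convolved boxcar of the selected conditions, sampled at the TR.

    The kernel is normalized to unit integral, so a sustained block
    plateaus at 1.  Linear in the boxcar by construction.
    """
    conditions = set(condition_subset)
    if not conditions:
        raise ValueError("condition_subset must be non-empty")
    unknown = conditions - {CRAVE, NOCRAVE}
    if unknown:
        raise ValueError(f"unknown conditions {sorted(unknown)}")
    dt = design.tr / oversample
    n_hi = design.n_volumes * oversample
    box = np.zeros(n_hi)
    t_hi = np.arange(n_hi) * dt
    for b in design.blocks:
        if b.condition in conditions:
            box[(t_hi >= b.onset) & (t_hi < b.onset + b.duration)] = 1.0
    kernel = double_gamma_hrf(np.arange(0.0, hrf_length, dt))
    area = kernel.sum() * dt
    kernel = kernel / area
    reg = np.convolve(box, kernel)[:n_hi] * dt
    return reg[::oversample]


# ---------------------------------------------------------------------------
# Brain geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atlas:
    """Integer region labels per voxel with a name lookup (0 = background)."""

    labels: np.ndarray  # flattened, int
    names: dict[int, str]
    grid_shape: tuple[int, int, int]

    def code_for(self, name: str) -> int:
        for code, n in self.names.items():
            if n == name:
                return code
        raise KeyError(f"unknown atlas label {name!r}")

    def voxels(self, name: str) -> np.ndarray:
        return self.labels == self.code_for(name)


def make_brain(grid_shape: tuple[int, int, int] = (12, 12, 10)):
    """Ellipsoidal brain mask and a 6-region slab atlas on a small grid.

    The posterior slab (lowest y) is labelled ``visual`` so that
    visual-exclusion masking is exercised; the rest are R1..R5.
    """
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r2 = (
        ((x - cx) / (0.48 * nx)) ** 2
        + ((y - cy) / (0.48 * ny)) ** 2
        + ((z - cz) / (0.48 * nz)) ** 2
    )
    mask = (r2 <= 1.0).ravel()

    labels = np.zeros(nx * ny * nz, dtype=int)
    names = {0: "background", 1: "visual", 2: "R1", 3: "R2", 4: "R3", 5: "R4", 6: "R5"}
    yy = y.ravel()
    edges = np.linspace(0, ny, 7)
    for i in range(6):
        slab = (yy >= edges[i]) & (yy < edges[i + 1]) & mask
        labels[slab] = i + 1
    return mask, Atlas(labels=labels, names=names, grid_shape=grid_shape)


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmokingMeasures:
    cigarettes_per_day: float
    cigarette_use_form: float
    ftnd_score: float
    sjws_smoking: float
    co_ppm: float
    co_hb_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "cigarettes_per_day": self.cigarettes_per_day,
            "cigarette_use_form": self.cigarette_use_form,
            "ftnd_score": self.ftnd_score,
            "sjws_smoking": self.sjws_smoking,
            "co_ppm": self.co_ppm,
            "co_hb_pct": self.co_hb_pct,
        }


@dataclass
class SubjectSpec:
    """Generative parameters for one simulated participant.

    ``w_true`` is the voxelwise crave-vs-nocrave discriminant pattern in
    arbitrary units; ``run_amplitudes`` scales the evoked effect per run and
    is the generative handle for learning across repeated feedback runs.
    """

    subject_id: str
    grid_shape: tuple[int, int, int] = (12, 12, 10)
    w_true: np.ndarray | None = None
    run_amplitudes: tuple[float, float, float] = (2.0, 2.0, 2.0)
    #: per-run multiplicative gain applied to w_true inside the behaviour ROI
    roi_gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_voxels: np.ndarray | None = None
    noise_sd: float = 2.0
    ar_coef: float = 0.3
    drift_amplitude: float = 1.0
    motion_sd: float = 0.02
    motion_coupling: float = 0.05
    baseline: float = 1000.0
    behavior: SmokingMeasures | None = None

    def __post_init__(self):
        if len(self.run_amplitudes) != 3:
            raise ValueError("run_amplitudes must have length 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BoldRun:
    """One run's voxel x volume signal with its mask, atlas and motion trace."""

    design: ExperimentDesign
    data: np.ndarray  # (n_voxels, n_volumes)
    mask: np.ndarray  # (n_voxels,) bool
    atlas: Atlas
    motion: np.ndarray  # (6, n_volumes): 3 translations (mm), 3 rotations (rad)

    def __post_init__(self):
        if self.data.shape[1] != self.design.n_volumes:
            raise ValueError(
                f"data has {self.data.shape[1]} volumes, design expects "
                f"{self.design.n_volumes}"
            )
        if not self.mask.any():
            raise ValueError("mask selects no voxels")


def _ar1_noise(rng: np.random.Generator, shape, phi: float) -> np.ndarray:
    """AR(1) series with approximately unit marginal variance."""
    e = rng.standard_normal(shape)
    ar = sp_signal.lfilter([1.0], [1.0, -phi], e, axis=-1)
    return ar * np.sqrt(1.0 - phi**2)


def _bounded_walk(
    rng: np.random.Generator, n: int, step_sd: float, bound: float
) -> np.ndarray:
    steps = rng.standard_normal(n) * step_sd
    out = np.empty(n)
    pos = 0.0
    for i in range(n):
        pos = float(np.clip(pos + steps[i], -bound, bound))
        out[i] = pos
    return out


def simulate_run(
    spec: SubjectSpec,
    design: ExperimentDesign,
    run_index: int,
    mask: np.ndarray,
    atlas: Atlas,
    seed: int,
) -> BoldRun:
    """Simulate a single run under the additive generative model.

    signal = baseline + amplitude * s_cond * w_true * HRF-regressor
             + 2nd-order Legendre drift + AR(1)-plus-white noise
             + motion-coupled component,
    with s_cond = +1 for crave and -1 for nocrave blocks.
    """
    n_vox = int(np.prod(spec.grid_shape))
    if spec.w_true is None or len(spec.w_true) != n_vox:
        raise ValueError("spec.w_true length must match the voxel grid")
    if len(atlas.labels) != n_vox or len(mask) != n_vox:
        raise ValueError("grid shape and atlas/mask size disagree")
    rng = np.random.default_rng(seed)
    T = design.n_volumes

    reg = hrf_regressor(design, (CRAVE,)) - hrf_regressor(design, (NOCRAVE,))
    w = spec.w_true.copy()
    if spec.roi_voxels is not None:
        w = w.copy()
        w[spec.roi_voxels] *= spec.roi_gain[run_index]
    amp = spec.run_amplitudes[run_index]

    data = np.where(mask, spec.baseline, 0.0)[:, None] + amp * np.outer(w, reg)

    if spec.drift_amplitude > 0:
        x = np.linspace(-1.0, 1.0, T)
        basis = np.vstack([x, 0.5 * (3 * x**2 - 1)])  # Legendre P1, P2
        coefs = rng.standard_normal((n_vox, 2)) * spec.drift_amplitude
        data = data + coefs @ basis

    if spec.noise_sd > 0:
        ar = _ar1_noise(rng, (n_vox, T), spec.ar_coef)
        white = rng.standard_normal((n_vox, T))
        data = data + spec.noise_sd * (ar + white) / np.sqrt(2.0)

    motion = np.zeros((6, T))
    if spec.motion_sd > 0:
        for j in range(3):
            motion[j] = _bounded_walk(rng, T, spec.motion_sd, 2.0)
        for j in range(3, 6):
            motion[j] = _bounded_walk(rng, T, spec.motion_sd / 50.0, 0.04)
        if spec.motion_coupling > 0:
            coupling = rng.standard_normal((n_vox, 6)) * spec.motion_coupling
            mscale = np.abs(motion).max(axis=1, keepdims=True)
            mscale[mscale == 0] = 1.0
            data = data + coupling @ (motion / mscale)

    return BoldRun(design=design, data=data, mask=mask, atlas=atlas, motion=motion)


def simulate_subject(
    spec: SubjectSpec,
    designs: Sequence[ExperimentDesign],
    seed: int,
    mask: np.ndarray | None = None,
    atlas: Atlas | None = None,
) -> list[BoldRun]:
    """Simulate the three-run session (run 1 no-feedback, runs 2-3 feedback)."""
    if len(designs) != 3:
        raise ValueError("expected exactly 3 run designs")
    if mask is None or atlas is None:
        mask, atlas = make_brain(spec.grid_shape)
    children = np.random.SeedSequence(seed).spawn(3)
    return [
        simulate_run(spec, d, i, mask, atlas, int(children[i].generate_state(1)[0] % 2**31))
        for i, d in enumerate(designs)
    ]


@dataclass
class CohortSpec:
    """Study-level generative configuration.

    ``shared_fraction`` (rho) mixes a cohort-shared discriminant pattern with
    subject-unique patterns; ``behavior_coupling`` sets the generative
    correlation between the latent smoking-severity factor and either the
    subjects' ROI pattern strength (scalar) or the per-run ROI gain
    (length-3 sequence, modelling coupling that changes with training).
    """

    grid_shape: tuple[int, int, int] = (12, 12, 10)
    shared_fraction: float = 0.5
    run_amplitudes: tuple[float, float, float] = (2.0, 2.5, 3.0)
    noise_sd: float = 2.0
    ar_coef: float = 0.3
    drift_amplitude: float = 1.0
    motion_sd: float = 0.02
    motion_coupling: float = 0.05
    tr: float = 2.0
    behavior_roi: str = "R3"
    behavior_coupling: float | tuple[float, float, float] = 0.0
    roi_gain_sd: float = 0.3
    n_missing_behavior: int = 0

    def __post_init__(self):
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")


@dataclass
class SubjectData:
    spec: SubjectSpec
    runs: list[BoldRun]


@dataclass
class Cohort:
    subjects: list[SubjectData]
    behavior: pd.DataFrame
    mask: np.ndarray
    atlas: Atlas
    ground_truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _measures_from_latent(
    rng: np.random.Generator, z: float
) -> SmokingMeasures:
    # loadings chosen so every measure carries the latent severity factor,
    # CO %Hb nearly collinear with CO ppm as in field practice
    def mix(load, scale, loc, lo=0.0, hi=None):
        val = loc + scale * (load * z + np.sqrt(1 - load**2) * rng.standard_normal())
        return float(np.clip(val, lo, hi))

    co_ppm = mix(0.8, 6.0, 15.0, lo=1.0)
    return SmokingMeasures(
        cigarettes_per_day=mix(0.8, 8.0, 20.0, lo=1.0),
        cigarette_use_form=mix(0.4, 1.0, 2.0, lo=0.0, hi=4.0),
        ftnd_score=mix(0.7, 2.0, 5.0, lo=0.0, hi=10.0),
        sjws_smoking=mix(0.6, 1.5, 3.5, lo=0.0, hi=7.0),
        co_ppm=co_ppm,
        co_hb_pct=float(max(0.16 * co_ppm + 0.1 * rng.standard_normal(), 0.0)),
    )


def simulate_cohort(
    n_subjects: int,
    cohort_spec: CohortSpec | None = None,
    seed: int = 0,
) -> Cohort:
    """Simulate a full multi-subject cohort with ground truth attached.

    Each subject's discriminant pattern is
    ``w = unit(rho * w_shared + (1 - rho) * w_unique)`` over in-mask voxels.
    A latent smoking-severity factor drives the behaviour table; depending on
    ``behavior_coupling`` it is tied to the subjects' ROI pattern strength or
    to per-run ROI gains.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    spec = cohort_spec or CohortSpec()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    mask, atlas = make_brain(spec.grid_shape)
    n_vox = mask.size
    roi = atlas.voxels(spec.behavior_roi) & mask

    w_shared = np.zeros(n_vox)
    w_shared[mask] = rng.standard_normal(mask.sum())
    w_shared = _unit(w_shared)

    rho = spec.shared_fraction
    w_true = np.zeros((n_subjects, n_vox))
    for s in range(n_subjects):
        w_u = np.zeros(n_vox)
        w_u[mask] = rng.standard_normal(mask.sum())
        w_true[s] = _unit(rho * w_shared + (1.0 - rho) * _unit(w_u))

    per_run = isinstance(spec.behavior_coupling, (tuple, list, np.ndarray))
    roi_strength = np.abs(w_true[:, roi]).mean(axis=1)
    if per_run:
        z = rng.standard_normal(n_subjects)
        targets = np.asarray(spec.behavior_coupling, dtype=float)
        gains = np.ones((n_subjects, 3))
        for k in range(3):
            r = targets[k]
            y = r * z + np.sqrt(max(1 - r**2, 0.0)) * rng.standard_normal(n_subjects)
            gains[:, k] = 1.0 + spec.roi_gain_sd * y
    else:
        r = float(spec.behavior_coupling)
        f = (roi_strength - roi_strength.mean()) / (roi_strength.std() or 1.0)
        z = r * f + np.sqrt(max(1 - r**2, 0.0)) * rng.standard_normal(n_subjects)
        gains = np.ones((n_subjects, 3))

    design_seeds = ss.spawn(n_subjects)
    run_seeds = ss.spawn(n_subjects)
    subjects: list[SubjectData] = []
    rows = []
    missing = rng.choice(n_subjects, size=spec.n_missing_behavior, replace=False)
    for s in range(n_subjects):
        d_ss = design_seeds[s].spawn(3)
        designs = [
            make_run_design("no_feedback", spec.tr, int(d_ss[0].generate_state(1)[0] % 2**31)),
            make_run_design("feedback", spec.tr, int(d_ss[1].generate_state(1)[0] % 2**31)),
            make_run_design("feedback", spec.tr, int(d_ss[2].generate_state(1)[0] % 2**31)),
        ]
        measures = _measures_from_latent(rng, z[s])
        subj_spec = SubjectSpec(
            subject_id=f"sub-{s + 1:02d}",
            grid_shape=spec.grid_shape,
            w_true=w_true[s],
            run_amplitudes=tuple(spec.run_amplitudes),
            roi_gain=tuple(gains[s]),
            roi_voxels=roi if per_run else None,
            noise_sd=spec.noise_sd,
            ar_coef=spec.ar_coef,
            drift_amplitude=spec.drift_amplitude,
            motion_sd=spec.motion_sd,
            motion_coupling=spec.motion_coupling,
            behavior=measures,
        )
        runs = simulate_subject(
            subj_spec, designs, int(run_seeds[s].generate_state(1)[0] % 2**31),
            mask=mask, atlas=atlas,
        )
        subjects.append(SubjectData(spec=subj_spec, runs=runs))
        row = {"subject_id": subj_spec.subject_id, **measures.as_dict()}
        if s in missing:
            row = {k: (np.nan if k != "subject_id" else v) for k, v in row.items()}
        rows.append(row)

    behavior = pd.DataFrame(rows)
    ground_truth = {
        "w_shared": w_shared,
        "w_true": w_true,
        "latent": z,
        "roi_strength": roi_strength,
        "roi_gains": gains,
        "roi_label": spec.behavior_roi,
        "roi_voxels": roi,
        "cohort_spec": spec,
    }
    return Cohort(
        subjects=subjects,
        behavior=behavior,
        mask=mask,
        atlas=atlas,
        ground_truth=ground_truth,
    )
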