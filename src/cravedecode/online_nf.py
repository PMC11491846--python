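"""Real-time neurofeedback loop simulation.

Train a linear SVM (C = 200) on the prior run, classify each streamed task
volume of the current run by its signed hyperplane distance, remove a causal
running linear trend from the distance, discretize its magnitude into a dead
zone plus four bins, and integrate the binned signal into a slider that is
reset at each task-block onset.  Feedback is withheld during the first crave
and first nocrave blocks of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .synth import CRAVE, NOCRAVE, BoldRun

#: cumulative |d| thresholds: below the first is the no-move dead zone
BIN_THRESHOLDS = (0.2, 0.4, 0.6, 0.8)


@dataclass
class ClassifierModel:
    """Linear decision rule d(x) = weights . x + bias."""

    weights: np.ndarray
    bias: float
    hyperparams: dict
    scaling: tuple[float, float] | None = None  # (min, max) fitted on training data
    #: per-voxel training-run mean removed before classification (offset removal)
    reference: np.ndarray | None = None
    label_map: dict = field(default_factory=lambda: {1: CRAVE, -1: NOCRAVE})

    def decision(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.weights.shape[0]:
            raise ValueError(
                f"volume has {x.shape[-1]} features, model expects "
                f"{self.weights.shape[0]}"
            )
        if self.reference is not None:
            x = x - self.reference
        if self.scaling is not None:
            lo, hi = self.scaling
            x = (x - lo) / (hi - lo)
        return float(x @ self.weights + self.bias)


def train_online(
    samples: np.ndarray, labels: np.ndarray, C: float = 200.0
) -> ClassifierModel:
    """Fit the soft-margin linear SVM used for the online decoder.

    ``samples`` are (n_samples, n_voxels) preprocessed volumes with the first
    two volumes of every block already excluded; labels are +1 (crave) /
    -1 (nocrave).  The per-voxel training mean is removed before fitting
    (raw BOLD intensities sit on a large common baseline that would swamp
    the kernel) and stored in the model so streamed volumes receive the
    identical offset removal.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    X = np.asarray(samples, dtype=float)
    reference = X.mean(axis=0)
    svc = SVC(kernel="linear", C=C, tol=1e-6)
    svc.fit(X - reference, y)
    # sklearn orients coef_ toward the larger class label (+1)
    return ClassifierModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        hyperparams={"kernel": "linear", "C": C},
        reference=reference,
    )


def stream_classify(model: ClassifierModel, volume: np.ndarray) -> float:
    """Signed hyperplane distance (decision value) of one volume."""
    return model.decision(volume)


class RunningDetrender:
    """Causal removal of a linear trend and offset from the distance stream.

    At each step the OLS line through all distances observed so far in the
    run is subtracted from the current value; with fewer than two
    observations only the running mean is removed.
    """

    def __init__(self) -> None:
        self.n = 0
        self._st = self._stt = self._sd = self._std = 0.0

    def update(self, d: float) -> float:
        t = float(self.n)
        self.n += 1
        self._st += t
        self._stt += t * t
        self._sd += d
        self._std += t * d
        n = self.n
        mean_t = self._st / n
        mean_d = self._sd / n
        var_t = self._stt / n - mean_t**2
        if n < 2 or var_t <= 0:
            return d - mean_d
        slope = (self._std / n - mean_t * mean_d) / var_t
        intercept = mean_d - slope * mean_t
        return d - (intercept + slope * t)


def detrend_distance(history: np.ndarray) -> float:
    """Detrended value of the final element of a distance history."""
    det = RunningDetrender()
    out = 0.0
    for d in np.asarray(history, dtype=float):
        out = det.update(float(d))
    return out


def bin_distance(d_detrended: float) -> int:
    """Discretize |d| into bins 0..4 (half-open, lower-inclusive intervals).

    Bin 0 (|d| < 0.2) is the dead zone producing no slider movement; bin 4
    (|d| >= 0.8) is the ideal-performance bin.
    """
    return int(np.searchsorted(BIN_THRESHOLDS, abs(d_detrended), side="right"))


def update_slider(
    position: float,
    d_detrended: float,
    bin_index: int,
    block_length: int,
    feedback_active: bool = True,
) -> float:
    """One slider step: sign(d) * (bin/4) * (1/L), clamped to [-1, +1].

    With bin 4 and a consistent sign the slider reaches the endpoint exactly
    at block end; the slider is frozen while feedback is withheld.
    """
    if not feedback_active or bin_index == 0 or block_length <= 0:
        return position
    step = np.sign(d_detrended) * (bin_index / 4.0) / block_length
    return float(np.clip(position + step, -1.0, 1.0))


@dataclass
class FeedbackTrace:
    """Per-task-volume record of one simulated neurofeedback run."""

    table: pd.DataFrame  # volume, block, condition, d, d_detrended, bin,
    #                      slider, feedback_active, predicted, correct
    accuracy: float  # volume-wise accuracy on task volumes, fraction
    model: ClassifierModel


def training_samples(
    run: BoldRun, mask: np.ndarray | None = None, drop_initial_volumes: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Task-volume samples and +/-1 labels from a run, excluding the first
    ``drop_initial_volumes`` volumes of every block."""
    mask = run.mask if mask is None else mask
    keep = run.design.retained_task_volumes(drop_initial_volumes=drop_initial_volumes)
    conds = run.design.volume_conditions()
    X = run.data[np.asarray(mask, bool)][:, keep].T
    y = np.where(conds[keep] == CRAVE, 1, -1)
    return X, y


def run_nf_session(
    prior_run: BoldRun,
    current_run: BoldRun,
    mask: np.ndarray | None = None,
    C: float = 200.0,
) -> FeedbackTrace:
    """Full closed-loop simulation of one feedback run.

    The decoder is trained on the prior run; each task volume of the current
    run is then classified in stream order, distance-detrended causally,
    binned and integrated into the slider.  Fixation volumes emit nothing.
    """
    if prior_run.data.shape[0] != current_run.data.shape[0]:
        raise ValueError("prior and current runs use different voxel grids")
    mask = prior_run.mask if mask is None else np.asarray(mask, bool)
    X_train, y_train = training_samples(prior_run, mask)
    model = train_online(X_train, y_train, C=C)

    design = current_run.design
    conds = design.volume_conditions()
    block_ids = design.volume_block_ids()
    data = current_run.data[mask]

    # feedback withheld on the first crave and first nocrave block
    inactive_blocks = set()
    seen = set()
    for i, b in enumerate(design.blocks):
        if b.condition in (CRAVE, NOCRAVE) and b.condition not in seen:
            inactive_blocks.add(i)
            seen.add(b.condition)

    block_lengths = {
        i: int((block_ids == i).sum()) for i in np.unique(block_ids) if i >= 0
    }

    detrender = RunningDetrender()
    rows = []
    slider = 0.0
    prev_block = None
    for t in range(design.n_volumes):
        if conds[t] not in (CRAVE, NOCRAVE):
            continue
        blk = int(block_ids[t])
        if blk != prev_block:
            slider = 0.0
            prev_block = blk
        d = model.decision(data[:, t])
        d_det = detrender.update(d)
        b = bin_distance(d_det)
        active = blk not in inactive_blocks
        slider = update_slider(slider, d_det, b, block_lengths[blk], active)
        predicted = CRAVE if d > 0 else NOCRAVE
        rows.append(
            {
                "volume": t,
                "block": blk,
                "condition": conds[t],
                "d": d,
                "d_detrended": d_det,
                "bin": b,
                "slider": slider,
                "feedback_active": active,
                "predicted": predicted,
                "correct": predicted == conds[t],
            }
        )
    table = pd.DataFrame(rows)
    return FeedbackTrace(
        table=table, accuracy=float(table["correct"].mean()), model=model
    )
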