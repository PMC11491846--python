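"""Readers and writers for the standard on-disk formats.

Synthetic runs are written as 4D NIfTI plus BIDS-style events / motion TSVs;
full cohorts round-trip through a compact single-file .npz archive for
tests and pipeline restarts.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synth import Atlas, Block, BoldRun, ExperimentDesign


def write_run_nifti(run: BoldRun, path: str | Path, grid_shape) -> Path:
    """4D volume (x, y, z, t) with an identity affine."""
    vol = run.data.reshape(*grid_shape, run.data.shape[1])
    img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
    path = Path(path)
    nib.save(img, path)
    return path


def read_run_nifti(path: str | Path) -> np.ndarray:
    """Return (n_voxels, n_volumes) from a 4D NIfTI."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return data.reshape(-1, data.shape[-1])


def write_mask_nifti(mask: np.ndarray, path: str | Path, grid_shape) -> Path:
    img = nib.Nifti1Image(
        np.asarray(mask).reshape(grid_shape).astype(np.int16), affine=np.eye(4)
    )
    path = Path(path)
    nib.save(img, path)
    return path


def read_mask_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).ravel() > 0


def write_events_tsv(design: ExperimentDesign, path: str | Path) -> Path:
    rows = [
        {"onset": b.onset, "duration": b.duration, "trial_type": b.condition}
        for b in design.blocks
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(
    path: str | Path, run_type: str, tr: float
) -> ExperimentDesign:
    df = pd.read_csv(path, sep="\t")
    blocks = tuple(
        Block(r.trial_type, float(r.onset), float(r.duration))
        for r in df.itertuples()
    )
    total = max(b.onset + b.duration for b in blocks)
    return ExperimentDesign(
        run_type=run_type, tr=tr, blocks=blocks,
        total_duration=total, n_volumes=int(round(total / tr)),
    )


def write_motion_tsv(motion: np.ndarray, path: str | Path) -> Path:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    path = Path(path)
    pd.DataFrame(motion.T, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def read_motion_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(float).T


def write_behavior_tsv(behavior: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    behavior.to_csv(path, sep="\t", index=False)
    return path


def _design_record(design: ExperimentDesign) -> dict:
    return {
        "run_type": design.run_type,
        "tr": design.tr,
        "total_duration": design.total_duration,
        "n_volumes": design.n_volumes,
        "blocks": [[b.condition, b.onset, b.duration] for b in design.blocks],
    }


def _design_from_record(rec: dict) -> ExperimentDesign:
    return ExperimentDesign(
        run_type=rec["run_type"],
        tr=rec["tr"],
        blocks=tuple(Block(c, o, d) for c, o, d in rec["blocks"]),
        total_duration=rec["total_duration"],
        n_volumes=rec["n_volumes"],
    )


def write_cohort_archive(cohort, path: str | Path) -> Path:
    """Single-file .npz archive of a cohort's matrices and metadata."""
    from .synth import Cohort  # noqa: F401 - documented arg type

    arrays: dict[str, np.ndarray] = {
        "mask": cohort.mask,
        "atlas_labels": cohort.atlas.labels,
    }
    meta = {
        "grid_shape": list(cohort.atlas.grid_shape),
        "atlas_names": {str(k): v for k, v in cohort.atlas.names.items()},
        "subjects": [],
    }
    for s, subj in enumerate(cohort.subjects):
        meta["subjects"].append(
            {
                "subject_id": subj.spec.subject_id,
                "designs": [_design_record(r.design) for r in subj.runs],
            }
        )
        for r, run in enumerate(subj.runs):
            arrays[f"data_{s}_{r}"] = run.data.astype(np.float32)
            arrays[f"motion_{s}_{r}"] = run.motion
    arrays["behavior_json"] = np.frombuffer(
        cohort.behavior.to_json().encode(), dtype=np.uint8
    )
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    path = Path(path)
    np.savez_compressed(path, **arrays)
    return path


def read_cohort_archive(path: str | Path):
    """Rebuild the run-level view of a cohort archive (no ground truth)."""
    from .synth import Cohort, SubjectData, SubjectSpec

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        from io import StringIO

        behavior = pd.read_json(StringIO(bytes(z["behavior_json"]).decode()))
        mask = z["mask"]
        atlas = Atlas(
            labels=z["atlas_labels"],
            names={int(k): v for k, v in meta["atlas_names"].items()},
            grid_shape=tuple(meta["grid_shape"]),
        )
        subjects = []
        for s, rec in enumerate(meta["subjects"]):
            runs = []
            for r, drec in enumerate(rec["designs"]):
                runs.append(
                    BoldRun(
                        design=_design_from_record(drec),
                        data=z[f"data_{s}_{r}"].astype(float),
                        mask=mask.astype(bool),
                        atlas=atlas,
                        motion=z[f"motion_{s}_{r}"],
                    )
                )
            spec = SubjectSpec(
                subject_id=rec["subject_id"],
                grid_shape=tuple(meta["grid_shape"]),
                w_true=np.zeros(mask.size),
            )
            subjects.append(SubjectData(spec=spec, runs=runs))
    return Cohort(
        subjects=subjects, behavior=behavior, mask=mask.astype(bool),
        atlas=atlas, ground_truth={},
    )


def write_cohort_bids(cohort, out_dir: str | Path) -> Path:
    """BIDS-style layout: per-subject NIfTI runs + events/motion TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cohort.atlas.grid_shape
    write_mask_nifti(cohort.mask, out / "mask.nii.gz", grid)
    write_mask_nifti(cohort.atlas.labels, out / "atlas.nii.gz", grid)
    write_behavior_tsv(cohort.behavior, out / "participants.tsv")
    for subj in cohort.subjects:
        sdir = out / subj.spec.subject_id
        sdir.mkdir(exist_ok=True)
        for r, run in enumerate(subj.runs, start=1):
            write_run_nifti(run, sdir / f"run-{r}_bold.nii.gz", grid)
            write_events_tsv(run.design, sdir / f"run-{r}_events.tsv")
            write_motion_tsv(run.motion, sdir / f"run-{r}_motion.tsv")
    return out
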