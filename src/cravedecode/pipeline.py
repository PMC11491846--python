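"""End-to-end orchestration of the simulate / preprocess / online-NF /
classify / infer / associate pipeline, with a single master seed, a manifest
of every derived seed, and a structured JSON + TSV report bundle.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, behavior, classify, inference, online_nf, preprocess
from .synth import Cohort, CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(master: int, *keys) -> int:
    """Deterministic child seed from the master seed and a key path.

    Strings are hashed with CRC32; the derived value stays below 2**31 so it
    is valid for every downstream RNG.
    """
    ints = [int(master)]
    for k in keys:
        ints.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults are the canonical analysis constants
    (C = 200, nu grid 0.1-0.8 step 0.1, 10 folds, 20/100 CV repeats,
    10 000 permutations and bootstraps, bin thresholds 0.2/0.4/0.6/0.8)."""

    out_dir: str = "cravedecode_out"
    seed: int = 0
    # synthesis
    n_subjects: int = 8
    grid_shape: tuple[int, int, int] = (12, 12, 10)
    shared_fraction: float = 0.5
    run_amplitudes: tuple[float, float, float] = (2.0, 2.5, 3.0)
    noise_sd: float = 2.0
    behavior_coupling: float | tuple[float, float, float] = 0.0
    n_missing_behavior: int = 0
    # classifiers
    svm_c: float = 200.0
    nu_grid: tuple[float, ...] = classify.NU_GRID
    n_folds: int = 10
    n_repeats_individual: int = 20
    n_repeats_group: int = 100
    # inference / behaviour
    n_perm: int = 10_000
    n_boot: int = 10_000
    mad_k: float = 2.5
    anova_alpha: float = 0.05
    roi_min_extent: int = 3
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "preprocess", "online_nf", "classify", "infer", "assoc",
    )
    #: contrasts evaluated in the classify stage; None = all twelve
    contrast_set: str = "condition"  # "condition" | "run_pair" | "all"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nu_grid"] = list(self.nu_grid)
        return d


def _contrasts_for(config: PipelineConfig) -> list[classify.Contrast]:
    if config.contrast_set == "condition":
        return classify.condition_contrasts()
    if config.contrast_set == "run_pair":
        return classify.run_pair_contrasts()
    return classify.run_pair_contrasts() + classify.condition_contrasts()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the JSON-serializable summary.  A stage failure raises
    :class:`PipelineStageError` naming the stage; outputs of completed
    stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(), "stages": {}}
    manifest: dict = {
        "master_seed": config.seed,
        "derived_seeds": {},
        "versions": _versions(),
    }

    cohort: Cohort | None = None
    stage = "simulate"
    try:
        if "simulate" in config.stages:
            seed = derive_seed(config.seed, "simulate")
            manifest["derived_seeds"]["simulate"] = seed
            cohort = simulate_cohort(
                config.n_subjects,
                CohortSpec(
                    grid_shape=config.grid_shape,
                    shared_fraction=config.shared_fraction,
                    run_amplitudes=config.run_amplitudes,
                    noise_sd=config.noise_sd,
                    behavior_coupling=config.behavior_coupling,
                    n_missing_behavior=config.n_missing_behavior,
                ),
                seed=seed,
            )
            summary["stages"]["simulate"] = {
                "n_subjects": cohort.n_subjects,
                "n_voxels_in_mask": int(cohort.mask.sum()),
                "run_durations_s": [
                    r.design.total_duration for r in cohort.subjects[0].runs
                ],
            }
            cohort.behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)

        stage = "preprocess"
        fd_rows = []
        if "preprocess" in config.stages and cohort is not None:
            for subj in cohort.subjects:
                for r, run in enumerate(subj.runs):
                    tr_fd = preprocess.compute_fd(run.motion, run.design)
                    fd_rows.append(
                        {
                            "subject_id": subj.spec.subject_id,
                            "run": r + 1,
                            "fd_mean": float(tr_fd.fd.mean()),
                            "fd_crave": tr_fd.condition_means.get("crave", np.nan),
                            "fd_nocrave": tr_fd.condition_means.get("nocrave", np.nan),
                        }
                    )
            fd_df = pd.DataFrame(fd_rows)
            fd_df.to_csv(out / "fd.tsv", sep="\t", index=False)
            summary["stages"]["preprocess"] = {
                "mean_fd_mm": float(fd_df["fd_mean"].mean())
            }

        stage = "online_nf"
        if "online_nf" in config.stages and cohort is not None:
            nf_rows = []
            for subj in cohort.subjects:
                for prior, current in ((0, 1), (1, 2)):
                    trace = online_nf.run_nf_session(
                        subj.runs[prior], subj.runs[current], cohort.mask,
                        C=config.svm_c,
                    )
                    active = trace.table[trace.table.feedback_active]
                    ends = active.groupby("block")["slider"].last().abs()
                    nf_rows.append(
                        {
                            "subject_id": subj.spec.subject_id,
                            "feedback_run": current + 1,
                            "online_accuracy": trace.accuracy,
                            "mean_final_abs_slider": float(ends.mean()),
                        }
                    )
            nf_df = pd.DataFrame(nf_rows)
            nf_df.to_csv(out / "online_nf.tsv", sep="\t", index=False)
            summary["stages"]["online_nf"] = {
                "mean_online_accuracy": float(nf_df["online_accuracy"].mean()),
                "mean_final_abs_slider": float(nf_df["mean_final_abs_slider"].mean()),
            }

        stage = "classify"
        tables: dict[str, classify.AccuracyTable] = {}
        if "classify" in config.stages and cohort is not None:
            contrasts = _contrasts_for(config)
            for level, n_rep in (
                ("individual", config.n_repeats_individual),
                ("group", config.n_repeats_group),
            ):
                seed = derive_seed(config.seed, "classify", level)
                manifest["derived_seeds"][f"classify.{level}"] = seed
                tables[level] = classify.run_contrasts(
                    cohort, contrasts, level,
                    classify.CvScheme(config.n_folds, n_rep, seed),
                )
            frames = [t.to_frame() for t in tables.values()]
            acc = pd.concat(frames, ignore_index=True)
            acc.to_csv(out / "accuracy.tsv", sep="\t", index=False)
            summary["stages"]["classify"] = {
                row["level"] + ":" + row["contrast"] + ":" + row["phase"]:
                    round(row["mean_acc"], 4)
                for _, row in acc.iterrows()
            }

        stage = "infer"
        roi_set = None
        weight_stack = None
        if "infer" in config.stages and tables.get("individual") is not None:
            tab = tables["individual"]
            n = cohort.n_subjects
            in_mask = cohort.mask
            per_run = []
            for r in range(3):
                cname = f"condition:run{r + 1}:collapsed"
                maps = []
                for subj in cohort.subjects:
                    model = tab.models[(cname, "individual", subj.spec.subject_id)]
                    full = np.zeros(in_mask.size)
                    full[in_mask] = model.weights
                    maps.append(inference.pseudo_z(full, in_mask)[in_mask])
                per_run.append(np.array(maps))
            stack = np.stack(per_run, axis=1)  # (n, 3, V_in_mask)
            seed = derive_seed(config.seed, "infer")
            manifest["derived_seeds"]["infer"] = seed
            stat_map = inference.permutation_correct(
                stack, in_mask, stat="F", n_perm=config.n_perm, seed=seed,
                alpha=config.anova_alpha,
            )
            roi_set = inference.extract_rois(
                stat_map, cohort.atlas, min_extent=config.roi_min_extent
            )
            import nibabel as nib

            grid = cohort.atlas.grid_shape
            stat_vol = stat_map.to_grid(
                np.where(np.isfinite(stat_map.statistic), stat_map.statistic, 0.0),
                grid,
            )
            p_vol = stat_map.to_grid(stat_map.p_corrected, grid)
            nib.save(
                nib.Nifti1Image(
                    np.stack([stat_vol, p_vol], axis=-1).astype(np.float32),
                    affine=np.eye(4),
                ),
                out / "group_anova_statmap.nii.gz",
            )
            weight_stack = np.zeros((n, 3, in_mask.size))
            weight_stack[:, :, in_mask] = stack
            pd.DataFrame(
                [
                    {
                        "label": roi.label,
                        "size": len(roi.voxels),
                        "centroid": ",".join(f"{c:.1f}" for c in roi.centroid),
                        "mean_statistic": roi.mean_statistic,
                    }
                    for roi in roi_set
                ]
            ).to_csv(out / "rois.tsv", sep="\t", index=False)
            summary["stages"]["infer"] = {
                "n_significant_voxels": int(stat_map.significant.sum()),
                "n_rois": len(roi_set),
            }

        stage = "assoc"
        if "assoc" in config.stages and roi_set is not None:
            seed = derive_seed(config.seed, "assoc")
            manifest["derived_seeds"]["assoc"] = seed
            assoc, het = behavior.run_association_stage(
                cohort.behavior, weight_stack, roi_set,
                n_perm=config.n_perm, n_boot=config.n_boot,
                seed=seed, mad_k=config.mad_k,
            )
            assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
            het.to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
            summary["stages"]["assoc"] = {
                "n_associations": len(assoc),
                "n_rois_tested": len(het),
            }
    except Exception as exc:  # noqa: BLE001 - re-raised with the stage name
        raise PipelineStageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "cravedecode": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pandas": pd.__version__,
    }
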