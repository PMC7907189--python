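"""End-to-end orchestration and the cohort summary report.

`run_all` chains the pipeline stages — mask loading and QC, subfield
coding, severity mapping, connectome contrast, thickness models, cohort
summary — on a directory layout like the one `lesionmap simulate` writes,
and records every output with a content hash in a manifest so that a rerun
on identical inputs can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import __version__
from .core_volumes import (
    LesionMask,
    SubfieldLandmarks,
    SubjectRecord,
    VolumeGrid,
    assign_subfields,
    dice,
    lesion_volume_cc,
    read_mask,
    read_table,
    read_volume,
    write_map,
    write_mask,
    write_table,
)
from .errors import LesionMapError, StageError
from .normative_connectome import laterality_contrast, rmap
from .severity_mapping import build_severity_mapset, engel_ccsfs_association
from .thickness_models import (
    PRESET_AGE_AT_DIAGNOSIS,
    PRESET_AGE_AT_SURGERY,
    slope_by_laterality,
    tail_interaction,
)

P_FILE_SENTINEL = -1.0  # stored in p-map files for untested voxels (NaN in memory)


@dataclasses.dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    All statistical thresholds carry the analysis defaults (alpha=0.05,
    frequency fraction=0.10, FDR q=0.01) but live in configuration: they
    are choices of the analysis, not constants.
    """

    subjects: str
    landmarks: str | None = None
    masks_root: str | None = None  # base dir for relative mask_path entries
    rater_b_dir: str | None = None  # second-rater masks for Dice QC
    seeds_bold_dir: str | None = None  # per-subject seed masks on the BOLD grid
    normative_dir: str | None = None
    out_dir: str = "lesionmap-out"
    alpha: float = 0.05
    fraction: float = 0.10
    mu0: float | None = None  # None = cohort mean score
    q: float = 0.01
    seed: int = 0
    write_rmaps: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_cohort(cfg: PipelineConfig) -> tuple[list[SubjectRecord], list[LesionMask]]:
    """Read the subject table and the lesion mask of every subject."""
    records = read_table(cfg.subjects)
    base = Path(cfg.masks_root) if cfg.masks_root else Path(cfg.subjects).parent
    masks = []
    for rec in records:
        if rec.mask_path is None:
            raise StageError("load", f"subject {rec.subject_id} has no mask_path")
        p = Path(rec.mask_path)
        if not p.is_absolute():
            p = base / p
        masks.append(
            read_mask(p, subject_id=rec.subject_id, laterality=rec.laterality, score=rec.score)
        )
    return records, masks


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage whose inputs are configured; return the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage_seconds: dict[str, float] = {}
    log_lines = [f"lesionmap {__version__}"]

    def record(relpath: str) -> None:
        outputs[relpath] = _sha256(out / relpath)

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
                log_lines.append(f"stage {name}: {stage_seconds[name]} s")
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, str(exc)) from exc
        return _Timer()

    with stage("load"):
        records, masks = load_cohort(cfg)
        landmarks = SubfieldLandmarks.from_json(cfg.landmarks) if cfg.landmarks else None

    if cfg.rater_b_dir is not None:
        with stage("dice_qc"):
            rows = []
            ref = masks[0].grid
            for m in masks:
                p = Path(cfg.rater_b_dir) / f"{m.subject_id}.nii.gz"
                if not p.exists():
                    p = Path(cfg.rater_b_dir) / f"{m.subject_id}.nii"
                other = read_mask(p, reference=ref, subject_id=m.subject_id,
                                  laterality=m.laterality, score=m.score)
                rows.append((m.subject_id, dice(m, other)))
            import pandas as pd

            pd.DataFrame(rows, columns=["subject_id", "dice"]).to_csv(
                out / "dice_qc.csv", index=False
            )
            record("dice_qc.csv")

    with stage("subfields"):
        if landmarks is not None:
            for rec, m in zip(records, masks):
                rec.has_head, rec.has_body, rec.has_tail = assign_subfields(m, landmarks)
        for rec, m in zip(records, masks):
            rec.lesion_volume = lesion_volume_cc(m)
        write_table(records, out / "subjects_annotated.csv")
        record("subjects_annotated.csv")

    with stage("severity_map"):
        mapset = build_severity_mapset(
            masks, alpha=cfg.alpha, fraction=cfg.fraction, mu0=cfg.mu0
        )
        write_map(mapset.average_map.like(np.nan_to_num(mapset.average_map.data)),
                  out / "average_map.nii.gz")
        write_map(mapset.frequency_map, out / "frequency_map.nii.gz")
        p_stored = np.where(
            np.isfinite(mapset.p_map.data), mapset.p_map.data, P_FILE_SENTINEL
        )
        write_map(mapset.p_map.like(p_stored), out / "p_map.nii.gz")
        write_map(mapset.final_map, out / "final_map.nii.gz")
        sidecar = {
            "alpha": mapset.alpha,
            "fraction": mapset.fraction,
            "mu0": mapset.mu0,
            "n_subjects": mapset.n_subjects,
            "threshold_count": mapset.threshold_count,
            "p_file_sentinel": P_FILE_SENTINEL,
            "diagnostics": mapset.diagnostics,
        }
        (out / "severity_map.json").write_text(json.dumps(sidecar, indent=2))
        for rel in ("average_map.nii.gz", "frequency_map.nii.gz", "p_map.nii.gz",
                    "final_map.nii.gz", "severity_map.json"):
            record(rel)
        assoc = engel_ccsfs_association(records)
        (out / "engel_association.json").write_text(
            json.dumps(dataclasses.asdict(assoc), indent=2)
        )
        record("engel_association.json")

    if cfg.seeds_bold_dir is not None and cfg.normative_dir is not None:
        with stage("connectome"):
            seeds = []
            for rec in records:
                p = Path(cfg.seeds_bold_dir) / f"{rec.subject_id}.nii.gz"
                if not p.exists():
                    p = Path(cfg.seeds_bold_dir) / f"{rec.subject_id}.nii"
                seeds.append(read_mask(p, subject_id=rec.subject_id,
                                       laterality=rec.laterality, score=rec.score))
            normative_paths = sorted(Path(cfg.normative_dir).glob("*.nii*"))
            if not normative_paths:
                raise StageError("connectome", f"no normative volumes in {cfg.normative_dir}")
            rmaps = [rmap(seed, normative_paths) for seed in seeds]
            if cfg.write_rmaps:
                (out / "rmaps").mkdir(exist_ok=True)
                for cm in rmaps:
                    write_map(cm.grid.like(np.nan_to_num(cm.grid.data)),
                              out / "rmaps" / f"{cm.seed_subject_id}.nii.gz")
                    record(f"rmaps/{cm.seed_subject_id}.nii.gz")
            contrast = laterality_contrast(rmaps, q=cfg.q)
            write_map(contrast.stat_map.like(np.nan_to_num(contrast.stat_map.data)),
                      out / "laterality_stat.nii.gz")
            p_stored = np.where(np.isfinite(contrast.p_map.data),
                                contrast.p_map.data, P_FILE_SENTINEL)
            write_map(contrast.p_map.like(p_stored), out / "laterality_p.nii.gz")
            write_mask(VolumeGrid(np.asarray(contrast.fdr_mask.data, dtype=np.uint8),
                                  affine=contrast.fdr_mask.affine),
                       out / "laterality_fdr_mask.nii.gz")
            (out / "connectome.json").write_text(
                json.dumps({"q": cfg.q, **contrast.diagnostics}, indent=2)
            )
            for rel in ("laterality_stat.nii.gz", "laterality_p.nii.gz",
                        "laterality_fdr_mask.nii.gz", "connectome.json"):
                record(rel)

    with stage("thickness"):
        report = thickness_report(records)
        (out / "thickness_models.json").write_text(json.dumps(report, indent=2))
        record("thickness_models.json")

    with stage("summary"):
        summary = cohort_summary(records)
        (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
        record("cohort_summary.json")

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stage_seconds": stage_seconds,
        "outputs": outputs,
    }
    cfg_hash = hashlib.sha256(
        json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()
    ).hexdigest()
    log_lines.insert(1, f"config sha256 {cfg_hash}")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest


def _fit_to_dict(fit) -> dict:
    return {
        "n": fit.n,
        "r_squared": fit.r_squared,
        "residual_sd": fit.residual_sd,
        "coefficients": {
            term: {
                "coef": float(fit.table.loc[term, "coef"]),
                "se": float(fit.table.loc[term, "se"]),
                "p": float(fit.table.loc[term, "p"]),
            }
            for term in fit.table.index
        },
    }


def thickness_report(records: Sequence[SubjectRecord]) -> dict:
    """Thickness fits under both age-covariate presets, plus per-side slopes
    and (when tail flags vary on the right) the duration x tail interaction."""
    report: dict = {}
    for name, mode in (("age_at_diagnosis", "age_at_diagnosis"),
                       ("age_at_surgery", "age_at_surgery")):
        slopes = slope_by_laterality(records, covariate_mode=mode)
        report[name] = {
            "left_slope": slopes.left_slope,
            "left_se": slopes.left_se,
            "left_p": slopes.left_p,
            "right_slope": slopes.right_slope,
            "right_se": slopes.right_se,
            "right_p": slopes.right_p,
            "interaction_coef": slopes.interaction_coef,
            "interaction_p": slopes.interaction_p,
            "fit": _fit_to_dict(slopes.fit),
        }
    right = [r for r in records if r.laterality == "right"]
    tails = {r.has_tail for r in right}
    if len(right) >= 6 and tails == {True, False}:
        try:
            report["tail_interaction_right"] = _fit_to_dict(tail_interaction(records))
        except LesionMapError as exc:
            report["tail_interaction_right"] = {"error": str(exc)}
    return report


def _median_range(values: Iterable[float]) -> dict | None:
    vals = [float(v) for v in values]
    if not vals:
        return None
    return {
        "median": float(np.median(vals)),
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
    }


def cohort_summary(records: Sequence[SubjectRecord]) -> dict:
    """Per-laterality descriptive summary of a subject table.

    Reports group size, percent female (when sex is recorded), median and
    range of onset age, surgery age and years to surgery, the severity
    score distribution, and the Engel-1 (seizure-free) proportion of the
    whole group. Empty groups yield null entries rather than an error.
    """
    summary: dict = {"n_total": len(records)}
    for side in ("left", "right"):
        group = [r for r in records if r.laterality == side]
        n = len(group)
        entry: dict = {"n": n}
        if n == 0:
            entry.update({
                "percent_female": None, "age_at_onset": None, "age_at_surgery": None,
                "years_to_surgery": None, "score_counts": None,
                "engel_1_n": None, "engel_1_percent": None,
            })
            summary[side] = entry
            continue
        sexes = [r.sex for r in group if r.sex is not None]
        entry["percent_female"] = (
            100.0 * sum(s == "F" for s in sexes) / len(sexes) if sexes else None
        )
        entry["age_at_onset"] = _median_range(r.age_at_onset for r in group)
        entry["age_at_surgery"] = _median_range(r.age_at_surgery for r in group)
        entry["years_to_surgery"] = _median_range(r.duration for r in group)
        entry["score_counts"] = {
            str(s): sum(r.score == s for r in group) for s in range(5)
        }
        engel1 = sum(r.engel_class == "1" for r in group)
        entry["engel_1_n"] = engel1
        entry["engel_1_percent"] = 100.0 * engel1 / n
        summary[side] = entry
    return summary
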