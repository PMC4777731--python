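"""End-to-end orchestration: simulate -> GLM -> univariate -> MVPA -> correlation.

One global seed expands deterministically into per-stage seeds
(SeedSequence spawn keys indexed by stage), so stages can be rerun in
isolation; a manifest records configuration, seeds and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as dz
from . import io as fio
from . import mvpa, neurocorr, synth, univariate
from .glm import build_design_matrix, fit_ols

STAGES = ("design", "simulate", "glm", "univariate", "mvpa", "ratings", "correlate")


@dataclass
class PipelineConfig:
    n_subjects: int = synth.N_SUBJECTS_DEFAULT
    n_voxels_per_roi: int = synth.N_VOXELS_PER_ROI_DEFAULT
    roi_labels: tuple[str, ...] = synth.ROI_LABELS
    n_selected_voxels: int = mvpa.N_SELECTED_VOXELS
    n_perm: int = 1000
    seed: int = 0
    svm_c: float = 1.0
    alpha: float = 0.05
    noise: synth.NoiseModel = field(default_factory=synth.NoiseModel)
    mvpa_problems: tuple[str, ...] = ("motion", "size", "stereo")

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_voxels_per_roi < 8:
            raise ValueError("n_voxels_per_roi must be >= 8")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        unknown = set(self.roi_labels) - set(synth.ROI_LABELS)
        if unknown:
            raise ValueError(f"unknown ROI labels {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        noise = synth.NoiseModel(**raw.pop("noise", {}))
        for key in ("roi_labels", "mvpa_problems"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(noise=noise, **raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (documented counter scheme)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "outputs": {str(p): _sha256(p) for p in outputs},
            }
        )


@dataclass
class PipelineResult:
    dataset: synth.BOLDDataset
    bold_tables: dict[str, pd.DataFrame]
    anova: dict[str, univariate.AnovaResult]
    posthoc: dict[str, list]
    mvpa_results: dict[str, mvpa.ClassificationResult]
    ratings: pd.DataFrame
    rating_anova: univariate.AnovaResult
    correlations: pd.DataFrame
    pair_comparisons: pd.DataFrame
    manifest: RunManifest


def fit_subject_glms(dataset: synth.BOLDDataset, mode: str):
    """Per subject, one GLM per run (condition- or trial-wise)."""
    out = {}
    for subj in dataset.subjects:
        results = []
        for table, data, nuis in zip(subj.schedules, subj.runs, subj.nuisance):
            dm = build_design_matrix(table, mode=mode, nuisance=nuis)
            results.append(fit_ols(dm, data))
        out[subj.subject_id] = results
    return out


def roi_samples(
    dataset: synth.BOLDDataset,
    trial_glms: dict,
    roi_label: str,
    n_selected: int = mvpa.N_SELECTED_VOXELS,
) -> mvpa.MultiVoxelSamples:
    """Cross-subject concatenated, activation-ranked samples for one ROI."""
    per_subject = []
    for subj in dataset.subjects:
        per_subject.append(
            mvpa.build_subject_samples(
                trial_glms[subj.subject_id],
                subj.roi_columns(roi_label),
                subj.baseline(),
                subj.subject_id,
                roi_label=roi_label,
            )
        )
    pooled = mvpa.concatenate_subjects(per_subject)
    k = min(n_selected, pooled.n_voxels)
    return mvpa.select_voxels(pooled, k)


def roi_bold_tables(
    dataset: synth.BOLDDataset, condition_glms: dict
) -> dict[str, pd.DataFrame]:
    tables = {}
    for roi in dataset.roi_labels:
        tables[roi] = univariate.roi_condition_means(
            condition_glms,
            {s.subject_id: s.roi_columns(roi) for s in dataset.subjects},
            {s.subject_id: s.baseline() for s in dataset.subjects},
        )
    return tables


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the full replica pipeline for one configuration."""
    config.validate()
    manifest = RunManifest(config=config.to_dict())
    out_path = Path(out_dir) if out_dir is not None else None

    dataset = synth.make_default_dataset(
        n_subjects=config.n_subjects,
        n_voxels_per_roi=config.n_voxels_per_roi,
        roi_labels=config.roi_labels,
        noise=config.noise,
        seed=stage_seed(config.seed, "simulate"),
    )
    outputs: list[Path] = []
    if out_path is not None:
        for subj in dataset.subjects:
            for table in subj.schedules:
                outputs.append(
                    fio.write_events_tsv(
                        table,
                        out_path
                        / "design"
                        / f"{subj.subject_id}_run-{table.run_id:02d}_events.tsv",
                    )
                )
        outputs.append(
            fio.write_json(
                dz.design_manifest(dataset.subjects[0].schedules, config.seed),
                out_path / "design" / "manifest.json",
            )
        )
        manifest.record("design", outputs)

    condition_glms = fit_subject_glms(dataset, "condition")
    trial_glms = fit_subject_glms(dataset, "trial")

    bold_tables = roi_bold_tables(dataset, condition_glms)
    anova = {roi: univariate.rm_anova_3way(tbl) for roi, tbl in bold_tables.items()}
    posthoc = {
        roi: univariate.posthoc_paired_t_holm(tbl, "motion")
        for roi, tbl in bold_tables.items()
    }

    svm = mvpa.SVMConfig(C=config.svm_c)
    problems = {
        "motion": mvpa.motion_labels(),
        "size": mvpa.size_labels(),
        "stereo": mvpa.stereo_labels(),
    }
    mvpa_results = {}
    mvpa_seed = stage_seed(config.seed, "mvpa")
    for roi in config.roi_labels:
        samples = roi_samples(dataset, trial_glms, roi, config.n_selected_voxels)
        for pname in config.mvpa_problems:
            lm = problems[pname]
            res = mvpa.permutation_test(
                samples, lm, n_perm=config.n_perm,
                seed=mvpa_seed + zlib.crc32(f"{roi}:{pname}".encode()) % 10000,
                svm_config=svm,
            )
            mvpa_results[f"{roi}:{pname}"] = res

    ratings = synth.simulate_ratings(
        config.n_subjects, seed=stage_seed(config.seed, "ratings")
    )
    rating_anova = univariate.rm_anova_3way(ratings)

    corr_frame, pair_frame = neurocorr.correlation_analysis(
        bold_tables, ratings, mode="pooled"
    )

    if out_path is not None:
        extra = [
            fio.write_ratings_tsv(ratings, out_path / "ratings" / "ratings.tsv"),
            _write_frame(univariate.effects_table(anova), out_path / "univariate" / "effects.tsv"),
            _write_frame(corr_frame, out_path / "correlate" / "roi_correlations.tsv"),
            _write_frame(pair_frame, out_path / "correlate" / "pair_comparisons.tsv"),
            fio.write_json(
                {
                    key: {
                        "accuracy": res.accuracy,
                        "p_value": res.p_value,
                        "null_95th": res.null_95th,
                        "n_voxels": res.n_voxels,
                    }
                    for key, res in mvpa_results.items()
                },
                out_path / "mvpa" / "accuracies.json",
            ),
        ]
        manifest.record("analysis", extra)
        fio.write_json(
            {"config": manifest.config, "stages": manifest.stages},
            out_path / "manifest.json",
        )

    return PipelineResult(
        dataset=dataset,
        bold_tables=bold_tables,
        anova=anova,
        posthoc=posthoc,
        mvpa_results=mvpa_results,
        ratings=ratings,
        rating_anova=rating_anova,
        correlations=corr_frame,
        pair_comparisons=pair_frame,
        manifest=manifest,
    )


def _write_frame(frame: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def report_text(result: PipelineResult) -> str:
    """Plain-text consolidated report of the three result families."""
    lines = ["# Univariate effects (p values per ROI)", ""]
    eff = univariate.effects_table(result.anova)
    lines.append(
        eff.pivot(index="effect", columns="roi", values="p").round(4).to_string()
    )
    lines += ["", "# Decoding accuracies (permutation p)", ""]
    for key, res in result.mvpa_results.items():
        mark = "*" if (res.p_value is not None and res.p_value < 0.05) else " "
        lines.append(
            f"  {key:24s} acc={res.accuracy:.3f} p={res.p_value:.4f} {mark}"
        )
    lines += ["", "# Neuro-perceptual correlations", ""]
    lines.append(result.correlations.round(4).to_string(index=False))
    lines += ["", "# ROI pair comparisons (dependent correlations)", ""]
    lines.append(result.pair_comparisons.round(4).to_string(index=False))
    return "\n".join(lines) + "\n"
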