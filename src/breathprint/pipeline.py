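"""End-to-end pipeline orchestration and report bundling.

A single :class:`PipelineConfig` drives simulation or manifest loading,
preprocessing, augmentation with equivalence validation, cross-validated and
holdout evaluation, and the optional ablation / attribution / PCA diagnostics.
One global seed fans out to per-stage seeds through ``stage_seed`` so any stage
can be re-run in isolation; every report embeds the fully resolved
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ablation import backward_ablation, select_minimum_optimal
from .attribution import run_cv_attribution
from .augment import AugmentationConfig, augment, validate_equivalence
from .device_io import read_manifest, write_manifest
from .evaluate import (
    CvPlan,
    LogisticRecipe,
    MlpRecipe,
    run_cv,
    run_cv_paper_faithful,
    run_holdout,
)
from .models import MlpConfig
from .preprocess import (
    apply_standardizer,
    fit_standardizer,
    prepare_features,
    sensor_blocks,
)
from .stats import pca
from .synthetic import CohortConfig, generate_cohort


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the global seed."""
    digest = sum((i + 1) * b for i, b in enumerate(stage.encode()))
    return int(np.random.SeedSequence([global_seed, digest]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Fully resolved run configuration; defaults are the study conditions."""

    seed: int = 0
    manifest: str | None = None  # load cohort from disk; None => simulate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: str = "mlp"  # "mlp" | "logistic"
    mlp: MlpConfig = field(default_factory=MlpConfig)
    ridge_penalty: float = 1.0  # evaluation logistic recipe
    scorer_ridge_penalty: float = 200.0  # ablation/attribution scorer
    n_folds: int = 5
    train_fraction: float = 0.7
    run_ablation: bool = True
    run_attribution: bool = True
    run_pca: bool = True
    protocol: str = "leakage-safe"  # or "paper-faithful"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
        if "augmentation" in kwargs:
            kwargs["augmentation"] = AugmentationConfig(**kwargs["augmentation"])
        if "mlp" in kwargs:
            mlp = dict(kwargs["mlp"])
            if "hidden_sizes" in mlp:
                mlp["hidden_sizes"] = tuple(mlp["hidden_sizes"])
            kwargs["mlp"] = MlpConfig(**mlp)
        return cls(**kwargs)

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                obj = dataclasses.asdict(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return enc(self)


def _recipe(config: PipelineConfig):
    if config.model == "logistic":
        return LogisticRecipe(ridge_penalty=config.ridge_penalty)
    if config.model == "mlp":
        return MlpRecipe(config=config.mlp)
    raise ValueError(f"unknown model {config.model!r}")


def simulate_cohort_to_dir(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Write the configured synthetic cohort as device CSVs plus a manifest."""
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=stage_seed(config.seed, "cohort")
    )
    samples = generate_cohort(cohort_cfg)
    return write_manifest(samples, out_dir)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return (and optionally write) the summary.

    Stages: cohort (simulate or load) -> preprocess -> augmentation equivalence
    validation -> evaluation (CV + holdout) -> optional ablation, attribution,
    PCA diagnostic.  Deterministic for a fixed config.
    """
    stage = "cohort"
    try:
        if config.manifest is not None:
            _, samples = read_manifest(config.manifest)
        else:
            cohort_cfg = dataclasses.replace(
                config.cohort, seed=stage_seed(config.seed, "cohort")
            )
            samples = generate_cohort(cohort_cfg)

        stage = "preprocess"
        features = prepare_features(samples)
        blocks = sensor_blocks(features.feature_names)

        stage = "augment-validate"
        aug_cfg = dataclasses.replace(
            config.augmentation, seed=stage_seed(config.seed, "augment")
        )
        scaler = fit_standardizer(features)
        std = apply_standardizer(scaler, features)
        augmented = augment(std, aug_cfg)
        equivalence = validate_equivalence(std, augmented)

        stage = "evaluate"
        recipe = _recipe(config)
        plan = CvPlan(n_folds=config.n_folds, seed=stage_seed(config.seed, "cv"))
        if config.protocol == "paper-faithful":
            cv_report = run_cv_paper_faithful(features, recipe, aug_cfg, plan)
        else:
            cv_report = run_cv(features, recipe, aug_cfg, plan)
        holdout_report = run_holdout(
            features, recipe, aug_cfg,
            train_fraction=config.train_fraction,
            seed=stage_seed(config.seed, "holdout"),
        )

        summary: dict = {
            "package_version": __version__,
            "python_version": platform.python_version(),
            "config": config.resolved(),
            "n_samples": features.n_samples,
            "n_features": features.n_features,
            "equivalence": equivalence.summary(),
            "cv": cv_report.to_dict(),
            "holdout": holdout_report.to_dict(),
        }

        if config.run_ablation:
            stage = "ablation"
            ab_plan = CvPlan(
                n_folds=config.n_folds, seed=stage_seed(config.seed, "ablation")
            )
            trace = backward_ablation(
                features, blocks, plan=ab_plan,
                ridge_penalty=config.scorer_ridge_penalty,
            )
            summary["ablation"] = {
                "steps": [
                    {
                        "removed": s.removed,
                        "k": len(s.remaining),
                        "mean_auc": s.mean_auc,
                        "sd_auc": s.sd_auc,
                    }
                    for s in trace.steps
                ],
                "best_k": trace.best_k,
                "best_subset": list(select_minimum_optimal(trace)),
            }

        if config.run_attribution:
            stage = "attribution"
            at_plan = CvPlan(
                n_folds=config.n_folds, seed=stage_seed(config.seed, "attribution")
            )
            report = run_cv_attribution(
                features, blocks, plan=at_plan,
                ridge_penalty=config.scorer_ridge_penalty,
            )
            summary["attribution"] = {
                "ranking": report.ranking,
                "mean_scores": dict(zip(report.sensors, report.mean_scores.tolist())),
            }

        if config.run_pca:
            stage = "pca"
            result = pca(std.values, n_components=2)
            summary["pca"] = {
                "explained_variance_ratio_2": float(
                    result.explained_variance_ratio[:2].sum()
                )
            }
    except Exception as exc:  # annotate failures with the stage that raised
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        equivalence.to_frame().to_csv(out_dir / "equivalence.csv", index=False)
        if config.run_ablation:
            trace.to_frame().to_csv(out_dir / "ablation.csv", index=False)
        if config.run_attribution:
            report.to_frame().to_csv(out_dir / "attribution.csv", index=False)
    return summary
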