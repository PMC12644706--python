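"""Stratified cross-validation and holdout evaluation with leakage-safe augmentation.

The default protocol keeps every test partition strictly real and fold-local:
within each fold the standardizer is fitted on the training rows, only the
training rows are augmented, the model is trained, and the untouched real
held-out rows are scored.  A "paper-faithful" variant (standardize globally,
augment the whole cohort, then split) is available so the size of the leakage
effect can be quantified; it is clearly labelled in the report it produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .augment import AugmentationConfig, augment
from .models import LogisticModel, MlpConfig, MlpModel, fit_logistic, train_mlp
from .preprocess import (
    FeatureMatrix,
    apply_standardizer,
    assert_all_real,
    fit_standardizer,
)
from .stats import binary_metrics, roc_auc
from .synthetic import LABEL_CANCER, ORIGIN_REAL

POSITIVE_LABEL = LABEL_CANCER
THRESHOLD = 0.5


@dataclass(frozen=True)
class CvPlan:
    n_folds: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.stratified:
            raise ValueError("only stratified plans are supported")


@dataclass
class FoldResult:
    fold: int
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: dict
    auc: float | None
    roc: dict | None = None


@dataclass
class EvalReport:
    protocol: str
    folds: list[FoldResult]
    mean_metrics: dict
    pooled_confusion: dict
    pooled_metrics: dict

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "folds": [
                {
                    "fold": f.fold,
                    "confusion": {"tp": f.tp, "fp": f.fp, "tn": f.tn, "fn": f.fn},
                    "metrics": f.metrics,
                    "auc": f.auc,
                }
                for f in self.folds
            ],
            "mean_metrics": self.mean_metrics,
            "pooled_confusion": self.pooled_confusion,
            "pooled_metrics": self.pooled_metrics,
        }


class ModelRecipe(Protocol):
    name: str

    def fit(self, X: np.ndarray, y01: np.ndarray, seed: int): ...


@dataclass(frozen=True)
class LogisticRecipe:
    ridge_penalty: float = 1.0
    name: str = "logistic"

    def fit(self, X: np.ndarray, y01: np.ndarray, seed: int) -> LogisticModel:
        return fit_logistic(X, y01, ridge_penalty=self.ridge_penalty)


@dataclass(frozen=True)
class MlpRecipe:
    config: MlpConfig = MlpConfig()
    name: str = "mlp"

    def fit(self, X: np.ndarray, y01: np.ndarray, seed: int) -> MlpModel:
        from dataclasses import replace

        return train_mlp(X, y01, config=replace(self.config, seed=seed))


def stratified_folds(labels, plan: CvPlan) -> np.ndarray:
    """Fold id per sample: per-class seeded shuffle then round-robin assignment.

    Within each class, fold sizes differ by at most one.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(plan.seed)
    folds = np.full(labels.shape[0], -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < plan.n_folds:
            raise ValueError(
                f"class {cls!r} has {idx.size} samples, fewer than {plan.n_folds} folds"
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % plan.n_folds
    return folds


def _score_fold(
    probs: np.ndarray, y01: np.ndarray
) -> tuple[int, int, int, int, dict, float | None, dict | None]:
    pred = (probs >= THRESHOLD).astype(int)
    tp = int(np.sum((pred == 1) & (y01 == 1)))
    fp = int(np.sum((pred == 1) & (y01 == 0)))
    tn = int(np.sum((pred == 0) & (y01 == 0)))
    fn = int(np.sum((pred == 0) & (y01 == 1)))
    metrics = binary_metrics(tp, fp, tn, fn)
    if y01.min() == y01.max():
        return tp, fp, tn, fn, metrics, None, None
    roc = roc_auc(probs, y01, positive_label=1)
    roc_data = {"fpr": roc.fpr.tolist(), "tpr": roc.tpr.tolist()}
    return tp, fp, tn, fn, metrics, roc.auc, roc_data


def _fit_and_score(
    X: FeatureMatrix,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    recipe: ModelRecipe,
    aug_config: AugmentationConfig | None,
    fold_seed: int,
) -> tuple:
    train = X.subset(train_rows)
    test = X.subset(test_rows)
    assert np.all(test.origin == ORIGIN_REAL), "synthetic sample in a test partition"
    scaler = fit_standardizer(train)
    train_std = apply_standardizer(scaler, train)
    test_std = apply_standardizer(scaler, test)
    if aug_config is not None:
        train_std = augment(train_std, aug_config)
    y_train = (train_std.labels == POSITIVE_LABEL).astype(int)
    model = recipe.fit(train_std.values, y_train, seed=fold_seed)
    probs = model.predict_proba(test_std.values)
    y_test = (test.labels == POSITIVE_LABEL).astype(int)
    return _score_fold(probs, y_test)


def _aggregate(protocol: str, fold_results: list[FoldResult]) -> EvalReport:
    keys = ["accuracy", "sensitivity", "specificity", "f1"]
    mean_metrics: dict = {}
    for k in keys:
        vals = [f.metrics[k] for f in fold_results if f.metrics[k] is not None]
        mean_metrics[k] = float(np.mean(vals)) if vals else None
    aucs = [f.auc for f in fold_results if f.auc is not None]
    mean_metrics["auc"] = float(np.mean(aucs)) if aucs else None
    mean_metrics["auc_sd"] = float(np.std(aucs)) if aucs else None
    tp = sum(f.tp for f in fold_results)
    fp = sum(f.fp for f in fold_results)
    tn = sum(f.tn for f in fold_results)
    fn = sum(f.fn for f in fold_results)
    return EvalReport(
        protocol=protocol,
        folds=fold_results,
        mean_metrics=mean_metrics,
        pooled_confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        pooled_metrics=binary_metrics(tp, fp, tn, fn),
    )


def run_cv(
    samples: FeatureMatrix,
    recipe: ModelRecipe,
    aug_config: AugmentationConfig | None,
    plan: CvPlan,
    keep_roc: bool = False,
) -> EvalReport:
    """Leakage-safe stratified k-fold cross-validation on real samples.

    Per fold: fit standardizer on training rows, augment training rows only,
    train the recipe's model, and score the strictly real held-out fold at a
    0.5 probability threshold.  A fold whose test partition is single-class
    has an undefined AUC, reported as ``None``.
    """
    assert_all_real(samples)
    folds = stratified_folds(samples.labels, plan)
    fold_results = []
    for k in range(plan.n_folds):
        test_rows = np.nonzero(folds == k)[0]
        train_rows = np.nonzero(folds != k)[0]
        fold_aug = (
            None
            if aug_config is None
            else AugmentationConfig(
                sigma_a=aug_config.sigma_a,
                m_cancer=aug_config.m_cancer,
                m_healthy=aug_config.m_healthy,
                seed=int(np.random.SeedSequence([aug_config.seed, k]).generate_state(1)[0] % (2**31)),
            )
        )
        tp, fp, tn, fn, metrics, auc, roc_data = _fit_and_score(
            samples, train_rows, test_rows, recipe, fold_aug, fold_seed=plan.seed + k
        )
        fold_results.append(
            FoldResult(k, tp, fp, tn, fn, metrics, auc, roc_data if keep_roc else None)
        )
    return _aggregate(f"cv-{plan.n_folds}fold-leakage-safe", fold_results)


def run_holdout(
    samples: FeatureMatrix,
    recipe: ModelRecipe,
    aug_config: AugmentationConfig | None,
    train_fraction: float = 0.7,
    seed: int = 0,
    keep_roc: bool = True,
) -> EvalReport:
    """Single stratified train/test split with the same leakage-safe protocol."""
    assert_all_real(samples)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    labels = samples.labels
    rng = np.random.default_rng(seed)
    train_rows, test_rows = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.nonzero(labels == cls)[0])
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_rows.extend(idx[:n_train])
        test_rows.extend(idx[n_train:])
    train_rows = np.sort(np.array(train_rows))
    test_rows = np.sort(np.array(test_rows))
    tp, fp, tn, fn, metrics, auc, roc_data = _fit_and_score(
        samples, train_rows, test_rows, recipe, aug_config, fold_seed=seed
    )
    fold = FoldResult(0, tp, fp, tn, fn, metrics, auc, roc_data if keep_roc else None)
    return _aggregate(f"holdout-{train_fraction:.0%}", [fold])


def run_cv_paper_faithful(
    samples: FeatureMatrix,
    recipe: ModelRecipe,
    aug_config: AugmentationConfig,
    plan: CvPlan,
) -> EvalReport:
    """Global-standardization, augment-before-split protocol (leaky; labelled).

    Standardizes the whole cohort at once, augments it, then cross-validates
    over the combined real+synthetic rows.  Synthetic rows can land in test
    partitions; use only to quantify the leakage effect against :func:`run_cv`.
    """
    assert_all_real(samples)
    scaler = fit_standardizer(samples)
    std = apply_standardizer(scaler, samples)
    full = augment(std, aug_config)
    folds = stratified_folds(full.labels, plan)
    fold_results = []
    for k in range(plan.n_folds):
        train = full.subset(folds != k)
        test = full.subset(folds == k)
        y_train = (train.labels == POSITIVE_LABEL).astype(int)
        model = recipe.fit(train.values, y_train, seed=plan.seed + k)
        probs = model.predict_proba(test.values)
        y_test = (test.labels == POSITIVE_LABEL).astype(int)
        tp, fp, tn, fn, metrics, auc, _ = _score_fold(probs, y_test)
        fold_results.append(FoldResult(k, tp, fp, tn, fn, metrics, auc))
    return _aggregate(f"cv-{plan.n_folds}fold-paper-faithful", fold_results)
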