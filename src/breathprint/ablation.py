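"""Progressive backward sensor elimination scored by cross-validated AUC.

Starting from the full array, each step evaluates every candidate single-sensor
removal with a stratified k-fold cross-validated ridge-logistic pipeline
(fold-wise standardization, AUC on the held-out fold) and removes the sensor
whose removal yields the highest mean CV AUC; ties break by canonical sensor
order.  The minimum-optimal subset is the remaining set at the size with the
best mean AUC (smaller subset on ties).  Ablation runs on real samples only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import CvPlan, POSITIVE_LABEL, stratified_folds
from .models import fit_logistic
from .preprocess import FeatureMatrix, apply_standardizer, fit_standardizer
from .stats import roc_auc


@dataclass
class AblationStep:
    removed: str | None  # None for the initial full-array entry
    remaining: tuple[str, ...]
    mean_auc: float
    sd_auc: float


@dataclass
class AblationTrace:
    steps: list[AblationStep]

    @property
    def best_k(self) -> int:
        return len(self.best_subset)

    @property
    def best_subset(self) -> tuple[str, ...]:
        best = self.steps[0]
        for step in self.steps[1:]:
            if step.mean_auc > best.mean_auc + 1e-12:
                best = step
            elif (
                abs(step.mean_auc - best.mean_auc) <= 1e-12
                and len(step.remaining) < len(best.remaining)
            ):
                best = step
        return best.remaining

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (i, s.removed, len(s.remaining), s.mean_auc, s.sd_auc)
                for i, s in enumerate(self.steps)
            ],
            columns=["step", "removed", "k", "mean_auc", "sd_auc"],
        )


#: Default ridge strength for the ablation/attribution scorer.  With 46
#: samples and 348 features a weakly penalized logistic fit is dominated by
#: overfit noise directions, making greedy selection and attribution unstable;
#: a strong penalty pulls the scorer toward the stable univariate
#: class-difference profile while preserving held-out ranking quality.
SCORER_RIDGE_PENALTY = 200.0


def cv_fold_aucs(
    X: FeatureMatrix,
    cols: np.ndarray,
    folds: np.ndarray,
    n_folds: int,
    ridge_penalty: float = SCORER_RIDGE_PENALTY,
) -> list[float]:
    """Held-out-fold AUCs for a feature subset.

    Fold-wise: standardize on training rows, fit ridge logistic, AUC of the
    held-out scores.  Single-class test folds are skipped (AUC undefined).
    """
    y = (X.labels == POSITIVE_LABEL).astype(int)
    vals = X.values[:, cols]
    aucs = []
    for k in range(n_folds):
        test = folds == k
        train = ~test
        y_test = y[test]
        if y_test.min() == y_test.max():
            continue
        scaler = fit_standardizer(vals[train])
        model = fit_logistic(
            apply_standardizer_values(scaler, vals[train]),
            y[train],
            ridge_penalty=ridge_penalty,
        )
        probs = model.predict_proba(apply_standardizer_values(scaler, vals[test]))
        aucs.append(roc_auc(probs, y_test, positive_label=1).auc)
    if not aucs:
        raise ValueError("no fold produced a defined AUC")
    return aucs


def cv_auc_for_features(
    X: FeatureMatrix,
    cols: np.ndarray,
    fold_sets: list[np.ndarray],
    n_folds: int,
    ridge_penalty: float = SCORER_RIDGE_PENALTY,
) -> tuple[float, float]:
    """Mean and sd of held-out AUC over one or more repeated fold assignments."""
    aucs: list[float] = []
    for folds in fold_sets:
        aucs.extend(cv_fold_aucs(X, cols, folds, n_folds, ridge_penalty))
    return float(np.mean(aucs)), float(np.std(aucs))


def apply_standardizer_values(scaler, values: np.ndarray) -> np.ndarray:
    from .preprocess import DEGENERATE_SCALE

    safe = np.where(scaler.scale < DEGENERATE_SCALE, 1.0, scaler.scale)
    out = (values - scaler.mean) / safe
    out[:, scaler.scale < DEGENERATE_SCALE] = 0.0
    return out


def backward_ablation(
    X: FeatureMatrix,
    sensor_blocks: dict[str, np.ndarray],
    plan: CvPlan | None = None,
    ridge_penalty: float = SCORER_RIDGE_PENALTY,
    n_repeats: int = 5,
) -> AblationTrace:
    """Greedy backward elimination over sensor blocks; records every subset size.

    ``X`` holds unscaled real samples (standardization happens inside each
    fold).  The trace's first entry is the full array; subsequent entries
    record each removal down to a single sensor.  The score of a candidate
    subset is the mean held-out AUC over ``n_repeats`` repeated stratified
    fold assignments (seeds ``plan.seed + r``): fold-level AUC on ~9-sample
    test sets is coarse, and repetition stabilizes the greedy choice.
    Deterministic under a fixed plan seed: the same fold assignments are
    reused for every candidate at every step.
    """
    if plan is None:
        plan = CvPlan()
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    sensors = list(sensor_blocks.keys())  # canonical order = insertion order
    if len(sensors) < 2:
        raise ValueError("need at least 2 sensors to ablate")
    all_cols = np.concatenate([sensor_blocks[s] for s in sensors])
    covered = np.unique(all_cols)
    if covered.size != X.n_features or covered.size != all_cols.size:
        raise ValueError("every feature must belong to exactly one sensor block")

    from dataclasses import replace

    fold_sets = [
        stratified_folds(X.labels, replace(plan, seed=plan.seed + r))
        for r in range(n_repeats)
    ]
    remaining = list(sensors)

    def cols_for(subset: list[str]) -> np.ndarray:
        return np.concatenate([sensor_blocks[s] for s in subset])

    mean0, sd0 = cv_auc_for_features(
        X, cols_for(remaining), fold_sets, plan.n_folds, ridge_penalty
    )
    steps = [AblationStep(None, tuple(remaining), mean0, sd0)]
    while len(remaining) > 1:
        best_sensor, best_stats = None, None
        for cand in remaining:  # canonical order => first best wins ties
            subset = [s for s in remaining if s != cand]
            stats = cv_auc_for_features(
                X, cols_for(subset), fold_sets, plan.n_folds, ridge_penalty
            )
            if best_stats is None or stats[0] > best_stats[0] + 1e-12:
                best_sensor, best_stats = cand, stats
        remaining = [s for s in remaining if s != best_sensor]
        steps.append(AblationStep(best_sensor, tuple(remaining), *best_stats))
    return AblationTrace(steps=steps)


def select_minimum_optimal(trace: AblationTrace) -> tuple[str, ...]:
    """Remaining set at the subset size maximizing mean CV AUC; smaller on ties."""
    if not trace.steps:
        raise ValueError("empty trace")
    return trace.best_subset
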