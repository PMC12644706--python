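"""Baseline correction, flattening, and standardization of breath recordings.

The feature vector of one sample is the baseline-corrected response matrix
flattened sensor-major: sensor 1's 29 time points, then sensor 2's, and so on,
giving 12 x 29 = 348 features under the default acquisition grid.  Feature
names are ``"<sensor>:<timeindex>"`` with time indices 0-based.

Standardization (zero mean, unit population variance per feature) is fitted on
training rows only and reused on the corresponding test rows; a constant
feature is mapped to zero rather than dividing by a vanishing scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import ORIGIN_REAL, BreathSample

#: Scales below this are treated as degenerate (constant feature).
DEGENERATE_SCALE = 1e-12


@dataclass
class FeatureMatrix:
    """Flattened per-sample feature vectors with labels and origin flags."""

    values: np.ndarray  # (n_samples, d)
    labels: np.ndarray  # (n_samples,) str
    origin: np.ndarray  # (n_samples,) str, "real" or "synthetic"
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin)
        n, d = self.values.shape
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal feature count")
        if self.labels.shape[0] != n or self.origin.shape[0] != n:
            raise ValueError("labels/origin length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[rows], self.labels[rows], self.origin[rows], self.feature_names
        )

    def select_features(self, cols: np.ndarray) -> "FeatureMatrix":
        cols = np.asarray(cols)
        return FeatureMatrix(
            self.values[:, cols],
            self.labels,
            self.origin,
            [self.feature_names[int(c)] for c in cols],
        )

    def concat(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if self.feature_names != other.feature_names:
            raise ValueError("feature spaces differ")
        return FeatureMatrix(
            np.vstack([self.values, other.values]),
            np.concatenate([self.labels, other.labels]),
            np.concatenate([self.origin, other.origin]),
            self.feature_names,
        )


@dataclass
class StandardizationModel:
    """Per-feature location/scale learned from training rows only."""

    mean: np.ndarray
    scale: np.ndarray  # population sd; entries below DEGENERATE_SCALE flag constants
    n_fitted: int

    def __post_init__(self) -> None:
        if np.any(self.scale < 0):
            raise ValueError("scale must be non-negative")


def baseline_correct(sample: BreathSample) -> BreathSample:
    """Subtract each sensor's baseline-phase mean from its signals.

    Removes environmental offsets so responses are comparable across sessions.
    Idempotent beyond round-off, since a centered baseline has mean ~0.
    """
    if sample.baseline.shape[1] == 0:
        raise ValueError("baseline phase is empty")
    means = sample.baseline.mean(axis=1, keepdims=True)
    return replace(
        sample,
        baseline=sample.baseline - means,
        response=sample.response - means,
        time_grid=sample.time_grid.copy(),
    )


def flatten(samples: list[BreathSample]) -> FeatureMatrix:
    """Stack samples into an (n, d) matrix, sensor-major flattening order."""
    if not samples:
        raise ValueError("no samples to flatten")
    names = samples[0].sensor_names
    shape = samples[0].response.shape
    for s in samples:
        if s.sensor_names != names or s.response.shape != shape:
            raise ValueError(f"{s.sample_id}: heterogeneous sensor set or grid length")
    values = np.stack([s.response.reshape(-1) for s in samples])
    feature_names = [f"{name}:{k}" for name in names for k in range(shape[1])]
    return FeatureMatrix(
        values=values,
        labels=np.array([s.label for s in samples]),
        origin=np.array([s.origin for s in samples]),
        feature_names=feature_names,
    )


def sensor_blocks(feature_names: list[str]) -> dict[str, np.ndarray]:
    """Map each sensor to the column indices of its time points, in order."""
    blocks: dict[str, list[int]] = {}
    for j, fname in enumerate(feature_names):
        sensor = fname.rsplit(":", 1)[0]
        blocks.setdefault(sensor, []).append(j)
    return {k: np.array(v) for k, v in blocks.items()}


def fit_standardizer(training: FeatureMatrix | np.ndarray) -> StandardizationModel:
    """Learn per-feature mean and population standard deviation from training rows."""
    X = training.values if isinstance(training, FeatureMatrix) else np.asarray(training, float)
    return StandardizationModel(
        mean=X.mean(axis=0), scale=X.std(axis=0), n_fitted=X.shape[0]
    )


def apply_standardizer(model: StandardizationModel, X: FeatureMatrix) -> FeatureMatrix:
    """Center and scale; degenerate (constant) features map to exactly zero."""
    safe = np.where(model.scale < DEGENERATE_SCALE, 1.0, model.scale)
    values = (X.values - model.mean) / safe
    values[:, model.scale < DEGENERATE_SCALE] = 0.0
    return FeatureMatrix(values, X.labels, X.origin, X.feature_names)


def invert_standardizer(model: StandardizationModel, X: FeatureMatrix) -> FeatureMatrix:
    """Undo standardization for non-degenerate features (degenerate map to the mean)."""
    safe = np.where(model.scale < DEGENERATE_SCALE, 0.0, model.scale)
    return FeatureMatrix(X.values * safe + model.mean, X.labels, X.origin, X.feature_names)


def prepare_features(samples: list[BreathSample]) -> FeatureMatrix:
    """Baseline-correct and flatten a cohort (no scaling; scaling is fold-wise)."""
    return flatten([baseline_correct(s) for s in samples])


def assert_all_real(X: FeatureMatrix) -> None:
    if not np.all(X.origin == ORIGIN_REAL):
        raise ValueError("expected a matrix of real samples only")
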