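"""Gaussian augmentation contract and equivalence validation."""

import numpy as np
import pytest

from breathprint.augment import AugmentationConfig, EquivalenceReport, augment, validate_equivalence
from breathprint.preprocess import FeatureMatrix, apply_standardizer, fit_standardizer


def toy_matrix(rng, n_cancer=18, n_healthy=28, d=6, shift=1.0):
    values = rng.normal(size=(n_healthy + n_cancer, d))
    values[n_healthy:] += shift
    labels = np.array(["healthy"] * n_healthy + ["cancer"] * n_cancer)
    return FeatureMatrix(values, labels, np.array(["real"] * len(labels)),
                         [f"f{j}:0" for j in range(d)])


def test_default_counts_and_ordering(rng):
    X = toy_matrix(rng)
    out = augment(X, AugmentationConfig(seed=0))
    assert out.n_samples == 46 + 35 + 25
    # original rows first and untouched
    assert np.array_equal(out.values[:46], X.values)
    assert np.all(out.origin[:46] == "real")
    assert np.all(out.origin[46:] == "synthetic")
    synth_labels = out.labels[46:]
    assert np.sum(synth_labels == "cancer") == 35
    assert np.sum(synth_labels == "healthy") == 25
    # total cancer rows: 18 real + 35 synthetic = 53
    assert int(np.sum(out.labels == "cancer")) == 53


def test_augment_deterministic(rng):
    X = toy_matrix(rng)
    cfg = AugmentationConfig(seed=5)
    a, b = augment(X, cfg), augment(X, cfg)
    assert np.array_equal(a.values, b.values)
    c = augment(X, AugmentationConfig(seed=6))
    assert not np.array_equal(a.values, c.values)


def test_noise_statistics_match_sigma(rng):
    # one real parent per class: every synthetic row's deviation IS the noise
    X = toy_matrix(rng, n_cancer=1, n_healthy=1, d=40)
    cfg = AugmentationConfig(sigma_a=0.6, m_cancer=2000, m_healthy=2000, seed=1)
    out = augment(X, cfg)
    for cls, parent_row in (("cancer", X.values[1]), ("healthy", X.values[0])):
        rows = out.values[(out.labels == cls) & (out.origin == "synthetic")]
        dev = rows - parent_row
        assert dev.mean() == pytest.approx(0.0, abs=0.01)
        assert dev.var() == pytest.approx(0.36, rel=0.02)


def test_parents_drawn_from_same_class(rng):
    # zero noise: synthetic rows must equal some same-class real row exactly
    X = toy_matrix(rng)
    out = augment(X, AugmentationConfig(sigma_a=0.0, m_cancer=50, m_healthy=50, seed=2))
    real_by_class = {
        cls: X.values[X.labels == cls] for cls in ("cancer", "healthy")
    }
    for row, cls in zip(out.values[46:], out.labels[46:]):
        dists = np.abs(real_by_class[cls] - row).max(axis=1)
        assert dists.min() == 0.0


def test_class_means_preserved(rng):
    X = toy_matrix(rng, d=10)
    out = augment(X, AugmentationConfig(m_cancer=4000, m_healthy=4000, seed=3))
    for cls in ("cancer", "healthy"):
        real_mean = X.values[X.labels == cls].mean(axis=0)
        synth = out.values[(out.labels == cls) & (out.origin == "synthetic")]
        # noise is zero-mean and parents are uniform over the class, so the
        # synthetic class mean converges to the real class mean
        assert np.allclose(synth.mean(axis=0), real_mean, atol=0.06)


def test_rejects_synthetic_input(rng):
    X = toy_matrix(rng)
    once = augment(X, AugmentationConfig(seed=0))
    with pytest.raises(ValueError, match="real samples only"):
        augment(once, AugmentationConfig(seed=0))


def test_zero_counts_are_noop(rng):
    X = toy_matrix(rng)
    out = augment(X, AugmentationConfig(m_cancer=0, m_healthy=0))
    assert out is X


def test_config_validation():
    with pytest.raises(ValueError):
        AugmentationConfig(sigma_a=-0.1)
    with pytest.raises(ValueError):
        AugmentationConfig(m_cancer=-1)


def test_equivalence_report_on_default_cohort(default_features):
    scaler = fit_standardizer(default_features)
    std = apply_standardizer(scaler, default_features)
    out = augment(std, AugmentationConfig(seed=4))
    report = validate_equivalence(std, out)
    s = report.summary()
    # one Mann-Whitney test per feature and class
    assert s["n_tests"] == 2 * 348
    # augmentation preserves class location, so "significant" differences
    # occur at roughly the chance rate; well under 4x alpha in any case
    assert s["fraction_below_alpha"] < 0.20
    assert 0.0 <= s["min_p"] <= 1.0
    frame = report.to_frame()
    assert len(frame) == 2 * 348
    assert set(frame["class"]) == {"cancer", "healthy"}


def test_equivalence_kde_curves(default_features):
    scaler = fit_standardizer(default_features)
    std = apply_standardizer(scaler, default_features)
    out = augment(std, AugmentationConfig(seed=4))
    fname = std.feature_names[0]
    report = validate_equivalence(std, out, kde_features=[fname])
    curves = report.kde_curves[fname]["cancer"]
    for side in ("original", "augmented"):
        g, d = curves[side]["grid"], curves[side]["density"]
        assert np.trapezoid(d, g) == pytest.approx(1.0, abs=5e-3)


def test_equivalence_detects_distorted_augmentation(rng):
    # a deliberately biased "augmentation" must light up the report
    X = toy_matrix(rng, d=8)
    out = augment(X, AugmentationConfig(seed=7))
    shifted = FeatureMatrix(
        np.where((out.origin == "synthetic")[:, None], out.values + 3.0, out.values),
        out.labels, out.origin, out.feature_names,
    )
    report = validate_equivalence(X, shifted)
    assert report.fraction_below_alpha > 0.9


def test_equivalence_rejects_mismatched_features(rng):
    X = toy_matrix(rng, d=4)
    Y = toy_matrix(rng, d=5)
    with pytest.raises(ValueError, match="feature spaces"):
        validate_equivalence(X, Y)
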