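"""Statistical kernel: oracles first, then independent library cross-checks."""

import numpy as np
import pytest
import scipy.stats as sps
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import roc_auc_score

from breathprint.stats import (
    binary_metrics,
    chi2_contingency,
    chi2_contingency_yates,
    fisher_exact,
    gaussian_kde,
    mann_whitney_u,
    pca,
    roc_auc,
    silverman_bandwidth,
    welch_t_from_summary,
)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def test_mwu_extreme_separation_exact():
    # all of b above a: U = 0; two-sided exact p = 2 / C(6,3) = 0.1
    res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)


def test_mwu_identical_samples():
    res = mann_whitney_u([5, 5, 5], [5, 5, 5], method="exact")
    assert res.p_value == 1.0
    res_n = mann_whitney_u([5.0] * 20, [5.0] * 20, method="normal")
    assert res_n.p_value == 1.0  # zero variance under total ties


def test_mwu_u_definition_with_ties():
    # a = [1, 2], b = [2, 3]: pairs (1,2),(1,3) lose, (2,2) half, (2,3) loses
    res = mann_whitney_u([1, 2], [2, 3], method="normal")
    assert res.statistic == pytest.approx(0.5)


def test_mwu_exact_matches_scipy(rng):
    for _ in range(10):
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        ours = mann_whitney_u(a, b, method="exact")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_mwu_normal_matches_scipy_with_ties(rng):
    for _ in range(10):
        a = rng.integers(0, 6, size=25).astype(float)
        b = rng.integers(0, 6, size=30).astype(float)
        ours = mann_whitney_u(a, b, method="normal")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_mwu_auto_switches_on_pooled_size():
    small = mann_whitney_u([1, 2, 3], [4, 5, 6])
    large = mann_whitney_u(list(range(10)), list(range(10, 20)))
    assert small.method == "mann-whitney-exact"
    assert large.method == "mann-whitney-normal"


def test_mwu_empty_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# Contingency tables and Welch t


def test_chi2_yates_reference_table():
    res = chi2_contingency_yates([[9, 9], [11, 17]])
    ref = sps.chi2_contingency([[9, 9], [11, 17]], correction=True)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_chi2_pearson_matches_scipy(rng):
    for _ in range(10):
        t = rng.integers(1, 40, size=(2, 2))
        ours = chi2_contingency(t)
        ref = sps.chi2_contingency(t, correction=False)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_chi2_invalid_tables_rejected():
    with pytest.raises(ValueError):
        chi2_contingency_yates([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        chi2_contingency_yates([[0, 0], [3, 4]])  # zero margin
    with pytest.raises(ValueError):
        chi2_contingency_yates([[1.5, 2], [3, 4]])  # non-integer


def test_fisher_exact_matches_scipy(rng):
    for _ in range(10):
        t = rng.integers(0, 15, size=(2, 2))
        if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
            continue
        ours = fisher_exact(t)
        ref = sps.fisher_exact(t, alternative="two-sided")
        assert ours.p_value == pytest.approx(ref[1], rel=1e-7)


def test_welch_t_matches_scipy(rng):
    for _ in range(10):
        a = rng.normal(0.0, 1.0, size=12)
        b = rng.normal(0.4, 1.5, size=17)
        ours = welch_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_welch_t_degenerate_conventions():
    assert welch_t_from_summary(1.0, 0.0, 5, 1.0, 0.0, 5).p_value == 1.0
    assert welch_t_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5).p_value == 0.0
    with pytest.raises(ValueError):
        welch_t_from_summary(0.0, 1.0, 1, 0.0, 1.0, 5)


# ---------------------------------------------------------------------------
# KDE and PCA


def test_silverman_bandwidth_formula(rng):
    x = rng.normal(size=200)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    expected = 0.9 * min(sd, abs(iqr) / 1.34) * 200 ** (-0.2)
    assert silverman_bandwidth(x) == pytest.approx(expected)


def test_kde_integrates_to_one(rng):
    x = rng.normal(size=150)
    grid, density = gaussian_kde(x)
    assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-3)
    assert np.all(density >= 0)


def test_kde_matches_scipy(rng):
    x = rng.normal(size=100)
    h = 0.4
    grid = np.linspace(-3, 3, 50)
    _, density = gaussian_kde(x, bandwidth=h, grid=grid)
    ref = sps.gaussian_kde(x, bw_method=h / x.std(ddof=1))(grid)
    assert np.allclose(density, ref, rtol=1e-9)


def test_kde_constant_input_rejected():
    with pytest.raises(ValueError, match="distinct"):
        gaussian_kde([2.0, 2.0, 2.0])


def test_pca_matches_sklearn(rng):
    X = rng.normal(size=(40, 8)) @ rng.normal(size=(8, 8))
    ours = pca(X, n_components=3)
    ref = SkPCA(n_components=3).fit(X)
    assert np.allclose(
        ours.explained_variance_ratio, ref.explained_variance_ratio_, rtol=1e-9
    )
    # loadings agree up to sign
    for k in range(3):
        dot = abs(float(ours.loadings[:, k] @ ref.components_[k]))
        assert dot == pytest.approx(1.0, abs=1e-9)


def test_pca_scores_reconstruct_centered_data(rng):
    X = rng.normal(size=(20, 5))
    res = pca(X)
    centered = X - X.mean(axis=0)
    assert np.allclose(res.scores @ res.loadings.T, centered, atol=1e-9)
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ROC / metrics


def test_roc_auc_matches_sklearn(rng):
    for _ in range(10):
        y = rng.integers(0, 2, size=60)
        if y.min() == y.max():
            continue
        scores = rng.normal(size=60) + y  # informative but noisy
        ours = roc_auc(scores, y, positive_label=1)
        assert ours.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_roc_auc_with_tied_scores(rng):
    y = rng.integers(0, 2, size=80)
    y[:2] = [0, 1]
    scores = rng.integers(0, 4, size=80).astype(float)  # heavy ties
    ours = roc_auc(scores, y, positive_label=1)
    assert ours.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_roc_perfect_and_reversed():
    y = [0, 0, 1, 1]
    assert roc_auc([0.1, 0.2, 0.8, 0.9], y).auc == 1.0
    assert roc_auc([0.9, 0.8, 0.2, 0.1], y).auc == 0.0


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([0.1, 0.2], [1, 1])


def test_binary_metrics_known_values():
    m = binary_metrics(tp=8, fp=2, tn=25, fn=3)
    assert m["accuracy"] == pytest.approx(33 / 38)
    assert m["sensitivity"] == pytest.approx(8 / 11)
    assert m["specificity"] == pytest.approx(25 / 27)
    assert m["f1"] == pytest.approx(16 / 21)


def test_binary_metrics_undefined_is_none():
    m = binary_metrics(tp=0, fp=0, tn=10, fn=0)
    assert m["sensitivity"] is None
    assert m["f1"] is None
    assert m["specificity"] == 1.0
    with pytest.raises(ValueError):
        binary_metrics(0, 0, 0, 0)
    with pytest.raises(ValueError):
        binary_metrics(-1, 0, 1, 0)
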