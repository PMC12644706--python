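"""Self-contained statistical kernel for the pipeline.

Hand-authored implementations of the tests and summaries the analysis uses:
Mann-Whitney U (midranks, tie-corrected normal approximation with continuity
correction, exact enumeration for small pooled n), Yates-corrected chi-square
for 2x2 tables, Welch's t from summary statistics, Gaussian KDE with
Silverman bandwidth, PCA, trapezoidal ROC/AUC, and confusion-matrix metrics.
Only distribution CDFs come from scipy; scipy.stats / scikit-learn serve as
independent cross-checks in the test suite, never as the implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Callable

import numpy as np
from scipy.special import ndtr, stdtr
from scipy.stats import chi2 as _chi2_dist


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    auxiliary: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC rates must be non-decreasing")


@dataclass
class PcaResult:
    loadings: np.ndarray  # (d, n_components), columns are principal axes
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (n, n_components)


# ---------------------------------------------------------------------------
# Rank tests


def _rank_midranks(pooled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of pooled values and the tie-group sizes."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    tie_sizes = []
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        tie_sizes.append(j - i + 1)
        i = j + 1
    return ranks, np.array(tie_sizes)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks, _ = _rank_midranks(pooled)
    r_a = ranks[: len(a)].sum()
    return r_a - len(a) * (len(a) + 1) / 2.0


def mann_whitney_u(
    a,
    b,
    method: str = "auto",
    continuity: bool = True,
    exact_threshold: int = 12,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U counts, over all pairs, how often a value of ``a`` exceeds one of ``b``
    (ties count one half).  ``method`` is ``"auto"`` (exact enumeration when the
    pooled size is at most ``exact_threshold``, else tie-corrected normal
    approximation), ``"exact"``, or ``"normal"``.  The exact mode enumerates
    every assignment of the pooled values to the two groups, so it is correct
    under ties as well.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    u = _u_statistic(a, b)
    mu = n_a * n_b / 2.0

    if method == "auto":
        method = "exact" if n_a + n_b <= exact_threshold else "normal"

    if method == "exact":
        pooled = np.concatenate([a, b])
        dev = abs(u - mu)
        total = 0
        hits = 0
        idx = range(n_a + n_b)
        for comb in combinations(idx, n_a):
            total += 1
            u_perm = _u_statistic(pooled[list(comb)], np.delete(pooled, list(comb)))
            if abs(u_perm - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
        return TestResult(u, p, "mann-whitney-exact", {"n_a": n_a, "n_b": n_b})

    if method != "normal":
        raise ValueError(f"unknown method {method!r}")
    _, tie_sizes = _rank_midranks(np.concatenate([a, b]))
    n = n_a + n_b
    tie_term = float(np.sum(tie_sizes**3 - tie_sizes))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied
        return TestResult(u, 1.0, "mann-whitney-normal", {"variance": 0.0})
    dev = abs(u - mu)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var)
    p = min(1.0, 2.0 * (1.0 - ndtr(z)))
    return TestResult(
        u, p, "mann-whitney-normal",
        {"z": z, "variance": var, "tie_correction": tie_term, "continuity": continuity},
    )


# ---------------------------------------------------------------------------
# Contingency and summary-statistic tests


def chi2_contingency_yates(table) -> TestResult:
    """Yates continuity-corrected chi-square test of independence on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("both margins must be positive")
    expected = np.outer(row, col) / n
    corr = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    stat = float(np.sum(corr**2 / expected))
    p = float(_chi2_dist.sf(stat, df=1))
    return TestResult(stat, p, "chi2-yates", {"df": 1, "expected": expected})


def chi2_contingency(table) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table (comparison variant)."""
    t = np.asarray(table, dtype=float)
    row, col, n = t.sum(axis=1), t.sum(axis=0), t.sum()
    expected = np.outer(row, col) / n
    stat = float(np.sum((t - expected) ** 2 / expected))
    return TestResult(stat, float(_chi2_dist.sf(stat, df=1)), "chi2-pearson", {"df": 1})


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table (comparison variant).

    Two-sided p sums hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    t = np.asarray(table, dtype=int)
    a, b = t[0]
    c, d = t[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def log_prob(x: int) -> float:
        return (
            _log_binom(r1, x)
            + _log_binom(n - r1, c1 - x)
            - _log_binom(n, c1)
        )

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    lp_obs = log_prob(a)
    p = sum(
        math.exp(log_prob(x)) for x in range(lo, hi + 1) if log_prob(x) <= lp_obs + 1e-9
    )
    return TestResult(float(a), min(1.0, p), "fisher-exact", {})


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Two-sided Welch t-test from summary statistics (means, sds, counts)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both sample sizes must be >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        p = 1.0 if mean1 == mean2 else 0.0
        return TestResult(0.0 if mean1 == mean2 else math.inf, p, "welch-t", {"df": math.nan})
    t = (mean1 - mean2) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * (1.0 - stdtr(df, abs(t)))
    return TestResult(t, min(1.0, max(0.0, p)), "welch-t", {"df": df})


# ---------------------------------------------------------------------------
# Density estimation and PCA


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = values.std(ddof=1)
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * len(values) ** (-0.2)


def gaussian_kde(
    values, bandwidth: float | None = None, grid: np.ndarray | None = None, n_grid: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density estimate on a grid; returns (grid, density).

    The default bandwidth is Silverman's rule; the default grid extends three
    bandwidths beyond the sample range so the density integrates to ~1.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise ValueError(
            "KDE requires at least 2 distinct values; constant input suggests "
            "a degenerate feature"
        )
    h = bandwidth if bandwidth is not None else silverman_bandwidth(values)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, n_grid)
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z**2).sum(axis=1) / (len(values) * h * math.sqrt(2 * math.pi))
    return grid, density


def pca(X, n_components: int | None = None) -> PcaResult:
    """Principal component analysis via SVD of the column-centered data."""
    X = np.asarray(getattr(X, "values", X), dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    centered = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    ratios = var / total if total > 0 else np.zeros_like(var)
    k = n_components or len(s)
    loadings = vt[:k].T
    return PcaResult(
        loadings=loadings,
        explained_variance_ratio=ratios[:k],
        scores=centered @ loadings,
    )


# ---------------------------------------------------------------------------
# ROC and classification metrics


def roc_auc(scores, labels, positive_label=1) -> RocCurve:
    """ROC curve over all distinct score thresholds; AUC by the trapezoidal rule.

    Tied scores cross their threshold simultaneously, which makes the AUC agree
    exactly with the rescaled Mann-Whitney statistic U / (n+ * n-).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel() == positive_label
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = y[order].astype(float)
    # collapse tied scores into single threshold steps
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(sorted_scores) - 1]
    tp = np.cumsum(sorted_pos)[distinct]
    fp = (distinct + 1) - tp
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def binary_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """Accuracy, sensitivity (cancer recall), specificity (healthy recall), F1.

    A metric with a zero denominator is reported as ``None`` (undefined), not 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion counts sum to zero")

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
    }
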