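"""Effect sizes, mutual information, permutation tests, and importance reports.

* ``a_w`` — the nonparametric common-language effect size: the probability
  that a random draw from one sample exceeds a random draw from the other
  (ties counted half), folded to the [0.5, 1] range by disregarding
  direction.
* ``mutual_information`` — plug-in MI (bits) on a 10x10 contingency table of
  equal-count (quantile) bins; variables with fewer than 10 unique values
  are treated as naturally discrete. Significance via a permutation null.
* ``compare_cc_groups`` — permutation test on the difference between the
  medians of two groups of correlation coefficients.
* ``importance_with_null`` — median absolute Shapley attribution per base
  feature over partitions (chunk-statistic attributions folded into their
  base feature), with one-tailed p-values against shuffled-label runs.
* ``group_tests`` — Mann-Whitney U, Wilcoxon signed-rank, and Kruskal-Wallis
  with rank-based Tukey HSD correction for pairwise comparisons.

Permutation p-values use the add-one estimator (k+1)/(n+1), which is never
exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .registry import BASE_FEATURES, base_feature_of


@dataclass(frozen=True)
class EffectSize:
    a_w: float  # in [0.5, 1]
    direction: int  # +1 if sample_a tends larger, -1 smaller, 0 none
    p_value: float  # two-tailed Mann-Whitney U


def a_w(sample_a, sample_b) -> EffectSize:
    """Common-language effect size A_w between two samples.

    p_hat = [#(a > b) + 0.5 #(a = b)] / (n_a n_b); A_w = max(p_hat, 1-p_hat).
    Equals 0.5 for fully intermixed samples and 1 for disjoint ones.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p_hat = res.statistic / (a.size * b.size)  # U counts ties as 1/2
    folded = max(p_hat, 1.0 - p_hat)
    direction = 0 if p_hat == 0.5 else (1 if p_hat > 0.5 else -1)
    return EffectSize(a_w=float(folded), direction=direction, p_value=float(res.pvalue))


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-count (quantile) binning; natural categories for discrete data.

    Quantile bins are assigned by rank order, so the binning — and hence the
    MI — is invariant under strictly monotone transforms.
    """
    x = np.asarray(x)
    uniq, codes = np.unique(x, return_inverse=True)
    if uniq.size < bins:
        return codes
    order = np.argsort(x, kind="stable")
    out = np.empty(x.size, dtype=int)
    out[order] = (np.arange(x.size) * bins) // x.size
    return out


def _plugin_mi_bits(cx: np.ndarray, cy: np.ndarray) -> float:
    joint = pd.crosstab(cx, cy).to_numpy(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())


def mutual_information(
    x,
    y,
    bins: int = 10,
    n_perm: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """(MI in bits, one-tailed permutation p-value) between two variables.

    With 10 bins the MI is capped at log2(10) ~ 3.32 bits, attained when the
    two variables are perfectly dependent.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size or x.size < 10:
        raise ValueError("x and y must have equal length >= 10")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cx = _discretize(x, bins)
    cy = _discretize(y, bins)
    mi = _plugin_mi_bits(cx, cy)
    exceed = 0
    for _ in range(n_perm):
        if _plugin_mi_bits(cx, rng.permutation(cy)) >= mi:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return mi, p


def compare_cc_groups(
    cc_group_a,
    cc_group_b,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """One-tailed permutation p for the median difference between two groups
    of correlation coefficients (observed statistic: median(a) - median(b))."""
    a = np.asarray(cc_group_a, dtype=float)
    b = np.asarray(cc_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observed = np.median(a) - np.median(b)
    pooled = np.concatenate([a, b])
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if np.median(perm[: a.size]) - np.median(perm[a.size :]) >= observed:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def fold_attributions(attributions: dict[str, float]) -> pd.Series:
    """Sum chunk-statistic attributions into their base feature (34 rows)."""
    folded = {name: 0.0 for name in BASE_FEATURES}
    for column, value in attributions.items():
        folded[base_feature_of(column)] += float(value)
    return pd.Series(folded)


def importance_with_null(runs, null_runs) -> pd.DataFrame:
    """Median |attribution| per base feature with a shuffled-label null.

    ``runs`` / ``null_runs`` are sequences of :class:`ModelRun` carrying
    per-column mean absolute Shapley attributions. Chunk-statistic columns
    are folded into their base feature before aggregation. The one-tailed
    p-value is the (add-one) fraction of null runs whose folded attribution
    meets or exceeds the observed median.
    """
    real = [fold_attributions(r.attributions) for r in runs if r.attributions]
    null = [fold_attributions(r.attributions) for r in null_runs if r.attributions]
    if not real or not null:
        raise ValueError("runs and null_runs must carry attributions")
    real_df = pd.DataFrame(real)
    null_df = pd.DataFrame(null)
    if list(real_df.columns) != list(null_df.columns):
        raise ValueError("mismatched feature sets between runs and null runs")
    observed = real_df.median()
    exceed = (null_df >= observed).sum()
    p = (exceed + 1) / (len(null_df) + 1)
    return pd.DataFrame({"importance": observed, "p_value": p})


def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied; U test degenerate (p = 1)")
        return 0.5 * a.size * b.size, 1.0
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(a, b=None, alternative: str = "greater") -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired samples or of one sample against 0."""
    a = np.asarray(a, float)
    diff = a - np.asarray(b, float) if b is not None else a
    if np.all(diff == 0):
        warnings.warn("all differences zero; Wilcoxon degenerate (p = 1)")
        return 0.0, 1.0
    res = sps.wilcoxon(diff, alternative=alternative, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def kruskal_with_tukey(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus test plus rank-based Tukey HSD pairwise tests.

    Pairwise comparisons run Tukey's HSD on the pooled ranks of the data
    (a nonparametric post hoc consistent with the omnibus test).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    values = [np.asarray(groups[g], float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied; tests degenerate (p = 1)")
        pairs = {(g1, g2): 1.0 for i, g1 in enumerate(names) for g2 in names[i + 1 :]}
        return {"statistic": 0.0, "p_value": 1.0, "pairwise": pairs}
    stat, p = sps.kruskal(*values)
    ranks = sps.rankdata(pooled)
    labels = np.concatenate([[g] * len(v) for g, v in zip(names, values)])
    tukey = pairwise_tukeyhsd(ranks, labels)
    pairs = {
        tuple(sorted((str(r[0]), str(r[1])))): float(r[3])
        for r in tukey.summary().data[1:]
    }
    return {"statistic": float(stat), "p_value": float(p), "pairwise": pairs}


def group_tests(values_by_group: dict[str, np.ndarray], test: str = "auto") -> dict:
    """Dispatch the appropriate nonparametric group comparison.

    Two groups -> Mann-Whitney U (two-tailed); more -> Kruskal-Wallis with
    rank-based Tukey-corrected pairwise comparisons.
    """
    names = list(values_by_group)
    if len(names) == 2 and test in ("auto", "mannwhitney"):
        stat, p = mann_whitney(values_by_group[names[0]], values_by_group[names[1]])
        return {"test": "mannwhitneyu", "statistic": stat, "p_value": p}
    result = kruskal_with_tukey(values_by_group)
    result["test"] = "kruskal-tukey"
    return result
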