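"""Nonparametric statistical battery for small clinical cohorts.

Longitudinal change across the four timepoints is tested with Friedman's
test (tie-corrected, with an exact permutation mode for tiny samples),
effect size by Kendall's W = chi2_F / (n (k-1)), and Dunn's pairwise post
hocs with Bonferroni correction. Between-cluster comparisons use
Kruskal-Wallis plus Dunn; two-group continuous comparisons gate between an
unpaired t-test and the Wilcoxon rank-sum on Shapiro-Wilk normality and an
F-test of variances; categorical associations gate between chi-square with
Yates continuity correction and Fisher's exact test on expected counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import expected_freq


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    p_value: float
    n_subjects: int
    k_timepoints: int
    kendalls_w: float
    method: str = "asymptotic"


@dataclass
class GroupComparisonResult:
    variable: str
    grouping: str
    test_used: str
    statistic: float
    p_value: float
    gating_trace: dict = field(default_factory=dict)


def _rank_matrix(wide: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, wide)


def _friedman_stat(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a within-row rank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    A = float((ranks ** 2).sum())
    C = n * k * (k + 1) ** 2 / 4.0
    denom = A - C
    if denom <= 0:
        return 0.0
    num = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    return num / denom


def friedman_test(wide, method: str = "auto") -> FriedmanResult:
    """Friedman's test on an n x k repeated-measures matrix.

    ``method`` is ``"asymptotic"`` (chi-square with k-1 df), ``"exact"``
    (full enumeration of the (k!)^n equally likely within-row rank
    configurations under the null), or ``"auto"`` (exact when the
    enumeration has at most 50 000 configurations). Kendall's W is
    chi2_F / (n (k-1)) in both modes.
    """
    wide = _as_complete_matrix(wide)
    n, k = wide.shape
    if n < 2 or k < 3:
        raise ValueError("Friedman needs n >= 2 subjects and k >= 3 conditions")
    ranks = _rank_matrix(wide)
    stat = _friedman_stat(ranks)
    w = stat / (n * (k - 1))

    n_configs = math.factorial(k) ** n
    if method == "auto":
        method = "exact" if n_configs <= 50_000 else "asymptotic"
    if method == "exact":
        if n_configs > 2_000_000:
            raise ValueError(f"exact enumeration infeasible: {n_configs} configurations")
        # Permute each row's own rank vector (ties preserved); the squared-rank
        # term A is permutation-invariant, so the statistic depends only on the
        # column sums of the permuted rank matrix.
        perm_idx = list(itertools.permutations(range(k)))
        A = float((ranks ** 2).sum())
        C = n * k * (k + 1) ** 2 / 4.0
        denom = A - C
        variants = [np.array([row[list(p)] for p in perm_idx]) for row in ranks]
        col_sums = np.zeros((1, k))
        for var in variants:  # cartesian accumulation of per-row contributions
            col_sums = (col_sums[:, None, :] + var[None, :, :]).reshape(-1, k)
        if denom <= 0:
            stats_null = np.zeros(len(col_sums))
        else:
            dev = col_sums - n * (k + 1) / 2.0
            stats_null = (k - 1) * (dev ** 2).sum(axis=1) / denom
        p = float((stats_null >= stat - 1e-12).mean())
    elif method == "asymptotic":
        p = float(sps.chi2.sf(stat, k - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return FriedmanResult(
        statistic=float(stat), df=k - 1, p_value=float(p),
        n_subjects=n, k_timepoints=k, kendalls_w=float(w), method=method,
    )


def _as_complete_matrix(wide) -> np.ndarray:
    if isinstance(wide, pd.DataFrame):
        wide = wide.to_numpy(dtype=float)
    wide = np.asarray(wide, dtype=float)
    if wide.ndim != 2:
        raise ValueError("expected an n x k matrix")
    if np.isnan(wide).any():
        raise ValueError("missing cells are not allowed (no imputation)")
    return wide


def dunn_posthoc_friedman(wide, level_names: list[str] | None = None) -> pd.DataFrame:
    """Dunn's pairwise post hocs after Friedman, Bonferroni-adjusted.

    z = (mean rank a - mean rank b) / sqrt(k (k+1) / (6 n)); the raw
    two-sided normal p is multiplied by the k(k-1)/2 pair count (capped at 1).
    """
    wide = _as_complete_matrix(wide)
    n, k = wide.shape
    if n < 2 or k < 3:
        raise ValueError("Friedman needs n >= 2 subjects and k >= 3 conditions")
    if level_names is None:
        level_names = [f"t{i + 1}" for i in range(k)]
    ranks = _rank_matrix(wide)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    m = k * (k - 1) // 2
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw = float(2 * sps.norm.sf(abs(z)))
        raw = min(raw, 1.0)
        rows.append({
            "level_a": level_names[a], "level_b": level_names[b],
            "z": float(z), "p_raw": raw,
            "p_adjusted": min(1.0, raw * m),
            "method": "dunn_bonferroni",
        })
    return pd.DataFrame(rows)


def _dunn_posthoc_independent(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks after Kruskal-Wallis,
    with tie correction, Bonferroni over the pair count."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term

    mean_rank = {}
    start = 0
    for g in names:
        size = len(groups[g])
        mean_rank[g] = float(ranks[start:start + size].mean())
        start += size
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        raw = min(1.0, float(2 * sps.norm.sf(abs(z))))
        rows.append({
            "level_a": a, "level_b": b, "z": float(z),
            "p_raw": raw, "p_adjusted": min(1.0, raw * m),
            "method": "dunn_bonferroni",
        })
    return pd.DataFrame(rows)


def compare_clusters_numeric(
    groups: dict[str, np.ndarray] | pd.Series,
    variable: str = "value", grouping: str = "cluster",
    alpha: float = 0.05, posthoc: str = "auto",
) -> tuple[GroupComparisonResult, pd.DataFrame | None]:
    """Kruskal-Wallis across clusters, Dunn/Bonferroni post hoc when
    the omnibus p is at or below alpha (``posthoc="always"`` forces it).

    ``groups`` is either {cluster: values} or a Series of values indexed by
    cluster label. All-identical values give statistic 0, p 1.
    """
    if isinstance(groups, pd.Series):
        groups = {str(g): sub.to_numpy(dtype=float)
                  for g, sub in groups.groupby(level=0)}
    groups = {str(g): np.asarray(v, dtype=float) for g, v in sorted(groups.items())}
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty cluster")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        result = GroupComparisonResult(
            variable=variable, grouping=grouping, test_used="kruskal_wallis",
            statistic=0.0, p_value=1.0,
            gating_trace={"note": "all values identical"},
        )
        return result, None
    stat, p = sps.kruskal(*groups.values())
    result = GroupComparisonResult(
        variable=variable, grouping=grouping, test_used="kruskal_wallis",
        statistic=float(stat), p_value=float(p),
    )
    table = None
    if posthoc == "always" or (posthoc == "auto" and p <= alpha):
        table = _dunn_posthoc_independent(groups)
    return result, table


def compare_two_groups_continuous(
    a, b, alpha: float = 0.05, bonferroni_m: int = 1,
    variable: str = "value", grouping: str = "group",
) -> GroupComparisonResult:
    """Gated two-group comparison.

    Both groups pass Shapiro-Wilk normality and the variance-ratio F-test at
    alpha -> unpaired t-test; otherwise Wilcoxon rank-sum (Mann-Whitney with
    normal approximation and tie correction). Groups smaller than 3 skip the
    gate and go straight to the rank-sum test. The final p is multiplied by
    ``bonferroni_m`` and capped at 1; the gate outcomes are recorded in
    ``gating_trace``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    trace: dict = {}

    use_t = False
    if min(len(a), len(b)) >= 3:
        sw_ps = []
        for name, g in (("a", a), ("b", b)):
            if np.ptp(g) == 0:
                sw_ps.append(0.0)  # constant sample: treat as non-normal
                trace[f"shapiro_p_{name}"] = 0.0
            else:
                p_sw = float(sps.shapiro(g).pvalue)
                sw_ps.append(p_sw)
                trace[f"shapiro_p_{name}"] = p_sw
        f_p = _variance_f_test(a, b)
        trace["variance_f_p"] = f_p
        use_t = all(p > alpha for p in sw_ps) and f_p > alpha
    else:
        trace["note"] = "group too small for normality gate; rank-sum used"

    if use_t:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        test = "t_test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        test = "wilcoxon_rank_sum"
    p_adj = min(1.0, float(p) * bonferroni_m)
    trace["bonferroni_m"] = bonferroni_m
    trace["p_unadjusted"] = float(p)
    return GroupComparisonResult(
        variable=variable, grouping=grouping, test_used=test,
        statistic=float(stat), p_value=p_adj, gating_trace=trace,
    )


def _variance_f_test(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2 * min(sps.f.cdf(f, dfa, dfb), sps.f.sf(f, dfa, dfb))
    return float(min(p, 1.0))


def categorical_association(
    table, variable: str = "value", grouping: str = "group",
) -> GroupComparisonResult:
    """Chi-square (Yates for 2x2) or Fisher's exact, gated on expected counts.

    Fisher's exact is used when any expected cell is below 5 (for 2x2
    tables; larger sparse tables fall back to the uncorrected chi-square
    with a warning recorded in the gating trace). Tables with all expected
    counts >= 5 use chi-square — Yates-corrected for 2x2, uncorrected for
    larger tables.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a 2-way contingency table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return GroupComparisonResult(
            variable=variable, grouping=grouping, test_used="chi_square_yates",
            statistic=0.0, p_value=1.0,
            gating_trace={"note": "degenerate table after dropping empty margins"},
        )
    expected = expected_freq(table)
    trace = {"min_expected": float(expected.min())}
    is_2x2 = table.shape == (2, 2)
    if expected.min() < 5:
        if is_2x2:
            stat, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
            return GroupComparisonResult(
                variable=variable, grouping=grouping, test_used="fisher_exact",
                statistic=float(stat), p_value=float(p), gating_trace=trace,
            )
        trace["warning"] = "expected counts < 5 in an r x c table; chi-square approximate"
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    else:
        stat, p, _, _ = sps.chi2_contingency(table, correction=is_2x2)
    return GroupComparisonResult(
        variable=variable, grouping=grouping,
        test_used="chi_square_yates" if is_2x2 else "chi_square",
        statistic=float(stat), p_value=float(p), gating_trace=trace,
    )
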