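"""Rank-based statistical test battery, per-sample antibody burden
summaries, cohort balance checks, and pipeline orchestration entry point.

All tests are two-sided and return p-values in (0, 1].  Friedman and
Kruskal-Wallis statistics are computed with midrank tie handling; fully
tied data yield statistic 0 and p = 1 rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "TestResult", "SampleBurden", "flagellin_burden", "wilcoxon_rank_sum",
    "spearman_rho", "friedman", "kruskal_dunn", "cohort_balance_check",
    "run_pipeline",
]


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p: float
    n: tuple
    p_adjusted: float | None = None
    adjustment: str = "none"
    extra: dict | None = None

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ParameterError(f"p-value {self.p} outside (0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p:
            raise ParameterError("adjusted p must be >= raw p")


def _clip_p(p):
    return float(min(max(p, 1e-300), 1.0))


@dataclass(frozen=True)
class SampleBurden:
    sample_id: str
    group: str
    n_seropositive_total: int
    n_seropositive_flagellin: int

    @property
    def flagellin_ratio(self):
        if self.n_seropositive_total == 0:
            return 0.0
        return self.n_seropositive_flagellin / self.n_seropositive_total


def flagellin_burden(calls, flagellin_flags, groups=None):
    """Per-sample seropositive totals and flagellin ratio.

    ``calls`` is the long-format calls table from :mod:`flagseq.enrich`;
    ``flagellin_flags`` maps peptide id -> bool.  The ratio denominator is
    all seropositive peptides (see output header note: the alternative
    flagellin/non-flagellin ratio is a monotone transform).
    """
    flags = pd.Series(flagellin_flags)
    sero = calls[calls["seropositive"]]
    burdens = []
    for sample in calls["sample_id"].unique():
        sub = sero[sero["sample_id"] == sample]
        total = len(sub)
        n_flag = int(flags.reindex(sub["peptide_id"]).fillna(False).sum())
        group = "" if groups is None else groups.get(sample, "")
        if total == 0:
            import warnings
            warnings.warn(f"sample {sample} has zero seropositive peptides "
                          "(should have been QC-excluded)", stacklevel=2)
        burdens.append(SampleBurden(sample, group, total, n_flag))
    return burdens


def wilcoxon_rank_sum(x, y, exact_max_n=10):
    """Two-sided Mann-Whitney U; exact p for small groups (both n <= 10),
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ParameterError("both vectors must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult("wilcoxon_rank_sum", len(x) * len(y) / 2.0, 1.0,
                          (len(x), len(y)))
    has_ties = len(np.unique(pooled)) < len(x) + len(y)
    exact = len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    p = 1.0 if np.isnan(res.pvalue) else res.pvalue
    return TestResult("wilcoxon_rank_sum", float(res.statistic),
                      _clip_p(p), (len(x), len(y)))


def spearman_rho(x, y):
    """Spearman rank correlation with midrank ties, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ParameterError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ParameterError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    if np.isnan(rho):
        raise ParameterError("correlation undefined")
    return TestResult("spearman", float(rho), _clip_p(p), (len(x),))


def _friedman_statistic(ranks, n, k, denom):
    rank_sums = ranks.sum(axis=0)
    return 12.0 * np.sum((rank_sums - n * (k + 1) / 2.0) ** 2) / denom


def friedman(blocks, exact_limit=50_000):
    """Friedman test on within-block midranks.

    ``blocks`` is an (n_blocks x k_treatments) matrix without missing cells.
    Fully tied data return statistic 0 and p = 1.  When the full
    within-block permutation distribution is small enough to enumerate
    (``(k!)^n <= exact_limit``) the p-value is exact; otherwise the
    chi-square approximation with tie correction is used.
    """
    import itertools
    import math

    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise ParameterError("blocks must be a 2-D matrix")
    if np.any(np.isnan(blocks)):
        raise ParameterError("missing cells are not allowed")
    n, k = blocks.shape
    if n < 3 or k < 2:
        raise ParameterError("need >= 3 blocks and >= 2 treatments")
    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    # Tie correction over within-block tie groups (permutation invariant).
    tie_term = 0.0
    for row in blocks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts ** 3 - counts))
    denom = n * k * (k + 1) - tie_term * k / (k - 1)
    if denom <= 0:
        return TestResult("friedman", 0.0, 1.0, (n, k))
    statistic = _friedman_statistic(ranks, n, k, denom)
    n_perms = math.factorial(k) ** n
    if n_perms <= exact_limit:
        perms = list(itertools.permutations(range(k)))
        observed = statistic
        count = 0
        for combo in itertools.product(perms, repeat=n):
            permuted = np.array([ranks[i, list(c)] for i, c in enumerate(combo)])
            if _friedman_statistic(permuted, n, k, denom) >= observed - 1e-12:
                count += 1
        p = count / n_perms
    else:
        p = sps.chi2.sf(statistic, k - 1)
    return TestResult("friedman", float(statistic), _clip_p(p), (n, k))


def _kw_statistic(groups):
    all_values = np.concatenate(groups)
    N = len(all_values)
    ranks = sps.rankdata(all_values)
    offsets = np.cumsum([0] + [len(g) for g in groups[:-1]])
    h = 0.0
    for off, g in zip(offsets, groups):
        r = ranks[off:off + len(g)]
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(all_values, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_term / (N ** 3 - N) if N > 1 else 0.0
    if correction <= 0:
        return 0.0, ranks, tie_term, N
    return h / correction, ranks, tie_term, N


def kruskal_dunn(groups, alpha=0.05):
    """Kruskal-Wallis H with tie correction, followed (when p <= alpha) by
    Dunn z-tests for all pairs with Bonferroni adjustment.

    Returns ``(TestResult, pairwise_df)``; the pairwise table is empty when
    the omnibus test is not significant.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3 or any(len(g) == 0 for g in groups):
        raise ParameterError("need >= 3 non-empty groups")
    h, ranks, tie_term, N = _kw_statistic(groups)
    k = len(groups)
    if h == 0.0:
        omnibus = TestResult("kruskal_wallis", 0.0, 1.0,
                             tuple(len(g) for g in groups))
    else:
        p = sps.chi2.sf(h, k - 1)
        omnibus = TestResult("kruskal_wallis", float(h), _clip_p(p),
                             tuple(len(g) for g in groups))
    columns = ["group_i", "group_j", "z", "p", "p_adj", "higher"]
    rows = []
    if omnibus.p <= alpha and omnibus.statistic > 0:
        offsets = np.cumsum([0] + [len(g) for g in groups[:-1]])
        mean_ranks = [ranks[off:off + len(g)].mean()
                      for off, g in zip(offsets, groups)]
        pooled_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
        n_pairs = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(pooled_var * (1.0 / len(groups[i])
                                           + 1.0 / len(groups[j])))
                z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
                p_raw = 2.0 * sps.norm.sf(abs(z))
                rows.append({"group_i": i, "group_j": j, "z": float(z),
                             "p": _clip_p(p_raw),
                             "p_adj": _clip_p(min(1.0, p_raw * n_pairs)),
                             "higher": i if z > 0 else j})
    return omnibus, pd.DataFrame(rows, columns=columns)


def chi_square_contingency(table):
    """Pearson chi-square on a contingency table, without continuity
    correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ParameterError("degenerate contingency table (empty margin)")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return TestResult("chi_square", float(stat), _clip_p(p),
                      tuple(int(x) for x in table.sum(axis=1)))


def cohort_balance_check(metadata):
    """Wilcoxon on ordinal age bins and chi-square on sex x group; requires
    ``group`` (case/control), ``age_bin``, ``sex`` columns."""
    for col in ("group", "age_bin", "sex"):
        if col not in metadata.columns:
            raise ParameterError(f"metadata lacks column {col!r}")
    groups = metadata["group"].unique()
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    age_codes = pd.Categorical(metadata["age_bin"],
                               categories=sorted(metadata["age_bin"].unique()),
                               ordered=True).codes
    case_ages = age_codes[(metadata["group"] == "case").to_numpy()]
    ctrl_ages = age_codes[(metadata["group"] == "control").to_numpy()]
    age_test = wilcoxon_rank_sum(case_ages, ctrl_ages)
    sex_table = pd.crosstab(metadata["group"], metadata["sex"])
    if sex_table.shape[1] < 2:
        raise ParameterError("all samples share one sex; chi-square degenerate")
    sex_test = chi_square_contingency(sex_table.to_numpy())
    return age_test, sex_test


def run_pipeline(config):
    """End-to-end orchestration; see :mod:`flagseq.pipeline`."""
    from .pipeline import run_pipeline as _run
    return _run(config)
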