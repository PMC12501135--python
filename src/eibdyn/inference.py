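"""Nonparametric group comparisons across sessions: Kruskal–Wallis with Dunn
post hoc mean-rank differences, and multiple-comparison adjustment.

The Kruskal–Wallis H statistic (tie-corrected, reported against a χ² reference
with g − 1 degrees of freedom) tests for any difference across condition
groups; pairwise follow-up uses Dunn's method — differences of the groups'
mean pooled ranks, standardized with the tie-corrected pooled-rank variance —
with Benjamini–Hochberg or Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PosthocPair", "TestResult", "kruskal_wallis_mrd", "adjust_pvalues"]


@dataclass(frozen=True)
class PosthocPair:
    pair: tuple
    mean_rank_difference: float
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class TestResult:
    """Kruskal–Wallis outcome with Dunn post hoc comparisons.

    ``statistic`` is H, referenced to χ² with ``df = groups − 1``; report
    formatting follows the χ²(df, N) convention.
    """

    statistic: float
    df: int
    n: int
    p: float
    posthoc: list

    def report(self) -> str:
        return f"chi2({self.df},{self.n}) = {self.statistic:.2f}, P = {self.p:.3g}"


def kruskal_wallis_mrd(groups, labels=None, adjust: str = "fdr_bh") -> TestResult:
    """Kruskal–Wallis test with Dunn mean-rank-difference post hoc.

    ``groups`` is a list of 1-D samples.  Post hoc: for every pair (i, j) the
    difference of mean pooled ranks, its Dunn z statistic

        z = (R̄_i − R̄_j) / sqrt(V · (1/n_i + 1/n_j)),
        V = (N(N+1)/12) · tie-correction,

    and a two-sided normal p-value, adjusted by ``adjust`` (fdr_bh or
    bonferroni, or None for raw).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    if labels is None:
        labels = list(range(len(groups)))
    pooled = np.concatenate(groups)
    N = pooled.size

    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + g.size].mean()))
        sizes.append(g.size)
        start += g.size

    # tie-corrected pooled-rank variance for Dunn z
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    V = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1)) if N > 1 else 0.0

    pairs, diffs, zs, p_raw = [], [], [], []
    for i, j in combinations(range(len(groups)), 2):
        diff = mean_ranks[i] - mean_ranks[j]
        se = np.sqrt(V * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = diff / se if se > 0 else 0.0
        pairs.append((labels[i], labels[j]))
        diffs.append(diff)
        zs.append(z)
        p_raw.append(float(2.0 * stats.norm.sf(abs(z))))

    p_adj = adjust_pvalues(p_raw, method=adjust) if adjust else list(p_raw)
    posthoc = [
        PosthocPair(pair=pr, mean_rank_difference=d, z=float(z),
                    p_raw=praw, p_adjusted=float(padj))
        for pr, d, z, praw, padj in zip(pairs, diffs, zs, p_raw, p_adj)
    ]
    return TestResult(statistic=float(H), df=len(groups) - 1, n=N,
                      p=float(p), posthoc=posthoc)


def adjust_pvalues(p, method: str = "fdr_bh") -> list:
    """Benjamini–Hochberg step-up or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in {"fdr_bh", "bonferroni"}:
        raise ValueError(f"unknown method {method!r}")
    if p.size == 0:
        return []
    return multipletests(p, method=method)[1].tolist()
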