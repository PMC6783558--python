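"""Nonparametric group comparisons for community data.

ANOSIM (analysis of similarity) is implemented from scratch: all
n(n-1)/2 pairwise dissimilarities are ranked (average ranks on ties) and

    R = (mean rank between groups - mean rank within groups) / (n(n-1)/4)

so R is in [-1, 1], with large positive R meaning samples are more similar
within groups than between them.  Significance comes from a one-sided
permutation test over group labels with the +1 convention
p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations), which never returns
zero.  Kruskal-Wallis and Mann-Whitney U wrap scipy.stats with tie
handling and report two-sided p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DistanceMatrix

__all__ = [
    "AnosimResult",
    "RankTestResult",
    "anosim",
    "pairwise_anosim",
    "kruskal_wallis",
    "mann_whitney",
]


@dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    group_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.p_value >= 1.0 / (self.n_permutations + 1)


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    """R from a square matrix of pairwise-distance ranks and group labels."""
    n = labels.size
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    denom = n * (n - 1) / 4.0
    return float((between.mean() - within.mean()) / denom)


def anosim(
    distances: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """ANOSIM permutation test on a distance matrix.

    Parameters
    ----------
    groups
        Per-sample group labels: a pandas Series indexed by sample id, a
        mapping, or a sequence aligned with ``distances.sample_ids``.
    """
    labels = _align_labels(groups, distances.sample_ids)
    uniques, counts = np.unique(labels, return_counts=True)
    if uniques.size < 2:
        raise ValueError("ANOSIM requires at least two groups")
    small = uniques[counts < 2].tolist()
    if small:
        raise ValueError(f"groups with fewer than two samples: {small}")

    n = labels.size
    iu = np.triu_indices(n, k=1)
    condensed = distances.values[iu]
    ranks = stats.rankdata(condensed)  # average ranks on ties
    rank_matrix = np.zeros((n, n))
    rank_matrix[iu] = ranks
    rank_matrix = rank_matrix + rank_matrix.T

    r_obs = _anosim_r(rank_matrix, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(rank_matrix, perm) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(
        r_statistic=r_obs,
        p_value=p,
        n_permutations=n_permutations,
        group_labels=tuple(str(u) for u in uniques),
    )


def _align_labels(groups, sample_ids) -> np.ndarray:
    if isinstance(groups, pd.Series):
        missing = [s for s in sample_ids if s not in groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        return groups.reindex(sample_ids).to_numpy()
    if isinstance(groups, dict):
        return _align_labels(pd.Series(groups), sample_ids)
    labels = np.asarray(list(groups))
    if labels.size != len(sample_ids):
        raise ValueError("group labels do not align with distance matrix samples")
    return labels


def pairwise_anosim(
    distances: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise two-group ANOSIMs, subsetting the precomputed matrix.

    Returns one row per unordered group pair: comparison, R, P.  For k
    groups there are k(k-1)/2 rows.
    """
    labels = pd.Series(_align_labels(groups, distances.sample_ids),
                       index=distances.sample_ids)
    uniques = sorted(labels.unique())
    ss = np.random.SeedSequence(seed).spawn(len(uniques) * (len(uniques) - 1) // 2)
    rows = []
    for k, (a, b) in enumerate(combinations(uniques, 2)):
        keep = labels.index[labels.isin([a, b])].tolist()
        sub = distances.subset(keep)
        sub_seed = int(np.random.default_rng(ss[k]).integers(2**31))
        res = anosim(sub, labels.loc[keep], n_permutations=n_permutations, seed=sub_seed)
        rows.append(
            {
                "comparison": f"{a} vs. {b}",
                "R": res.r_statistic,
                "P": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(values, groups) -> RankTestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p on k-1 df)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(groups))
    if values.size != labels.size:
        raise ValueError("values and group labels differ in length")
    uniques = np.unique(labels)
    if uniques.size < 2:
        raise ValueError("Kruskal-Wallis requires at least two groups")
    samples = [values[labels == u] for u in uniques]
    sizes = tuple(int(s.size) for s in samples)
    if any(s == 0 for s in sizes):
        raise ValueError("every group needs at least one value")
    if np.all(values == values[0]):
        return RankTestResult(statistic=0.0, p_value=1.0, group_sizes=sizes)
    h, p = stats.kruskal(*samples)
    return RankTestResult(statistic=float(h), p_value=float(p), group_sizes=sizes)


def mann_whitney(values_a, values_b) -> RankTestResult:
    """Two-sided Mann-Whitney U test; reports the smaller of U_a, U_b.

    Exact enumeration when n_a * n_b <= 400 and the data are tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, a.size * b.size - u1)
    return RankTestResult(
        statistic=u,
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(int(a.size), int(b.size)),
    )
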