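"""Rarefaction, alpha-diversity indices and Bray-Curtis dissimilarities.

Implemented from the standard definitions: Shannon H = -sum p_i ln p_i
(natural log by default), bias-corrected Chao1 richness
S_obs + F1(F1-1)/(2(F2+1)), Pielou evenness H / ln S_obs, and
Bray-Curtis d(A,B) = 1 - 2 sum_i min(A_i,B_i) / (sum A + sum B).
Rarefaction subsamples each sample without replacement to a common depth
(multivariate hypergeometric draw), equalising sequencing effort before
diversity is compared across samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CountTable

__all__ = [
    "AlphaDiversityRecord",
    "DistanceMatrix",
    "rarefy",
    "shannon",
    "chao1",
    "evenness",
    "observed_taxa",
    "alpha_diversity",
    "bray_curtis_matrix",
    "rarefaction_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlphaDiversityRecord:
    sample_id: str
    observed_taxa: int
    shannon_H: float
    chao1: float
    evenness: float  # NaN marks "undefined" (single observed taxon)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities in [0, 1] with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])


def _positive_vector(counts) -> np.ndarray:
    v = np.asarray(counts, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if np.any(v < 0):
        raise ValueError("counts must be non-negative")
    if v.sum() == 0:
        raise ValueError("all-zero count vector")
    return v[v > 0]


def rarefy(
    table: CountTable,
    depth: int,
    seed: int,
    drop_shallow: bool = False,
) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads raise an error unless
    ``drop_shallow`` is set, in which case they are removed with a logged
    warning.  Deterministic for a fixed ``seed``.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    sums = table.sample_sums
    shallow = sums.index[sums < depth].tolist()
    counts = table.counts
    if shallow:
        if not drop_shallow:
            raise ValueError(
                f"samples shallower than depth {depth}: {shallow}; "
                "pass drop_shallow=True to remove them"
            )
        logger.warning("rarefy: dropping %d shallow samples: %s", len(shallow), shallow)
        counts = counts.drop(columns=shallow)
        if counts.shape[1] == 0:
            raise ValueError("all samples shallower than requested depth")

    rng = np.random.default_rng(seed)
    out = np.empty(counts.shape, dtype=np.int64)
    matrix = counts.to_numpy()
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    rarefied = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return CountTable(rarefied, table.taxonomy)


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log unless ``base``)."""
    v = _positive_vector(counts)
    p = v / v.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def observed_taxa(counts) -> int:
    """Number of taxa with a positive count."""
    return int(_positive_vector(counts).size)


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton (F1) and doubleton (F2) counts.

    Bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default (defined even
    when F2 = 0); the classic form S_obs + F1^2/(2 F2) via
    ``bias_corrected=False`` (returns S_obs when F1 = 0).
    """
    v = _positive_vector(counts)
    s_obs = v.size
    f1 = int((v == 1).sum())
    f2 = int((v == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return float(s_obs)
    return s_obs + f1 * f1 / (2.0 * f2)


def evenness(counts) -> float:
    """Pielou evenness H / ln S_obs in [0, 1]; NaN when only one taxon."""
    v = _positive_vector(counts)
    if v.size < 2:
        return math.nan
    return shannon(v) / math.log(v.size)


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Per-sample alpha-diversity table (observed, Shannon, Chao1, evenness)."""
    rows = []
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        rows.append(
            {
                "sample_id": sample,
                "observed_taxa": observed_taxa(col),
                "shannon": shannon(col),
                "chao1": chao1(col),
                "evenness": evenness(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)


def bray_curtis_matrix(table: CountTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis dissimilarities over samples."""
    if len(table.sample_ids) < 2:
        raise ValueError("need at least two samples for a distance matrix")
    x = table.counts.to_numpy(dtype=float)
    sums = x.sum(axis=0)
    if np.any(sums == 0):
        raise ValueError("zero-sum sample column")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[:, i][:, None], x[:, i + 1 :]).sum(axis=0)
        d[i, i + 1 :] = 1.0 - 2.0 * mins / (sums[i] + sums[i + 1 :])
    d = d + d.T
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(table.sample_ids, d)


def rarefaction_curve(
    table: CountTable,
    depths,
    seed: int,
    n_iterations: int = 1,
) -> pd.DataFrame:
    """Observed richness at a grid of rarefaction depths (long format).

    Each (depth, iteration) uses an independent substream of ``seed``.
    Depths above a sample's total are skipped for that sample.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for k, depth in enumerate(depths):
        for it in range(n_iterations):
            sub_seed = np.random.default_rng(ss.spawn(1)[0]).integers(2**31)
            sub = rarefy(table, int(depth), int(sub_seed), drop_shallow=True)
            for sample in sub.sample_ids:
                rows.append(
                    {
                        "depth": int(depth),
                        "iteration": it,
                        "sample_id": sample,
                        "observed_taxa": observed_taxa(sub.counts[sample].to_numpy()),
                    }
                )
    return pd.DataFrame(rows)
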