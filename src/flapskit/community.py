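"""Community composition statistics: normalization, Bray-Curtis, clustering,
and permutation tests (ANOSIM, PERMANOVA).

Count tables (samples x taxa) are normalized by dividing each row by its
sample total; samples under a read-depth threshold (default 10,000) are
flagged but retained. Pairwise Bray-Curtis dissimilarities

    BC(x, y) = sum_i |x_i - y_i| / sum_i (x_i + y_i)

feed average-linkage (UPGMA) clustering and two permutation tests:

* ANOSIM R contrasts the mean rank of between-group vs within-group
  dissimilarities, scaled by n(n-1)/4 so R is in [-1, 1];
* PERMANOVA partitions the squared-dissimilarity sum into between- and
  within-group components and forms a pseudo-F.

Significance for both comes from random relabeling, with the add-one
estimator p = (1 + #{perm stat >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

LOW_READ_THRESHOLD = 10_000


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Sample x taxon counts with per-sample metadata.

    ``metadata`` is indexed by sample id and carries at least station,
    substrate, timepoint_d and replicate; ``reads_total`` is (re)derived
    from the counts. Samples below ``low_read_threshold`` reads are flagged
    in ``low_reads`` but never dropped.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    low_read_threshold: int = LOW_READ_THRESHOLD

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.metadata.index):
            raise ValueError("counts and metadata must share the same sample index")
        self.metadata = self.metadata.copy()
        self.metadata["reads_total"] = self.counts.sum(axis=1).astype(int)

    @property
    def reads_total(self) -> pd.Series:
        return self.counts.sum(axis=1).astype(int)

    @property
    def low_reads(self) -> pd.Series:
        return flag_low_reads(self.counts, self.low_read_threshold)

    def to_tsv(self, counts_path, metadata_path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.metadata.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path, **kwargs) -> "CommunityTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(counts=counts, metadata=meta, **kwargs)


def _counts_frame(table) -> pd.DataFrame:
    return table.counts if isinstance(table, CommunityTable) else table


def normalize_relative(table) -> pd.DataFrame:
    """Relative abundances: each sample's counts divided by its total."""
    counts = _counts_frame(table)
    totals = counts.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"empty sample(s) cannot be normalized: "
                         f"{list(empty.index)}")
    rel = counts.div(totals, axis=0)
    return rel


def flag_low_reads(table, threshold: int = LOW_READ_THRESHOLD) -> pd.Series:
    """True for samples whose read total is under the threshold (retained)."""
    counts = _counts_frame(table)
    return (counts.sum(axis=1) < threshold).rename("low_reads")


# ---------------------------------------------------------------------------
# Dissimilarity
# ---------------------------------------------------------------------------

def bray_curtis(rel_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity matrix of composition rows."""
    x = np.asarray(rel_table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 samples")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    sums = x.sum(axis=1)
    den = sums[:, None] + sums[None, :]
    np.fill_diagonal(den, 1.0)  # diagonal numerator is 0 anyway
    if (den <= 0).any():
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    d = num / den
    np.fill_diagonal(d, 0.0)
    idx = rel_table.index if isinstance(rel_table, pd.DataFrame) \
        else pd.RangeIndex(x.shape[0])
    return pd.DataFrame(d, index=idx, columns=idx)


def _as_square(matrix) -> tuple[np.ndarray, pd.Index]:
    d = np.asarray(matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12) or np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    idx = matrix.index if isinstance(matrix, pd.DataFrame) \
        else pd.RangeIndex(d.shape[0])
    return d, idx


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterTree:
    """Average-linkage merge history over samples."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) format
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def merge_table(self) -> pd.DataFrame:
        z = self.linkage_matrix
        return pd.DataFrame({"left": z[:, 0].astype(int),
                             "right": z[:, 1].astype(int),
                             "height": z[:, 2], "size": z[:, 3].astype(int)})


def cluster_average(matrix) -> ClusterTree:
    """Agglomerative average-linkage (UPGMA) clustering of a dissimilarity matrix."""
    d, idx = _as_square(matrix)
    z = linkage(squareform(d, checks=False), method="average")
    return ClusterTree(linkage_matrix=z, labels=tuple(str(i) for i in idx))


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationTestResult:
    """Observed statistic with its permutation p-value."""

    name: str
    statistic: float
    n_perm: int
    p_value: float
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("permutation p-value must be in (0, 1]")


def _group_codes(groups, idx) -> np.ndarray:
    g = np.asarray(groups)
    if len(g) != len(idx):
        raise ValueError("one group label per sample is required")
    codes, counts = np.unique(g, return_counts=True)
    if len(codes) < 2:
        raise ValueError("at least 2 groups are required")
    if counts.min() < 2:
        raise ValueError("every group must contain at least 2 samples")
    return np.searchsorted(codes, g)


def _perm_matrix(codes: np.ndarray, n_perm, seed: int) -> tuple[np.ndarray, int]:
    """Stack of permuted label vectors; 'exhaustive' enumerates all orderings."""
    n = len(codes)
    if n_perm == "exhaustive":
        perms = np.array(list(itertools.permutations(range(n))))
        return codes[perms], len(perms)
    rng = np.random.default_rng(seed)
    mat = np.stack([rng.permutation(codes) for _ in range(int(n_perm))])
    return mat, int(n_perm)


def _within_sums(label_mat: np.ndarray, sq: np.ndarray,
                 codes: np.ndarray) -> np.ndarray:
    """Per-permutation sum of sq[i, j] over unordered within-group pairs."""
    total = np.zeros(label_mat.shape[0])
    for g in np.unique(codes):
        m = (label_mat == g).astype(float)
        total += 0.5 * np.einsum("pi,ij,pj->p", m, sq, m)
    return total


def _anosim_r(label_mat: np.ndarray, rank_sq: np.ndarray,
              codes: np.ndarray) -> np.ndarray:
    n = rank_sq.shape[0]
    m_pairs = n * (n - 1) // 2
    _, counts = np.unique(codes, return_counts=True)
    n_within = int((counts * (counts - 1) // 2).sum())
    n_between = m_pairs - n_within
    total_rank = rank_sq.sum() / 2.0
    sw = _within_sums(label_mat, rank_sq, codes)
    r_w = sw / n_within
    r_b = (total_rank - sw) / n_between
    return (r_b - r_w) / (n * (n - 1) / 4.0)


def anosim(matrix, groups, n_perm: int | str = 999, seed: int = 0,
           ) -> PermutationTestResult:
    """Analysis of similarity on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    ranks taken over all pairwise dissimilarities with mid-ranks for ties.
    ``n_perm='exhaustive'`` enumerates every label ordering (small n only);
    otherwise ``n_perm`` random relabelings drawn with ``seed``.
    """
    d, idx = _as_square(matrix)
    codes = _group_codes(groups, idx)
    condensed = squareform(d, checks=False)
    ranks = rankdata(condensed)
    rank_sq = squareform(ranks, checks=False)

    observed = float(_anosim_r(codes[None, :], rank_sq, codes)[0])
    label_mat, m = _perm_matrix(codes, n_perm, seed)
    perm_stats = _anosim_r(label_mat, rank_sq, codes)
    b = int(np.sum(perm_stats >= observed - 1e-12))
    return PermutationTestResult(name="ANOSIM R", statistic=observed, n_perm=m,
                                 p_value=(1 + b) / (1 + m),
                                 seed=None if n_perm == "exhaustive" else seed)


def _permanova_f(label_mat: np.ndarray, d2: np.ndarray,
                 codes: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    a = len(np.unique(codes))
    ss_total = d2.sum() / 2.0 / n
    _, counts = np.unique(codes, return_counts=True)
    # within-group pair sums per group, each divided by its group size
    ss_within = np.zeros(label_mat.shape[0])
    for g, n_g in zip(np.unique(codes), counts):
        m = (label_mat == g).astype(float)
        ss_within += 0.5 * np.einsum("pi,ij,pj->p", m, d2, m) / n_g
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        return np.where(ss_within > 0,
                        (ss_between / (a - 1)) / (ss_within / (n - a)),
                        np.inf)


def permanova(matrix, groups, n_perm: int | str = 999, seed: int = 0,
              ) -> PermutationTestResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums within-group pairs
    scaled by group size; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).
    A degenerate SS_within of 0 reports an infinite F, with the p-value
    still taken from the permutation null.
    """
    d, idx = _as_square(matrix)
    codes = _group_codes(groups, idx)
    d2 = d ** 2

    observed = float(_permanova_f(codes[None, :], d2, codes)[0])
    label_mat, m = _perm_matrix(codes, n_perm, seed)
    perm_stats = _permanova_f(label_mat, d2, codes)
    threshold = observed if np.isinf(observed) else observed - 1e-12
    b = int(np.sum(perm_stats >= threshold))
    return PermutationTestResult(name="PERMANOVA pseudo-F", statistic=observed,
                                 n_perm=m, p_value=(1 + b) / (1 + m),
                                 seed=None if n_perm == "exhaustive" else seed)
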