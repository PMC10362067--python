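"""Genotype similarity vs repertoire similarity.

Allele sharing distance (ASD) between two individuals at one diploid locus is
d = 2 - |multiset intersection of the two allele pairs| (0 when the genotypes
are identical, 2 when they share no allele); the pairwise ASD is the mean of
d/2 over loci where both calls are diploid and non-missing.  Repertoire
similarity is the Pearson correlation of two samples' usage-fraction vectors
over all retained genes.  Sample pairs are binned by ASD quantiles and the
usage correlations of the lowest- and highest-ASD bins are compared with a
two-sample Kolmogorov-Smirnov test (pair non-independence is ignored, a
documented caveat of this comparison).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenotypeMatrix, MISSING


def allele_sharing_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """ASD between two genotype vectors given as (n_loci, 2) allele arrays
    (negative codes = hemizygous/missing; such loci are skipped)."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 >= 0).all(axis=1) & (g2 >= 0).all(axis=1)
    if not ok.any():
        raise ValueError("no shared complete diploid loci")
    a = np.sort(g1[ok], axis=1)
    b = np.sort(g2[ok], axis=1)
    # multiset intersection of two sorted allele pairs: 2 iff identical,
    # 1 iff they share at least one allele, else 0
    same_any = (
        (a[:, 0] == b[:, 0])
        | (a[:, 0] == b[:, 1])
        | (a[:, 1] == b[:, 0])
        | (a[:, 1] == b[:, 1])
    )
    shared = np.where((a == b).all(axis=1), 2, np.where(same_any, 1, 0))
    d = 2 - shared
    return float(d.mean() / 2.0)


def asd_matrix(genotypes: GenotypeMatrix, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise ASD over the given variants (default: all biallelic)."""
    ids = variant_ids or [v.id for v in genotypes.variants if v.is_biallelic]
    cols = [genotypes.variant_index(v) for v in ids]
    a1 = genotypes.a1[:, cols]
    a2 = genotypes.a2[:, cols]
    n = genotypes.n_samples
    stacked = np.stack([a1, a2], axis=2)  # (n, loci, 2)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = allele_sharing_distance(stacked[i], stacked[j])
    return pd.DataFrame(out, index=genotypes.samples, columns=genotypes.samples)


def pairwise_usage_correlation(fractions: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of usage-fraction vectors
    (genes x samples input; needs >= 3 genes)."""
    if fractions.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    X = fractions.to_numpy(float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance usage vector")
    return pd.DataFrame(
        np.corrcoef(X.T), index=fractions.columns, columns=fractions.columns
    )


@dataclass
class SimilarityResult:
    asd: pd.DataFrame
    correlations: pd.DataFrame
    bin_assignments: pd.Series  # pair (i,j) -> bin index
    bin_means: pd.Series  # bin -> mean usage correlation
    bin_counts: pd.Series
    ks_statistic: float
    ks_p: float
    low_bin_mean: float
    high_bin_mean: float


def compare_asd_groups(
    asd: pd.DataFrame,
    correlations: pd.DataFrame,
    n_bins: int = 4,
) -> SimilarityResult:
    """Bin unordered sample pairs by ASD quantile; compare the usage
    correlations of the lowest- and highest-ASD bins (KS test)."""
    if list(asd.index) != list(correlations.index):
        raise ValueError("ASD and correlation matrices must be aligned")
    n = len(asd)
    iu = np.triu_indices(n, k=1)
    asd_vals = asd.to_numpy()[iu]
    cor_vals = correlations.to_numpy()[iu]
    if len(asd_vals) < 2 * n_bins:
        raise ValueError("fewer pairs than 2 x n_bins")
    if np.all(asd_vals == asd_vals[0]):
        raise ValueError("all pairs have identical ASD; binning is degenerate")
    # quantile bins; duplicate edges merged (rank-based to break ties stably)
    ranks = stats.rankdata(asd_vals, method="average")
    bins = np.minimum((ranks - 1) / len(ranks) * n_bins, n_bins - 1).astype(int)
    pair_index = pd.MultiIndex.from_arrays(
        [np.asarray(asd.index)[iu[0]], np.asarray(asd.index)[iu[1]]]
    )
    assignments = pd.Series(bins, index=pair_index)
    means = pd.Series(
        {
            b: (cor_vals[bins == b].mean() if (bins == b).any() else math.nan)
            for b in range(n_bins)
        }
    )
    counts = pd.Series({b: int((bins == b).sum()) for b in range(n_bins)})
    low = cor_vals[bins == 0]
    high = cor_vals[bins == n_bins - 1]
    ks = stats.ks_2samp(low, high)
    return SimilarityResult(
        asd=asd,
        correlations=correlations,
        bin_assignments=assignments,
        bin_means=means,
        bin_counts=counts,
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        low_bin_mean=float(low.mean()),
        high_bin_mean=float(high.mean()),
    )
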