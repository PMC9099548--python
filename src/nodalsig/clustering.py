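"""Unsupervised sample clustering with SD-cutoff selection and consensus.

Samples are clustered by average-linkage agglomeration on 1 - Pearson
correlation.  The variability filter is chosen iteratively: for each
candidate SD cutoff, genes below the cutoff are removed, the remaining
matrix is clustered, and the anti-correlation A(sigma) between the two
top-level groups (mean cross-group pairwise sample correlation) is
measured; the chosen cutoff minimizes A(sigma) subject to A(sigma) < 0 and
at least ``min_genes`` (default 3,000) genes retained — anti-correlations
near zero indicate grouping by chance.  Cluster robustness is then
quantified by consensus clustering: repeated subsampling (default 10,000
iterations leaving out 40% of samples), with consensus(i, j) = co-cluster
count / co-sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

N_CUTOFFS_DEFAULT = 40
MIN_GENES_DEFAULT = 3000
N_ITERATIONS_DEFAULT = 10_000
SUBSAMPLE_FRACTION_DEFAULT = 0.6


def center_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's mean across samples.

    Sample-sample correlations on raw logCPM are dominated by the shared
    abundance profile (all near +1); clustering and the anti-correlation
    criterion operate on per-gene-centered deviations, where dissimilar
    samples can genuinely anti-correlate.
    """
    return expr.sub(expr.mean(axis=1), axis=0)


def pearson_distance(expr: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation between sample columns; range [0, 2]."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = expr.std(axis=0, ddof=1)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        bad = list(expr.columns[(sd == 0) | ~np.isfinite(sd)])
        raise ValueError(f"zero-variance sample(s): {bad}")
    dist = 1.0 - expr.corr(method="pearson")
    np.fill_diagonal(dist.values, 0.0)
    return dist


def average_linkage(dist: pd.DataFrame) -> np.ndarray:
    """UPGMA linkage matrix (scipy format) from a square distance matrix."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return average(squareform(d, checks=False))


def top_split(linkage_matrix: np.ndarray) -> np.ndarray:
    """Labels (1/2) of the two groups at the highest level of the hierarchy."""
    return fcluster(linkage_matrix, 2, criterion="maxclust")


@dataclass
class SDSelection:
    """Record of the SD-cutoff sweep and the chosen variability filter."""

    cutoffs: np.ndarray
    genes_retained: np.ndarray
    anticorrelation: np.ndarray  # A(sigma) per cutoff (NaN if not evaluated)
    chosen_cutoff: float | None
    chosen_gene_set: list[str]
    status: str  # "ok" or "no_structure"


def _cross_group_mean_correlation(expr: pd.DataFrame, labels: np.ndarray) -> float:
    corr = expr.corr(method="pearson").to_numpy()
    mask1 = labels == labels[0]
    block = corr[np.ix_(mask1, ~mask1)]
    return float(block.mean())


def select_sd_cutoff(
    expr: pd.DataFrame,
    min_genes: int = MIN_GENES_DEFAULT,
    n_cutoffs: int = N_CUTOFFS_DEFAULT,
) -> SDSelection:
    """Choose the SD cutoff whose top split is most anti-correlated.

    Candidate cutoffs are ``n_cutoffs`` evenly spaced quantiles of the
    gene-wise SD distribution.  For each cutoff with >= ``min_genes`` genes
    retained, the retained matrix is clustered (1 - Pearson, average
    linkage), cut into its two top-level groups, and A(sigma) = mean
    cross-group pairwise sample correlation is recorded.  The chosen cutoff
    minimizes A(sigma) among cutoffs with A(sigma) < 0; if none is
    negative, status is ``"no_structure"`` (clustering would group samples
    by chance).  Genes are mean-centered before correlations are taken
    (:func:`center_genes`), so dissimilar top groups can genuinely
    anti-correlate.
    """
    if expr.shape[0] < min_genes:
        raise ValueError(
            f"only {expr.shape[0]} genes available, need >= {min_genes}"
        )
    gene_sd = expr.std(axis=1, ddof=1).to_numpy()
    expr = center_genes(expr)
    probs = np.linspace(0.0, 1.0, n_cutoffs, endpoint=False)
    cutoffs = np.quantile(gene_sd, probs)

    retained = np.zeros(n_cutoffs, dtype=int)
    anticorr = np.full(n_cutoffs, np.nan)
    best_idx, best_genes = None, None
    for i, cut in enumerate(cutoffs):
        keep = gene_sd > cut if i > 0 else np.ones_like(gene_sd, bool)
        retained[i] = int(keep.sum())
        if retained[i] < max(min_genes, 2) or retained[i] == 0:
            continue
        sub = expr.loc[keep]
        sd_cols = sub.std(axis=0, ddof=1)
        if (sd_cols == 0).any():
            continue
        labels = top_split(average_linkage(pearson_distance(sub)))
        anticorr[i] = _cross_group_mean_correlation(sub, labels)
        if anticorr[i] < 0 and (
            best_idx is None or anticorr[i] < anticorr[best_idx]
        ):
            best_idx, best_genes = i, list(sub.index)

    if best_idx is None:
        return SDSelection(cutoffs, retained, anticorr, None, [], "no_structure")
    return SDSelection(
        cutoffs, retained, anticorr, float(cutoffs[best_idx]), best_genes, "ok"
    )


@dataclass
class ConsensusResult:
    """Subsampled consensus matrix and the derived cluster assignment."""

    consensus: pd.DataFrame
    co_sampled: pd.DataFrame
    k: int
    assignments: pd.Series
    n_iterations: int
    subsample_fraction: float
    linkage: np.ndarray = field(repr=False, default=None)


def consensus_cluster(
    expr: pd.DataFrame,
    k_range=3,
    n_iterations: int = N_ITERATIONS_DEFAULT,
    subsample_fraction: float = SUBSAMPLE_FRACTION_DEFAULT,
    seed: int | None = None,
) -> dict[int, ConsensusResult]:
    """Consensus clustering by repeated sample subsampling.

    Each iteration draws ``ceil(fraction * n)`` samples without
    replacement, clusters them (1 - Pearson, average linkage) and cuts into
    k clusters; consensus(i, j) is the fraction of co-sampled iterations in
    which i and j co-clustered.  The final assignment clusters
    ``1 - consensus`` by average linkage cut at k.  Returns one result per
    k in ``k_range`` (an int is treated as a single k); use
    :func:`cdf_delta_area` to compare k values.
    """
    if seed is None:
        raise ValueError("a seed is required for consensus clustering")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must be in (0, 1]")
    ks = [int(k_range)] if np.isscalar(k_range) else [int(k) for k in k_range]
    n = expr.shape[1]
    m = int(np.ceil(subsample_fraction * n))
    if m <= max(ks):
        raise ValueError("subsample keeps too few samples for the largest k")
    sample_ids = list(expr.columns)

    # Pearson correlation of a column pair is unaffected by which other
    # columns are in the subsample, so the full distance matrix is computed
    # once (on gene-centered expression) and subset per iteration.
    full_dist = pearson_distance(center_genes(expr)).to_numpy()

    rng = np.random.Generator(np.random.PCG64(seed))
    draws = [rng.choice(n, size=m, replace=False) for _ in range(n_iterations)]

    results: dict[int, ConsensusResult] = {}
    for k in ks:
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for idx in draws:
            sub = full_dist[np.ix_(idx, idx)]
            labels = fcluster(average(squareform(sub, checks=False)),
                              k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_sample[np.ix_(idx, idx)] += 1
            co_cluster[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            consensus = np.where(co_sample > 0, co_cluster / co_sample, 0.0)
        cons_df = pd.DataFrame(consensus, index=sample_ids, columns=sample_ids)
        link = average(squareform(1.0 - consensus, checks=False))
        assign = fcluster(link, k, criterion="maxclust")
        results[k] = ConsensusResult(
            cons_df,
            pd.DataFrame(co_sample.astype(int), index=sample_ids,
                         columns=sample_ids),
            k,
            pd.Series(assign, index=sample_ids, name="cluster"),
            n_iterations, subsample_fraction, link,
        )
    return results


def consensus_cdf(result: ConsensusResult, grid: int = 101) -> np.ndarray:
    """Empirical CDF of the off-diagonal consensus entries on [0, 1]."""
    c = result.consensus.to_numpy()
    vals = c[np.triu_indices_from(c, k=1)]
    xs = np.linspace(0.0, 1.0, grid)
    return np.array([(vals <= x).mean() for x in xs])


def cdf_delta_area(results: dict[int, ConsensusResult]) -> dict[int, float]:
    """Relative increase in area under the consensus CDF per k.

    The standard summary for choosing k: the area under the consensus CDF
    grows as k increases; the relative gain flattens once k exceeds the
    true cluster count.
    """
    ks = sorted(results)
    xs = np.linspace(0.0, 1.0, 101)
    areas = {k: float(np.trapezoid(consensus_cdf(results[k]), xs)) for k in ks}
    delta: dict[int, float] = {}
    prev = None
    for k in ks:
        if prev is None:
            delta[k] = areas[k]
        else:
            delta[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] else 0.0
        prev = k
    return delta
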