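"""Synthetic data generation for the nodal-signature pipeline.

No public accession exists for the motivating FFPE RNA-seq cohort, so every
downstream stage is exercised on simulated data with the statistical
structure the analysis assumes: negative-binomial counts with gene-wise
dispersions and FFPE-like dropout, three latent sample clusters driven by
block-structured differentially expressed gene modules, node-status labels
mirroring the cohort composition (16 N+ / 12 N-), clinical covariates drawn
at the published table frequencies, and overlap-merged FASTQ reads for the
read-splitting utility.

All randomness flows from a single seed; each stage draws from a
deterministically spawned child stream, so outputs are byte-identical for a
fixed seed regardless of which stages run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NODE_NEG, NODE_POS, CountMatrix
from . import datasets

_BASES = np.array(list("ACGT"))

# logistic decay of dropout probability with log2 mean expression
DROPOUT_MIDPOINT_LOG2 = 5.0   # 32 counts: half the low-expression dropout rate
DROPOUT_SHAPE = 1.0


@dataclass
class SimConfig:
    """Parameters of the count-matrix simulator.

    The defaults emulate the motivating cohort: three expression clusters of
    7/10/11 samples with node-positive compositions 7/0, 6/4 and 3/8
    (16 N+ / 12 N- in total), ~18k genes, and one upregulated DE gene module
    per cluster.

    Attributes
    ----------
    n_genes
        Number of genes simulated.
    cluster_labels
        Mapping cluster name -> (n_Npos, n_Nneg); cluster sizes are the sums.
    de_block_sizes
        Genes per DE module; module ``i`` is upregulated in the ``i``-th
        cluster (cycling if more modules than clusters).
    log2_fc
        Per-module log2 fold change (scalar broadcast to all modules).
    baseline_mean_log, baseline_sd_log
        Natural-log mean/SD of the log-normal gene abundance distribution.
    dispersion_median, dispersion_shape
        Gene-wise NB dispersion phi (variance mu + phi mu^2) drawn log-normal
        with this median and log-SD.
    libsize_range
        Library sizes drawn log-uniform over this range; the default
        straddles the 5M QC inclusion threshold.
    zero_inflation
        Dropout probability for a vanishingly expressed gene.  Dropout is
        independent Bernoulli per entry with probability decaying
        logistically in log2 mean expression (midpoint 32 counts), so
        degradation zeros concentrate in low-abundance genes — a highly
        expressed gene essentially never drops to zero, as in real
        libraries.
    de_min_abundance_quantile
        DE-module genes draw their baseline abundance from above this
        quantile of the abundance distribution, so a module gene is
        actually expressed and can carry its stated effect (a gene at
        near-zero counts is not informative at any nominal fold change).
    """

    n_genes: int = 18000
    cluster_labels: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"A": (7, 0), "B": (6, 4), "C": (3, 8)}
    )
    de_block_sizes: list[int] = field(default_factory=lambda: [400, 400, 300])
    log2_fc: float | list[float] = 2.0
    baseline_mean_log: float = 3.0
    baseline_sd_log: float = 1.6
    dispersion_median: float = 0.15
    dispersion_shape: float = 0.5
    libsize_range: tuple[int, int] = (5_000_000, 20_000_000)
    zero_inflation: float = 0.05
    de_min_abundance_quantile: float = 0.5
    seed: int = 0

    @property
    def cluster_sizes(self) -> dict[str, int]:
        return {k: p + n for k, (p, n) in self.cluster_labels.items()}

    @property
    def n_samples(self) -> int:
        return sum(self.cluster_sizes.values())

    @property
    def module_log2_fc(self) -> list[float]:
        if np.isscalar(self.log2_fc):
            return [float(self.log2_fc)] * len(self.de_block_sizes)
        fcs = list(self.log2_fc)
        if len(fcs) != len(self.de_block_sizes):
            raise ValueError("log2_fc list length must match de_block_sizes")
        return [float(f) for f in fcs]

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.cluster_labels:
            raise ValueError("at least one cluster required")
        for name, (npos, nneg) in self.cluster_labels.items():
            if npos < 0 or nneg < 0 or npos + nneg <= 0:
                raise ValueError(f"cluster {name!r} has invalid sample counts")
        if any(b <= 0 for b in self.de_block_sizes):
            raise ValueError("de_block_sizes must be positive")
        if sum(self.de_block_sizes) > self.n_genes:
            raise ValueError("DE modules exceed gene count")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid libsize_range")
        if self.dispersion_shape <= 0 or self.dispersion_median <= 0:
            raise ValueError("dispersion parameters must be positive")
        if not 0.0 <= self.de_min_abundance_quantile < 1.0:
            raise ValueError("de_min_abundance_quantile must be in [0, 1)")
        self.module_log2_fc  # raises on length mismatch


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and matching sample metadata.

    Counts are negative binomial with library-size offsets: gene ``g`` in
    sample ``s`` has mean ``q_g * R_s * 2^fc`` where ``q_g`` is a normalized
    log-normal relative abundance, ``R_s`` the target library size and ``fc``
    the module effect when the sample's cluster carries the module.  A
    ``zero_inflation`` fraction of entries is then zeroed at random.
    """
    config.validate()
    (rng_ab, rng_disp, rng_lib, rng_counts,
     rng_drop, _rng_meta) = _streams(config.seed, 6)

    clusters = list(config.cluster_labels)
    sample_cluster: list[str] = []
    node_status: list[str] = []
    for name in clusters:
        npos, nneg = config.cluster_labels[name]
        sample_cluster += [name] * (npos + nneg)
        node_status += [NODE_POS] * npos + [NODE_NEG] * nneg
    n_samples = len(sample_cluster)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    abundance = rng_ab.lognormal(
        config.baseline_mean_log, config.baseline_sd_log, config.n_genes
    )
    n_module = sum(config.de_block_sizes)
    if n_module and config.de_min_abundance_quantile > 0:
        # module genes are expressed: truncated log-normal above the quantile
        q0 = config.de_min_abundance_quantile
        u = rng_ab.uniform(q0, 1.0, n_module)
        abundance[:n_module] = np.exp(
            config.baseline_mean_log
            + config.baseline_sd_log * stats.norm.ppf(u)
        )
    rel = abundance / abundance.sum()
    phi = rng_disp.lognormal(
        np.log(config.dispersion_median), config.dispersion_shape, config.n_genes
    )
    lo, hi = config.libsize_range
    libsizes = np.exp(rng_lib.uniform(np.log(lo), np.log(hi), n_samples))

    # log2 fold-change matrix: module i upregulated in cluster i (cyclic)
    lfc = np.zeros((config.n_genes, n_samples))
    start = 0
    module_genes: dict[str, list[str]] = {c: [] for c in clusters}
    for i, (size, fc) in enumerate(zip(config.de_block_sizes, config.module_log2_fc)):
        target = clusters[i % len(clusters)]
        cols = [j for j, c in enumerate(sample_cluster) if c == target]
        lfc[start:start + size, cols] = fc
        module_genes[target] += gene_ids[start:start + size]
        start += size

    mu = rel[:, None] * libsizes[None, :] * np.exp2(lfc)
    n_param = 1.0 / phi[:, None]
    p_param = n_param / (n_param + mu)
    counts = rng_counts.negative_binomial(
        np.broadcast_to(n_param, mu.shape), p_param
    )
    if config.zero_inflation > 0:
        p_drop = config.zero_inflation / (
            1.0 + np.exp(DROPOUT_SHAPE * (np.log2(mu + 1e-12)
                                          - DROPOUT_MIDPOINT_LOG2))
        )
        drop = rng_drop.random(mu.shape) < p_drop
        counts = np.where(drop, 0, counts)

    matrix = CountMatrix(counts.astype(np.int64), gene_ids, sample_ids)
    meta = pd.DataFrame(
        {"node_status": node_status, "true_cluster": sample_cluster},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta.attrs["module_genes"] = module_genes
    return matrix, meta


def simulate_clinical_table(
    seed: int,
    n_per_arm: tuple[int, int] = (datasets.N_NEG, datasets.N_POS),
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Draw per-sample clinico-pathological covariates.

    Categorical levels are sampled per arm with the published cohort cell
    frequencies; tumor size is normal with the published per-arm mean/SD
    (46.8/22.5 mm in N-, 50.1/25.9 mm in N+).  ``n_per_arm`` is
    (n N-, n N+); an arm may be 0 for a degenerate single-arm table.
    """
    rng = _streams(seed, 1)[0]
    n_neg, n_pos = n_per_arm
    if n_neg < 0 or n_pos < 0 or n_neg + n_pos == 0:
        raise ValueError("need at least one sample")
    status = [NODE_NEG] * n_neg + [NODE_POS] * n_pos
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(len(status))]
    if len(sample_ids) != len(status):
        raise ValueError("sample_ids length does not match arm sizes")

    columns: dict[str, list] = {"node_status": status}
    for cov, table in datasets.CATEGORICAL_TABLES.items():
        levels = list(table)
        p_neg = np.array([table[l][0] for l in levels], dtype=float)
        p_pos = np.array([table[l][1] for l in levels], dtype=float)
        p_neg /= p_neg.sum()
        p_pos /= p_pos.sum()
        draws = [levels[i] for i in rng.choice(len(levels), n_neg, p=p_neg)]
        draws += [levels[i] for i in rng.choice(len(levels), n_pos, p=p_pos)]
        columns[cov] = draws
    for cov, ((m_neg, s_neg), (m_pos, s_pos)) in datasets.CONTINUOUS_SUMMARIES.items():
        vals = np.concatenate([
            rng.normal(m_neg, s_neg, n_neg), rng.normal(m_pos, s_pos, n_pos)
        ])
        columns[cov] = np.round(vals, 1)
    return pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))


def simulate_merged_reads(
    path, n_pairs: int, read_len: int = 75, overlap: int = 50, seed: int = 0
) -> int:
    """Write a single-end FASTQ of overlap-merged fragments.

    Each record emulates a paired-end fragment whose R1/R2 mates of length
    ``read_len`` overlapped by ``overlap`` bases and were merged into one
    sequence of length ``2*read_len - overlap``.  The merged length is
    recorded in the read name so splitting utilities can be checked against
    ground truth.  Returns the number of records written.
    """
    if not 0 < overlap < read_len:
        raise ValueError("require 0 < overlap < read_len")
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    rng = _streams(seed, 1)[0]
    merged_len = 2 * read_len - overlap
    with open(path, "w") as fh:
        for i in range(n_pairs):
            seq = "".join(_BASES[rng.integers(0, 4, merged_len)])
            qual = "".join(chr(33 + q) for q in rng.integers(20, 41, merged_len))
            fh.write(f"@frag{i:06d}:mergedlen={merged_len}:overlap={overlap}\n")
            fh.write(f"{seq}\n+\n{qual}\n")
    return n_pairs
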