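"""Core data containers shared across the pipeline.

The central object is :class:`CountMatrix`, a genes x samples integer count
table with per-sample library sizes, read and written as plain TSV (gzip
accepted on read by extension).  Sample metadata travels alongside as a
pandas DataFrame indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NODE_POS = "Npos"
NODE_NEG = "Nneg"


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with library sizes.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape (n_genes, n_samples).
    gene_ids, sample_ids
        Unique identifiers for rows / columns.
    aligned_totals
        Optional per-sample aligned-read totals overriding the column sums
        for QC purposes (the matrix itself only sees post-alignment counts).
    """

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    aligned_totals: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (genes x samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValueError("sample_ids length does not match counts columns")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.aligned_totals is not None:
            self.aligned_totals = np.asarray(self.aligned_totals)
            if self.aligned_totals.shape != (self.counts.shape[1],):
                raise ValueError("aligned_totals length does not match samples")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums (counted fragments)."""
        return self.counts.sum(axis=0)

    def zero_gene_counts(self) -> np.ndarray:
        """Number of genes with zero counts, per sample."""
        return (self.counts == 0).sum(axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        at = None if self.aligned_totals is None else self.aligned_totals[idx]
        return CountMatrix(
            self.counts[:, idx], list(self.gene_ids), list(sample_ids), at
        )

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return CountMatrix(
            self.counts[idx, :], list(gene_ids), list(self.sample_ids),
            self.aligned_totals,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   aligned_totals: np.ndarray | None = None) -> "CountMatrix":
        return cls(
            frame.to_numpy(), list(frame.index.astype(str)),
            list(frame.columns.astype(str)), aligned_totals,
        )

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV indexed by ``sample_id``."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")
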