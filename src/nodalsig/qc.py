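"""Sample-inclusion quality control for FFPE RNA-seq count matrices.

An imbalanced number of zero-count genes between samples biases
normalization, so a sample enters the analysis if and only if its total
aligned count exceeds 5 million fragments AND it has fewer than 3,500
zero-count genes.  Both thresholds are strict inequalities.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .containers import CountMatrix

MIN_ALIGNED_DEFAULT = 5_000_000
MAX_ZERO_GENES_DEFAULT = 3_500


def sample_qc(
    counts: CountMatrix,
    min_aligned: int = MIN_ALIGNED_DEFAULT,
    max_zero_genes: int = MAX_ZERO_GENES_DEFAULT,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Filter samples by aligned totals and zero-gene counts.

    ``aligned_total`` is the sample's column sum unless the matrix carries
    an explicit ``aligned_totals`` override.  Inclusion requires
    ``aligned_total > min_aligned`` and ``zero_gene_count < max_zero_genes``
    (both strict).  Returns the filtered matrix and a per-sample report with
    one row per input sample.
    """
    if counts.n_samples == 0:
        raise ValueError("empty count matrix")
    aligned = (counts.aligned_totals if counts.aligned_totals is not None
               else counts.library_sizes)
    zeros = counts.zero_gene_counts()

    rows = []
    for i, sid in enumerate(counts.sample_ids):
        reasons = []
        if not aligned[i] > min_aligned:
            reasons.append(f"aligned_total {int(aligned[i])} <= {min_aligned}")
        if not zeros[i] < max_zero_genes:
            reasons.append(f"zero_gene_count {int(zeros[i])} >= {max_zero_genes}")
        rows.append({
            "sample_id": sid,
            "aligned_total": int(aligned[i]),
            "zero_gene_count": int(zeros[i]),
            "included": not reasons,
            "reason": "; ".join(reasons) if reasons else "pass",
        })
    report = pd.DataFrame(rows).set_index("sample_id")

    kept = [s for s, ok in zip(counts.sample_ids, report["included"]) if ok]
    if not kept:
        warnings.warn("all samples excluded by QC", stacklevel=2)
        filtered = CountMatrix(
            counts.counts[:, :0], list(counts.gene_ids), [],
            None if counts.aligned_totals is None else counts.aligned_totals[:0],
        )
    else:
        filtered = counts.subset_samples(kept)
    return filtered, report
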