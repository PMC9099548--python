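"""voom-weighted moderated-t differential expression.

The count matrix is transformed to log2 counts-per-million (logCPM) with
0.5 / 1 offsets; a mean-variance trend fitted by lowess on the square-root
residual standard deviations assigns each observation a precision weight
(inverse fourth power of the predicted sqrt-SD at its fitted log-count);
per-gene weighted least squares then estimates the group log2 fold change,
and an empirical-Bayes prior estimated by moment matching on the log
residual variances moderates the t statistics.  p-values are adjusted by
the Benjamini-Hochberg step-up procedure and genes are called
differentially expressed at FDR < 0.05 with fold change >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .containers import CountMatrix

FDR_DEFAULT = 0.05
MIN_FC_DEFAULT = 2.0
LOWESS_SPAN = 0.5

_TREND_FLOOR = 1e-4  # sqrt-SD floor so weights stay finite on degenerate genes


def logcpm(counts: CountMatrix) -> np.ndarray:
    """log2 counts per million: log2((c + 0.5) / (R + 1) * 1e6)."""
    lib = counts.library_sizes.astype(float)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    return np.log2((counts.counts + 0.5) / (lib + 1.0) * 1e6)


def _group_design(groups) -> tuple[np.ndarray, list]:
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups).tolist())
    design = np.column_stack([(groups == g).astype(float) for g in levels])
    return design, levels


@dataclass
class VoomResult:
    """logCPM matrix, observation weights and the fitted mean-variance trend."""

    logcpm: np.ndarray
    weights: np.ndarray
    trend_x: np.ndarray  # average log2 count
    trend_y: np.ndarray  # sqrt residual SD
    gene_ids: list[str]
    sample_ids: list[str]
    library_sizes: np.ndarray = field(repr=False, default=None)


def voom_weights(counts: CountMatrix, groups) -> VoomResult:
    """Fit the mean-variance trend and compute observation-level weights.

    A group-means model is fitted to each gene's logCPM; lowess (span 0.5)
    regresses the square root of the residual SD on the average log2 count;
    each observation's weight is the trend value at its fitted log2 count
    raised to the power -4, with trend evaluation clamped to the fitted
    range.
    """
    design, levels = _group_design(groups)
    n_group = design.sum(axis=0)
    if np.any(n_group < 2):
        raise ValueError("every group needs at least 2 samples")
    y = logcpm(counts)
    n_genes, n_samples = y.shape
    df_resid = n_samples - len(levels)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    # group means per gene: (genes x groups)
    means = (y @ design) / n_group
    fitted = means @ design.T
    resid = y - fitted
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)

    lib = counts.library_sizes.astype(float)
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    smoothed = sm_lowess(sy, sx, frac=LOWESS_SPAN, return_sorted=True)
    trend_x, trend_y = smoothed[:, 0], np.maximum(smoothed[:, 1], _TREND_FLOOR)

    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_logcount, trend_x, trend_y)  # clamps at range ends
    weights = pred ** -4
    return VoomResult(y, weights, trend_x, trend_y,
                      list(counts.gene_ids), list(counts.sample_ids), lib)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) by moment matching on log variances.

    Works on ``z = log(s^2)``, whose distribution under a scaled-chi-square
    model has known digamma/trigamma moments.  Returns ``d0 = inf`` when the
    observed spread of ``z`` does not exceed the chi-square sampling spread
    (near-constant variances).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.exp(np.mean(np.log(s2[ok])))) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


@dataclass
class DGEResult:
    """Per-gene differential expression table plus the shared EB prior.

    ``table`` columns: log2fc, t, df_total, p_raw, p_adj, is_de, s2
    (residual variance), s2_post (moderated variance); index = gene id.
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    fdr: float = FDR_DEFAULT
    min_fc: float = MIN_FC_DEFAULT
    contrast: tuple[str, str] | None = None


def fit_moderated_t(
    voom: VoomResult,
    groups,
    contrast: tuple[str, str] | None = None,
    fdr: float = FDR_DEFAULT,
    min_fc: float = MIN_FC_DEFAULT,
    prior: bool = True,
) -> DGEResult:
    """Two-group moderated t test on voom-weighted logCPM.

    ``contrast = (reference, treatment)``: log2fc is treatment minus
    reference (defaults to the two group labels in sorted order).  Per gene,
    weighted least squares gives the group means and residual variance
    ``s_g^2``; the prior ``(d0, s0^2)`` is estimated across genes and the
    moderated variance is ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)``; t has
    ``d0 + d_g`` degrees of freedom.  Set ``prior=False`` to disable
    moderation (ordinary weighted t).
    """
    groups = np.asarray(groups)
    design, levels = _group_design(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if len(groups) < 3:
        raise ValueError("need at least 3 samples")
    if contrast is None:
        contrast = (levels[0], levels[1])
    ref, trt = contrast
    if set(contrast) != set(levels):
        raise ValueError(f"contrast {contrast} does not match groups {levels}")

    y, w = voom.logcpm, voom.weights
    mask_ref = groups == ref
    mask_trt = groups == trt
    sw_ref = w[:, mask_ref].sum(axis=1)
    sw_trt = w[:, mask_trt].sum(axis=1)
    mean_ref = (w[:, mask_ref] * y[:, mask_ref]).sum(axis=1) / sw_ref
    mean_trt = (w[:, mask_trt] * y[:, mask_trt]).sum(axis=1) / sw_trt
    log2fc = mean_trt - mean_ref

    fitted = np.where(mask_trt[None, :], mean_trt[:, None], mean_ref[:, None])
    df_resid = y.shape[1] - 2
    s2 = (w * (y - fitted) ** 2).sum(axis=1) / df_resid
    stdev_unscaled = np.sqrt(1.0 / sw_ref + 1.0 / sw_trt)

    if prior:
        d0, s02 = estimate_prior(s2, df_resid)
    else:
        d0, s02 = 0.0, 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / (np.sqrt(s2_post) * stdev_unscaled)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_adj = bh_adjust(p)
    is_de = (p_adj < fdr) & (np.abs(log2fc) >= np.log2(min_fc))

    table = pd.DataFrame(
        {
            "log2fc": log2fc, "t": t,
            "df_total": np.full(len(t), df_total),
            "p_raw": p, "p_adj": p_adj, "is_de": is_de,
            "s2": s2, "s2_post": s2_post,
        },
        index=pd.Index(voom.gene_ids, name="gene_id"),
    )
    return DGEResult(table, d0, s02, fdr, min_fc, (ref, trt))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1, and restore the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_de(
    dge: DGEResult, fdr: float = FDR_DEFAULT, min_fc: float = MIN_FC_DEFAULT
) -> dict[str, list[str]]:
    """Genes passing FDR and fold-change thresholds, split by direction.

    Returns ``{"up": [...], "down": [...]}`` with up/down meaning higher /
    lower in the treatment group of the fitted contrast.
    """
    tab = dge.table
    called = (tab["p_adj"] < fdr) & (tab["log2fc"].abs() >= np.log2(min_fc))
    up = tab.index[called & (tab["log2fc"] > 0)].tolist()
    down = tab.index[called & (tab["log2fc"] < 0)].tolist()
    return {"up": up, "down": down}


def run_dge(
    counts: CountMatrix, groups,
    contrast: tuple[str, str] | None = None,
    fdr: float = FDR_DEFAULT, min_fc: float = MIN_FC_DEFAULT,
) -> DGEResult:
    """Convenience chain: remove all-zero genes, voom, moderated t."""
    keep = counts.counts.sum(axis=1) > 0
    gene_ids = [g for g, k in zip(counts.gene_ids, keep) if k]
    filtered = counts.subset_genes(gene_ids)
    voom = voom_weights(filtered, groups)
    return fit_moderated_t(voom, groups, contrast, fdr, min_fc)
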