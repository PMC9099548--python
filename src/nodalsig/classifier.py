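"""Nearest-shrunken-centroids signature discovery and MSE centroid validation.

The shrunken-centroids classifier standardizes each gene's class-centroid
offset, soft-thresholds it by Delta (performing embedded gene selection)
and classifies by the discriminant score against the shrunken centroids.
Cross-validation over a Delta grid selects the signature size; ties are
broken toward larger Delta (smaller signature).

The centroid validator is an independent check of a fixed gene signature:
group centroids are the mean expression of each signature gene over the
training samples of that group; a validation sample is assigned to the
group minimizing the mean squared error (MSE) to its centroid, with
significance assessed by randomizing the MSE (permuting the sample's
expression values across the signature genes) and a confusion matrix
summarizing accuracy, sensitivity and specificity (node-positive as the
positive class).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import NODE_POS

B_RANDOMIZATIONS_DEFAULT = 1000
N_FOLDS_DEFAULT = 10


# ---------------------------------------------------------------------------
# nearest shrunken centroids
# ---------------------------------------------------------------------------

@dataclass
class NSCModel:
    """Fitted shrunken-centroids state (genes x classes where applicable)."""

    gene_ids: list[str]
    classes: list[str]
    overall_centroid: np.ndarray          # x_bar_i
    class_centroids: np.ndarray           # x_bar_ik, genes x classes
    shrunken_centroids: np.ndarray        # x_bar'_ik
    pooled_sd: np.ndarray                 # s_i
    fudge: float                          # s_0, median of s_i
    m_k: np.ndarray                       # sqrt(1/n_k - 1/n)
    delta: float
    d_ik: np.ndarray
    d_shrunk: np.ndarray                  # d'_ik
    priors: np.ndarray

    @property
    def surviving_genes(self) -> list[str]:
        keep = np.any(self.d_shrunk != 0.0, axis=1)
        return [g for g, k in zip(self.gene_ids, keep) if k]

    def discriminant(self, expr: pd.DataFrame) -> pd.DataFrame:
        """delta_k(x) = sum_i (x_i - x_bar'_ik)^2 / (s_i+s_0)^2 - 2 log pi_k."""
        x = expr.loc[self.gene_ids].to_numpy()
        denom = (self.pooled_sd + self.fudge) ** 2
        scores = np.empty((x.shape[1], len(self.classes)))
        for k in range(len(self.classes)):
            diff = x - self.shrunken_centroids[:, [k]]
            scores[:, k] = (diff ** 2 / denom[:, None]).sum(axis=0)
        scores -= 2.0 * np.log(self.priors)[None, :]
        return pd.DataFrame(scores, index=expr.columns, columns=self.classes)

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        scores = self.discriminant(expr)
        # ties resolve to the first class in sorted order (argmin convention)
        return pd.Series(
            [self.classes[i] for i in np.argmin(scores.to_numpy(), axis=1)],
            index=expr.columns, name="predicted",
        )


@dataclass
class _NSCStats:
    """Delta-independent sufficient statistics of a training set."""

    gene_ids: list[str]
    classes: list[str]
    overall: np.ndarray
    class_centroids: np.ndarray
    pooled_sd: np.ndarray
    s0: float
    m_k: np.ndarray
    d_ik: np.ndarray
    priors: np.ndarray

    def at_delta(self, delta: float) -> NSCModel:
        if delta < 0:
            raise ValueError("delta must be >= 0")
        denom = self.m_k[None, :] * (self.pooled_sd + self.s0)[:, None]
        d_shrunk = np.sign(self.d_ik) * np.maximum(np.abs(self.d_ik) - delta, 0.0)
        shrunken = self.overall[:, None] + denom * d_shrunk
        return NSCModel(
            self.gene_ids, self.classes, self.overall, self.class_centroids,
            shrunken, self.pooled_sd, self.s0, self.m_k, float(delta),
            self.d_ik, d_shrunk, self.priors,
        )


def _nsc_stats(expr: pd.DataFrame, labels, priors: str) -> _NSCStats:
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    classes = sorted(labels.unique().tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n = expr.shape[1]
    x = expr.to_numpy()

    n_k = np.array([(labels == c).sum() for c in classes])
    if np.any(n_k < 2):
        raise ValueError("every class needs at least 2 samples")

    class_centroids = np.column_stack(
        [x[:, (labels == c).to_numpy()].mean(axis=1) for c in classes]
    )
    overall = x.mean(axis=1)
    within_ss = np.zeros(x.shape[0])
    for j, c in enumerate(classes):
        sub = x[:, (labels == c).to_numpy()]
        within_ss += ((sub - class_centroids[:, [j]]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    m_k = np.sqrt(1.0 / n_k - 1.0 / n)

    denom = m_k[None, :] * (pooled_sd + s0)[:, None]
    d_ik = (class_centroids - overall[:, None]) / denom

    if priors == "frequency":
        pi = n_k / n
    elif priors == "uniform":
        pi = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError("priors must be 'frequency' or 'uniform'")
    return _NSCStats(list(expr.index), classes, overall, class_centroids,
                     pooled_sd, s0, m_k, d_ik, pi)


def fit_shrunken_centroids(
    expr: pd.DataFrame, labels, delta: float, priors: str = "frequency"
) -> NSCModel:
    """Fit nearest shrunken centroids at threshold ``delta``.

    ``d_ik = (x_bar_ik - x_bar_i) / (m_k * (s_i + s_0))`` is soft-thresholded
    to ``d'_ik = sign(d_ik) * max(|d_ik| - delta, 0)`` and the centroids are
    reconstructed as ``x_bar_i + m_k * (s_i + s_0) * d'_ik``.  Genes with any
    nonzero ``d'_ik`` survive the shrinkage and form the signature.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    return _nsc_stats(expr, labels, priors).at_delta(delta)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(labels: pd.Series, n_folds: int, seed: int) -> list[np.ndarray]:
    """Index folds stratified by class; shuffled deterministically."""
    rng = np.random.Generator(np.random.PCG64(seed))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in sorted(labels.unique()):
        idx = np.flatnonzero((labels == c).to_numpy())
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.array(sorted(f), dtype=int) for f in folds if f]


def _binary_rates(
    true: pd.Series, pred: pd.Series, positive: str
) -> tuple[float, float, float, pd.DataFrame]:
    classes = sorted(set(true) | set(pred))
    confusion = pd.crosstab(
        pd.Categorical(true, categories=classes),
        pd.Categorical(pred, categories=classes), dropna=False,
    )
    confusion.index.name, confusion.columns.name = "true", "predicted"
    accuracy = float((true.to_numpy() == pred.to_numpy()).mean())
    sens = spec = float("nan")
    if positive in classes and len(classes) == 2:
        neg = next(c for c in classes if c != positive)
        tp = int(((true == positive) & (pred == positive)).sum())
        fn = int(((true == positive) & (pred == neg)).sum())
        tn = int(((true == neg) & (pred == neg)).sum())
        fp = int(((true == neg) & (pred == positive)).sum())
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
    return accuracy, sens, spec, confusion


@dataclass
class CVResult:
    """Cross-validated Delta selection and the resulting signature."""

    cv_table: pd.DataFrame        # delta, n_genes, cv_errors, cv_error_rate
    chosen_delta: float
    signature_genes: list[str]
    model: NSCModel
    predictions: pd.Series        # out-of-fold predictions at chosen delta
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: pd.DataFrame
    n_folds: int
    seed: int


def cross_validate_nsc(
    expr: pd.DataFrame, labels, delta_grid,
    n_folds: int = N_FOLDS_DEFAULT, seed: int = 0,
    positive_label: str = NODE_POS, priors: str = "frequency",
) -> CVResult:
    """Select Delta by stratified cross-validation and refit the signature.

    Per Delta, the CV misclassification count is accumulated over folds;
    the chosen Delta minimizes CV error with ties broken toward larger
    Delta (smaller signature).  When the smallest class has fewer members
    than ``n_folds``, folds fall back to leave-one-out.  The signature is
    the surviving gene set of the model refit on all samples at the chosen
    Delta; accuracy / sensitivity / specificity are cross-validated
    (out-of-fold) with ``positive_label`` as the positive class.
    """
    delta_grid = sorted(float(d) for d in delta_grid)
    if not delta_grid:
        raise ValueError("empty delta grid")
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    min_class = labels.value_counts().min()
    if min_class < n_folds:
        n_folds = int(expr.shape[1])  # leave-one-out
        folds = [np.array([i]) for i in range(expr.shape[1])]
    else:
        folds = _stratified_folds(labels, n_folds, seed)

    n = expr.shape[1]
    errors = np.zeros(len(delta_grid), dtype=int)
    oof = {d: pd.Series(index=expr.columns, dtype=object) for d in delta_grid}
    for fold in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[fold] = False
        tr_expr, va_expr = expr.iloc[:, train_mask], expr.iloc[:, fold]
        stats = _nsc_stats(tr_expr, labels.iloc[train_mask], priors)
        for i, d in enumerate(delta_grid):
            pred = stats.at_delta(d).predict(va_expr)
            errors[i] += int((pred.to_numpy() != labels.iloc[fold].to_numpy()).sum())
            oof[d].iloc[fold] = pred.to_numpy()

    best_err = errors.min()
    chosen = max(d for d, e in zip(delta_grid, errors) if e == best_err)
    full_stats = _nsc_stats(expr, labels, priors)
    full = full_stats.at_delta(chosen)
    preds = oof[chosen]
    acc, sens, spec, confusion = _binary_rates(labels, preds, positive_label)

    sizes = [len(full_stats.at_delta(d).surviving_genes) for d in delta_grid]
    table = pd.DataFrame({
        "delta": delta_grid, "n_genes": sizes,
        "cv_errors": errors, "cv_error_rate": errors / n,
    })
    return CVResult(table, chosen, full.surviving_genes, full, preds,
                    acc, sens, spec, confusion, n_folds, seed)


# ---------------------------------------------------------------------------
# MSE centroid validator
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Per-sample MSE scores, randomization p-values and summary rates."""

    scores: pd.DataFrame          # samples x groups MSE + predicted, p, tie
    confusion: pd.DataFrame
    accuracy: float
    sensitivity: float
    specificity: float
    signature_genes: list[str] = field(repr=False, default=None)


def centroid_validator(
    train_expr: pd.DataFrame, train_labels,
    valid_expr: pd.DataFrame, valid_labels,
    signature_genes: list[str],
    n_randomizations: int = B_RANDOMIZATIONS_DEFAULT,
    seed: int = 0, exhaustive: bool = False,
    positive_label: str = NODE_POS,
) -> ValidationReport:
    """Validate a fixed gene signature by MSE distance to group centroids.

    For each validation sample the score against group k is the mean over
    signature genes of (value - centroid_k)^2; the predicted group is the
    argmin (ties to the first group in sorted order, flagged).  The
    randomization p-value is the fraction of null scores <= the observed
    best score, the null built by permuting the sample's expression values
    across the signature genes and recomputing the best MSE; sampled nulls
    use the add-one estimate (r+1)/(B+1), ``exhaustive=True`` enumerates
    all permutations (small signatures only).
    """
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise ValueError("empty signature")
    for frame, name in ((train_expr, "training"), (valid_expr, "validation")):
        missing = [g for g in signature_genes if g not in frame.index]
        if missing:
            raise ValueError(f"signature genes missing from {name} data: "
                             f"{missing[:5]}")
    train_labels = pd.Series(np.asarray(train_labels), index=train_expr.columns)
    valid_labels = pd.Series(np.asarray(valid_labels), index=valid_expr.columns)
    groups = sorted(train_labels.unique().tolist())
    unknown = set(valid_labels) - set(groups)
    if unknown:
        raise ValueError(f"validation labels not seen in training: {unknown}")

    tr = train_expr.loc[signature_genes]
    va = valid_expr.loc[signature_genes].to_numpy()
    centroids = np.column_stack(
        [tr.loc[:, (train_labels == g).to_numpy()].mean(axis=1) for g in groups]
    )  # genes x groups

    n_valid = va.shape[1]
    mse = np.empty((n_valid, len(groups)))
    for k in range(len(groups)):
        mse[:, k] = ((va - centroids[:, [k]]) ** 2).mean(axis=0)
    pred_idx = np.argmin(mse, axis=1)
    best = mse[np.arange(n_valid), pred_idx]
    is_tie = (mse == best[:, None]).sum(axis=1) > 1

    rng = np.random.Generator(np.random.PCG64(seed))
    p_vals = np.empty(n_valid)
    n_genes = len(signature_genes)
    for j in range(n_valid):
        v = va[:, j]
        if exhaustive:
            n_perm = math.factorial(n_genes)
            r = 0
            for perm in itertools.permutations(range(n_genes)):
                null_best = min(
                    float(((v[list(perm)] - centroids[:, k]) ** 2).mean())
                    for k in range(len(groups))
                )
                if null_best <= best[j]:
                    r += 1
            p_vals[j] = r / n_perm
        else:
            r = 0
            for _ in range(n_randomizations):
                vp = rng.permutation(v)
                null_best = ((vp[:, None] - centroids) ** 2).mean(axis=0).min()
                if null_best <= best[j]:
                    r += 1
            p_vals[j] = (r + 1) / (n_randomizations + 1)

    predicted = pd.Series([groups[i] for i in pred_idx],
                          index=valid_expr.columns, name="predicted")
    acc, sens, spec, confusion = _binary_rates(valid_labels, predicted,
                                               positive_label)
    scores = pd.DataFrame(mse, index=valid_expr.columns,
                          columns=[f"mse_{g}" for g in groups])
    scores["predicted"] = predicted
    scores["expected"] = valid_labels
    scores["randomization_p"] = p_vals
    scores["tie"] = is_tie
    return ValidationReport(scores, confusion, acc, sens, spec, signature_genes)
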