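"""Count-matrix handling: low-count filtering, log-CPM, precision weights, PCA.

The expression scale throughout the package is log2 counts-per-million
(log-CPM) with a half-count prior, and hypothesis tests downstream use
per-observation precision weights derived from the empirical mean-variance
trend, so that the heteroskedasticity of count data is absorbed into a
weighted linear model rather than a count likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CONDITIONS

logger = logging.getLogger(__name__)

#: total-count threshold below which a transcript is considered unexpressed
#: (on average less than one read per replicate in a nine-sample design)
DEFAULT_MIN_TOTAL = 9

#: pseudo-count added to every count before the log-CPM transform
DEFAULT_PRIOR_COUNT = 0.5

#: lowess span for the mean-variance trend
DEFAULT_TREND_SPAN = 0.5


@dataclass
class CountMatrix:
    """Integer counts (transcripts x samples) with a sample -> condition design."""

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate transcript IDs")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        bad = sorted(set(self.design.loc[list(self.counts.columns)]) - set(CONDITIONS))
        if bad:
            raise ValueError(f"unknown conditions: {bad}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def conditions(self) -> pd.Series:
        """Condition of each sample, in column order."""
        return self.design.loc[list(self.counts.columns)]


@dataclass
class ExpressionMatrix:
    """log2-CPM values on the same axes as the source counts, plus optional weights."""

    values: pd.DataFrame
    design: pd.Series
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite expression values")
        if self.weights is not None:
            w = self.weights.to_numpy()
            if not (np.isfinite(w).all() and (w > 0).all()):
                raise ValueError("weights must be strictly positive and finite")

    def conditions(self) -> pd.Series:
        return self.design.loc[list(self.values.columns)]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray = field(repr=False)


def filter_low_counts(counts: CountMatrix, min_total: int = DEFAULT_MIN_TOTAL) -> CountMatrix:
    """Drop transcripts whose total count across all samples is below ``min_total``.

    A transcript is retained iff its row sum is >= ``min_total``; with the
    default of 9 in a nine-sample design this keeps transcripts averaging at
    least one read per sample. Row order of the survivors is preserved and
    the operation is idempotent.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = counts.counts.sum(axis=1) >= min_total
    removed = int((~keep).sum())
    logger.info("low-count filter: removed %d of %d transcripts (min_total=%d)",
                removed, len(keep), min_total)
    return CountMatrix(counts.counts.loc[keep], counts.design)


def normalize_logcpm(counts: CountMatrix, prior_count: float = DEFAULT_PRIOR_COUNT) -> ExpressionMatrix:
    """log2 counts-per-million: ``log2((count + prior) / (libsize + 1) * 1e6)``.

    Library size is the column sum of raw counts. The half-count prior keeps
    zeros finite; the +1 offset on the library size keeps the transform
    defined for the prior-augmented counts.
    """
    lib = counts.counts.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s), cannot normalize: {zero}")
    logger.info("library sizes: %s", dict(lib))
    vals = np.log2((counts.counts + prior_count).div(lib + 1.0, axis=1) * 1e6)
    return ExpressionMatrix(vals, counts.design)


def _condition_design_matrix(conditions: pd.Series) -> np.ndarray:
    """Intercept + KD + OE indicator columns (WT is the reference level)."""
    n = len(conditions)
    X = np.zeros((n, 3))
    X[:, 0] = 1.0
    X[:, 1] = (conditions.values == "KD").astype(float)
    X[:, 2] = (conditions.values == "OE").astype(float)
    return X


def _groupwise_fit(values: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Unweighted per-row least squares; returns (fitted, residual sd, residual df)."""
    beta, *_ = np.linalg.lstsq(X, values.T, rcond=None)
    fitted = (X @ beta).T
    df = values.shape[1] - np.linalg.matrix_rank(X)
    if df < 1:
        raise ValueError("no residual degrees of freedom in the design")
    resid = values - fitted
    sd = np.sqrt((resid**2).sum(axis=1) / df)
    return fitted, sd, df


def compute_precision_weights(
    expr: ExpressionMatrix, span: float = DEFAULT_TREND_SPAN
) -> ExpressionMatrix:
    """Mean-variance precision weights for the weighted linear model.

    Each transcript is fitted by ordinary least squares on the condition
    design; a lowess trend of sqrt(residual sd) on mean log-CPM is then
    evaluated at every fitted value, and each observation receives weight
    ``trend(fitted)**-4`` — the reciprocal of the predicted variance of the
    observation. Values outside the fitted abundance range use the boundary
    value of the trend.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    vals = np.ascontiguousarray(expr.values.to_numpy())
    X = _condition_design_matrix(expr.conditions())
    fitted, sd, _df = _groupwise_fit(vals, X)
    mean_log = vals.mean(axis=1)

    sqrt_sd = np.sqrt(sd)
    use = sd > 0  # flat transcripts contribute nothing to the trend
    if use.sum() < 2:
        raise ValueError("not enough variable transcripts to fit a trend")
    smoothed = lowess(sqrt_sd[use], mean_log[use], frac=span, return_sorted=True)
    grid_x, grid_y = smoothed[:, 0], smoothed[:, 1]
    # np.interp clamps to the boundary values outside the fitted range
    pred = np.interp(fitted, grid_x, grid_y)
    pred = np.maximum(pred, 1e-4)
    weights = pred**-4.0
    wdf = pd.DataFrame(weights, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(expr.values, expr.design, wdf)


def run_pca(expr: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of samples on transcript-centered log-CPM."""
    from sklearn.decomposition import PCA

    vals = expr.values.to_numpy()
    n_samples = vals.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components is None:
        n_components = min(n_samples - 1, vals.shape[0])
    centered = (vals - vals.mean(axis=1, keepdims=True)).T  # samples x transcripts
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centered)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=expr.values.columns, columns=cols),
        variance_fraction=pca.explained_variance_ratio_,
    )
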