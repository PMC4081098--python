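"""Moderated differential expression and directional target selection.

Per-transcript weighted least squares on the three-condition design, with
empirical-Bayes shrinkage of the residual variances toward a pooled prior:
the posterior variance is (d0*s0^2 + d*s^2)/(d0 + d), where the prior
degrees of freedom d0 and prior variance s0^2 are estimated by matching
moments of the log residual variances (a scaled chi-square log-moment fit
via digamma/trigamma relations). Moderated t statistics per contrast and a
moderated F across both contrasts use d0 + d degrees of freedom.

Selection then follows a three-step rule set keyed to how a direct miRNA
target must respond to the perturbations:

* significant set: BH-adjusted p of the moderated F < alpha;
* loose directional set: additionally down under over-expression OR up
  under knockdown (either arm may fail in a whole-embryo experiment);
* stringent set: down under OE AND up under KD AND present in the
  sequence-based prediction list — the seed set for correlation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .annotation import PredictionSet
from .counts import ExpressionMatrix, _condition_design_matrix

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class DEResult:
    """Per-transcript moderated statistics for the KD/WT and OE/WT contrasts."""

    table: pd.DataFrame  # logFC_KD, logFC_OE, t_KD, t_OE, F, p, adj_p
    prior_df: float  # d0
    prior_var: float  # s0^2
    residual_df: float

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SelectionSets:
    """Nested directional selections; stringent ⊆ loose ⊆ significant."""

    significant: frozenset[str]  # adj p < alpha
    directional: frozenset[str]  # + (OE down OR KD up)
    stringent: frozenset[str]  # + (OE down AND KD up AND predicted)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * x:
            return x_new
        x = x_new
    return x


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to residual variances.

    On the log scale, log(s^2) for a scaled chi-square variable has known
    mean and variance in terms of digamma/trigamma; subtracting the
    sampling component of the variance leaves the prior's contribution,
    inverted through the trigamma function. Zero variances are excluded
    from the fit (but still get moderated downstream). Returns
    ``(d0, s0_sq)``; ``d0`` may be ``inf`` when the variances are no more
    dispersed than sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def posterior_variance(s2: np.ndarray, df: float, d0: float, s0_sq: float) -> np.ndarray:
    """Shrunken variance (d0*s0^2 + df*s^2) / (d0 + df); prior-only at d0 = inf."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


def fit_moderated_model(
    expr: ExpressionMatrix,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DEResult:
    """Fit the weighted model and moderate the variances.

    ``prior_df``/``prior_var`` override the estimated hyperparameters
    (``prior_df=0`` gives the ordinary unmoderated t; ``prior_df=inf``
    pins every posterior variance at the prior).
    """
    if expr.weights is None:
        raise ValueError("precision weights not computed; run compute_precision_weights first")
    conds = expr.conditions()
    present = set(conds)
    if present != {"WT", "KD", "OE"}:
        raise ValueError(f"need all three conditions, got {sorted(present)}")

    Y = np.ascontiguousarray(expr.values.to_numpy())
    W = np.ascontiguousarray(expr.weights.to_numpy())
    X = _condition_design_matrix(conds)
    n, p = X.shape
    d = n - p
    if d < 1:
        raise ValueError("no residual degrees of freedom")

    # per-transcript WLS, vectorized over transcripts
    XtW = W[:, None, :] * X.T[None, :, :]  # G x p x n
    A = XtW @ X  # G x p x p
    b = np.einsum("gpn,gn->gp", XtW, Y)
    try:
        beta = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("non-estimable contrast: singular design for some transcript") from exc

    resid = Y - beta @ X.T
    s2 = np.einsum("gn,gn->g", W * resid, resid) / d

    if prior_df is None or prior_var is None:
        d0_est, s0_est = estimate_prior(s2, d)
        d0 = d0_est if prior_df is None else prior_df
        s0_sq = s0_est if prior_var is None else prior_var
    else:
        d0, s0_sq = prior_df, prior_var
    s2_post = posterior_variance(s2, d, d0, s0_sq)
    df_total = np.inf if np.isinf(d0) else d + d0

    # contrasts: beta[1] = KD - WT, beta[2] = OE - WT
    v_kd = Ainv[:, 1, 1]
    v_oe = Ainv[:, 2, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_kd = beta[:, 1] / np.sqrt(s2_post * v_kd)
        t_oe = beta[:, 2] / np.sqrt(s2_post * v_oe)

    # moderated F over both contrasts jointly
    C = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    bc = beta @ C.T  # G x 2
    V = C @ Ainv @ C.T  # G x 2 x 2
    Vinv = np.linalg.inv(V)
    quad = np.einsum("gi,gij,gj->g", bc, Vinv, bc)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = quad / (2.0 * s2_post)
    if np.isinf(df_total):
        p_val = stats.chi2.sf(2.0 * F, 2)
    else:
        p_val = stats.f.sf(F, 2, df_total)

    table = pd.DataFrame(
        {
            "logFC_KD": beta[:, 1],
            "logFC_OE": beta[:, 2],
            "t_KD": t_kd,
            "t_OE": t_oe,
            "F": F,
            "p": p_val,
            "adj_p": bh_adjust(p_val),
        },
        index=expr.values.index,
    )
    logger.info("moderated fit: G=%d, d0=%.3g, s0^2=%.3g", len(table), d0, s0_sq)
    return DEResult(table=table, prior_df=float(d0), prior_var=float(s0_sq), residual_df=float(d))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def select_de(de: DEResult, alpha: float = DEFAULT_ALPHA) -> frozenset[str]:
    """Transcripts with BH-adjusted moderated-F p strictly below alpha."""
    t = de.table
    return frozenset(t.index[t["adj_p"] < alpha])


def select_directional(significant: frozenset[str], de: DEResult) -> frozenset[str]:
    """Loose directional rule: within the significant set, OE down OR KD up."""
    t = de.table.loc[sorted(significant)]
    keep = (t["logFC_OE"] < 0) | (t["logFC_KD"] > 0)
    return frozenset(t.index[keep])


def select_stringent(
    significant: frozenset[str], de: DEResult, predictions: PredictionSet
) -> frozenset[str]:
    """Stringent rule: OE down AND KD up AND sequence-predicted.

    This set seeds the correlation analysis; an empty result is legal but
    makes seeding impossible, so it is logged as a warning.
    """
    t = de.table.loc[sorted(significant)]
    keep = (t["logFC_OE"] < 0) & (t["logFC_KD"] > 0) & t.index.isin(predictions.ids)
    out = frozenset(t.index[keep])
    if not out:
        logger.warning("stringent selection is empty; correlation seeding impossible")
    return out


def selection_sets(
    de: DEResult, predictions: PredictionSet, alpha: float = DEFAULT_ALPHA
) -> SelectionSets:
    """All three nested selections in one pass."""
    sig = select_de(de, alpha)
    return SelectionSets(
        significant=sig,
        directional=select_directional(sig, de),
        stringent=select_stringent(sig, de, predictions),
    )


def de_table_with_sets(de: DEResult, sets: SelectionSets) -> pd.DataFrame:
    """Flat results table with selection membership flags, for TSV export."""
    t = de.table.copy()
    t["in_significant"] = t.index.isin(sets.significant)
    t["in_directional"] = t.index.isin(sets.directional)
    t["in_stringent"] = t.index.isin(sets.stringent)
    return t
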