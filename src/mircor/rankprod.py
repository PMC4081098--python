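"""Correlation-to-seed scoring with Rank Product and permutation pfp.

The premise: transcripts directly targeted by the same miRNA are
co-expressed, so a stringent seed set of high-confidence targets can pull
in additional targets by correlation alone — including targets whose fold
changes are too small for significance-based selection. Every expressed
transcript is Pearson-correlated with every seed transcript across all
nine samples pooled over the three conditions (replicate-level variation
in perturbation strength is signal here, not noise).

Scoring uses the Rank Product: within each seed column, transcripts are
ranked by correlation (rank 1 = most correlated, ties averaged) and a
transcript's RP is the geometric mean of its per-column ranks. Small RP
means consistently top-ranked against the whole seed set. Significance is
a permutation-based percentage of false prediction (pfp): each seed column
is independently permuted across transcripts, RP recomputed, and the
expected number of null RPs at or below an observed RP, divided by the
observed RP's ascending rank, estimates the false-prediction rate at that
cutoff — an FDR-like quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .de import DEResult

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 100
DEFAULT_PFP_MAX = 0.01


@dataclass
class CorrelationMatrix:
    """Pearson correlations of every transcript (rows) against the seed set."""

    values: pd.DataFrame  # G x K
    zero_variance_ids: frozenset[str] = frozenset()

    @property
    def seed_ids(self) -> list[str]:
        return list(self.values.columns)

    def seed_block(self) -> pd.DataFrame:
        """The K x K seed-vs-seed submatrix."""
        return self.values.loc[list(self.values.columns)]


@dataclass
class RankProductResult:
    """Per-transcript RP, mean correlation, rank and (once estimated) pfp."""

    table: pd.DataFrame  # mean_corr, RP, rank; pfp filled by estimate_pfp
    n_perm: int | None = None


@dataclass
class CohesionReport:
    """How tightly the seed set co-expresses."""

    mean_offdiagonal: float
    dendrogram_order: list[str] = field(default_factory=list)


def correlate_to_seeds(expr, seed_ids) -> CorrelationMatrix:
    """Pearson-correlate all transcripts with the seed transcripts.

    Correlations are computed on normalized log expression across all
    samples jointly, pooling the three conditions. Transcripts with zero
    variance have no defined correlation; their rows are set to 0 and
    flagged rather than dropped, keeping row alignment with the DE table.
    """
    seed_ids = sorted(seed_ids)
    if len(seed_ids) < 2:
        raise ValueError("need at least 2 seed transcripts")
    missing = [s for s in seed_ids if s not in expr.values.index]
    if missing:
        raise ValueError(f"seed transcripts absent from expression matrix: {missing[:5]}")
    vals = np.ascontiguousarray(expr.values.to_numpy())
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")

    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    flat = norms == 0
    safe = np.where(flat, 1.0, norms)
    Z = centered / safe[:, None]

    seed_pos = expr.values.index.get_indexer(seed_ids)
    corr = Z @ Z[seed_pos].T
    corr[flat, :] = 0.0
    corr[:, np.asarray(flat)[seed_pos]] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    # a non-degenerate seed correlates exactly 1 with itself
    for j, pos in enumerate(seed_pos):
        if not flat[pos]:
            corr[pos, j] = 1.0

    zero_ids = frozenset(expr.values.index[flat])
    if zero_ids:
        logger.warning("%d zero-variance transcripts set to correlation 0", len(zero_ids))
    return CorrelationMatrix(
        values=pd.DataFrame(corr, index=expr.values.index, columns=seed_ids),
        zero_variance_ids=zero_ids,
    )


def seed_cohesion(seed_block: pd.DataFrame) -> CohesionReport:
    """Mean off-diagonal correlation and average-linkage dendrogram order.

    Clustering uses distance 1 - correlation. The report is diagnostic
    only: the pipeline proceeds with the full seed set regardless.
    """
    K = seed_block.shape[0]
    if K < 2 or seed_block.shape[1] != K:
        raise ValueError("seed block must be square with K >= 2")
    m = seed_block.to_numpy()
    off = m[~np.eye(K, dtype=bool)]
    dist = 1.0 - (m + m.T) / 2.0  # symmetrize against float round-off
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    return CohesionReport(
        mean_offdiagonal=float(off.mean()),
        dendrogram_order=[seed_block.index[i] for i in order],
    )


def _rp_from_corr(corr: np.ndarray) -> np.ndarray:
    """RP = geometric mean over columns of descending ranks (ties averaged)."""
    ranks = rankdata(-corr, axis=0, method="average")
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product(corr: CorrelationMatrix) -> RankProductResult:
    """Score each transcript by Rank Product over the seed columns."""
    m = corr.values.to_numpy()
    rp = _rp_from_corr(m)
    table = pd.DataFrame(
        {
            "mean_corr": m.mean(axis=1),
            "RP": rp,
            "rank": rankdata(rp, method="average"),
        },
        index=corr.values.index,
    )
    return RankProductResult(table=table)


def estimate_pfp(
    corr: CorrelationMatrix,
    result: RankProductResult,
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
) -> RankProductResult:
    """Permutation-based percentage of false prediction for each RP.

    For each permutation, every seed column is independently shuffled
    across transcripts and RP recomputed. For transcript g,

        E_g  = #{null RP values <= RP_g, pooled} / n_perm
        pfp_g = E_g / rank(RP_g ascending)

    Deterministic under ``rng_seed``. Resolution is 1/(n_perm * G); a
    warning is logged when n_perm cannot resolve pfp at the default cutoff.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    m = corr.values.to_numpy()
    G, K = m.shape
    if n_perm * G < 1.0 / DEFAULT_PFP_MAX:
        logger.warning("n_perm=%d gives pfp resolution coarser than %.3g",
                       n_perm, DEFAULT_PFP_MAX)
    rng = np.random.default_rng(rng_seed)
    rp_obs = result.table["RP"].to_numpy()
    order = np.argsort(rp_obs, kind="mergesort")
    sorted_obs = rp_obs[order]

    # count null RPs <= each observed RP, pooled over permutations
    counts = np.zeros(G, dtype=np.int64)
    perm = np.empty_like(m)
    for _ in range(n_perm):
        for k in range(K):
            perm[:, k] = m[rng.permutation(G), k]
        rp_null = np.sort(_rp_from_corr(perm))
        counts += np.searchsorted(rp_null, sorted_obs, side="right")

    e_g = counts / n_perm
    pfp_sorted = e_g / rankdata(sorted_obs, method="average")
    pfp = np.empty(G)
    pfp[order] = pfp_sorted

    table = result.table.copy()
    table["pfp"] = pfp
    return RankProductResult(table=table, n_perm=n_perm)


def select_correlated(
    result: RankProductResult,
    pfp_max: float = DEFAULT_PFP_MAX,
    require_directional: DEResult | None = None,
) -> frozenset[str]:
    """Correlation-selected target set: mean_corr > 0 (strict) and pfp < pfp_max.

    ``require_directional`` optionally adds the loose directional
    fold-change filter (OE down OR KD up) on top of the correlation rule;
    the default applies the two-condition rule only.
    """
    t = result.table
    if "pfp" not in t.columns:
        raise ValueError("pfp not estimated; run estimate_pfp first")
    keep = (t["mean_corr"] > 0) & (t["pfp"] < pfp_max)
    if require_directional is not None:
        d = require_directional.table.reindex(t.index)
        keep &= (d["logFC_OE"] < 0) | (d["logFC_KD"] > 0)
    return frozenset(t.index[keep])


def threshold_sweep(
    result: RankProductResult,
    de: DEResult,
    grid=None,
) -> pd.DataFrame:
    """Expected-direction fractions as the mean-correlation threshold rises.

    For each threshold, among transcripts with mean_corr >= threshold:
    the count, the fraction with logFC_OE < 0 and the fraction with
    logFC_KD > 0. Empty strata report NaN fractions. As the threshold
    increases the surviving transcripts should behave increasingly like
    true targets, first in the OE arm and only at the highest correlations
    in the KD arm as well.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    t = result.table
    d = de.table.reindex(t.index)
    rows = []
    for thr in grid:
        mask = t["mean_corr"] >= thr
        n = int(mask.sum())
        if n == 0:
            rows.append((thr, 0, np.nan, np.nan))
            continue
        sub = d.loc[mask]
        rows.append((
            thr,
            n,
            float((sub["logFC_OE"] < 0).mean()),
            float((sub["logFC_KD"] > 0).mean()),
        ))
    return pd.DataFrame(rows, columns=["threshold", "n_above", "frac_oe_down", "frac_kd_up"])
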